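"""TST and RRKM rates, state counting, path degeneracy, Eckart tunneling."""

import itertools

import numpy as np
import pytest

from mechkit.constants import C_CM, KT_CM_PER_K, R_KCAL, thermal_energy_cm
from mechkit.kinetics import (
    beyer_swinehart,
    eckart_correction,
    network_rates,
    path_degeneracy,
    rrkm_rate,
    tst_rate,
)
from mechkit.network import (
    NetworkValidationError,
    TransitionStateRecord,
    Well,
    network_from_dict,
)


def brute_force_count(freqs, E_max):
    """Enumerate all harmonic states with sum(n_k nu_k) <= E_max."""
    energies = [0.0]
    for nu in freqs:
        new = []
        for e in energies:
            n = 0
            while e + n * nu <= E_max:
                new.append(e + n * nu)
                n += 1
        energies = new
    return sorted(energies)


class TestPathDegeneracy:
    @pytest.mark.parametrize(
        "m, m_ts, expected", [(1, 2, 2.0), (1, 1, 1.0), (2, 1, 0.5)]
    )
    def test_optical_isomer_ratio(self, m, m_ts, expected):
        assert path_degeneracy(m, m_ts) == pytest.approx(expected)

    def test_symmetry_numbers_compose(self):
        assert path_degeneracy(1, 1, symm_reactant=6, symm_ts=2) == pytest.approx(3.0)

    @pytest.mark.parametrize("bad", [(0, 1), (1, 0), (-2, 1)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            path_degeneracy(*bad)


class TestTST:
    def test_zero_barrier_gives_kbt_over_h(self):
        k = tst_rate(0.0, 298.15)
        assert k.value == pytest.approx(6.212e12, rel=1e-3)
        assert k.units == "s^-1"

    def test_linear_in_sigma(self):
        k1 = tst_rate(5.0, 400.0, sigma=1.0).value
        k2 = tst_rate(5.0, 400.0, sigma=2.0).value
        assert k2 == pytest.approx(2.0 * k1, rel=1e-12)

    def test_decade_identity(self):
        T = 298.15
        dG = R_KCAL * T * np.log(10.0)
        assert tst_rate(dG, T).value == pytest.approx(
            tst_rate(0.0, T).value / 10.0, rel=1e-12
        )

    def test_monotone_in_temperature(self):
        ks = [tst_rate(10.0, T).value for T in (300, 400, 500, 800)]
        assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_bimolecular_standard_state_factor(self):
        import scipy.constants as sc

        T = 298.15
        k0 = tst_rate(3.0, T, delta_n=0).value
        k1 = tst_rate(3.0, T, delta_n=1)
        expected_vol = sc.R * T / 1e5 * 1e6 / sc.N_A  # cm^3 per molecule at 1 bar
        assert k1.value == pytest.approx(k0 * expected_vol, rel=1e-12)
        assert "cm^3" in k1.units

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            tst_rate(0.0, -10.0)


class TestBeyerSwinehart:
    def test_single_oscillator_worked_value(self):
        # levels 0, 100, 200, 300 below 350
        sc = beyer_swinehart([100.0], 350.0, grain=10.0)
        assert sc.sum_of_states(350.0) == 4

    def test_two_oscillators_worked_value(self):
        # pairs (n1, n2) with 100(n1+n2) <= 250: six states
        sc = beyer_swinehart([100.0, 100.0], 250.0, grain=10.0)
        assert sc.sum_of_states(250.0) == 6

    def test_ground_state_only(self):
        for freqs in ([100.0], [70.0, 110.0], [63.0, 127.0, 251.0]):
            assert beyer_swinehart(freqs, 0.0, grain=1.0).sum_of_states(0.0) == 1

    @pytest.mark.parametrize(
        "freqs",
        [
            [100.0],
            [100.0, 100.0],
            [70.0, 110.0],
            [63.0, 127.0, 251.0],
            [100.0, 150.0, 300.0, 450.0],
            [333.0, 777.0, 1234.0, 2500.0],
        ],
    )
    def test_matches_brute_force_enumeration(self, freqs):
        """Direct count equals explicit state enumeration (grain 1 cm^-1,
        integer frequencies, up to 5000 cm^-1)."""
        E = 5000.0
        sc = beyer_swinehart(freqs, E, grain=1.0)
        states = brute_force_count(freqs, E)
        for probe in (0.0, 500.0, 1234.0, 2500.0, 5000.0):
            expected = sum(1 for e in states if e <= probe)
            assert sc.sum_of_states(probe) == expected

    @pytest.mark.parametrize("grain", [1.0, 10.0])
    def test_grain_multiples_exact(self, grain):
        freqs = [100.0, 150.0, 300.0, 450.0]
        E = 5000.0
        sc = beyer_swinehart(freqs, E, grain=grain)
        states = brute_force_count(freqs, E)
        assert sc.sum_of_states(E) == len(states)

    def test_cumulative_nondecreasing_and_consistent(self):
        sc = beyer_swinehart([80.0, 215.0, 642.0], 4000.0, grain=10.0)
        W = sc.W
        assert np.all(np.diff(W) >= 0)
        assert np.allclose(W, np.cumsum(sc.rho) * sc.grain)
        assert W[0] == 1

    def test_halving_grain_small_change_at_high_energy(self):
        freqs = [90.0, 210.0, 455.0, 1200.0]
        E = 5000.0
        w10 = beyer_swinehart(freqs, E, grain=10.0).sum_of_states(E)
        w5 = beyer_swinehart(freqs, E, grain=5.0).sum_of_states(E)
        assert abs(w10 - w5) / w5 < 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            beyer_swinehart([], 100.0)
        with pytest.raises(ValueError):
            beyer_swinehart([100.0], -1.0)
        with pytest.raises(ValueError):
            beyer_swinehart([-5.0], 100.0)


class TestRRKM:
    def _toy(self, barrier=10.0):
        well = Well(label="A", energy=0.0, freqs=[500.0, 1000.0, 1500.0])
        ts = TransitionStateRecord(
            label="TS", energy=barrier, freqs=[450.0, 900.0],
            connects=("A", "B"),
        )
        return well, ts

    def test_below_threshold_closed_channel(self):
        well, ts = self._toy(barrier=50.0)
        k = rrkm_rate(well, ts, E_total=40.0)
        assert k.value == 0.0

    def test_inaccessible_well_rejected(self):
        well = Well(label="A", energy=30.0, freqs=[500.0])
        ts = TransitionStateRecord(
            label="TS", energy=40.0, freqs=[450.0], connects=("A", "B")
        )
        with pytest.raises(ValueError, match="inaccessible"):
            rrkm_rate(well, ts, E_total=20.0)

    def test_linear_in_sigma(self):
        well, ts = self._toy()
        k1 = rrkm_rate(well, ts, 40.0, sigma=1.0).value
        k2 = rrkm_rate(well, ts, 40.0, sigma=2.0).value
        assert k2 == pytest.approx(2.0 * k1, rel=1e-12)

    def test_zero_barrier_equal_freqs_matches_enumeration(self):
        """With identical well/TS frequencies and no barrier,
        k = W(E)/(h rho(E)); cross-check against brute-force counts."""
        freqs = [200.0, 400.0]
        grain = 10.0
        well = Well(label="A", energy=0.0, freqs=freqs)
        ts = TransitionStateRecord(
            label="TS", energy=0.0, freqs=freqs, connects=("A", "B")
        )
        E_cm = 3405.0  # sits in a bin that contains a harmonic level
        E_kcal = E_cm / 349.755
        k = rrkm_rate(well, ts, E_kcal, sigma=1.0, grain=grain).value
        states = brute_force_count(freqs, E_cm + grain)
        b = int(E_cm // grain)
        W = sum(1 for e in states if e // grain <= b)
        in_bin = sum(1 for e in states if int(e // grain) == b)
        rho = in_bin / grain
        assert k == pytest.approx(W * C_CM / rho, rel=1e-9)

    def test_rate_grows_with_energy(self):
        well, ts = self._toy(barrier=20.0)
        ks = [rrkm_rate(well, ts, E).value for E in (25.0, 40.0, 60.0, 90.0)]
        assert all(b > a for a, b in zip(ks, ks[1:]))


class TestEckart:
    def test_classical_limit_no_imaginary_mode(self):
        assert eckart_correction(10.0, 10.0, 0.0, 300.0) == 1.0

    def test_approaches_one_for_small_imaginary_frequency(self):
        kappa = eckart_correction(10.0, 10.0, 20.0, 300.0)
        assert kappa == pytest.approx(1.0, abs=5e-4)

    def test_decreases_with_temperature(self):
        kappas = [eckart_correction(12.0, 10.0, 800.0, T) for T in (250, 400, 700, 1500)]
        assert all(b < a for a, b in zip(kappas, kappas[1:]))
        assert all(k >= 1.0 - 1e-9 for k in kappas)

    def test_wigner_limit_symmetric_barrier(self):
        """High, wide symmetric barrier: kappa -> 1 + (h c nu / k_B T)^2 / 24."""
        for T, nu in ((300.0, 100.0), (1000.0, 100.0), (500.0, 200.0)):
            kappa = eckart_correction(15.0, 15.0, nu, T)
            u = nu / thermal_energy_cm(T)
            wigner = 1.0 + u * u / 24.0
            assert abs(kappa - wigner) / kappa < 0.01

    def test_substantial_tunneling_for_heavy_barrier(self):
        kappa = eckart_correction(10.0, 8.0, 1500.0, 300.0)
        assert kappa > 5.0

    def test_nonpositive_barrier_rejected(self):
        with pytest.raises(ValueError):
            eckart_correction(-1.0, 5.0, 1000.0, 300.0)


class TestNetworkSchema:
    def _base(self):
        return {
            "reference": "A",
            "wells": [
                {"label": "A", "energy_kcal": 0.0, "freqs_cm": [100.0]},
                {"label": "B", "energy_kcal": -5.0, "freqs_cm": [100.0], "sink": True},
            ],
            "transition_states": [
                {"label": "TS", "energy_kcal": 10.0, "freqs_cm": [90.0],
                 "connects": ["A", "B"]}
            ],
        }

    def test_valid_roundtrip(self, tmp_path):
        from mechkit.network import load_network

        net = network_from_dict(self._base())
        p = tmp_path / "net.json"
        net.save(p)
        back = load_network(p)
        assert set(back.wells) == {"A", "B"}
        assert back.wells["B"].is_product_sink

    def test_unknown_connected_well_rejected(self):
        doc = self._base()
        doc["transition_states"][0]["connects"] = ["A", "Z"]
        with pytest.raises(NetworkValidationError, match="'Z'"):
            network_from_dict(doc)

    def test_missing_field_named(self):
        doc = self._base()
        del doc["wells"][0]["energy_kcal"]
        with pytest.raises(NetworkValidationError, match="energy_kcal"):
            network_from_dict(doc)

    def test_negative_frequency_rejected(self):
        doc = self._base()
        doc["wells"][0]["freqs_cm"] = [-100.0]
        with pytest.raises(NetworkValidationError, match="'A'"):
            network_from_dict(doc)

    def test_network_rates_canonical_and_tunneling(self):
        doc = self._base()
        doc["transition_states"][0]["imag_freq_cm"] = 1200.0
        net = network_from_dict(doc)
        plain = network_rates(net, "canonical", T=300.0)
        corrected = network_rates(net, "canonical", T=300.0, tunneling="eckart")
        edge = ("A", "TS")
        assert corrected[edge] > plain[edge]
        assert ("B", "TS") not in plain  # sinks have no outgoing channels
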