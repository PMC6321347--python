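"""Stochastic master-equation solution, ODE oracle, scans and rate laws."""

import numpy as np
import pytest

import mechkit as mk
from mechkit.kmc import (
    KMCConfig,
    branching_scan,
    fit_reaction_orders,
    ode_mass_action,
    ode_reference,
    reactions_from_network,
    run_kmc,
)
from mechkit.network import Reaction
from mechkit.synthfix import make_toy_network


def config(**kw):
    base = dict(mode="canonical", replicas=2000, t_max=20.0, seed=7,
                initial={"A": 1.0})
    base.update(kw)
    return KMCConfig(**base)


class TestRunKMC:
    def test_two_channel_branching(self):
        net = make_toy_network("two_channel", k1=2.0, k2=1.0)
        res = run_kmc(net, dict(net.explicit_rates), config(replicas=10000))
        p = 2.0 / 3.0
        tol = 3.0 * np.sqrt(p * (1 - p) / 10000)
        assert res.branching["B"] == pytest.approx(p, abs=tol)
        assert sum(res.branching.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_channel_mean_lifetime(self):
        net = make_toy_network("sequential", k1=1.0, k2=1e9)
        # with k2 huge, time to reach the sink ~ Exp(1); estimate the mean
        # from the A population decay on the grid
        res = run_kmc(net, dict(net.explicit_rates),
                      config(replicas=10000, t_max=10.0, n_grid=200))
        # population of A at t=1 should be e^-1 within 3 binomial sigmas
        idx = np.argmin(np.abs(res.times - 1.0))
        expected = np.exp(-res.times[idx])
        tol = 3.0 * np.sqrt(expected * (1 - expected) / 10000)
        assert res.populations["A"][idx] == pytest.approx(expected, abs=tol)

    def test_all_rates_zero(self):
        net = make_toy_network("two_channel", k1=0.0, k2=0.0)
        res = run_kmc(net, {}, config(replicas=100))
        assert res.n_events == 0
        assert np.all(res.populations["A"] == 1.0)

    def test_nonsink_dead_end_warns(self):
        net = make_toy_network("sequential")
        rates = dict(net.explicit_rates)
        del rates[("B", "TS2")]  # strand B without declaring it a sink
        with pytest.warns(UserWarning, match="'B'"):
            run_kmc(net, rates, config(replicas=50))

    def test_fixed_seed_bit_identical(self):
        net = make_toy_network("two_channel")
        r1 = run_kmc(net, dict(net.explicit_rates), config(seed=123))
        r2 = run_kmc(net, dict(net.explicit_rates), config(seed=123))
        assert r1.n_events == r2.n_events
        assert r1.branching == r2.branching
        for sp in r1.populations:
            assert np.array_equal(r1.populations[sp], r2.populations[sp])

    def test_population_conservation(self):
        net = make_toy_network("sequential")
        res = run_kmc(net, dict(net.explicit_rates), config(replicas=500))
        total = sum(res.populations[s] for s in res.populations)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_doubling_replicas_halves_variance(self):
        """Branching estimator variance scales as 1/replicas."""
        net = make_toy_network("two_channel", k1=2.0, k2=1.0)
        rates = dict(net.explicit_rates)

        def estimates(replicas, seeds):
            return [
                run_kmc(net, rates, config(replicas=replicas, seed=s)).branching["B"]
                for s in seeds
            ]

        seeds = range(1000, 1050)
        v_small = np.var(estimates(150, seeds))
        v_large = np.var(estimates(600, [s + 5000 for s in seeds]))
        # fourfold replicas: variance ratio ~ 4; allow wide statistical slack
        assert 1.8 < v_small / v_large < 9.0


class TestODEReference:
    def test_single_exponential(self):
        net = make_toy_network("sequential", k1=1.0, k2=5.0)
        t = np.linspace(0, 5, 30)
        pops = ode_reference(net, dict(net.explicit_rates), {"A": 1.0}, t)
        assert np.allclose(pops["A"], np.exp(-t), atol=1e-10)

    def test_sequential_closed_form(self):
        k = 1.3
        net = make_toy_network("sequential", k1=k, k2=k)
        t = np.linspace(0, 6, 40)
        pops = ode_reference(net, dict(net.explicit_rates), {"A": 1.0}, t)
        assert np.allclose(pops["B"], k * t * np.exp(-k * t), atol=1e-10)

    def test_symmetric_equilibrium(self):
        doc = {
            "reference": "A",
            "wells": [
                {"label": "A", "energy_kcal": 0.0, "freqs_cm": [100.0]},
                {"label": "B", "energy_kcal": 0.0, "freqs_cm": [100.0]},
            ],
            "transition_states": [
                {"label": "TS", "energy_kcal": 10.0, "freqs_cm": [90.0],
                 "connects": ["A", "B"]}
            ],
            "rates": [
                {"from": "A", "ts": "TS", "k_s": 2.0},
                {"from": "B", "ts": "TS", "k_s": 2.0},
            ],
        }
        from mechkit.network import network_from_dict

        net = network_from_dict(doc)
        pops = ode_reference(net, dict(net.explicit_rates), {"A": 1.0}, [50.0])
        assert pops["A"][0] == pytest.approx(0.5, abs=1e-9)

    def test_kmc_agrees_with_ode_on_linear_networks(self):
        """Mean stochastic populations track the deterministic master
        equation within 3 standard errors on a 50-point grid."""
        for kind, kwargs in (
            ("sequential", dict(k1=1.0, k2=1.0)),
            ("sequential", dict(k1=2.0, k2=0.5)),
            ("two_channel", dict(k1=2.0, k2=1.0)),
        ):
            net = make_toy_network(kind, **kwargs)
            rates = dict(net.explicit_rates)
            n_rep = 10000
            cfg = config(replicas=n_rep, t_max=6.0, n_grid=50, seed=11)
            res = run_kmc(net, rates, cfg)
            pops = ode_reference(net, rates, {"A": 1.0}, res.times)
            for sp in net.wells:
                p = pops[sp]
                se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n_rep)
                assert np.all(np.abs(res.populations[sp] - p) <= 3 * se + 1e-9), sp


class TestBranchingScan:
    def _rrkm_net(self):
        return make_toy_network("vcn_like")

    def test_fractions_sum_to_one(self):
        net = self._rrkm_net()
        cfg = config(mode="microcanonical", replicas=400, t_max=1e-6,
                     initial={"R": 1.0})
        table = branching_scan(net, cfg, [110.0, 130.0, 150.0], vary="E")
        frac_cols = [c for c in table.columns if c != "E"]
        assert np.allclose(table[frac_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self):
        net = self._rrkm_net()
        cfg = config(mode="microcanonical", replicas=300, t_max=1e-6,
                     initial={"R": 1.0}, seed=99)
        t1 = branching_scan(net, cfg, [120.0, 140.0], vary="E")
        t2 = branching_scan(net, cfg, [120.0, 140.0], vary="E")
        assert t1.equals(t2)

    def test_lower_barrier_dominates_near_threshold(self):
        """Two RRKM channels from one well: as E approaches the lower
        barrier from above, its branching fraction tends to 1."""
        doc = {
            "reference": "A",
            "wells": [
                {"label": "A", "energy_kcal": 0.0,
                 "freqs_cm": [300.0, 800.0, 1500.0, 2500.0]},
                {"label": "B", "energy_kcal": -10.0, "freqs_cm": [100.0],
                 "sink": True},
                {"label": "C", "energy_kcal": -5.0, "freqs_cm": [100.0],
                 "sink": True},
            ],
            "transition_states": [
                {"label": "TS_low", "energy_kcal": 40.0,
                 "freqs_cm": [280.0, 750.0, 1400.0], "connects": ["A", "B"]},
                {"label": "TS_high", "energy_kcal": 50.0,
                 "freqs_cm": [280.0, 750.0, 1400.0], "connects": ["A", "C"]},
            ],
        }
        from mechkit.network import network_from_dict

        net = network_from_dict(doc)
        cfg = config(mode="microcanonical", replicas=1500, t_max=1.0,
                     initial={"A": 1.0}, seed=5)
        table = branching_scan(net, cfg, [42.0, 60.0, 90.0], vary="E")
        b = table["B"].to_numpy()
        assert b[0] > 0.99  # just above the low barrier: exclusive channel
        assert b[0] > b[1] > b[2]  # high channel opens with energy


class TestReactionOrders:
    def test_elementary_bimolecular(self):
        rxns = [Reaction(["A", "B"], ["P"], 1.0)]
        orders = fit_reaction_orders(
            rxns, {"A": 1.0, "B": 1.0}, [0.25, 0.5, 1, 2, 4], product="P"
        )
        assert orders["A"] == pytest.approx(1.0, abs=0.1)
        assert orders["B"] == pytest.approx(1.0, abs=0.1)

    def test_spectator_species_zero_order(self):
        rxns = [Reaction(["A", "B"], ["P"], 1.0)]
        orders = fit_reaction_orders(
            rxns, {"A": 1.0, "B": 1.0, "X": 1.0}, [0.25, 0.5, 1, 2, 4],
            product="P", vary=["X"],
        )
        assert orders["X"] == pytest.approx(0.0, abs=0.1)

    def test_catalytic_cycle_negative_inhibitor_order(self):
        """Reversible catalyst sequestration by CO gives a negative CO order
        and near-first-order behaviour in alkene and catalyst."""
        net = make_toy_network("catalytic_cycle")
        base = {"cat": 0.01, "CO": 1.0, "H2": 1.0, "alkene": 1.0}
        orders = fit_reaction_orders(
            net.reactions, base, [0.5, 1, 2, 4], product="P"
        )
        assert orders["CO"] < 0.0
        assert orders["alkene"] == pytest.approx(1.0, abs=0.2)
        assert orders["cat"] == pytest.approx(1.0, abs=0.2)
        assert 0.0 <= orders["H2"] < 0.5

    def test_invalid_inputs(self):
        rxns = [Reaction(["A"], ["P"], 1.0)]
        with pytest.raises(ValueError):
            fit_reaction_orders(rxns, {"A": -1.0}, [0.5, 1, 2, 4], product="P")
        with pytest.raises(ValueError):
            fit_reaction_orders(rxns, {"A": 1.0}, [1, 2], product="P")

    def test_mass_action_integrator_sequential(self):
        rxns = [Reaction(["A"], ["B"], 1.0), Reaction(["B"], ["C"], 1.0)]
        t = np.linspace(0, 5, 60)
        pops = ode_mass_action(rxns, {"A": 1.0}, t)
        assert np.allclose(pops["B"], t * np.exp(-t), atol=1e-6)

    def test_reactions_from_first_order_network(self):
        net = make_toy_network("sequential", k1=2.0, k2=3.0)
        rxns = reactions_from_network(net, dict(net.explicit_rates))
        ks = sorted(r.k for r in rxns)
        assert ks == [2.0, 3.0]
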