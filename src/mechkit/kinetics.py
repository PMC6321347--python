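"""Canonical (Eyring TST) and microcanonical (RRKM) rate constants.

Canonical rates follow

    k(T) = sigma * (k_B T / h) * (R T / p0)^dn * exp(-dG_ddag / R T)

with p0 = 1 bar and dn = 1 for bimolecular, 0 for unimolecular steps;
sigma is the reaction-path degeneracy, computed from the optical-isomer
counts of reactant and transition state (sigma = m_TS / m), optionally
combined with rotational symmetry numbers.

Microcanonical rates follow

    k(E) = sigma * W_TS(E - E_TS) / (h * rho(E - E_well))

with the sum of states W at the transition state and the density of states
rho at the reactant, both from a Beyer-Swinehart direct count of harmonic
vibrational levels on an energy grain.  All species energies are
ZPE-inclusive and relative to a common network reference; state counts are
measured from each species' own zero-point level.

An optional asymmetric-Eckart tunneling correction multiplies canonical
rates by the Boltzmann-averaged transmission through a barrier matched to
the forward/reverse barrier heights and the imaginary frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.integrate

from .constants import (
    C_CM,
    H_PLANCK,
    K_B,
    N_A,
    P0_PA,
    R_KCAL,
    kcal_to_cm,
    thermal_energy_cm,
)
from .network import ReactionNetwork, TransitionStateRecord, Well

import scipy.constants as _sc

__all__ = [
    "StateCount",
    "RateCoefficient",
    "path_degeneracy",
    "tst_rate",
    "beyer_swinehart",
    "rrkm_rate",
    "eckart_correction",
    "network_rates",
    "DEFAULT_GRAIN",
]

DEFAULT_GRAIN = 10.0  # cm^-1


@dataclass
class StateCount:
    """Beyer-Swinehart direct count on an energy grain (cm^-1).

    ``counts[b]`` is the number of harmonic states in bin b, ``W[b]`` the
    cumulative sum of states up to and including bin b, ``rho[b]`` the
    density of states (states per cm^-1) in bin b.  Energies are measured
    from the zero-point level, which occupies bin 0 (so W(0) = 1).
    """

    grain: float
    counts: np.ndarray
    E_max: float

    @property
    def W(self) -> np.ndarray:
        return np.cumsum(self.counts)

    @property
    def rho(self) -> np.ndarray:
        return self.counts / self.grain

    def _bin(self, E: float) -> int:
        if E < 0:
            raise ValueError(f"energy must be >= 0, got {E}")
        b = int(np.floor(E / self.grain))
        return min(b, len(self.counts) - 1)

    def sum_of_states(self, E: float) -> float:
        """W(E): number of states at or below energy E (cm^-1)."""
        return float(self.W[self._bin(E)])

    def density_of_states(self, E: float) -> float:
        """rho(E): states per cm^-1 in the bin containing E."""
        return float(self.rho[self._bin(E)])


@dataclass
class RateCoefficient:
    value: float
    mode: Literal["canonical", "microcanonical"]
    units: str = "s^-1"
    edge: tuple[str, str] | None = None
    tunneling: Literal["none", "eckart"] = "none"
    T: float | None = None
    E_total: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"rate must be finite and >= 0, got {self.value}")


def path_degeneracy(
    m_reactant: int,
    m_ts: int,
    symm_reactant: int = 1,
    symm_ts: int = 1,
) -> float:
    """Reaction-path degeneracy sigma = (m_TS/m) * (symm_reactant/symm_TS).

    ``m`` counts optical isomers; with the default symmetry numbers the
    result is the plain optical-isomer ratio.
    """
    for name, v in (
        ("m_reactant", m_reactant),
        ("m_ts", m_ts),
        ("symm_reactant", symm_reactant),
        ("symm_ts", symm_ts),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    return (m_ts / m_reactant) * (symm_reactant / symm_ts)


def tst_rate(
    dG_ddag: float,
    T: float,
    sigma: float = 1.0,
    delta_n: int = 0,
    kappa: float = 1.0,
) -> RateCoefficient:
    """Eyring rate from a free energy of activation (kcal/mol).

    ``delta_n = 0`` gives a unimolecular rate in s^-1; ``delta_n = 1``
    applies the 1-bar standard-state volume factor RT/p0 and reports the
    bimolecular rate in cm^3 molecule^-1 s^-1 (RT/p0 in m^3/mol, converted
    by 1e6 cm^3/m^3 and divided by Avogadro's number).  ``kappa`` is an
    optional tunneling transmission factor.
    """
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    if delta_n not in (0, 1):
        raise ValueError(f"delta_n must be 0 or 1, got {delta_n}")
    k = kappa * sigma * (K_B * T / H_PLANCK) * np.exp(-dG_ddag / (R_KCAL * T))
    units = "s^-1"
    if delta_n == 1:
        vol_cm3_per_molecule = (_sc.R * T / P0_PA) * 1e6 / N_A
        k *= vol_cm3_per_molecule
        units = "cm^3 molecule^-1 s^-1"
    return RateCoefficient(
        value=float(k),
        mode="canonical",
        units=units,
        T=T,
        tunneling="none" if kappa == 1.0 else "eckart",
    )


def beyer_swinehart(
    freqs: list[float], E_max: float, grain: float = DEFAULT_GRAIN
) -> StateCount:
    """Direct count of harmonic vibrational states up to E_max (cm^-1).

    The classic convolution: start from a single ground state in bin 0 and
    fold in each oscillator by adding shifted copies of the running count.
    Energies sum as Sigma n_k nu_k, measured from the zero-point level.
    """
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    if any(f <= 0 for f in freqs):
        raise ValueError("all frequencies must be > 0")
    if grain <= 0:
        raise ValueError(f"grain must be > 0, got {grain}")
    if E_max < 0:
        raise ValueError(f"E_max must be >= 0, got {E_max}")
    n_bins = int(np.floor(E_max / grain)) + 1
    counts = np.zeros(n_bins)
    counts[0] = 1.0
    for nu in freqs:
        r = max(1, int(round(nu / grain)))
        for b in range(r, n_bins):
            counts[b] += counts[b - r]
    return StateCount(grain=grain, counts=counts, E_max=E_max)


def rrkm_rate(
    well: Well,
    ts: TransitionStateRecord,
    E_total: float,
    sigma: float | None = None,
    grain: float = DEFAULT_GRAIN,
) -> RateCoefficient:
    """Microcanonical rate k(E) = sigma * W_TS / (h * rho_well).

    ``E_total`` is the ZPE-inclusive excitation energy (kcal/mol) relative
    to the network reference.  The internal energy available to the well is
    E_total - E_well, the energy above the barrier is E_total - E_TS; both
    are converted to cm^-1 (349.755 cm^-1 per kcal/mol).  A channel below
    threshold has k = 0; a well that is itself inaccessible is an error.
    With rho in states/cm^-1, 1/h is expressed as c in cm/s.
    """
    if sigma is None:
        sigma = path_degeneracy(well.m_opt, ts.m_opt_ts)
    E_w = kcal_to_cm(E_total - well.energy)
    if E_w <= 0:
        raise ValueError(
            f"well {well.label!r} is energetically inaccessible at "
            f"E_total = {E_total} kcal/mol"
        )
    E_ts = kcal_to_cm(E_total - ts.energy)
    if E_ts < 0:
        return RateCoefficient(
            value=0.0, mode="microcanonical",
            edge=(well.label, ts.label), E_total=E_total,
        )
    W = beyer_swinehart(ts.freqs, max(E_ts, grain), grain).sum_of_states(E_ts)
    rho = beyer_swinehart(well.freqs, max(E_w, grain), grain).density_of_states(E_w)
    if rho == 0.0:
        # empty bin at coarse grain: use the nearest occupied lower bin
        sc = beyer_swinehart(well.freqs, max(E_w, grain), grain)
        occupied = np.nonzero(sc.counts)[0]
        rho = float(sc.counts[occupied[occupied * grain <= E_w][-1]] / grain)
    k = sigma * W * C_CM / rho
    return RateCoefficient(
        value=float(k),
        mode="microcanonical",
        edge=(well.label, ts.label),
        E_total=E_total,
    )


def _eckart_transmission(E: float, V1: float, V2: float, nu: float) -> float:
    """Transmission probability through an asymmetric Eckart barrier.

    Energies in cm^-1, E measured from the reactant asymptote; V1/V2 are
    the forward/reverse barrier heights and nu the magnitude of the
    imaginary frequency.  Standard a/b/d parametrization; evaluated with
    exponent shifting so large barriers do not overflow.
    """
    if E <= max(0.0, V1 - V2):
        return 0.0
    alpha1 = 2.0 * np.pi * V1 / nu
    alpha2 = 2.0 * np.pi * V2 / nu
    inv = 1.0 / np.sqrt(alpha1) + 1.0 / np.sqrt(alpha2)
    xi = E / V1
    a2pi = 2.0 * np.sqrt(alpha1 * xi) / inv                  # 2*pi*a
    b2pi = 2.0 * np.sqrt(alpha1 * (xi - 1.0) + alpha2) / inv  # 2*pi*b
    S = a2pi + b2pi
    Dlt = abs(a2pi - b2pi)
    disc = alpha1 * alpha2 - np.pi**2 / 4.0
    # P = [cosh(S) - cosh(Dlt)] / [cosh(S) + cosh(2*pi*d)], shifted by the
    # largest exponent so high barriers do not overflow
    if disc >= 0.0:
        D = 2.0 * np.sqrt(disc)                               # 2*pi*d
        M = max(S, Dlt, D)
        num = np.exp(Dlt - M) + np.exp(-Dlt - M) + np.exp(D - M) + np.exp(-D - M)
        den = np.exp(S - M) + np.exp(-S - M) + np.exp(D - M) + np.exp(-D - M)
    else:
        cosD = 2.0 * np.cos(2.0 * np.sqrt(-disc))             # 2*cosh with d imaginary
        M = max(S, Dlt)
        num = np.exp(Dlt - M) + np.exp(-Dlt - M) + cosD * np.exp(-M)
        den = np.exp(S - M) + np.exp(-S - M) + cosD * np.exp(-M)
    P = 1.0 - num / den
    return float(min(max(P, 0.0), 1.0))


def eckart_correction(
    dE_forward: float,
    dE_reverse: float,
    imag_freq: float,
    T: float,
    rel_tol: float = 1e-6,
) -> float:
    """Thermal transmission coefficient kappa(T) for an Eckart barrier.

    Barriers in kcal/mol (both > 0), imaginary frequency in cm^-1.  The
    transmission probability is averaged over a Boltzmann distribution:

        kappa = integral P(V1 + kT y) e^{-y} dy,   y from -(V1-E_min)/kT

    which equals 1 when P is the classical step function.  kappa -> 1 as
    the imaginary frequency -> 0 (wide barrier) or T -> infinity.
    """
    if dE_forward <= 0 or dE_reverse <= 0:
        raise ValueError("Eckart barriers must be > 0 in both directions")
    if imag_freq < 0:
        raise ValueError("imaginary frequency must be >= 0")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if imag_freq == 0.0:
        return 1.0
    V1 = kcal_to_cm(dE_forward)
    V2 = kcal_to_cm(dE_reverse)
    kT = thermal_energy_cm(T)
    E_min = max(0.0, V1 - V2)
    y0 = (E_min - V1) / kT

    def integrand(y: float) -> float:
        return _eckart_transmission(V1 + kT * y, V1, V2, imag_freq) * np.exp(-y)

    below, _ = scipy.integrate.quad(
        integrand, y0, 0.0, epsrel=rel_tol, limit=400
    )
    above, _ = scipy.integrate.quad(
        integrand, 0.0, 60.0, epsrel=rel_tol, limit=400
    )
    return float(below + above)


def network_rates(
    net: ReactionNetwork,
    mode: Literal["canonical", "microcanonical"],
    T: float | None = None,
    E_total: float | None = None,
    grain: float = DEFAULT_GRAIN,
    tunneling: Literal["none", "eckart"] = "none",
) -> dict[tuple[str, str], float]:
    """First-order rate for every open directed edge (well, ts) of a network.

    Explicit ``rates`` entries in the network take precedence.  Canonical
    rates use dG_ddag = E_TS - E_well (energies standing in for free
    energies when no free-energy table is supplied), with an optional
    Eckart correction where the TS carries an imaginary frequency.
    Microcanonical rates use RRKM at the common total energy; wells lying
    above E_total get no outgoing channels (they are never populated).
    Sinks have no outgoing edges.
    """
    if mode == "canonical" and T is None:
        raise ValueError("canonical mode requires a temperature")
    if mode == "microcanonical" and E_total is None:
        raise ValueError("microcanonical mode requires a total energy")
    rates: dict[tuple[str, str], float] = {}
    for ts in net.transition_states.values():
        for well_label in ts.connects:
            well = net.wells[well_label]
            if well.is_product_sink:
                continue
            edge = (well_label, ts.label)
            if edge in net.explicit_rates:
                rates[edge] = net.explicit_rates[edge]
                continue
            if net.explicit_rates:
                # explicit-rate networks: absent edges are closed channels
                continue
            sigma = path_degeneracy(well.m_opt, ts.m_opt_ts)
            if mode == "canonical":
                dG = max(ts.energy - well.energy, 0.0)
                kappa = 1.0
                if tunneling == "eckart" and ts.imag_freq:
                    other = net.wells[net.other_end(ts.label, well_label)]
                    dE_f = ts.energy - well.energy
                    dE_r = ts.energy - other.energy
                    if dE_f > 0 and dE_r > 0:
                        kappa = eckart_correction(dE_f, dE_r, ts.imag_freq, T)
                rates[edge] = tst_rate(dG, T, sigma=sigma, kappa=kappa).value
            else:
                if E_total - well.energy <= 0:
                    continue
                rates[edge] = rrkm_rate(well, ts, E_total, sigma=sigma, grain=grain).value
    return rates
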