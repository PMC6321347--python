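# Methods

This note records the models implemented in `mechkit`, the default
parameter choices and their rationale, the scope of the synthetic-fixture
generators, and the main numerical decisions and limitations.

## Molecular graphs

**Bond criterion.** Two atoms are bonded when their distance is below
`scale × (r_cov_i + r_cov_j)` with `scale = 1.2` and Cordero covalent
radii (H 0.31, C 0.76, N 0.71, O 0.66 Å, tabulated through Xe in
`mechkit/data/covalent_radii.json`). The 1.2 factor accommodates
vibrationally stretched bonds without capturing van der Waals contacts:
an H–H covalent bond at 0.74 Å sits at 0.99× the 0.744 Å reference,
while typical non-bonded contacts exceed 1.5×.

**Weighted adjacency.** The smooth bond-order surrogate is the rational
switching function `a_ij = (1 − x^n)/(1 − x^m)` with `x = r/r_ref` and
`(n, m) = (6, 12)`. Because `m = 2n`, the expression reduces to the
everywhere-continuous closed form `1/(1 + x^6)`, which is what the code
evaluates; for other exponent pairs the removable singularity at
`x = 1` is filled with the algebraic limit `n/m`.

**Fragment counting.** The multiplicity of (near-)zero eigenvalues of
the graph Laplacian `L = D − A` equals the number of connected
components. Zero tolerances are `1e-6` for the binary adjacency (whose
eigenvalues are exactly 0 or ≥ algebraic-connectivity scale) and `1e-4`
for the weighted one (whose inter-fragment tails never vanish exactly).
`count_fragments` cross-checks the Laplacian count against a
traversal-based component labelling and raises if they disagree.

**Labeled spectra for deduplication.** The dedup descriptor is the
sorted eigenvalue spectrum of `A_Z`, the adjacency with diagonal
`1 + Z_i/10`. The spectrum is invariant to rotation, translation and
like-atom permutation. The *weighted* adjacency is used by default:
on a binary star graph all leaves are topologically equivalent, so an
unlike-atom swap among leaves leaves the binary `A_Z` spectrum exactly
unchanged, whereas the distance-weighted matrix separates the sites
(shift ≈ 0.07 for an O↔H swap in a 4-atom fixture, against a per-
eigenvalue tolerance of `1e-3`).

**SPRINT coordinates.** Per-atom descriptors
`s_i = sqrt(N) · λ_max · v_i` from the non-negative principal
eigenvector of the weighted adjacency, computed per connected component
and sorted within element groups, giving rotation/translation/
permutation invariance.

## Candidate harvesting (bond-event search)

The detector converts each trajectory frame to a binary adjacency,
extracts per-pair boolean time series, and suppresses vibrational
chatter with a run-length filter: a change of bond state must persist
for `debounce = 5` consecutive frames (or reach the trajectory end) to
count. Surviving flips within `gap = 10` frames of one another are
grouped into a single reactive event; the candidate geometry is the
middle frame of the group window. Each candidate carries reactant and
product adjacencies obtained by replaying the event list on the
initial-frame graph, so `reactant + events = product` holds by
construction; groups whose flips cancel are dropped, and windows that
touch frame 0 or the final frame are flagged as boundary-truncated.

## Screening

Three spectral filters run between harvesting and (external) saddle
optimization:

1. `dedup` removes candidates whose labeled spectra agree element-wise
   within `1e-3`, keeping the first in trajectory order.
2. `prescreen_fragmented` discards candidates that are fragmented —
   unweighted Laplacian zero count > 1, or extra weighted eigenvalues
   below `1e-4` — or weakly bound, with weighted spectral gap below
   `gap_min = 0.1`. The gap default separates covalent assemblies
   (gap ≳ 0.5) from van der Waals contacts: a dimer at 1.9× the
   reference distance has gap `2/(1 + 1.9^6) ≈ 0.042`.
3. `cluster_candidates` buckets candidates by the spectrum of the
   labeled average of reactant and product adjacencies (a reaction
   signature rather than a structure signature) and returns one
   representative per cluster — the member closest to the cluster mean.

## Rate theory

**Canonical (Eyring) rates.**
`k = σ (k_B T / h) (RT/p0)^Δn exp(−ΔG‡/RT)` with standard pressure
`p0 = 1 bar`. At 298.15 K the prefactor is `6.2124e12 s^-1`. For
bimolecular channels (`Δn = 1`) the standard-state volume factor
converts to `cm^3 molecule^-1 s^-1`. The path degeneracy σ is the ratio
of optical-isomer counts `m_TS/m_well`, optionally composed with
rotational symmetry numbers.

**State counts.** Harmonic sums and densities of states use the
direct-count (Beyer–Swinehart) convolution on an energy grain of
10 cm⁻¹ by default: starting from `counts[0] = 1`, each oscillator with
`r = round(ν/grain)` bins folds in via `counts[b] += counts[b − r]`.
The cumulative sum gives `W(E)`; the per-bin count over the grain gives
`ρ(E)`. With integer frequencies and grain 1 cm⁻¹ the count is exact
against brute-force enumeration.

**Microcanonical (RRKM) rates.**
`k(E) = σ W‡(E − E_TS) / (h ρ(E − E_well))`, evaluated with energies in
cm⁻¹ (1 kcal/mol = 349.755 cm⁻¹) so that `1/h` appears as the speed of
light in cm/s. Channels with `E < E_TS` are closed (`k = 0`); a well
lying above the total energy is an error. If the density bin at the
target energy is empty (sparse low-energy spectra), the nearest
occupied lower bin is used.

**Tunneling.** The asymmetric Eckart barrier transmission probability
is integrated over a thermal distribution,
`κ(T) = ∫ P(V1 + k_B T y) e^(−y) dy`, using adaptive quadrature on
`[y0, 0]` and `[0, 60]`. The cosh expressions are exponent-shifted to
avoid overflow. For a high, wide symmetric barrier κ reproduces the
Wigner limit `1 + u²/24` within 1%; `imag_freq = 0` returns exactly 1.

## Stochastic kinetics

`run_kmc` implements the Gillespie direct method: waiting time
`τ = −ln(u)/k_tot` and channel selection proportional to rate. Each
replica draws its generator from `numpy.random.SeedSequence.spawn`, so
results are bit-identical for a fixed seed and independent of replica
ordering. Populations are sampled onto a fixed time grid (50 points by
default); branching fractions count terminal states. Bimolecular
channels are folded in pseudo-first-order by scaling with the initial
partner concentration. A species with no outgoing channel that is not a
declared sink triggers a warning and is treated as terminal.

The deterministic cross-check `ode_reference` solves the linear master
equation exactly via the matrix exponential `p(t) = exp(Kt) p0`.
Nonlinear mass-action networks are integrated with LSODA
(`rtol = 1e-8`).

**Reaction orders.** `fit_reaction_orders` estimates initial product
formation rates from the deterministic mass-action solution over a 5%
conversion window (bracketing the end time upward from 1 ns), then fits
the slope of `ln(rate)` against `ln(concentration)` over a factor sweep
(default 0.25–4×). The ODE route is used instead of stochastic event
counting because initial-rate slopes require smooth, noise-free rates;
with a fast catalyst-sequestration pre-equilibrium it recovers negative
inhibitor orders (CO ≈ −0.9 in the bundled toy cycle).

## Synthetic fixtures

`make_trajectory` turns an `EventScript` into an XYZ trajectory whose
scripted pair distances follow exact linear ramps plus bounded uniform
jitter, and returns the ground-truth event list computed from the same
ramp arithmetic the generator uses — detector recovery is therefore
checked exactly, not approximately. Script validation enforces that
ramps straddle the bond threshold, stay monotone, fit inside the
trajectory and use disjoint atom pairs.

`make_toy_network` builds four network fixtures: `two_channel`
(branching benchmark with embedded rates), `sequential` (A→B→C with
closed-form populations), `catalytic_cycle` (mass-action cycle with
reversible CO sequestration giving a negative CO order), and `vcn_like`
(a three-barrier unimolecular chain with frequencies and imaginary
frequencies for RRKM and tunneling demonstrations).

## Limitations

- Energies, frequencies and connectivities of wells and transition
  states are inputs; no electronic-structure or saddle-point
  optimization is performed, so absolute rates are only as good as the
  supplied network.
- State counts are harmonic; no anharmonicity or rotational densities.
- Tunneling is one-dimensional Eckart along the imaginary mode.
- KMC assumes well-mixed, memoryless kinetics; bimolecular channels are
  linearized at the initial partner concentration.
- The bond criterion is geometric only and shares the usual limitations
  near transition states, which is why the debounce filter and spectral
  screens exist.
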