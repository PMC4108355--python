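# Methods

## Model and assumptions

The operon is a continuous-time Markov chain over six occupancy states of
its three operators: repressor-free (FREE), repressor singly bound at the
main operator O1 or an auxiliary operator O2/O3 (B1, B2, B3), and DNA-looped
with the tetramer bridging O1–O2 or O1–O3 (L12, L13). The O2–O3 loop is
excluded as sterically disfavored. A single repressor is assumed (the
operon rarely entertains more than one), its copy number is identical in
every cell (no extrinsic noise), and association to any operator is
diffusion-limited and therefore operator-independent, with aggregate
propensity k_a that already includes the repressor copy number.
Transcription proceeds at the full rate ν only in FREE and in B2; O3-bound
repressor occludes the activator site and leaves only a few percent of
activity, which the model neglects. mRNA decays at γ_m per molecule,
protein is made at k_p per mRNA and diluted at γ_p per molecule; 1/γ_p is
identified with the cell cycle throughout. Cell division is not modeled as
a discrete event, and only stationary distributions are computed.

Within-loop contact release uses the same propensity k_di as dissociation
of a singly bound repressor from operator Oi. This choice preserves the
detailed-balance structure of the bound subsystem (loop formation/opening
form a tree B2–L12–B1–L13–B3, so the quasi-equilibrium is fixed by rate
ratios alone) and is what makes the burst decomposition identities below
exact. Per-operator overrides (`kd1_loop` …) are provided for sensitivity
analysis.

## Parameters

Default (uninduced) values, all in s⁻¹:

| parameter | value | meaning |
|---|---|---|
| ν | 0.12 | mRNA synthesis in an active state (a = ν/γ_p = 600) |
| γ_m | 0.011 | mRNA decay |
| k_p | 0.044 | protein synthesis per mRNA (b = k_p/γ_m = 4) |
| γ_p | 0.0002 | protein dilution (cell cycle 1/γ_p ≈ 83 min) |
| k_a | 0.073 | association to any one operator (effective) |
| k_d1 | 0.0016 | dissociation from O1 |
| k_d2 | 0.019 | dissociation from O2 (transcribing auxiliary) |
| k_d3 | 0.73 | dissociation from O3 |
| kl_12 | 4 | O1–O2 loop formation |
| kl_13 | 24 | O1–O3 loop formation |

The association propensity is the one genuinely uncertain constant:
in vitro equilibrium data propagate to 0.73, while in vivo single-molecule
measurements give 0.014 per dimer, i.e. 0.14 for ten repressors. Neither
candidate is internally consistent with the derived large-burst statistics
(l_c = ν/3k_a ≈ 0.55 with auxiliary operators and ν/k_a ≈ 1.65 without,
ρ ≈ 0.2 via K = k_d2/k_a ≈ 0.25); the effective value 0.073 reproduces all
of them simultaneously and is the packaged default. Both alternatives ship
as `uninduced_invitro.yaml` and `uninduced_invivo.yaml`. Loading the default
set re-runs these consistency checks and refuses a mistranscribed file.
Under induction only k_a changes (decreasing with inducer concentration);
dissociation and looping propensities are inducer-independent at the
relevant concentrations, and inducer–repressor binding kinetics are not
modeled explicitly.

## Reduction and closed-form solution

Loop formation (4–24 s⁻¹) is two to four orders of magnitude faster than
every other propensity, so conditional on being bound the substates
{B1, B2, B3, L12, L13} follow their detailed-balance quasi-equilibrium
(computed as the null vector of the bound-subsystem generator; residual
flux imbalance is reported and tested below 10⁻¹⁰). The chain collapses to
two states with κ_b = 3k_a, κ_f = Σ P(Bi|bound) k_di = 3k_d1/Z (an exact
identity of the detailed-balance weights, Z their normalization), and
bound-state transcription ν_b = ν P(B2|bound). Conditional probabilities
stand in for absolute ones; the error is governed by κ_f/κ_b (~10⁻⁴
uninduced) and is exposed as a diagnostic rather than silently assumed.

With time in units of 1/γ_p and mRNA eliminated adiabatically (γ = γ_m/γ_p
= 55 ≫ 1), each mRNA contributes a geometric protein burst of mean
b = k_p/γ_m, and the stationary generating function solves a Gauss
hypergeometric ODE. Writing s = b(z−1), a = ν/γ_p, c = ν_b/γ_p,
κ̃ = κ/γ_p:

    G(z) = (1 − s)^(−c) ₂F₁(A, B; C; s),
    C = κ̃_f + κ̃_b,   A + B = C + a − c,   AB = κ̃_f (a − c).

Limiting checks: κ̃_b → 0 gives the constitutive negative binomial
(1−s)^(−a); c → 0 gives the two-state telegraph (negative hypergeometric)
law of the deletion strain; κ̃_b ≫ a merges both factors into a single
negative binomial whose shape parameter is the total mean transcription
frequency — the regime in which even large bursts are averaged out and
contribute to the mean but not the variance. The parameter mapping is
verified two independent ways: an arbitrary-precision ODE-residual check
on a dense grid (residual < 10⁻⁸, typically ~10⁻¹⁶), and total-variation
agreement < 10⁻³ with finite-state-projection steady states of the reduced
master equation.

## Numerical choices

- **pmf coefficients.** The negative-hypergeometric factor's Taylor
  coefficients satisfy a three-term recurrence obtained from the
  generating-function ODE. The pmf is its minimal solution (decaying like
  (b/(1+b))ⁿ versus 1/poly(n) for the parasitic solution), so the forward
  recurrence loses all accuracy within tens of terms; we run Miller's
  backward algorithm from a buffered start index (buffer sized so seed
  contamination is below double precision), normalize by total mass
  including a geometric tail estimate, and convolve with the negative
  binomial factor. Cross-checked against arbitrary-precision
  differentiation of ₂F₁ (mpmath) to 10⁻⁹ relative.
- **Truncations.** FSP state spaces and pmf supports grow by iterative
  doubling until boundary/tail mass < 10⁻⁹; explicitly requested
  truncations that capture too little mass raise (FSP) or warn with a
  suggested size (pmf).
- **Steady states.** Sparse direct solve of the truncated generator with a
  normalization row; probability conservation, flux balance
  (mean protein = (k_p/γ_p) × mean mRNA) and operon-marginal checks are
  part of the test suite.
- **Simulation.** Plain direct-method Gillespie in a numba kernel,
  independent cells sampled at t_end = 10/γ_p from (FREE, 0, 0) — long
  enough that the slowest mode (protein, relaxing like e^(−γ_p t))
  has equilibrated to within e⁻¹⁰. Per-cell xorshift128+ substreams are
  derived from (seed, cell index) via splitmix64, so outputs are
  bit-for-bit reproducible and extending n_cells preserves earlier cells.
  A single-trajectory time-average mode cross-checks the protocol.
- **Fitting.** Exact multinomial log-likelihood on integer counts (no
  continuous Gamma approximation); single-parameter fits use bounded
  scalar minimization over log k_a, multi-parameter fits a Nelder–Mead
  simplex with restarts; profile-likelihood intervals use the χ²₁
  threshold. Whether the original distribution fits were least-squares or
  likelihood-based is not documented; likelihood was chosen here and fits
  are validated by parameter recovery on synthetic data rather than by
  matching any published fitted values.

## Burst decomposition

Partial dissociations occur at rate P(L12)·k_d1 (detailed-balance flux out
of the transcribing loop), so n_p = P(L12) k_d1/γ_p per cell cycle; each
yields l_p = ν/kl_12 mRNAs during the ~1/kl_12 re-looping window. Complete
dissociations occur at f = κ_f/γ_p per cycle and yield l_c = ν/(3k_a)
mRNAs during the operator search (ν/k_a for the one-operator deletion
strain — hence the exact 1/3 cross-strain size ratio, and a frequency
ratio κ_f/k_d1 = 3/Z ≈ 1/80). These leading-order single-timescale forms
are not hidden behind further approximation: the simulator counts actual
dissociation events and the mRNAs inside each window, and the event-count
oracle quantifies their error (a few percent at the default set).

The decomposition identity ν_b/γ_p + κ_f ν/(3k_a γ_p) = n_p l_p + f l_c
holds exactly, and ρ = f l_c/(n_p l_p + f l_c) reduces algebraically to
K/(1+K) with K = k_d2/k_a. In the weak-induction regime (mean expression
≲1% of the fully induced a·b = 2400 for the looping strain, ≲5% for the
deletion strain; flags computed and reported), Fano = 1 + b(1 + ρ l_c) and
1/noise = b(n_p l_p + f l_c)/Fano, agreeing with the exact
generating-function moments to ~10⁻⁴ relative at the uninduced set. The
inversion solves this 2×2 system in closed form per titration point (no
smoothing), so the round trip is exact to floating-point precision.
Filtered data (large bursts removed, ρ = 0) therefore measure the
*translational* burst size 1+b ≈ b and the small-burst mRNA rate n_p l_p —
not the small-burst size and frequency individually, which rapid looping
averages out of the variance and renders unrecoverable.

## Synthetic data

No machine-readable single-cell LacY histograms are deposited, so the
generator draws i.i.d. multinomial samples from the model's own
steady-state pmf at stated parameters (deterministic per seed). This
emulates intrinsic-noise-limited single-cell counting with perfect
calibration: it reproduces the counts' sampling variability but not
extrinsic cell-to-cell variation, measurement noise of the fluorescence
assay, or cell-age structure. Passing recovery tests therefore demonstrate
identifiability and correctness of the likelihood machinery under the
model, not robustness to those real-data effects. Parameter-recovery
experiments use 10⁴ cells per histogram (the scale of the original
single-cell datasets); replicate counts (25 for recovery/coverage, 50 for
model preference) balance statistical resolution against suite runtime.

## Oracle problem sizes

Exact-oracle comparisons run at sizes where the oracles are themselves
trustworthy: FSP equivalence uses small random parameter sets (a ≤ 50,
b ≤ 5) with γ = 1500, since the closed form is the γ → ∞ adiabatic limit
and its O(1/γ) error (total variation ≈ 10⁻³ at the physical γ = 55) would
otherwise mask the 10⁻³ agreement being verified; the full-vs-reduced and
simulation-vs-analytic comparisons use the physical uninduced set at 10⁵
and 10⁴ cells respectively, where agreement is limited by sampling noise
plus the stated approximations.

## Known limitations

- Time-dependent (relaxation) distributions are out of scope; only steady
  states are computed.
- The adiabatic protein solution degrades as γ decreases toward 1 (it
  refuses γ ≤ 1 and warns below 10) and as induction strengthens beyond
  the weak-induction regime; the exact FSP route remains available there.
- The O2–O3 loop, repressor copy-number fluctuations, inducer–repressor
  binding kinetics and the bistable switching threshold are deliberately
  not modeled.
- Estimating b and f from titration plateaus is left to the user (the
  original analysis reads them off by eye); the inversion takes them as
  inputs.
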