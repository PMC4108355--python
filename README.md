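# loopburst

Stochastic gene expression of the *E. coli lac* operon with auxiliary
operators and DNA looping: exact simulation, quasi-steady-state model
reduction, closed-form steady-state protein distributions, transcriptional
burst-statistics decomposition, and maximum-likelihood fitting of
single-cell protein-count histograms.

## The problem

Single-molecule counting of LacY in individual cells shows two kinds of
transcriptional bursts. The single tetrameric Lac repressor is normally
trapped in a DNA loop bridging the main operator O1 and one auxiliary
operator (O2 downstream, O3 upstream). When it releases O1 but stays
tethered to the auxiliary operator — a *partial dissociation* — the loop
re-forms within a fraction of a second and only a small burst of
transcription escapes. When it leaves the DNA entirely — a *complete
dissociation* — the slow operator search permits a large burst. Interpreting
measured protein-distribution statistics (Fano factor σ²/μ, reciprocal
noise μ²/σ²) as burst sizes and frequencies is only valid under a model
that accounts for these operon states; this package implements such a
model, its analytical solution, and the inference it enables.

## The model

A six-state operon chain — repressor-free (FREE), singly bound (B1, B2,
B3), looped (L12, L13) — coupled to mRNA synthesis (propensity ν in FREE
and in the transcribing auxiliary-bound state B2), mRNA decay γ_m, protein
synthesis k_p per mRNA, and protein dilution γ_p (1/γ_p ≡ the cell cycle).
Two timescale separations make the chemical master equation tractable:

1. **Rapid loop formation** — the bound substates equilibrate by detailed
   balance, collapsing the scheme to a two-state (free/bound) model with
   effective switching propensities κ_b = 3k_a, κ_f = Σ P(Bi|bound)·k_di,
   and bound-state transcription ν_b = ν·P(B2|bound).
2. **Rapid mRNA decay** (γ_m ≫ γ_p) — each mRNA yields a geometric burst of
   b = k_p/γ_m proteins, and the stationary protein generating function is
   closed-form. With s = b(z−1), a = ν/γ_p, c = ν_b/γ_p and κ̃ = κ/γ_p:

       G(z) = (1 − s)^(−c) · ₂F₁(A, B; C; s),
       C = κ̃_f + κ̃_b,  A + B = C + a − c,  AB = κ̃_f (a − c)

   a convolution of a **negative binomial** (proteins from small bursts)
   with a **negative hypergeometric** (proteins from large bursts). The
   auxiliary-operator deletion strain is the c = 0 special case, the
   classic telegraph-model law.

The burst decomposition expresses the mean transcription frequency exactly
as n_p·l_p + f·l_c (partial-dissociation frequency × size plus
complete-dissociation frequency × size), with the fraction of proteins from
large bursts ρ = K/(1+K) fixed by the equilibrium constant K = k_d2/k_a
alone. The weak-induction relations Fano = 1 + b(1 + ρ·l_c) and
1/noise = b(n_p·l_p + f·l_c)/Fano invert in closed form, recovering
(l_c, ρ) from raw titration statistics. A finite-state-projection solver
for the untruncated master equation serves as the brute-force oracle for
every approximation, and a Gillespie simulator (full and reduced schemes)
provides exact samples and dissociation-event counts.

## Worked example

The packaged uninduced parameter set (`loopburst bursts --strain looping`):

```json
{
  "n_p": 6.888684404006696,
  "l_p": 0.03,
  "f": 0.09816375275708811,
  "l_c": 0.5479452054794521,
  "rho": 0.2065217391304226,
  "fano": 5.452650387135173,
  "inv_noise": 0.191062233081962
}
```

Read: an uninduced cell experiences ~6.9 partial dissociations per cell
cycle, each yielding only 0.03 mRNAs (looping is far faster than
transcription), and ~0.1 complete dissociations per cycle yielding 0.55
mRNAs each. About 79% of mRNAs come from the frequent small bursts, yet
21% of *proteins* (ρ ≈ 0.21) derive from the rare large ones. For the
deletion strain `loopburst bursts --strain noaux` gives f = 8 and
l_c ≈ 1.64 — the large-burst size ratio between strains is exactly 1/3
(three operators to rebind versus one) and the frequency ratio ≈ 1/80.

The exact moments (`loopburst moments --strain looping`) — mean 1.04
proteins, Fano 5.45 — agree with the weak-induction burst forms above to
0.01%. The same numbers are recovered by Gillespie simulation:

```bash
loopburst simulate --cells 10000 --seed 7 --out counts.csv --events events.csv
loopburst pmf --strain looping --out pmf.csv     # analytic pmf to compare
```

Fitting a synthetic 10⁴-cell histogram sampled at a 10-fold reduced
association rate recovers k_a within a few percent:

```bash
loopburst sample --strain noaux --cells 10000 --seed 1 --out h.csv
loopburst fit --hist h.csv --strain noaux --free k_a
```

## Layout

- `loopburst.params` / `loopburst.network` — kinetic parameterization and
  the six-state reaction network (packaged parameter sets under
  `loopburst/data/`).
- `loopburst.fsp` — finite-state-projection steady states (ground truth).
- `loopburst.reduction` — rapid-looping reduction and nondimensionalization.
- `loopburst.analytic` — generating functions, pmfs, moments, NB limits.
- `loopburst.ssa` — numba-accelerated Gillespie simulation and
  dissociation-event counting.
- `loopburst.bursts` — burst decomposition, Fano/noise forms, inversion,
  cross-strain relations.
- `loopburst.fitting` — synthetic-data generation, MLE fitting, model
  comparison.
- `loopburst.io` / `loopburst.cli` — file formats and the `loopburst`
  command-line tool.
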