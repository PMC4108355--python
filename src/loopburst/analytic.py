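"""Closed-form steady-state protein distributions of the reduced model.

In the fast-mRNA (adiabatic) limit each mRNA is translated into a
geometrically distributed burst of proteins of mean b, and the reduced
two-state operon model admits a closed-form steady-state generating
function.  With s = b(z - 1),

    G(z) = (1 - s)^(-c) * 2F1(A, B; C; s),

where c = a * phi_bound is the dimensionless transcription rate of the
bound superstate, C = kf + kb, A + B = C + a - c and A * B = kf * (a - c).
The two factors are the generating functions of the two independent protein
sub-populations: a negative binomial component from the small bursts
(transcription while the operon is bound) and a negative-hypergeometric
component from the large bursts (transcription while it is free).  The
auxiliary-operator deletion strain is the special case c = 0: a pure
negative hypergeometric distribution, the classic two-state (telegraph)
regulated-promoter law.

Protein pmf coefficients are generated by a backward three-term recurrence
derived from the generating-function ODE (Miller's algorithm, normalized by
total mass); the forward recurrence is exponentially unstable because the
parasitic solution decays only like 1/poly(n) while the pmf decays like
(b/(1+b))^n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .reduction import DimensionlessParameters

__all__ = [
    "GFParams",
    "ProteinDistribution",
    "Moments",
    "gf_params_looping",
    "gf_params_noaux",
    "pmf_looping",
    "pmf_noaux",
    "pmf_from_gf",
    "moments_looping",
    "moments_noaux",
    "moments_from_gf",
    "negative_binomial_limit",
    "gf_ode_residual",
    "total_variation",
]


@dataclass(frozen=True)
class GFParams:
    """Parameters of the steady-state generating function.

    ``A``, ``B`` are the numerator pair and ``C`` the denominator parameter
    of the Gauss hypergeometric factor; ``c`` the exponent of the negative
    binomial factor (0 for the deletion strain); ``b`` the translational
    burst size scaling the argument s = b(z - 1).
    """

    A: float
    B: float
    C: float
    c: float
    b: float


@dataclass(frozen=True)
class ProteinDistribution:
    """Steady-state protein pmf on 0..n_max with its achieved tail mass."""

    pmf: np.ndarray
    tail_mass: float
    # additive decomposition: proteins from small bursts (negative binomial)
    # and from large bursts (negative hypergeometric); the full pmf is their
    # convolution.  None when the decomposition is trivial.
    small_burst_pmf: np.ndarray | None = None
    large_burst_pmf: np.ndarray | None = None

    @property
    def n_max(self) -> int:
        return self.pmf.size - 1

    def mean(self) -> float:
        return float(np.arange(self.pmf.size) @ self.pmf)

    def variance(self) -> float:
        n = np.arange(self.pmf.size)
        mu = self.mean()
        return float((n - mu) ** 2 @ self.pmf)


@dataclass(frozen=True)
class Moments:
    """Exact moments of the protein distribution, with the weak-induction
    (rare-burst) approximation and its applicability diagnostic."""

    mean: float
    variance: float
    fano: float
    inv_noise: float
    weak_induction_ok: bool
    weak_induction_rel_err: float


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs (zero-padded to match)."""
    n = max(len(p), len(q))
    p = np.pad(np.asarray(p, float), (0, n - len(p)))
    q = np.pad(np.asarray(q, float), (0, n - len(q)))
    return 0.5 * float(np.abs(p - q).sum())


# ---------------------------------------------------------------------------
# generating-function parameters


def _gf_map(a: float, c: float, kf: float, kb: float, b: float) -> GFParams:
    if not all(map(math.isfinite, (a, c, kf, kb, b))):
        raise ValueError("non-finite generating-function inputs")
    if a < c:
        raise ValueError("bound-state transcription cannot exceed nu (c <= a)")
    C = kf + kb
    if C <= 0:
        raise ValueError("kf + kb must be positive (the operon must switch)")
    S = C + a - c
    P = kf * (a - c)
    disc = S * S - 4.0 * P
    root = math.sqrt(max(disc, 0.0))
    A = 0.5 * (S + root)
    B = P / A if A > 0 else 0.0
    return GFParams(A=A, B=B, C=C, c=c, b=b)


def gf_params_looping(d: DimensionlessParameters) -> GFParams:
    """GF parameters for the strain with auxiliary operators.

    Emits an advisory when gamma is not large: the adiabatic (fast-mRNA)
    solution carries an O(1/gamma) error.
    """
    if d.gamma <= 1:
        raise ValueError("gamma = g_m/g_p must exceed 1")
    if d.gamma < 10:
        warnings.warn(
            f"gamma = {d.gamma:.3g} is not >> 1; the fast-mRNA solution may "
            "be inaccurate",
            stacklevel=2,
        )
    return _gf_map(d.a, d.a * d.phi_bound, d.kf, d.kb, d.b)


def gf_params_noaux(d: DimensionlessParameters) -> GFParams:
    """GF parameters for the deletion strain (two states, transcription only
    in the free state): the c = 0 special case."""
    if d.phi_bound != 0:
        raise ValueError(
            "the deletion strain has no bound-state transcription; build d "
            "with dimensionless_noaux()"
        )
    if d.gamma <= 1:
        raise ValueError("gamma = g_m/g_p must exceed 1")
    return _gf_map(d.a, 0.0, d.kf, d.kb, d.b)


# ---------------------------------------------------------------------------
# pmf via backward recurrence


@njit(cache=True)
def _miller_loop(A, B, C, b, N):  # pragma: no cover - exercised via wrapper
    g = np.zeros(N + 2)
    g[N] = 1e-250
    one_2b = 1.0 + 2.0 * b
    cb = C + (A + B + 1.0) * b
    for n in range(N - 1, -1, -1):
        g[n] = (
            (n + 1) * ((one_2b * n + cb) * g[n + 1] - (1.0 + b) * (n + 2) * g[n + 2])
        ) / (b * (n + A) * (n + B))
        if g[n] > 1e260:
            for j in range(n, N + 2):
                g[j] *= 1e-260
    return g


def _hyp_coeffs(
    A: float, B: float, C: float, b: float, n_max: int
) -> tuple[np.ndarray, float]:
    """Taylor coefficients in z of 2F1(A, B; C; b(z-1)), i.e. the pmf of the
    large-burst (negative hypergeometric) component, by Miller's backward
    recurrence, normalized against the total mass including a geometric
    estimate of the tail beyond n_max.  Returns (coefficients on 0..n_max,
    tail mass beyond n_max)."""
    if A * B == 0.0:  # no large bursts at all
        out = np.zeros(n_max + 1)
        out[0] = 1.0
        return out, 0.0
    q = b / (1.0 + b)
    # contamination of the backward recurrence decays like q^k; size the
    # buffer so it is below double precision where coefficients are kept or
    # used for the tail estimate
    buffer = min(2 * (int(math.ceil(-37.0 / math.log(q))) + 50), 40000)
    g = _miller_loop(A, B, C, b, n_max + buffer)
    est_end = n_max + buffer // 2  # contamination-free up to here
    ratio = g[est_end] / g[est_end - 1] if g[est_end - 1] > 0 else 0.0
    ratio = min(ratio, q)  # the pmf tail ratio approaches q from below
    tail_beyond = g[est_end] * ratio / (1.0 - ratio) if ratio > 0 else 0.0
    total = g[: est_end + 1].sum() + tail_beyond
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("backward recurrence failed to converge")
    kept = g[: n_max + 1] / total
    tail = max(1.0 - kept.sum(), 0.0)
    return kept, tail


def pmf_from_gf(
    gf: GFParams,
    n_max: int | None = None,
    tail_tol: float = 1e-9,
    max_doublings: int = 14,
) -> ProteinDistribution:
    """Expand the generating function into a protein pmf.

    With ``n_max`` omitted the support is grown by doubling until the tail
    mass is below ``tail_tol``.  An explicitly requested ``n_max`` that
    leaves more than 1e-6 in the tail triggers a warning with a suggested
    truncation.
    """
    explicit = n_max is not None
    if explicit and n_max < 0:
        raise ValueError("n_max must be >= 0")
    mean = gf.b * (gf.c + gf.A * gf.B / gf.C)
    if n_max is None:
        n_max = max(32, int(8 * mean))
    for _ in range(max_doublings + 1):
        large, large_tail = _hyp_coeffs(gf.A, gf.B, gf.C, gf.b, n_max)
        if gf.c > 0:
            small = stats.nbinom.pmf(
                np.arange(n_max + 1), gf.c, 1.0 / (1.0 + gf.b)
            )
            pmf = np.convolve(small, large)[: n_max + 1]
        else:
            small = None
            pmf = large
        tail = max(1.0 - pmf.sum(), large_tail)
        if tail <= tail_tol or explicit:
            break
        n_max *= 2
    if explicit and tail > 1e-6:
        # rough geometric tail extrapolation for the suggestion
        ratio = pmf[-1] / pmf[-2] if pmf.size > 1 and pmf[-2] > 0 else 0.9
        extra = int(math.log(1e-9 / max(tail, 1e-300)) / math.log(max(ratio, 0.5)))
        warnings.warn(
            f"tail mass {tail:.2e} exceeds 1e-06 at n_max={n_max}; consider "
            f"n_max >= {n_max + max(extra, 16)}",
            stacklevel=2,
        )
    return ProteinDistribution(pmf, tail, small, large)


def pmf_looping(
    d: DimensionlessParameters, n_max: int | None = None, **kw
) -> ProteinDistribution:
    """Steady-state protein pmf for the strain with auxiliary operators."""
    return pmf_from_gf(gf_params_looping(d), n_max, **kw)


def pmf_noaux(
    d: DimensionlessParameters, n_max: int | None = None, **kw
) -> ProteinDistribution:
    """Steady-state protein pmf for the auxiliary-operator deletion strain."""
    return pmf_from_gf(gf_params_noaux(d), n_max, **kw)


# ---------------------------------------------------------------------------
# moments


def moments_from_gf(gf: GFParams, weak_threshold: float = 0.01) -> Moments:
    """Exact mean/variance from generating-function derivatives at z = 1,
    compared against the weak-induction (burst-decomposition) forms."""
    A, B, C, c, b = gf.A, gf.B, gf.C, gf.c, gf.b
    mean = b * (c + A * B / C)
    # second factorial moment E[n(n-1)] = G''(1)
    m2 = b * b * (
        c * (c + 1.0)
        + 2.0 * c * A * B / C
        + A * (A + 1.0) * B * (B + 1.0) / (C * (C + 1.0))
    )
    var = m2 + mean - mean * mean
    fano = var / mean if mean > 0 else 1.0
    inv_noise = mean * mean / var if var > 0 else math.inf
    # weak-induction (rare-burst) form: Fano = 1 + b (1 + rho * l_c), where
    # l_c = a/kb is the mRNA burst size of complete dissociations and rho
    # the protein fraction they contribute.  Recover (a, kf, kb) from the
    # GF parameters: A+B = C + a - c and A*B = kf*(a - c).
    a = (A + B) - C + c
    kf = A * B / (a - c) if a > c else 0.0
    kb = C - kf
    l_c = a / kb if kb > 0 else math.inf
    flc = kf * l_c
    rho = flc / (c + flc) if (c + flc) > 0 else 0.0
    fano_wi = 1.0 + b * (1.0 + rho * l_c) if math.isfinite(l_c) else math.inf
    rel_err = abs(fano_wi - fano) / fano if fano > 0 else 0.0
    weak_ok = bool(mean <= weak_threshold * a * b)
    return Moments(float(mean), float(var), float(fano), float(inv_noise),
                   weak_ok, float(rel_err))


def moments_looping(d: DimensionlessParameters) -> Moments:
    """Exact protein moments for the looping strain; the weak-induction flag
    checks expression below 1% of the fully induced mean a*b."""
    return moments_from_gf(gf_params_looping(d), weak_threshold=0.01)


def moments_noaux(d: DimensionlessParameters) -> Moments:
    """Exact protein moments for the deletion strain; the weak-induction flag
    checks expression below 5% of the fully induced mean a*b."""
    return moments_from_gf(gf_params_noaux(d), weak_threshold=0.05)


# ---------------------------------------------------------------------------
# negative-binomial limit


def negative_binomial_limit(
    d: DimensionlessParameters, strain: str = "looping", n_max: int | None = None
) -> tuple[ProteinDistribution, float]:
    """Negative-binomial limit of the protein distribution.

    When the association propensity is much larger than the transcription
    propensity (kb >> a) the operon switches much faster than it
    transcribes, every burst is averaged out, and the distribution collapses
    to a negative binomial whose shape parameter is the total mean
    transcription frequency per cell cycle (large bursts then contribute to
    the mean but not the variance).  Returns the NB pmf and the
    applicability diagnostic kb / a.
    """
    gf = gf_params_looping(d) if strain == "looping" else gf_params_noaux(d)
    r = gf.c + gf.A * gf.B / gf.C  # matches the exact mean: r*b
    if n_max is None:
        n_max = max(32, int(stats.nbinom.ppf(1 - 1e-9, r, 1 / (1 + gf.b))) + 1)
    pmf = stats.nbinom.pmf(np.arange(n_max + 1), r, 1.0 / (1.0 + gf.b))
    diag = d.kb / d.a if d.a > 0 else math.inf
    return ProteinDistribution(pmf, max(1.0 - pmf.sum(), 0.0)), diag


# ---------------------------------------------------------------------------
# ODE-residual oracle


def gf_ode_residual(
    d: DimensionlessParameters,
    gf: GFParams | None = None,
    n_grid: int = 41,
) -> float:
    """Maximum relative residual of the steady-state generating-function ODE.

    The reduced master equations collapse, after eliminating mRNA in the
    fast-decay limit, to a single second-order ODE for G in s = b(z - 1):

        s (1-s)^2 G'' - (1-s) [s (a + 1 + c) - C (1-s)] G'
            + [a c s - (1-s) (kf a + kb c)] G = 0.

    The candidate solution G = (1-s)^(-c) 2F1(A, B; C; s) is evaluated in
    arbitrary precision (mpmath) on a dense z-grid in (0, 1), so the
    residual checks the (A, B, C, c) parameter mapping independently of the
    pmf recurrence.
    """
    import mpmath as mp

    if gf is None:
        gf = _gf_map(d.a, d.a * d.phi_bound, d.kf, d.kb, d.b)
    a, c = d.a, d.a * d.phi_bound
    kf, kb = d.kf, d.kb
    C = kf + kb
    A_, B_ = mp.mpf(gf.A), mp.mpf(gf.B)
    C_ = mp.mpf(gf.C)
    worst = 0.0
    with mp.workdps(60):
        for z in np.linspace(1e-3, 1 - 1e-3, n_grid):
            s = mp.mpf(gf.b) * (mp.mpf(z) - 1)
            F = mp.hyp2f1(A_, B_, C_, s)
            F1 = A_ * B_ / C_ * mp.hyp2f1(A_ + 1, B_ + 1, C_ + 1, s)
            F2 = (
                A_ * (A_ + 1) * B_ * (B_ + 1) / (C_ * (C_ + 1))
            ) * mp.hyp2f1(A_ + 2, B_ + 2, C_ + 2, s)
            pre = (1 - s) ** (-mp.mpf(c))
            G = pre * F
            G1 = pre * (c / (1 - s) * F + F1)
            G2 = pre * (c * (c + 1) / (1 - s) ** 2 * F + 2 * c / (1 - s) * F1 + F2)
            t1 = s * (1 - s) ** 2 * G2
            t2 = -(1 - s) * (s * (a + 1 + c) - C * (1 - s)) * G1
            t3 = (a * c * s - (1 - s) * (kf * a + kb * c)) * G
            scale = max(abs(t1), abs(t2), abs(t3), mp.mpf(1e-300))
            worst = max(worst, float(abs(t1 + t2 + t3) / scale))
    return worst
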