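"""Rapid-loop-formation reduction of the six-state scheme.

Loop formation (kl_12, kl_13) is much faster than every other propensity,
so conditional on the operon being repressor-bound, the five bound
substates {B1, B2, B3, L12, L13} equilibrate on the fast looping timescale
and obey detailed balance — loop formation/opening are the only transitions
inside the bound subsystem, and they form a tree (B2 - L12 - B1 - L13 - B3),
so the quasi-equilibrium distribution is fixed by rate ratios alone.

Averaging over that distribution collapses the scheme to a two-state
(free/bound) model: the free -> bound propensity is kappa_b = 3 k_a
(association to any of the three operators), the bound -> free propensity
kappa_f is the equilibrium-weighted complete-dissociation flux, and the
bound superstate transcribes at nu_bound = nu * P(transcribing substate),
which carries the entire effect of the small transcriptional bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import OperonState
from .params import RateParameters, validate_parameters

__all__ = [
    "BoundStateDistribution",
    "ReducedParameters",
    "DimensionlessParameters",
    "bound_state_probabilities",
    "effective_rates",
    "nondimensionalize",
    "dimensionless_noaux",
]

_BOUND_ORDER = (
    OperonState.B1,
    OperonState.B2,
    OperonState.B3,
    OperonState.L12,
    OperonState.L13,
)


@dataclass(frozen=True)
class BoundStateDistribution:
    """Quasi-equilibrium distribution of the repressor-bound substates."""

    p_b1: float
    p_b2: float
    p_b3: float
    p_l12: float
    p_l13: float
    detailed_balance_residual: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_b1, self.p_b2, self.p_b3, self.p_l12, self.p_l13])

    def __getitem__(self, s: OperonState) -> float:
        return float(self.as_array()[_BOUND_ORDER.index(s)])


@dataclass(frozen=True)
class ReducedParameters:
    """Effective propensities of the two-state (free/bound) reduced model."""

    kappa_f: float  # bound -> free
    kappa_b: float  # free -> bound
    nu_bound: float  # effective transcription propensity in the bound state
    conditional_ratio: float  # kappa_f / kappa_b; "conditional ~ absolute" diagnostic


@dataclass(frozen=True)
class DimensionlessParameters:
    """Reduced-model parameters rescaled by the protein dilution rate.

    a = nu/g_p is the frequency of unregulated transcription per cell cycle,
    b = k_p/g_m the translational burst size (mean proteins per mRNA),
    gamma = g_m/g_p the ratio of protein and mRNA lifetimes, kf and kb the
    free/bound switching frequencies per cell cycle, and phi_bound the
    bound-state transcription fraction nu_bound/nu.
    """

    a: float
    b: float
    gamma: float
    kf: float
    kb: float
    phi_bound: float


class DegenerateSubsystemError(ValueError):
    """The bound subsystem has no unique quasi-equilibrium."""


def _bound_generator(p: RateParameters) -> np.ndarray:
    """Generator of the 5-state bound subsystem (rows sum to zero), in
    _BOUND_ORDER.  Its only transitions are loop formation and opening."""
    r1, r2, r3 = p.loop_release_rates()
    i = {s: k for k, s in enumerate(_BOUND_ORDER)}
    Q = np.zeros((5, 5))
    edges = [
        (OperonState.B1, OperonState.L12, p.kl_12),
        (OperonState.B2, OperonState.L12, p.kl_12),
        (OperonState.B1, OperonState.L13, p.kl_13),
        (OperonState.B3, OperonState.L13, p.kl_13),
        (OperonState.L12, OperonState.B1, r2),
        (OperonState.L12, OperonState.B2, r1),
        (OperonState.L13, OperonState.B1, r3),
        (OperonState.L13, OperonState.B3, r1),
    ]
    for src, dst, rate in edges:
        Q[i[src], i[dst]] += rate
    Q[np.diag_indices(5)] -= Q.sum(axis=1)
    return Q


def _bound_weights(p: RateParameters) -> np.ndarray:
    """Quasi-equilibrium of the bound subsystem: null vector of its
    generator, normalized."""
    Q = _bound_generator(p)
    if np.all(Q == 0):
        raise DegenerateSubsystemError(
            "all loop-formation and loop-opening rates are zero: the bound "
            "subsystem has no unique equilibrium"
        )
    A = np.vstack([Q.T, np.ones(5)])
    rhs = np.zeros(6)
    rhs[-1] = 1.0
    w, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    w = np.maximum(w, 0.0)
    if w.sum() <= 0 or not np.all(np.isfinite(w)):
        raise DegenerateSubsystemError("bound subsystem has no valid equilibrium")
    return w


def _db_residual(p: RateParameters, probs: np.ndarray) -> float:
    """Max absolute net probability flux over bound-subsystem edges."""
    r1, r2, r3 = p.loop_release_rates()
    pb = dict(zip(_BOUND_ORDER, probs))
    edges = [
        (pb[OperonState.B1] * p.kl_12, pb[OperonState.L12] * r2),
        (pb[OperonState.B2] * p.kl_12, pb[OperonState.L12] * r1),
        (pb[OperonState.B1] * p.kl_13, pb[OperonState.L13] * r3),
        (pb[OperonState.B3] * p.kl_13, pb[OperonState.L13] * r1),
    ]
    return float(max(abs(a - b) for a, b in edges))


def bound_state_probabilities(p: RateParameters) -> BoundStateDistribution:
    """Quasi-equilibrium probabilities of the five bound substates.

    For the deletion strain (``has_aux_operators=False``) the repressor-bound
    operon is trivially in B1.
    """
    p = validate_parameters(p)
    if not p.has_aux_operators:
        return BoundStateDistribution(1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    w = _bound_weights(p)
    probs = w / w.sum()
    return BoundStateDistribution(*probs, _db_residual(p, probs))


def effective_rates(p: RateParameters) -> ReducedParameters:
    """Effective two-state propensities of the rapid-looping reduction.

    kappa_b = 3 k_a with auxiliary operators (association to any operator),
    k_a without.  kappa_f is the conditional complete-dissociation flux,
    summed over the singly bound substates.  nu_bound = nu * P(transcribing
    substate | bound).
    """
    p = validate_parameters(p)
    if not p.has_aux_operators:
        return ReducedParameters(
            kappa_f=p.k_d1,
            kappa_b=p.k_a,
            nu_bound=0.0,
            conditional_ratio=p.k_d1 / p.k_a if p.k_a > 0 else np.inf,
        )
    b = bound_state_probabilities(p)
    kappa_f = b.p_b1 * p.k_d1 + b.p_b2 * p.k_d2 + b.p_b3 * p.k_d3
    kappa_b = 3.0 * p.k_a
    transcribing = (
        OperonState.B2 if p.transcribing_operator == 2 else OperonState.B3
    )
    nu_bound = p.nu * b[transcribing]
    ratio = kappa_f / kappa_b if kappa_b > 0 else np.inf
    if ratio > 0.1:
        warnings.warn(
            f"kappa_f/kappa_b = {ratio:.3g}: the free state is not rare, so "
            "conditional bound-state probabilities may differ appreciably "
            "from absolute ones",
            stacklevel=2,
        )
    return ReducedParameters(kappa_f, kappa_b, nu_bound, ratio)


def nondimensionalize(
    p: RateParameters, r: ReducedParameters | None = None
) -> DimensionlessParameters:
    """Rescale the reduced model by the protein dilution rate g_p."""
    p = validate_parameters(p)
    if p.g_p <= 0:
        raise ValueError("g_p must be positive to nondimensionalize")
    if r is None:
        r = effective_rates(p)
    return DimensionlessParameters(
        a=p.nu / p.g_p,
        b=p.k_p / p.g_m,
        gamma=p.g_m / p.g_p,
        kf=r.kappa_f / p.g_p,
        kb=r.kappa_b / p.g_p,
        phi_bound=r.nu_bound / p.nu if p.nu > 0 else 0.0,
    )


def dimensionless_noaux(p: RateParameters) -> DimensionlessParameters:
    """Dimensionless parameters for the auxiliary-operator deletion strain."""
    return nondimensionalize(p.without_aux())
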