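"""Kinetic parameterization of the six-state lac operon scheme.

The single tetrameric Lac repressor can occupy the main operator O1 or one of
the auxiliary operators O2 (downstream) and O3 (upstream), and, being a dimer
of dimers, can bridge O1 with one auxiliary operator to form a DNA loop
(states L12, L13; the O2-O3 loop is sterically disfavored and excluded).
Transcription proceeds at full rate only when the operon is repressor-free or
when the repressor sits on the transcribing auxiliary operator alone (O2 by
default; occupancy of O3 alone blocks the activator site and leaves only a
few percent of activity, which the model neglects).

All propensities are first-order aggregate rates in s^-1; the association
propensity ``k_a`` already includes the cytosolic repressor copy number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace
from importlib import resources
from typing import Optional

__all__ = [
    "RateParameters",
    "ParameterValidationError",
    "TimescaleWarning",
    "validate_parameters",
    "load_packaged_parameters",
    "uninduced_parameters",
    "check_uninduced_consistency",
]


class ParameterValidationError(ValueError):
    """A kinetic parameter violates a model invariant."""


class TimescaleWarning(UserWarning):
    """A timescale-separation assumption of the reduction is strained."""


_RATE_FIELDS = (
    "k_a", "k_d1", "k_d2", "k_d3", "kl_12", "kl_13",
    "nu", "g_m", "k_p", "g_p",
)


@dataclass(frozen=True)
class RateParameters:
    """Dimensional kinetic constants of the six-state operon scheme.

    Parameters
    ----------
    k_a
        Association propensity of a cytosolic repressor to any one operator
        (s^-1); identical for O1, O2, O3 because association is
        diffusion-limited, and inclusive of the repressor copy number.
    k_d1, k_d2, k_d3
        Dissociation propensities of a singly bound repressor from O1, O2,
        O3 (s^-1).
    kl_12, kl_13
        Loop-formation propensities for the O1-O2 and O1-O3 loops (s^-1);
        formation from either anchoring operator proceeds at the same rate
        because both are driven by the same local-concentration effect.
    nu
        mRNA synthesis propensity in a transcriptionally active state (s^-1).
    g_m
        mRNA degradation propensity per molecule (s^-1).
    k_p
        Protein synthesis propensity per mRNA (s^-1).
    g_p
        Protein dilution propensity per molecule (s^-1); 1/g_p is the cell
        cycle / protein lifetime.
    has_aux_operators
        When False the scheme collapses to {FREE, B1} (the auxiliary-operator
        deletion strain); k_d2, k_d3, kl_12, kl_13 are then ignored.
    transcribing_operator
        Which auxiliary operator retains full promoter activity when singly
        bound (2 or 3; default 2, i.e. the downstream operator).
    kd1_loop, kd2_loop, kd3_loop
        Optional overrides for the within-loop contact release rates.  By
        default opening a loop by releasing operator Oi uses the same k_di as
        dissociation of a singly bound repressor from Oi, which preserves the
        detailed-balance structure of the bound subsystem.
    """

    k_a: float
    k_d1: float
    nu: float
    g_m: float
    k_p: float
    g_p: float
    k_d2: float = 0.0
    k_d3: float = 0.0
    kl_12: float = 0.0
    kl_13: float = 0.0
    has_aux_operators: bool = True
    transcribing_operator: int = 2
    kd1_loop: Optional[float] = None
    kd2_loop: Optional[float] = None
    kd3_loop: Optional[float] = None

    def loop_release_rates(self) -> tuple[float, float, float]:
        """Within-loop release rates for O1, O2, O3 contacts."""
        return (
            self.k_d1 if self.kd1_loop is None else self.kd1_loop,
            self.k_d2 if self.kd2_loop is None else self.kd2_loop,
            self.k_d3 if self.kd3_loop is None else self.kd3_loop,
        )

    def without_aux(self) -> "RateParameters":
        """The corresponding auxiliary-operator deletion strain."""
        return replace(self, has_aux_operators=False)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        return out


def validate_parameters(p: RateParameters) -> RateParameters:
    """Validate model invariants; return ``p`` unchanged if they hold.

    Raises :class:`ParameterValidationError` on a hard violation (negative
    rate, g_m <= g_p).  Emits :class:`TimescaleWarning` (never an error) when
    a timescale-separation diagnostic used by the model reduction fails.
    """
    for name in _RATE_FIELDS:
        v = getattr(p, name)
        if not math.isfinite(v):
            raise ParameterValidationError(f"{name} must be finite, got {v!r}")
        if v < 0:
            raise ParameterValidationError(f"{name} must be >= 0, got {v!r}")
    for name in ("kd1_loop", "kd2_loop", "kd3_loop"):
        v = getattr(p, name)
        if v is not None and (not math.isfinite(v) or v < 0):
            raise ParameterValidationError(f"{name} must be >= 0, got {v!r}")
    if p.g_m <= p.g_p:
        raise ParameterValidationError(
            f"fast-mRNA reduction requires g_m > g_p, got g_m={p.g_m!r}, g_p={p.g_p!r}"
        )
    if p.transcribing_operator not in (2, 3):
        raise ParameterValidationError(
            f"transcribing_operator must be 2 or 3, got {p.transcribing_operator!r}"
        )

    # advisory timescale diagnostics (quasi-steady-state validity)
    if p.g_m < 10 * p.g_p:
        warnings.warn(
            f"mRNA decay is only {p.g_m / p.g_p:.1f}x faster than protein "
            "dilution; the fast-mRNA approximation may be inaccurate",
            TimescaleWarning,
            stacklevel=2,
        )
    if p.has_aux_operators:
        slow = max(p.k_a, p.k_d1, p.nu, p.g_m)
        kl_min = min(p.kl_12, p.kl_13)
        if kl_min > 0 and kl_min < 10 * slow:
            warnings.warn(
                "loop formation is not clearly faster than the other operon "
                f"propensities (min kl = {kl_min!r}); the rapid-looping "
                "reduction may be inaccurate",
                TimescaleWarning,
                stacklevel=2,
            )
    return p


# ---------------------------------------------------------------------------
# packaged parameter sets


def load_packaged_parameters(name: str = "uninduced") -> RateParameters:
    """Load one of the packaged parameter sets by stem name.

    Available sets: ``uninduced`` (default; effective association propensity
    0.073 s^-1, calibrated against the derived-statistics checks),
    ``uninduced_invitro`` (in vitro association propensity 0.73 s^-1) and
    ``uninduced_invivo`` (in vivo estimate 0.14 s^-1 = 0.014 x 10 repressors).
    """
    from . import io  # local import to avoid a cycle

    ref = resources.files("loopburst.data").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise FileNotFoundError(f"no packaged parameter set named {name!r}")
    with resources.as_file(ref) as path:
        return io.read_params(path)


def uninduced_parameters() -> RateParameters:
    """The default uninduced parameter set, validated for self-consistency."""
    p = load_packaged_parameters("uninduced")
    check_uninduced_consistency(p)
    return p


def check_uninduced_consistency(p: RateParameters) -> None:
    """Reject a mistranscribed uninduced parameter set.

    The default set must reproduce the derived statistics it was calibrated
    against: a = 600, b = 4, l_p = 0.03, n_p = 6.9, rho ~ 0.2 and, for the
    auxiliary-operator deletion strain, f ~ 8 and l_c ~ 1.65.
    """
    from .bursts import burst_statistics
    from .reduction import effective_rates, nondimensionalize

    d = nondimensionalize(p, effective_rates(p))
    checks = []
    checks.append(("a", d.a, 600.0, 1e-9))
    checks.append(("b", d.b, 4.0, 1e-9))
    s = burst_statistics(p, strain="looping")
    checks.append(("l_p", s.l_p, 0.03, 1e-9))
    checks.append(("n_p", s.n_p, 6.9, 0.05))
    checks.append(("rho", s.rho, 0.2, 0.05))
    s0 = burst_statistics(p, strain="noaux")
    checks.append(("f_noaux", s0.f, 8.0, 0.05))
    checks.append(("l_c_noaux", s0.l_c, 1.65, 0.05))
    bad = [
        f"{name}: expected {want} +/- {tol * want if tol < 1 else tol}, got {got:.6g}"
        for name, got, want, tol in checks
        if abs(got - want) > tol * want
    ]
    if bad:
        raise ParameterValidationError(
            "uninduced parameter set fails its calibration checks:\n  "
            + "\n  ".join(bad)
        )
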