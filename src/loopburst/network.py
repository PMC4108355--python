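"""Reaction network of the full operon scheme.

The operon-state chain is reversible: every association has a dissociation,
every loop formation a loop opening.  Gene-expression channels (mRNA birth,
mRNA death, protein birth, protein death) ride on top of the operon chain;
mRNA birth fires only in the transcriptionally active states.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import RateParameters, validate_parameters

__all__ = ["OperonState", "Transition", "ReactionNetwork", "build_network"]


class OperonState(Enum):
    """Occupancy state of the operon's three operators.

    FREE: repressor-free; B1/B2/B3: repressor singly bound at O1/O2/O3;
    L12/L13: DNA-looped with the repressor bridging O1-O2 / O1-O3.  The
    O2-O3 loop is excluded as very unlikely to form.
    """

    FREE = 0
    B1 = 1
    B2 = 2
    B3 = 3
    L12 = 4
    L13 = 5


@dataclass(frozen=True)
class Transition:
    source: OperonState
    target: OperonState
    rate: float
    label: str


@dataclass(frozen=True)
class ReactionNetwork:
    """Operon-state transitions plus gene-expression channel rates."""

    params: RateParameters
    states: tuple[OperonState, ...]
    transitions: tuple[Transition, ...]
    # per-state mRNA synthesis propensity, aligned with `states`
    transcription_rates: tuple[float, ...]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, s: OperonState) -> int:
        return self.states.index(s)

    def operon_generator(self) -> np.ndarray:
        """Dense generator Q of the operon-state chain, Q[i, j] = rate i->j
        off-diagonal, columns of Q.T sum to zero (here rows sum to zero)."""
        n = self.n_states
        Q = np.zeros((n, n))
        for t in self.transitions:
            i, j = self.state_index(t.source), self.state_index(t.target)
            Q[i, j] += t.rate
        Q[np.diag_indices(n)] -= Q.sum(axis=1)
        return Q

    def is_reversible(self) -> bool:
        """Every operon transition has a reverse edge."""
        edges = {(t.source, t.target) for t in self.transitions}
        return all((b, a) in edges for (a, b) in edges)


def build_network(p: RateParameters) -> ReactionNetwork:
    """Assemble the operon-state transition list for ``p``.

    With auxiliary operators: 6 states and 14 transitions (3 association,
    3 dissociation, 4 loop formation, 4 loop opening).  Without: 2 states
    and 2 transitions.  Transcription fires in FREE and, with auxiliary
    operators, in the singly bound transcribing auxiliary state.
    """
    p = validate_parameters(p)
    S = OperonState
    if not p.has_aux_operators:
        states = (S.FREE, S.B1)
        transitions = (
            Transition(S.FREE, S.B1, p.k_a, "association O1"),
            Transition(S.B1, S.FREE, p.k_d1, "dissociation O1"),
        )
        tx = (p.nu, 0.0)
        return ReactionNetwork(p, states, transitions, tx)

    r1, r2, r3 = p.loop_release_rates()
    states = (S.FREE, S.B1, S.B2, S.B3, S.L12, S.L13)
    transitions = (
        Transition(S.FREE, S.B1, p.k_a, "association O1"),
        Transition(S.FREE, S.B2, p.k_a, "association O2"),
        Transition(S.FREE, S.B3, p.k_a, "association O3"),
        Transition(S.B1, S.FREE, p.k_d1, "dissociation O1"),
        Transition(S.B2, S.FREE, p.k_d2, "dissociation O2"),
        Transition(S.B3, S.FREE, p.k_d3, "dissociation O3"),
        Transition(S.B1, S.L12, p.kl_12, "loop O1-O2 from B1"),
        Transition(S.B2, S.L12, p.kl_12, "loop O1-O2 from B2"),
        Transition(S.B1, S.L13, p.kl_13, "loop O1-O3 from B1"),
        Transition(S.B3, S.L13, p.kl_13, "loop O1-O3 from B3"),
        Transition(S.L12, S.B1, r2, "open O1-O2, release O2"),
        Transition(S.L12, S.B2, r1, "open O1-O2, release O1"),
        Transition(S.L13, S.B1, r3, "open O1-O3, release O3"),
        Transition(S.L13, S.B3, r1, "open O1-O3, release O1"),
    )
    transcribing = S.B2 if p.transcribing_operator == 2 else S.B3
    tx = tuple(p.nu if s in (S.FREE, transcribing) else 0.0 for s in states)
    return ReactionNetwork(p, states, transitions, tx)
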