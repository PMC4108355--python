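"""Exact stochastic simulation of the full and reduced schemes.

Direct-method Gillespie simulation of independent cells, each started from
(FREE, 0 mRNA, 0 protein) and sampled at t_end (default ten protein
lifetimes, long enough for the protein count to be stationary).  Sampling
independent cells rather than one long trajectory avoids autocorrelation;
a time-average mode over a single long trajectory is provided for
cross-checking.

Each cell draws from its own counter-based RNG substream derived from
(seed, cell index), so results are bit-for-bit reproducible and enlarging
n_cells never reshuffles earlier cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .network import OperonState, build_network
from .params import RateParameters, validate_parameters
from .reduction import effective_rates

__all__ = [
    "SimulationConfig",
    "EventLog",
    "BurstCounts",
    "simulate",
    "simulate_time_average",
    "empirical_burst_counts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol for steady-state sampling of independent cells."""

    n_cells: int
    t_end: Optional[float] = None  # default: 10 protein lifetimes
    seed: int = 0
    record_events: bool = False
    model: str = "full"  # "full" | "reduced"

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.t_end is not None and self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.model not in ("full", "reduced"):
            raise ValueError("model must be 'full' or 'reduced'")


@dataclass(frozen=True)
class EventLog:
    """Per-cell dissociation-event counts and the mRNAs made in each window.

    Partial dissociations are transitions out of the transcribing loop into
    the transcribing singly bound state; the mRNAs of that window are those
    synthesized before the next operon transition (normally loop
    re-formation).  Complete dissociations are transitions from any bound
    state to FREE; their window lasts while the operon stays repressor-free.
    """

    n_partial: np.ndarray
    n_complete: np.ndarray
    mrna_partial: np.ndarray
    mrna_free: np.ndarray
    t_end: float
    g_p: float


@dataclass(frozen=True)
class BurstCounts:
    """Empirical burst statistics aggregated from an event log."""

    n_p: float  # partial dissociations per cell cycle (1/g_p)
    f: float  # complete dissociations per cell cycle
    l_p: float  # mean mRNAs per partial dissociation (nan if no events)
    l_c: float  # mean mRNAs per complete dissociation (nan if no events)


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return x, z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _next_u01(s0, s1):
    # xorshift128+; returns (s0, s1, uniform in (0, 1])
    x = s0
    y = s1
    s0 = y
    x ^= (x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    r = (s1 + y) & np.uint64(0xFFFFFFFFFFFFFFFF)
    u = (np.float64(r >> np.uint64(11)) + 1.0) * (1.0 / 9007199254740992.0)
    return s0, s1, u


@njit(cache=True)
def _run_cells(
    n_cells,
    seed,
    t_end,
    n_trans,
    trans_target,
    trans_rate,
    tx_rate,
    g_m,
    k_p,
    g_p,
    partial_src,
    partial_dst,
    record_events,
):
    proteins = np.zeros(n_cells, dtype=np.int64)
    mrnas = np.zeros(n_cells, dtype=np.int64)
    n_partial = np.zeros(n_cells, dtype=np.int64)
    n_complete = np.zeros(n_cells, dtype=np.int64)
    mrna_partial = np.zeros(n_cells, dtype=np.int64)
    mrna_free = np.zeros(n_cells, dtype=np.int64)

    for cell in range(n_cells):
        st, _ = _splitmix64(np.uint64(seed))
        st, s0 = _splitmix64(st + np.uint64(cell))
        _, s1 = _splitmix64(st ^ np.uint64(cell) * np.uint64(0xDA942042E4DD58B5))
        if s0 == np.uint64(0) and s1 == np.uint64(0):
            s1 = np.uint64(1)

        s = 0  # FREE
        m = 0
        n = 0
        t = 0.0
        in_partial = False
        in_free_burst = False  # free period that followed a complete dissociation
        while True:
            total = 0.0
            k = n_trans[s]
            for j in range(k):
                total += trans_rate[s, j]
            a_tx = tx_rate[s]
            a_md = m * g_m
            a_pb = m * k_p
            a_pd = n * g_p
            total += a_tx + a_md + a_pb + a_pd
            if total <= 0.0:
                break
            s0, s1, u = _next_u01(s0, s1)
            t += -np.log(u) / total
            if t > t_end:
                break
            s0, s1, u = _next_u01(s0, s1)
            r = u * total
            hit = False
            for j in range(k):
                r -= trans_rate[s, j]
                if r <= 0.0:
                    s_new = trans_target[s, j]
                    if record_events:
                        if s == partial_src and s_new == partial_dst:
                            n_partial[cell] += 1
                            in_partial = True
                        else:
                            in_partial = False
                        if s_new == 0 and s != 0:
                            n_complete[cell] += 1
                            in_free_burst = True
                        elif s_new != 0:
                            in_free_burst = False
                    s = s_new
                    hit = True
                    break
            if hit:
                continue
            r -= a_tx
            if r <= 0.0:
                m += 1
                if record_events:
                    if in_partial:
                        mrna_partial[cell] += 1
                    if in_free_burst:
                        mrna_free[cell] += 1
                continue
            r -= a_md
            if r <= 0.0:
                m -= 1
                continue
            r -= a_pb
            if r <= 0.0:
                n += 1
                continue
            n -= 1
        proteins[cell] = n
        mrnas[cell] = m
    return proteins, mrnas, n_partial, n_complete, mrna_partial, mrna_free


@njit(cache=True)
def _run_time_average(
    seed,
    t_total,
    burn_in,
    n_trans,
    trans_target,
    trans_rate,
    tx_rate,
    g_m,
    k_p,
    g_p,
    hist_size,
):
    hist = np.zeros(hist_size)
    st, _ = _splitmix64(np.uint64(seed))
    st, s0 = _splitmix64(st + np.uint64(0x5DEECE66D))
    _, s1 = _splitmix64(st)
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(1)
    s = 0
    m = 0
    n = 0
    t = 0.0
    while t < t_total:
        total = 0.0
        k = n_trans[s]
        for j in range(k):
            total += trans_rate[s, j]
        a_tx = tx_rate[s]
        a_md = m * g_m
        a_pb = m * k_p
        a_pd = n * g_p
        total += a_tx + a_md + a_pb + a_pd
        if total <= 0.0:
            if t > burn_in and n < hist_size:
                hist[n] += t_total - max(t, burn_in)
            break
        s0, s1, u = _next_u01(s0, s1)
        dt = -np.log(u) / total
        t_new = min(t + dt, t_total)
        if t_new > burn_in and n < hist_size:
            hist[n] += t_new - max(t, burn_in)
        t = t + dt
        if t >= t_total:
            break
        s0, s1, u = _next_u01(s0, s1)
        r = u * total
        hit = False
        for j in range(k):
            r -= trans_rate[s, j]
            if r <= 0.0:
                s = trans_target[s, j]
                hit = True
                break
        if hit:
            continue
        r -= a_tx
        if r <= 0.0:
            m += 1
            continue
        r -= a_md
        if r <= 0.0:
            m -= 1
            continue
        r -= a_pb
        if r <= 0.0:
            n += 1
            continue
        n -= 1
    tot = hist.sum()
    if tot > 0:
        hist /= tot
    return hist


# ---------------------------------------------------------------------------
# transition tables


def _full_tables(p: RateParameters):
    net = build_network(p)
    S = net.n_states
    max_k = 4
    n_trans = np.zeros(S, dtype=np.int64)
    trans_target = np.zeros((S, max_k), dtype=np.int64)
    trans_rate = np.zeros((S, max_k))
    for tr in net.transitions:
        i = net.state_index(tr.source)
        j = net.state_index(tr.target)
        k = n_trans[i]
        trans_target[i, k] = j
        trans_rate[i, k] = tr.rate
        n_trans[i] = k + 1
    tx = np.array(net.transcription_rates)
    if p.has_aux_operators:
        loop = OperonState.L12 if p.transcribing_operator == 2 else OperonState.L13
        bound = OperonState.B2 if p.transcribing_operator == 2 else OperonState.B3
        partial = (net.state_index(loop), net.state_index(bound))
    else:
        partial = (-1, -1)
    return n_trans, trans_target, trans_rate, tx, partial


def _reduced_tables(p: RateParameters):
    red = effective_rates(p)
    n_trans = np.array([1, 1], dtype=np.int64)
    trans_target = np.array([[1, 0], [0, 0]], dtype=np.int64)
    trans_rate = np.array([[red.kappa_b, 0.0], [red.kappa_f, 0.0]])
    tx = np.array([p.nu, red.nu_bound])
    return n_trans, trans_target, trans_rate, tx, (-1, -1)


# ---------------------------------------------------------------------------
# public API


def simulate(
    p: RateParameters, cfg: SimulationConfig
) -> tuple[np.ndarray, Optional[EventLog]]:
    """Simulate ``cfg.n_cells`` independent cells; return the protein count
    of each cell at t_end and, when requested, the dissociation event log."""
    p = validate_parameters(p)
    t_end = cfg.t_end if cfg.t_end is not None else 10.0 / p.g_p
    if t_end < 3.0 / p.g_p:
        warnings.warn(
            f"t_end = {t_end:.3g} is shorter than 3 protein lifetimes; the "
            "sampled distribution may not be stationary",
            stacklevel=2,
        )
    if cfg.model == "full":
        n_trans, tt, tr, tx, partial = _full_tables(p)
    else:
        n_trans, tt, tr, tx, partial = _reduced_tables(p)
    out = _run_cells(
        cfg.n_cells,
        np.uint64(cfg.seed),
        float(t_end),
        n_trans,
        tt,
        tr,
        tx,
        p.g_m,
        p.k_p,
        p.g_p,
        partial[0],
        partial[1],
        cfg.record_events,
    )
    proteins, _, n_p, n_c, m_p, m_f = out
    log = None
    if cfg.record_events:
        log = EventLog(n_p, n_c, m_p, m_f, t_end, p.g_p)
    return proteins, log


def simulate_time_average(
    p: RateParameters,
    t_total: float,
    seed: int = 0,
    burn_in: Optional[float] = None,
    model: str = "full",
    hist_size: int = 4096,
) -> np.ndarray:
    """Protein occupancy histogram from one long trajectory (cross-check for
    the independent-cells protocol)."""
    p = validate_parameters(p)
    if burn_in is None:
        burn_in = 10.0 / p.g_p
    if t_total <= burn_in:
        raise ValueError("t_total must exceed burn_in")
    if model == "full":
        n_trans, tt, tr, tx, _ = _full_tables(p)
    else:
        n_trans, tt, tr, tx, _ = _reduced_tables(p)
    return _run_time_average(
        np.uint64(seed),
        float(t_total),
        float(burn_in),
        n_trans,
        tt,
        tr,
        tx,
        p.g_m,
        p.k_p,
        p.g_p,
        hist_size,
    )


def empirical_burst_counts(log: EventLog, p: RateParameters) -> BurstCounts:
    """Aggregate an event log into per-cell-cycle burst statistics.

    Frequencies are normalized per protein lifetime 1/g_p (the cell cycle);
    burst sizes are the mean mRNAs synthesized per event window.  With zero
    events of a kind the frequency is 0 and the size NaN (with a warning).
    """
    cycles = log.n_partial.size * log.t_end * p.g_p
    tot_p = int(log.n_partial.sum())
    tot_c = int(log.n_complete.sum())
    n_p = tot_p / cycles
    f = tot_c / cycles
    if tot_p == 0:
        if p.has_aux_operators:
            warnings.warn("no partial dissociations recorded; l_p undefined",
                          stacklevel=2)
        l_p = float("nan")
    else:
        l_p = log.mrna_partial.sum() / tot_p
    if tot_c == 0:
        warnings.warn("no complete dissociations recorded; l_c undefined",
                      stacklevel=2)
        l_c = float("nan")
    else:
        l_c = log.mrna_free.sum() / tot_c
    return BurstCounts(n_p, f, float(l_p), float(l_c))
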