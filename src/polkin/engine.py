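"""Gillespie simulation and exact stationary analysis of the transcription cycle.

The chain is enumerated once (see :mod:`polkin.kinetics`); simulation then
reduces to a generic continuous-time jump process over the state index.  The
direct-method Gillespie kernel (two uniforms per event) is numba-compiled and
accumulates, per gene, the time-weighted occupancy of every compartment over
the measurement window.  Population means are averages over independent
per-gene trajectories whose RNG streams derive from the master seed and the
gene index, so results do not depend on execution order.

``ctmc_stationary_occupancy`` is the independent exact oracle: it solves
pi Q = 0 on the set of states reachable from the initial condition and
converts the stationary distribution into per-compartment occupancies.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from .kinetics import (
    GeneArchitecture,
    RateSet,
    SimulationConfig,
    TranscriptionState,
    TransitionTable,
    _iter_transitions,
    list_transitions,
    transition_table,
)

__all__ = [
    "OccupancyProfile",
    "simulate_gene",
    "simulate_population",
    "simulate_chain",
    "ctmc_stationary_occupancy",
    "stationary_distribution",
    "iterate_trajectory",
    "StateSpaceCapError",
    "ReducibleChainError",
]


class StateSpaceCapError(ValueError):
    """The architecture's state space exceeds the enumeration cap."""


class ReducibleChainError(ValueError):
    """The reachable chain has more than one closed communicating class."""


@dataclass(frozen=True)
class OccupancyProfile:
    """Time-averaged occupancy of each compartment with Monte-Carlo errors.

    ``mean[i]`` is the fraction of the measurement window compartment
    ``labels[i]`` was occupied, averaged over ``n_genes`` independent gene
    trajectories; ``se`` is the standard error of that mean (NaN at
    ``n_genes == 1``).  ``recruitments``, ``initiations`` and ``terminations``
    (= mRNAs produced) count events over the *full* run, summed over genes.
    """

    labels: tuple[str, ...]
    mean: np.ndarray
    se: np.ndarray
    n_genes: int
    window: tuple[float, float]
    recruitments: int = 0
    initiations: int = 0
    terminations: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        if np.any(self.mean < -1e-12) or np.any(self.mean > 1 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.se[np.isfinite(self.se)] < 0):
            raise ValueError("standard errors must be >= 0")

    def __getitem__(self, label: str) -> float:
        return float(self.mean[self.labels.index(label)])

    def se_of(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"compartment": self.labels, "occupancy": self.mean, "se": self.se})

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df["n_genes"] = self.n_genes
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


@njit(cache=True)
def _gillespie_kernel(indptr, targets, prop, total, occ, eclass, s0, t_total, w0, w1, seeds):
    """Direct-method Gillespie over the enumerated chain, one gene per seed.

    Returns per-compartment sums and sums of squares of window-averaged
    occupancy across genes, plus event tallies
    ``[n_events, recruitments, initiations, terminations]``.
    """
    ncomp = occ.shape[1]
    n = seeds.size
    wlen = w1 - w0
    sum_occ = np.zeros(ncomp)
    sum_sq = np.zeros(ncomp)
    counts = np.zeros(4, dtype=np.int64)
    occ_g = np.zeros(ncomp)
    for g in range(n):
        np.random.seed(seeds[g])
        t = 0.0
        s = s0
        for c in range(ncomp):
            occ_g[c] = 0.0
        while True:
            r_tot = total[s]
            if r_tot <= 0.0:
                t_next = t_total  # absorbing: fast-forward the clock
            else:
                t_next = t - np.log(np.random.random()) / r_tot
            a = t if t > w0 else w0
            b = t_next if t_next < w1 else w1
            if b > a:
                for c in range(ncomp):
                    if occ[s, c]:
                        occ_g[c] += b - a
            if r_tot <= 0.0 or t_next >= t_total:
                break
            r = np.random.random() * r_tot
            k = indptr[s]
            last = indptr[s + 1] - 1
            acc = prop[k]
            while acc < r and k < last:
                k += 1
                acc += prop[k]
            counts[0] += 1
            ec = eclass[k]
            if ec > 0:
                counts[ec] += 1
            s = targets[k]
            t = t_next
        for c in range(ncomp):
            o = occ_g[c] / wlen
            sum_occ[c] += o
            sum_sq[c] += o * o
    return sum_occ, sum_sq, counts


def _gene_seeds(master_seed: int, n_genes: int) -> np.ndarray:
    """Deterministic per-gene RNG seeds: word *i* of the master stream."""
    state = np.random.SeedSequence(master_seed).generate_state(n_genes, dtype=np.uint32)
    return state.astype(np.int64)


def simulate_chain(
    indptr: np.ndarray,
    targets: np.ndarray,
    prop: np.ndarray,
    total: np.ndarray,
    eclass: np.ndarray,
    occ: np.ndarray,
    labels: tuple[str, ...],
    s0: int,
    cfg: SimulationConfig,
) -> OccupancyProfile:
    """Simulate ``cfg.n_genes`` independent genes of an enumerated chain."""
    seeds = _gene_seeds(cfg.seed, cfg.n_genes)
    w0, w1 = cfg.measure_window
    sum_occ, sum_sq, counts = _gillespie_kernel(
        indptr, targets, prop, total, occ, eclass,
        np.int64(s0), float(cfg.t_total), float(w0), float(w1), seeds,
    )
    n = cfg.n_genes
    mean = sum_occ / n
    if n > 1:
        var = np.maximum(sum_sq - n * mean**2, 0.0) / (n - 1)
        se = np.sqrt(var / n)
    else:
        se = np.full_like(mean, np.nan)
    return OccupancyProfile(
        labels=labels,
        mean=np.clip(mean, 0.0, 1.0),
        se=se,
        n_genes=n,
        window=(w0, w1),
        recruitments=int(counts[1]),
        initiations=int(counts[2]),
        terminations=int(counts[3]),
        n_events=int(counts[0]),
    )


def _prepared(rates: RateSet, arch: GeneArchitecture, cfg: SimulationConfig):
    table = transition_table(arch, rates.gene_class)
    indptr, targets, prop, total, eclass = table.compressed(rates)
    init = cfg.initial_state or TranscriptionState.empty(arch)
    s0 = init.to_index(arch)
    return table, indptr, targets, prop, total, eclass, s0


def simulate_population(
    rates: RateSet, arch: GeneArchitecture, cfg: SimulationConfig
) -> OccupancyProfile:
    """Population-averaged occupancy over ``cfg.n_genes`` independent genes."""
    table, indptr, targets, prop, total, eclass, s0 = _prepared(rates, arch, cfg)
    return simulate_chain(indptr, targets, prop, total, eclass,
                          table.occupancy, table.labels, s0, cfg)


def simulate_gene(
    rates: RateSet, arch: GeneArchitecture, cfg: SimulationConfig, seed: int | None = None
) -> OccupancyProfile:
    """Single-gene occupancy record and event counts (reproducible from seed)."""
    one = SimulationConfig(
        t_total=cfg.t_total,
        measure_window=cfg.measure_window,
        n_genes=1,
        seed=cfg.seed if seed is None else seed,
        initial_state=cfg.initial_state,
    )
    return simulate_population(rates, arch, one)


def iterate_trajectory(
    rates: RateSet,
    arch: GeneArchitecture,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Pure-Python trajectory generator built directly on ``list_transitions``.

    Yields ``(event_time, event_label)`` tuples for one gene.  Used for
    trajectory dumps and as a structural cross-check of the compiled kernel.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    state = cfg.initial_state or TranscriptionState.empty(arch)
    t = 0.0
    while True:
        trans = list_transitions(state, rates, arch)
        if not trans:
            return
        events = sorted(trans)
        props = np.array([trans[e] for e in events])
        r_tot = props.sum()
        t += -np.log(rng.random()) / r_tot
        if t >= cfg.t_total:
            return
        pick = events[int(np.searchsorted(np.cumsum(props), rng.random() * r_tot))]
        idx = state.to_index(arch)
        for event, _rate, tgt, _ec in _iter_transitions(idx, arch, rates.gene_class):
            if event == pick:
                state = TranscriptionState.from_index(tgt, arch, clock=t)
                break
        yield t, pick


def dump_trajectory(path, rates: RateSet, arch: GeneArchitecture,
                    cfg: SimulationConfig) -> int:
    """Write one gene's event sequence (time, event label) as TSV; returns count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("time_s\tevent\n")
        for t, event in iterate_trajectory(rates, arch, cfg):
            fh.write(f"{t:.6f}\t{event}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------

def _reachable(indptr, targets, prop, s0: int) -> np.ndarray:
    seen = np.zeros(len(indptr) - 1, dtype=bool)
    seen[s0] = True
    queue = deque([s0])
    while queue:
        s = queue.popleft()
        for k in range(indptr[s], indptr[s + 1]):
            if prop[k] > 0 and not seen[targets[k]]:
                seen[targets[k]] = True
                queue.append(targets[k])
    return np.flatnonzero(seen)


def stationary_distribution(
    rates: RateSet,
    arch: GeneArchitecture,
    initial_state: TranscriptionState | None = None,
    state_cap: int = 100_000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, TransitionTable]:
    """Exact stationary distribution of the chain reachable from the start.

    Returns ``(states, pi, table)`` where ``states`` are global state indices
    of the closed communicating class and ``pi`` the stationary probabilities
    (summing to 1 within ``tol``).  Raises :class:`StateSpaceCapError` when
    the architecture would need more than ``state_cap`` states, and
    :class:`ReducibleChainError` when the reachable chain contains several
    closed classes (the stationary distribution is then not unique).
    """
    if arch.n_states > state_cap:
        raise StateSpaceCapError(
            f"architecture needs {arch.n_states} states, cap is {state_cap}; "
            f"raise state_cap to at least {arch.n_states}"
        )
    table = transition_table(arch, rates.gene_class)
    prop = table.propensities(rates)
    init = initial_state or TranscriptionState.empty(arch)
    s0 = init.to_index(arch)
    reach = _reachable(table.indptr, table.targets, prop, s0)
    local = -np.ones(table.n_states, dtype=np.int64)
    local[reach] = np.arange(len(reach))

    src = np.repeat(np.arange(table.n_states), np.diff(table.indptr))
    keep = (prop > 0) & (local[src] >= 0)
    rows = local[src[keep]]
    cols = local[table.targets[keep]]
    vals = prop[keep]
    m = len(reach)
    rate_mat = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))

    n_comp, labels_cc = sp.csgraph.connected_components(rate_mat, directed=True, connection="strong")
    # Closed classes: strongly connected components with no outgoing edge.
    out_class = labels_cc[rate_mat.indices]
    src_class = np.repeat(labels_cc, np.diff(rate_mat.indptr))
    open_classes = np.unique(src_class[out_class != src_class])
    closed = np.setdiff1d(np.arange(n_comp), open_classes)
    if len(closed) != 1:
        raise ReducibleChainError(
            f"reachable chain has {len(closed)} closed communicating classes"
        )
    members = np.flatnonzero(labels_cc == closed[0])
    sub = rate_mat[members][:, members].tocsr()
    exit_rates = np.asarray(sub.sum(axis=1)).ravel()
    q_t = (sub.T - sp.diags(exit_rates)).tocsr()
    # Replace one balance equation with the normalisation constraint.
    nm = len(members)
    a = sp.vstack([q_t[:-1], sp.csr_matrix(np.ones((1, nm)))]).tocsc()
    b = np.zeros(nm)
    b[-1] = 1.0
    pi = spla.spsolve(a, b)
    pi = np.where(np.abs(pi) < 1e-15, 0.0, pi)
    if pi.min() < -1e-9 or abs(pi.sum() - 1.0) > tol:
        raise ArithmeticError("stationary solve failed normalisation check")
    return reach[members], pi, table


def ctmc_stationary_occupancy(
    rates: RateSet,
    arch: GeneArchitecture,
    initial_state: TranscriptionState | None = None,
    state_cap: int = 100_000,
) -> OccupancyProfile:
    """Exact per-compartment stationary occupancy (the verification oracle)."""
    states, pi, table = stationary_distribution(rates, arch, initial_state, state_cap)
    occ = pi @ table.occupancy[states].astype(float)
    return OccupancyProfile(
        labels=table.labels,
        mean=np.clip(occ, 0.0, 1.0),
        se=np.zeros_like(occ),
        n_genes=0,
        window=(np.inf, np.inf),
    )
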