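"""Domain types and transition structure of the transcription-cycle Markov chain.

The transcription cycle is modelled as a continuous-time Markov chain over a
small lattice of 120 bp compartments: an optional UAS (enhancer), a promoter
with three sub-states (empty, polymerase awaiting TFIIH, polymerase after
TFIIH arrival), N identical transcript bins, and a terminator.  Every step is
a Poisson process; hard-core exclusion forbids two polymerases in one
compartment, so any move whose target compartment is occupied simply has zero
propensity (it is absent from the transition set, not rejection-sampled).

Two gene classes are supported.  STM genes recruit RNAPII exclusively through
the UAS (rates k1/k-1, transfer k2/k-2); TFO genes recruit directly to the
promoter (k3).  Dissociation from the promoter (k-3) is possible only until
TFIIH arrives (k4); TFIIH arrival is the committed step, after which
initiation (k5), elongation hops (k6), and terminator release (k7) are
irreversible.

The module enumerates the full state space once and exposes it as a CSR-style
:class:`TransitionTable`.  Both the stochastic engine and the exact
stationary-distribution oracle consume this table, so the transition
structure has a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator

import numpy as np

__all__ = [
    "RateSet",
    "GeneArchitecture",
    "TranscriptionState",
    "SimulationConfig",
    "TransitionTable",
    "InconsistentStateError",
    "list_transitions",
    "hop_rate",
    "transition_table",
    "PROMOTER_EMPTY",
    "PROMOTER_PRE_TFIIH",
    "PROMOTER_POST_TFIIH",
]

# Promoter sub-states.
PROMOTER_EMPTY = "EMPTY"
PROMOTER_PRE_TFIIH = "POL_PRE_TFIIH"
PROMOTER_POST_TFIIH = "POL_POST_TFIIH"
_PROMOTER_STATES = (PROMOTER_EMPTY, PROMOTER_PRE_TFIIH, PROMOTER_POST_TFIIH)

# Event classes used for tallies in the simulator.
EVENT_OTHER = 0
EVENT_RECRUIT = 1
EVENT_INITIATE = 2
EVENT_TERMINATE = 3

#: Names of the rate constants as they appear in propensities.  ``hop`` is the
#: per-compartment elongation rate derived from k6.
RATE_NAMES = ("k1", "k_rev1", "k2", "k_rev2", "k3", "k_rev3", "k4", "k5", "hop", "k7")


class InconsistentStateError(ValueError):
    """A state is incompatible with the architecture or gene class."""


def hop_rate(k6_bp_per_min: float, compartment_length: float) -> float:
    """Per-second hop rate between adjacent compartments.

    Elongation is quoted in bp/min (e.g. 1 kb/min); a polymerase crosses one
    ``compartment_length`` bp compartment at ``(k6/60)/L`` per second.
    """
    if not (k6_bp_per_min > 0 and compartment_length > 0):
        raise ValueError(
            "elongation rate and compartment length must be positive, got "
            f"{k6_bp_per_min!r} bp/min over {compartment_length!r} bp"
        )
    return (k6_bp_per_min / 60.0) / compartment_length


@dataclass(frozen=True)
class RateSet:
    """The ten transcription-cycle rate constants for one gene class.

    All first-order rates are in /s.  ``k6`` is stored in bp/s; use
    :meth:`with_elongation` (or the ``k6_bp_per_min`` argument of
    :meth:`create`) to supply the literature unit of bp/min.
    """

    k1: float = 0.0        # UAS association (STM)
    k_rev1: float = 0.0    # UAS dissociation (STM)
    k2: float = 0.0        # UAS -> promoter transfer (STM)
    k_rev2: float = 0.0    # promoter -> UAS reversal (STM, pre-TFIIH only)
    k3: float = 0.0        # direct promoter recruitment (TFO)
    k_rev3: float = 0.0    # promoter dissociation (pre-TFIIH only)
    k4: float = 0.0        # TFIIH recruitment (committed step)
    k5: float = 0.0        # initiation / promoter escape
    k6: float = 1000.0 / 60.0  # elongation, bp per SECOND
    k7: float = 0.0        # terminator release
    gene_class: str = "TFO"

    def __post_init__(self) -> None:
        if self.gene_class not in ("STM", "TFO"):
            raise ValueError(f"gene_class must be 'STM' or 'TFO', got {self.gene_class!r}")
        for name in ("k1", "k_rev1", "k2", "k_rev2", "k3", "k_rev3", "k4", "k5", "k6", "k7"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v!r}")
        # Unused rates are forced to zero so that equal parameterisations
        # compare equal regardless of how the unused fields were filled in.
        if self.gene_class == "TFO":
            for name in ("k1", "k_rev1", "k2", "k_rev2"):
                if getattr(self, name) != 0.0:
                    object.__setattr__(self, name, 0.0)
        else:  # STM: recruitment is exclusively via the UAS
            if self.k3 != 0.0:
                object.__setattr__(self, "k3", 0.0)

    @classmethod
    def create(cls, gene_class: str, *, k6_bp_per_min: float = 1000.0, **rates: float) -> "RateSet":
        """Build a rate set with elongation given in bp/min (the field unit)."""
        return cls(gene_class=gene_class, k6=k6_bp_per_min / 60.0, **rates)

    def with_elongation(self, k6_bp_per_min: float) -> "RateSet":
        return replace(self, k6=k6_bp_per_min / 60.0)

    def replace(self, **changes: float) -> "RateSet":
        unknown = set(changes) - {f for f in RATE_NAMES if f != "hop"} - {"k6"}
        if unknown:
            raise ValueError(f"unknown rate name(s): {sorted(unknown)}")
        return replace(self, **changes)

    def values(self, arch: "GeneArchitecture") -> np.ndarray:
        """Numeric rate per entry of :data:`RATE_NAMES` (hop derived from k6)."""
        out = np.array(
            [self.k1, self.k_rev1, self.k2, self.k_rev2, self.k3,
             self.k_rev3, self.k4, self.k5, self.k6 / arch.compartment_length, self.k7]
        )
        return out


@dataclass(frozen=True)
class GeneArchitecture:
    """Compartment layout of the model gene.

    Defaults give the canonical 1.2 kb yeast gene: ten 120 bp transcript bins
    flanked by single 120 bp promoter/terminator compartments (plus a UAS
    compartment for STM genes).
    """

    compartment_length: int = 120
    n_transcript_bins: int = 10
    has_uas: bool = False
    has_terminator: bool = True

    def __post_init__(self) -> None:
        if self.compartment_length <= 0:
            raise ValueError("compartment_length must be > 0")
        if self.n_transcript_bins < 1:
            raise ValueError("n_transcript_bins must be >= 1")

    @property
    def transcript_length(self) -> int:
        return self.n_transcript_bins * self.compartment_length

    @property
    def labels(self) -> tuple[str, ...]:
        out = (["UAS"] if self.has_uas else []) + ["promoter"]
        out += [f"bin_{i}" for i in range(1, self.n_transcript_bins + 1)]
        if self.has_terminator:
            out.append("terminator")
        return tuple(out)

    @property
    def n_flags(self) -> int:
        """Binary occupancy flags besides the 3-way promoter sub-state."""
        return int(self.has_uas) + self.n_transcript_bins + int(self.has_terminator)

    @property
    def n_states(self) -> int:
        return 3 * (1 << self.n_flags)

    def validate_class(self, gene_class: str) -> None:
        if gene_class == "STM" and not self.has_uas:
            raise InconsistentStateError("STM genes require an architecture with a UAS")
        if gene_class == "TFO" and self.has_uas:
            raise InconsistentStateError("TFO genes have no UAS compartment")


@dataclass(frozen=True)
class TranscriptionState:
    """One configuration of polymerases on the gene."""

    promoter_state: str = PROMOTER_EMPTY
    uas_occupied: bool = False
    transcript_occupancy: tuple[bool, ...] = ()
    terminator_occupied: bool = False
    clock: float = 0.0

    def __post_init__(self) -> None:
        if self.promoter_state not in _PROMOTER_STATES:
            raise InconsistentStateError(f"unknown promoter state {self.promoter_state!r}")

    def validate(self, arch: GeneArchitecture) -> None:
        if self.uas_occupied and not arch.has_uas:
            raise InconsistentStateError("UAS flag set on an architecture without a UAS")
        if len(self.transcript_occupancy) != arch.n_transcript_bins:
            raise InconsistentStateError(
                f"state has {len(self.transcript_occupancy)} transcript bins, "
                f"architecture has {arch.n_transcript_bins}"
            )
        if self.terminator_occupied and not arch.has_terminator:
            raise InconsistentStateError("terminator flag set without a terminator compartment")

    # -- integer encoding ---------------------------------------------------
    def to_index(self, arch: GeneArchitecture) -> int:
        self.validate(arch)
        bits = 0
        pos = 0
        if arch.has_uas:
            bits |= int(self.uas_occupied) << pos
            pos += 1
        for occ in self.transcript_occupancy:
            bits |= int(occ) << pos
            pos += 1
        if arch.has_terminator:
            bits |= int(self.terminator_occupied) << pos
        return _PROMOTER_STATES.index(self.promoter_state) + 3 * bits

    @classmethod
    def from_index(cls, idx: int, arch: GeneArchitecture, clock: float = 0.0) -> "TranscriptionState":
        p, bits = idx % 3, idx // 3
        pos = 0
        uas = False
        if arch.has_uas:
            uas = bool(bits >> pos & 1)
            pos += 1
        transcript = tuple(bool(bits >> (pos + i) & 1) for i in range(arch.n_transcript_bins))
        pos += arch.n_transcript_bins
        term = bool(bits >> pos & 1) if arch.has_terminator else False
        return cls(_PROMOTER_STATES[p], uas, transcript, term, clock)

    @classmethod
    def empty(cls, arch: GeneArchitecture) -> "TranscriptionState":
        return cls(transcript_occupancy=(False,) * arch.n_transcript_bins)


@dataclass(frozen=True)
class SimulationConfig:
    """Run-length, measurement window, and replication settings."""

    t_total: float = 1000.0
    measure_window: tuple[float, float] = (940.0, 1000.0)
    n_genes: int = 100_000
    seed: int = 0
    initial_state: TranscriptionState | None = None  # default: all empty

    def __post_init__(self) -> None:
        w0, w1 = self.measure_window
        if not (0.0 <= w0 < w1 <= self.t_total):
            raise ValueError(
                f"measure_window {self.measure_window} must lie inside [0, {self.t_total}]"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


# ---------------------------------------------------------------------------
# Transition enumeration
# ---------------------------------------------------------------------------

def _iter_transitions(idx: int, arch: GeneArchitecture, gene_class: str) -> Iterator[tuple[str, str, int, int]]:
    """Yield ``(event_label, rate_name, target_index, event_class)`` from state ``idx``.

    This generator is the single definition of the transition structure; both
    :func:`list_transitions` and :func:`transition_table` are built from it.
    Exclusion is structural: moves into occupied compartments are never
    yielded.
    """
    p, bits = idx % 3, idx // 3
    pos = 0
    uas_bit = -1
    if arch.has_uas:
        uas_bit = pos
        pos += 1
    bin_bits = list(range(pos, pos + arch.n_transcript_bins))
    pos += arch.n_transcript_bins
    term_bit = pos if arch.has_terminator else -1

    def occupied(b: int) -> bool:
        return bool(bits >> b & 1)

    def mk(p_new: int, bits_new: int) -> int:
        return p_new + 3 * bits_new

    if gene_class == "STM":
        if not occupied(uas_bit):
            yield "uas_recruit", "k1", mk(p, bits | 1 << uas_bit), EVENT_RECRUIT
        else:
            yield "uas_dissociate", "k_rev1", mk(p, bits & ~(1 << uas_bit)), EVENT_OTHER
            if p == 0:  # promoter empty: transfer UAS -> promoter
                yield "transfer", "k2", mk(1, bits & ~(1 << uas_bit)), EVENT_OTHER
        if p == 1 and not occupied(uas_bit):  # pre-TFIIH polymerase may reverse
            yield "reverse_transfer", "k_rev2", mk(0, bits | 1 << uas_bit), EVENT_OTHER
    else:  # TFO: direct promoter recruitment
        if p == 0:
            yield "promoter_recruit", "k3", mk(1, bits), EVENT_RECRUIT

    if p == 1:
        yield "promoter_dissociate", "k_rev3", mk(0, bits), EVENT_OTHER
        yield "tfiih_arrival", "k4", mk(2, bits), EVENT_OTHER
    if p == 2 and not occupied(bin_bits[0]):
        yield "initiate", "k5", mk(0, bits | 1 << bin_bits[0]), EVENT_INITIATE
    for i in range(arch.n_transcript_bins - 1):
        if occupied(bin_bits[i]) and not occupied(bin_bits[i + 1]):
            tgt = (bits & ~(1 << bin_bits[i])) | 1 << bin_bits[i + 1]
            yield f"hop_{i + 1}", "hop", mk(p, tgt), EVENT_OTHER
    last = bin_bits[-1]
    if occupied(last):
        if arch.has_terminator:
            if not occupied(term_bit):
                tgt = (bits & ~(1 << last)) | 1 << term_bit
                yield f"hop_{arch.n_transcript_bins}", "hop", mk(p, tgt), EVENT_OTHER
        else:
            yield "terminate", "k7", mk(p, bits & ~(1 << last)), EVENT_TERMINATE
    if arch.has_terminator and occupied(term_bit):
        yield "terminate", "k7", mk(p, bits & ~(1 << term_bit)), EVENT_TERMINATE


def list_transitions(
    state: TranscriptionState, rates: RateSet, arch: GeneArchitecture
) -> dict[str, float]:
    """Available events from ``state`` with their propensities (/s).

    Blocked moves (target compartment occupied) and zero-rate events are
    absent.  Raises :class:`InconsistentStateError` for state/architecture or
    rates/architecture mismatches, which is distinct from returning an empty
    set (an absorbing state).
    """
    arch.validate_class(rates.gene_class)
    idx = state.to_index(arch)
    vals = dict(zip(RATE_NAMES, rates.values(arch)))
    out: dict[str, float] = {}
    for event, rate_name, _tgt, _cls in _iter_transitions(idx, arch, rates.gene_class):
        k = vals[rate_name]
        if k > 0:
            out[event] = k
    return out


@dataclass(frozen=True)
class TransitionTable:
    """The enumerated chain in CSR form, shared by simulator and oracle.

    ``indptr``/``targets``/``rate_codes`` describe, for every state, its
    outgoing transitions; ``rate_codes`` indexes :data:`RATE_NAMES` so one
    structure serves every numeric rate set of the same gene class.
    ``occupancy[s, c]`` is 1 when compartment ``c`` (ordered as
    ``arch.labels``) is occupied in state ``s``; the promoter column counts
    both pre- and post-TFIIH sub-states.
    """

    arch: GeneArchitecture
    gene_class: str
    indptr: np.ndarray
    targets: np.ndarray
    rate_codes: np.ndarray
    event_classes: np.ndarray
    occupancy: np.ndarray
    labels: tuple[str, ...] = field(default=())

    @property
    def n_states(self) -> int:
        return len(self.indptr) - 1

    def propensities(self, rates: RateSet) -> np.ndarray:
        """Propensity of every structural transition under ``rates``."""
        if rates.gene_class != self.gene_class:
            raise InconsistentStateError(
                f"rates are for {rates.gene_class}, table for {self.gene_class}"
            )
        return rates.values(self.arch)[self.rate_codes]

    def compressed(self, rates: RateSet):
        """CSR arrays with zero-propensity transitions dropped.

        Returns ``(indptr, targets, prop, total, event_classes)`` ready for
        the Gillespie kernel.
        """
        prop = self.propensities(rates)
        keep = prop > 0
        state_of = np.repeat(np.arange(self.n_states), np.diff(self.indptr))
        counts = np.bincount(state_of[keep], minlength=self.n_states)
        indptr = np.zeros(self.n_states + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        total = np.zeros(self.n_states)
        np.add.at(total, state_of, prop)
        return (
            indptr,
            self.targets[keep].astype(np.int64),
            prop[keep],
            total,
            self.event_classes[keep].astype(np.int64),
        )


@lru_cache(maxsize=64)
def transition_table(arch: GeneArchitecture, gene_class: str) -> TransitionTable:
    """Enumerate the full state space of ``arch`` for ``gene_class``."""
    arch.validate_class(gene_class)
    n_states = arch.n_states
    indptr = [0]
    targets: list[int] = []
    codes: list[int] = []
    eclasses: list[int] = []
    rate_index = {name: i for i, name in enumerate(RATE_NAMES)}
    for idx in range(n_states):
        for _event, rate_name, tgt, ec in _iter_transitions(idx, arch, gene_class):
            targets.append(tgt)
            codes.append(rate_index[rate_name])
            eclasses.append(ec)
        indptr.append(len(targets))

    labels = arch.labels
    occ = np.zeros((n_states, len(labels)), dtype=np.uint8)
    for idx in range(n_states):
        p, bits = idx % 3, idx // 3
        col = 0
        pos = 0
        if arch.has_uas:
            occ[idx, col] = bits >> pos & 1
            col += 1
            pos += 1
        occ[idx, col] = 1 if p > 0 else 0  # promoter: pre or post TFIIH
        col += 1
        for i in range(arch.n_transcript_bins):
            occ[idx, col] = bits >> (pos + i) & 1
            col += 1
        pos += arch.n_transcript_bins
        if arch.has_terminator:
            occ[idx, col] = bits >> pos & 1

    table = TransitionTable(
        arch=arch,
        gene_class=gene_class,
        indptr=np.asarray(indptr, dtype=np.int64),
        targets=np.asarray(targets, dtype=np.int64),
        rate_codes=np.asarray(codes, dtype=np.int64),
        event_classes=np.asarray(eclasses, dtype=np.int64),
        occupancy=occ,
        labels=labels,
    )
    _assert_exclusion(table)
    return table


def _assert_exclusion(table: TransitionTable) -> None:
    """Hard assertion that no transition creates a double occupancy.

    The binary encoding makes two polymerases per compartment unrepresentable;
    this check additionally verifies that every transition only ever moves a
    polymerase into a compartment that was empty in the source state.
    """
    src = np.repeat(np.arange(table.n_states), np.diff(table.indptr))
    gained = (table.occupancy[table.targets].astype(np.int8) - table.occupancy[src].astype(np.int8))
    if gained.max(initial=0) > 1 or (gained == 1).sum(axis=1).max(initial=0) > 1:
        raise AssertionError("exclusion violated: a transition adds more than one polymerase")
    if np.any((gained == 1) & (table.occupancy[src] == 1)):
        raise AssertionError("exclusion violated: move into an occupied compartment")
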