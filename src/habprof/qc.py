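"""Read quality control: 3'-quality trimming and expected-error filtering.

A read is trimmed from the 3' end (sliding-window quality rule plus an
accumulated expected-error cap) and then either kept or discarded based on
three filters applied in fixed order:

1. error probability — the expected number of sequencing errors
   ``E = sum_i 10^(-Q_i/10)`` is too likely to exceed the accumulated-error
   ceiling (default 2.5, at probability >= 0.01 under a Poisson model);
2. ambiguity — more than ``max_ambiguous`` non-ACGT positions;
3. homopolymer — a homonucleotide run longer than ``max_homopolymer``.

Finally reads shorter than a fraction (default 70%) of the sample's
expected read length are removed.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import poisson

__all__ = [
    "SequenceRead",
    "QcParams",
    "QcDecision",
    "QcReport",
    "expected_errors",
    "trim_read",
    "filter_read",
    "length_filter",
    "process_sample",
]

_ACGT = frozenset("ACGT")


@dataclass
class SequenceRead:
    """A sequencing read: identifier, bases and per-base Phred scores."""

    id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if self.quals.ndim != 1 or len(self.bases) != self.quals.size:
            raise ValueError(
                f"read {self.id!r}: bases ({len(self.bases)}) and quality "
                f"scores ({self.quals.size}) differ in length"
            )
        if (self.quals < 0).any():
            raise ValueError(f"read {self.id!r}: negative quality score")

    def __len__(self) -> int:
        return len(self.bases)

    def prefix(self, n: int) -> "SequenceRead":
        """The first ``n`` bases as a new read (same id)."""
        if n >= len(self):
            return self
        return SequenceRead(self.id, self.bases[:n], self.quals[:n])


@dataclass(frozen=True)
class QcParams:
    """Thresholds of the trimming and filtering rules.

    ``error_model="poisson"`` discards a read when the probability that the
    realized error count exceeds ``max_accum_error`` is at least
    ``error_prob_threshold``, modelling the error count as Poisson with
    mean equal to the expected error ``E`` (a tractable surrogate for the
    exact Poisson-binomial). ``error_model="simple"`` discards when
    ``E > max_accum_error`` directly.
    """

    max_accum_error: float = 2.5
    error_prob_threshold: float = 0.01
    max_ambiguous: int = 1
    max_homopolymer: int = 15
    trim_window: int = 15
    trim_quality: float = 20.0
    trim_accum_error: float = 1.0
    min_length_fraction: float = 0.70
    error_model: str = "poisson"
    length_reference: str = "modal"  # or "max"

    def __post_init__(self) -> None:
        if not 0 < self.min_length_fraction <= 1:
            raise ValueError("min_length_fraction must be in (0, 1]")
        for name in ("max_accum_error", "max_ambiguous", "max_homopolymer",
                     "trim_window", "trim_quality", "trim_accum_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.error_prob_threshold <= 1:
            raise ValueError("error_prob_threshold must be a probability")
        if self.error_model not in ("poisson", "simple"):
            raise ValueError("error_model must be 'poisson' or 'simple'")
        if self.length_reference not in ("modal", "max"):
            raise ValueError("length_reference must be 'modal' or 'max'")


class QcDecision(NamedTuple):
    keep: bool
    reason: Optional[str]  # "error_prob" | "ambiguity" | "homopolymer"


@dataclass
class QcReport:
    """Bookkeeping of a QC run; removal counts plus kept sum to the input."""

    n_input: int = 0
    n_kept: int = 0
    removed: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        d = {"n_input": self.n_input, "n_kept": self.n_kept}
        for rule in ("error_prob", "ambiguity", "homopolymer", "short"):
            d[f"removed_{rule}"] = self.removed.get(rule, 0)
        return d


def expected_errors(read: SequenceRead) -> float:
    """Expected number of errors ``E = sum_i 10^(-Q_i/10)``."""
    if len(read) == 0:
        return 0.0
    return float(np.sum(10.0 ** (-read.quals / 10.0)))


def trim_read(read: SequenceRead, params: QcParams = QcParams()) -> SequenceRead:
    """Trim the 3' end by the window-quality and accumulated-error rules.

    The returned read is always a prefix of the input, and trimming is
    idempotent. Two rules are iterated to a fixed point:

    * while the 3'-terminal window of ``trim_window`` bases has mean
      quality below ``trim_quality``, that window is cut off;
    * the read is cut to its longest prefix whose expected error does not
      exceed ``trim_accum_error``.
    """
    w, minq = params.trim_window, params.trim_quality
    n = len(read)
    quals = read.quals
    # small slack absorbs float round-off at exact-threshold boundaries
    e_cap = params.trim_accum_error * (1 + 1e-9) + 1e-12
    changed = True
    while changed:
        changed = False
        while n >= w and quals[n - w:n].mean() < minq:
            n -= w
            changed = True
        if n:
            cum = np.cumsum(10.0 ** (-quals[:n] / 10.0))
            m = int(np.searchsorted(cum, e_cap, side="right"))
            if m < n:
                n = m
                changed = True
    return read.prefix(n)


def _longest_run(bases: str) -> int:
    return max((sum(1 for _ in grp) for _, grp in groupby(bases)), default=0)


def filter_read(read: SequenceRead, params: QcParams = QcParams()) -> QcDecision:
    """Keep/discard decision for an (already trimmed) read.

    Rules are evaluated in fixed order — error probability, ambiguity,
    homopolymer — and the reason names the first rule that fires.
    """
    e = expected_errors(read)
    if params.error_model == "poisson":
        # P(error count > max_accum_error) with count ~ Poisson(E)
        p_exceed = float(poisson.sf(math.floor(params.max_accum_error), e))
        bad = p_exceed >= params.error_prob_threshold
    else:
        bad = e > params.max_accum_error
    if bad:
        return QcDecision(False, "error_prob")
    n_ambig = sum(1 for b in read.bases.upper() if b not in _ACGT)
    if n_ambig > params.max_ambiguous:
        return QcDecision(False, "ambiguity")
    if _longest_run(read.bases.upper()) > params.max_homopolymer:
        return QcDecision(False, "homopolymer")
    return QcDecision(True, None)


def expected_read_length(reads: Sequence[SequenceRead], reference: str = "modal") -> int:
    """Per-sample expected read length: modal length (tie -> larger) or max."""
    lengths = [len(r) for r in reads]
    if not lengths:
        return 0
    if reference == "max":
        return max(lengths)
    counts = Counter(lengths)
    top = max(counts.values())
    return max(length for length, c in counts.items() if c == top)


def length_filter(
    reads: Sequence[SequenceRead], params: QcParams = QcParams()
) -> list[SequenceRead]:
    """Remove reads strictly shorter than ``min_length_fraction`` x L_max.

    L_max is the per-sample expected read length (modal length by default,
    configurable to the plain maximum). A read at exactly the threshold
    length is kept.
    """
    if not reads:
        return []
    lmax = expected_read_length(reads, params.length_reference)
    cutoff = params.min_length_fraction * lmax - 1e-9
    return [r for r in reads if len(r) >= cutoff]


def process_sample(
    reads: Iterable[SequenceRead], params: QcParams = QcParams()
) -> tuple[list[SequenceRead], QcReport]:
    """Trim, filter and length-filter one sample's reads.

    Returns the kept reads plus a :class:`QcReport` whose per-rule removal
    counts and kept count sum to the input count.
    """
    report = QcReport()
    raw = list(reads)
    report.n_input = len(raw)
    # the length reference is taken from the raw sample, before trimming
    lmax = expected_read_length(raw, params.length_reference)
    cutoff = params.min_length_fraction * lmax - 1e-9
    kept: list[SequenceRead] = []
    for read in raw:
        t = trim_read(read, params)
        decision = filter_read(t, params)
        if not decision.keep:
            report.removed[decision.reason] += 1
        elif len(t) < cutoff:
            report.removed["short"] += 1
        else:
            kept.append(t)
    report.n_kept = len(kept)
    return kept, report
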