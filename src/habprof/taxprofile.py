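"""miTag-style taxonomic profiling from alignment hit tables.

Read pairs that survive QC are merged by 3' overlap where possible and
otherwise interleaved (mate reverse-complemented and appended). Hits of
each query against an SSU reference are pre-filtered by e-value and fed to
a rank-gated lowest-common-ancestor (LCA) classifier: among near-best hits
a consensus taxon is sought rank by rank, and assignments at a rank are
voided when the best hit identity falls below that rank's minimum identity
gate (88% at phylum and 91% at class by default, Yarza-style thresholds;
gates below class are configurable extrapolations).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .qc import SequenceRead
from .taxonomy import RANKS, TaxonomyTree

__all__ = [
    "AlignmentHit",
    "RankGates",
    "LcaResult",
    "merge_or_interleave",
    "prefilter_hits",
    "lca_assign",
    "profile_sample",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One query-to-reference alignment record (BLAST-tabular style).

    ``annotation`` carries the target's lineage taxon id in taxonomic mode
    or its gene-family id in functional mode; ``domain`` tags functional
    targets as prokaryotic or eukaryotic.
    """

    query: str
    target: str
    identity: float  # percent, in [0, 100]
    align_length: int
    evalue: float
    bitscore: float
    subject_coverage: Optional[float] = None  # percent
    annotation: Optional[str] = None
    domain: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")


#: Default per-rank minimum identity (percent) of the best hit required to
#: keep an assignment at that rank. Phylum and class follow the 88/91
#: literature thresholds; deeper gates are extrapolated defaults.
DEFAULT_GATES: dict[str, float] = {
    "domain": 0.0,
    "phylum": 88.0,
    "class": 91.0,
    "order": 92.0,
    "family": 93.0,
    "genus": 94.5,
}


@dataclass(frozen=True)
class RankGates:
    """Per-rank identity gates plus the consensus fraction of the LCA vote."""

    min_identity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GATES)
    )
    consensus_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.5 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must be in (0.5, 1]")
        gates = [self.min_identity.get(r, 0.0) for r in RANKS]
        if any(b < a for a, b in zip(gates, gates[1:])):
            raise ValueError("identity gates must be non-decreasing with rank depth")

    def gate(self, rank: str) -> float:
        return float(self.min_identity.get(rank, 0.0))


def merge_or_interleave(
    r1: SequenceRead,
    r2: SequenceRead,
    min_overlap: int = 10,
    max_mismatch_fraction: float = 0.25,
) -> tuple[SequenceRead, str]:
    """Overlap-merge a read pair, or interleave it when no overlap is found.

    The mate is reverse-complemented and slid against the 3' end of the
    forward read; the longest overlap of at least ``min_overlap`` bases
    with a mismatch fraction at most ``max_mismatch_fraction`` is merged,
    taking the higher-quality base at each overlap position. Without an
    acceptable overlap the reads are interleaved: the reverse-complemented
    mate is appended to the forward read.

    Returns the combined read and a mode flag, ``"merged"`` or
    ``"interleaved"``.
    """
    rc_bases = reverse_complement(r2.bases)
    rc_quals = r2.quals[::-1]
    for o in range(min(len(r1), len(r2)), min_overlap - 1, -1):
        tail, head = r1.bases[-o:], rc_bases[:o]
        mismatches = sum(a != b for a, b in zip(tail, head))
        if mismatches / o <= max_mismatch_fraction:
            bases = list(r1.bases[:-o])
            quals = list(r1.quals[:-o])
            for i in range(o):
                q1, q2 = r1.quals[len(r1) - o + i], rc_quals[i]
                if tail[i] == head[i] or q1 >= q2:
                    bases.append(tail[i])
                else:
                    bases.append(head[i])
                quals.append(max(q1, q2))
            bases += list(rc_bases[o:])
            quals += list(rc_quals[o:])
            merged = SequenceRead(r1.id, "".join(bases), np.array(quals))
            return merged, "merged"
    combined = SequenceRead(
        r1.id, r1.bases + rc_bases, np.concatenate([r1.quals, rc_quals])
    )
    return combined, "interleaved"


def prefilter_hits(
    hits: Iterable[AlignmentHit], max_evalue: float = 1e-4
) -> list[AlignmentHit]:
    """Keep hits with e-value strictly below ``max_evalue``."""
    return [h for h in hits if h.evalue < max_evalue]


@dataclass
class LcaResult:
    """Outcome of rank-gated LCA for one query (possibly partial)."""

    query: str
    lineage: dict[str, str]  # rank -> taxon id, contiguous from "domain"
    best_identity: float
    n_retained: int

    @property
    def deepest_rank(self) -> Optional[str]:
        for rank in reversed(RANKS):
            if rank in self.lineage:
                return rank
        return None

    def taxon_at(self, rank: str) -> Optional[str]:
        return self.lineage.get(rank)


def lca_assign(
    hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    gates: RankGates = RankGates(),
    score_margin: float = 1.0,
) -> LcaResult:
    """Rank-gated consensus LCA assignment of one query.

    1. retain hits within ``score_margin`` identity points of the best hit;
    2. walk ranks from domain towards genus, assigning at each rank the
       taxon shared by at least ``consensus_fraction`` of retained hits and
       stopping at the first rank without such a consensus;
    3. void any rank (and all deeper ranks) whose identity gate exceeds
       the best hit identity.

    An empty hit set yields a fully unassigned result.
    """
    if not hits:
        return LcaResult("", {}, 0.0, 0)
    best = max(h.identity for h in hits)
    retained = [h for h in hits if h.identity >= best - score_margin]
    lineages = []
    for h in retained:
        if h.annotation is None or h.annotation not in tree:
            raise KeyError(f"hit target lineage {h.annotation!r} not in taxonomy")
        lineages.append({n.rank: n.taxon_id for n in tree.lineage(h.annotation)})
    n = len(retained)
    assigned: dict[str, str] = {}
    for rank in RANKS:
        votes = Counter(lin[rank] for lin in lineages if rank in lin)
        taxon, count = votes.most_common(1)[0] if votes else (None, 0)
        if taxon is None or count / n < gates.consensus_fraction:
            break
        if best < gates.gate(rank):
            break
        assigned[rank] = taxon
    return LcaResult(hits[0].query, assigned, best, n)


def profile_sample(
    assignments: Iterable[LcaResult],
    rank: str,
    total_reads: int,
) -> tuple[pd.Series, pd.Series]:
    """Aggregate per-read assignments into a count vector at one rank.

    Returns ``(counts, normalized)`` where the normalized abundances divide
    by the sample's *total* read count (not the assigned-read count), so
    the normalized vector sums to at most 1.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    counts = Counter(
        a.taxon_at(rank) for a in assignments if a.taxon_at(rank) is not None
    )
    series = pd.Series(counts, dtype=float).sort_index()
    return series, series / total_reads
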