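"""Functional profiling from protein-level alignment hit tables.

Reads are mapped against an orthologous-group (OG) reference competitively
across domains. Unmerged mate hits to the same target are combined (lower
e-value, summed bit scores); one best hit per query is selected by highest
bit score, then longest alignment, then highest identity; weak hits
(identity < 50% or e-value > 1e-9) are excluded. Surviving best hits are
aggregated into per-domain (prokaryote/eukaryote) sample x OG count
matrices. OGs whose representative sequences hit a carbohydrate-active
enzyme (CAZy) reference with seed-quality alignments (identity > 90,
e-value < 1e-20, subject coverage > 80, all strict) are mapped to CAZy
families, from which per-sample CAZyme profiles and a bacterial:fungal
CAZyme ratio are derived.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .taxprofile import AlignmentHit

__all__ = [
    "FunctionalTarget",
    "combine_pair_hits",
    "select_best_hit",
    "filter_hits",
    "build_og_matrix",
    "map_og_to_cazy",
    "cazyme_profile",
]

DOMAINS = ("prokaryote", "eukaryote")


@dataclass(frozen=True)
class FunctionalTarget:
    """A functional reference sequence: OG membership plus domain of origin."""

    target_id: str
    og: str
    domain: str  # "prokaryote" | "eukaryote"
    cazy_families: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")


def combine_pair_hits(h1: AlignmentHit, h2: AlignmentHit) -> AlignmentHit:
    """Combine two mate hits to the same target into one record.

    The combined hit takes the lower of the two e-values and the sum of
    the bit scores. Identity is carried as the alignment-length-weighted
    mean and alignment length as the sum (documented conventions; only the
    e-value and bit-score rules affect downstream selection thresholds).
    """
    if h1.target != h2.target:
        raise ValueError(
            f"cannot combine hits to different targets "
            f"({h1.target!r} vs {h2.target!r})"
        )
    total_len = h1.align_length + h2.align_length
    identity = (
        h1.identity * h1.align_length + h2.identity * h2.align_length
    ) / total_len
    cov = None
    if h1.subject_coverage is not None and h2.subject_coverage is not None:
        cov = max(h1.subject_coverage, h2.subject_coverage)
    return AlignmentHit(
        query=h1.query,
        target=h1.target,
        identity=identity,
        align_length=total_len,
        evalue=min(h1.evalue, h2.evalue),
        bitscore=h1.bitscore + h2.bitscore,
        subject_coverage=cov,
        annotation=h1.annotation,
        domain=h1.domain,
    )


def select_best_hit(hits: Sequence[AlignmentHit]) -> Optional[AlignmentHit]:
    """One best hit per query: highest bit score, then longest alignment,
    then highest identity; any remaining tie is broken by the
    lexicographically smallest target id, so the choice is invariant under
    input order."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bitscore, -h.align_length, -h.identity, h.target))


def filter_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Exclude hits with identity < 50% or e-value > 1e-9 (strict, so
    equality at either boundary is kept)."""
    return [h for h in hits if h.identity >= 50.0 and h.evalue <= 1e-9]


def build_og_matrix(
    best_hits_by_sample: Mapping[str, Sequence[AlignmentHit]],
    targets: Mapping[str, FunctionalTarget],
    total_reads: Mapping[str, int],
) -> dict[str, CountMatrix]:
    """Aggregate per-read best hits into per-domain sample x OG matrices.

    Each read is counted in exactly one domain, the one of its best hit's
    target. ``total_reads`` records the number of reads used for mapping
    per sample, the denominator of the normalized copies.
    """
    counts: dict[str, dict[str, Counter]] = {d: {} for d in DOMAINS}
    for sample, hits in best_hits_by_sample.items():
        for d in DOMAINS:
            counts[d].setdefault(sample, Counter())
        for hit in hits:
            if hit.target not in targets:
                raise KeyError(f"unknown target id {hit.target!r}")
            tgt = targets[hit.target]
            counts[tgt.domain][sample][tgt.og] += 1
    out: dict[str, CountMatrix] = {}
    samples = sorted(best_hits_by_sample)
    meta = pd.DataFrame(
        {"total_reads": [int(total_reads[s]) for s in samples]}, index=samples
    )
    for d in DOMAINS:
        df = (
            pd.DataFrame(counts[d], dtype=float)
            .T.reindex(samples)
            .fillna(0.0)
            .sort_index(axis=1)
        )
        out[d] = CountMatrix(df, sample_meta=meta)
    return out


def map_og_to_cazy(
    og_hits: Iterable[AlignmentHit],
    cazy_family_of: Mapping[str, str],
) -> dict[str, tuple[str, ...]]:
    """Map OGs to CAZy families via seed-quality hits of OG representatives.

    ``og_hits`` are alignments of OG representative sequences (query = OG
    id) against CAZy reference sequences; ``cazy_family_of`` gives the
    family of each CAZy target. An OG is mapped to a family iff at least
    one hit passes identity > 90, e-value < 1e-20 and subject coverage
    > 80 (all strict).
    """
    mapped: dict[str, set[str]] = {}
    for hit in og_hits:
        if hit.subject_coverage is None:
            raise ValueError(f"hit {hit.query!r}->{hit.target!r} lacks subject coverage")
        if hit.identity > 90.0 and hit.evalue < 1e-20 and hit.subject_coverage > 80.0:
            if hit.target not in cazy_family_of:
                raise KeyError(f"unknown CAZy target {hit.target!r}")
            mapped.setdefault(hit.query, set()).add(cazy_family_of[hit.target])
    return {og: tuple(sorted(fams)) for og, fams in sorted(mapped.items())}


def cazyme_profile(
    og_matrices: Mapping[str, CountMatrix],
    og2cazy: Mapping[str, Sequence[str]],
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Collapse OG abundances into CAZy-family profiles per domain.

    A family's abundance is the sum of the abundances of the OGs mapped to
    it; an OG mapped to k families contributes its full abundance to each
    (documented double counting). Returns the per-domain sample x family
    matrices and the per-sample prokaryote:eukaryote CAZyme ratio (NaN
    where the eukaryotic total is zero).
    """
    profiles: dict[str, pd.DataFrame] = {}
    for domain, cm in og_matrices.items():
        cols: dict[str, pd.Series] = {}
        for og in cm.features:
            for fam in og2cazy.get(og, ()):
                if fam in cols:
                    cols[fam] = cols[fam] + cm.counts[og]
                else:
                    cols[fam] = cm.counts[og].copy()
        profiles[domain] = (
            pd.DataFrame(cols).sort_index(axis=1)
            if cols
            else pd.DataFrame(index=cm.samples)
        )
    prok = profiles.get("prokaryote")
    euk = profiles.get("eukaryote")
    samples = next(iter(og_matrices.values())).samples
    prok_tot = prok.sum(axis=1).reindex(samples, fill_value=0.0) if prok is not None else pd.Series(0.0, index=samples)
    euk_tot = euk.sum(axis=1).reindex(samples, fill_value=0.0) if euk is not None else pd.Series(0.0, index=samples)
    ratio = prok_tot / euk_tot.replace(0.0, np.nan)
    ratio.name = "bf_cazyme_ratio"
    return profiles, ratio
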