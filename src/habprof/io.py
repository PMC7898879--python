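"""Readers and writers for the plain-text formats of the pipeline.

FASTQ (Sanger/Phred+33) via Biopython; hit tables as BLAST outfmt-6-style
TSV with trailing annotation columns; count matrices and metadata as TSV.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix
from .funcprofile import FunctionalTarget
from .qc import SequenceRead
from .taxprofile import AlignmentHit

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_hit_table",
    "write_hit_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_targets",
    "write_targets",
]

#: BLAST outfmt-6 column names, in order.
OUTFMT6 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fastq(path) -> list[SequenceRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SequenceRead(
                rec.id, str(rec.seq),
                np.asarray(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Iterable[SequenceRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_hit_table(hits: Sequence[AlignmentHit], path, kind: str = "tax") -> None:
    """Write hits as TSV: outfmt-6 plus an annotation column (taxonomic
    mode, 13 columns) or plus subject-coverage and annotation columns
    (functional mode, 14 columns). The annotation column carries the
    target lineage taxon id or ``og|domain``."""
    rows = []
    for h in hits:
        mismatch = int(round(h.align_length * (100.0 - h.identity) / 100.0))
        base = [
            h.query, h.target, h.identity, h.align_length, mismatch, 0,
            1, h.align_length, 1, h.align_length, h.evalue, h.bitscore,
        ]
        if kind == "tax":
            rows.append(base + [h.annotation])
        elif kind == "func":
            ann = h.annotation if h.domain is None else f"{h.annotation}|{h.domain}"
            rows.append(base + [h.subject_coverage, ann])
        else:
            raise ValueError("kind must be 'tax' or 'func'")
    cols = OUTFMT6 + (["annotation"] if kind == "tax" else ["scov", "annotation"])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, header=False)


def read_hit_table(path, kind: str = "tax") -> list[AlignmentHit]:
    if kind == "tax":
        cols = OUTFMT6 + ["annotation"]
    elif kind == "func":
        cols = OUTFMT6 + ["scov", "annotation"]
    else:
        raise ValueError("kind must be 'tax' or 'func'")
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    hits = []
    for r in df.itertuples(index=False):
        ann, domain, scov = r.annotation, None, None
        if kind == "func":
            scov = float(r.scov)
            if isinstance(ann, str) and "|" in ann:
                ann, domain = ann.rsplit("|", 1)
        hits.append(
            AlignmentHit(
                query=str(r.qseqid), target=str(r.sseqid),
                identity=float(r.pident), align_length=int(r.length),
                evalue=float(r.evalue), bitscore=float(r.bitscore),
                subject_coverage=scov,
                annotation=None if pd.isna(ann) else str(ann),
                domain=domain,
            )
        )
    return hits


def write_count_matrix(cm: CountMatrix, prefix: str) -> None:
    """Write ``<prefix>.counts.tsv`` (first column sample ids, header =
    feature ids) plus metadata TSVs when present."""
    cm.counts.to_csv(f"{prefix}.counts.tsv", sep="\t", index_label="sample")
    if cm.sample_meta is not None:
        cm.sample_meta.to_csv(f"{prefix}.samples.tsv", sep="\t", index_label="sample")
    if cm.feature_meta is not None:
        cm.feature_meta.to_csv(f"{prefix}.features.tsv", sep="\t", index_label="feature")


def read_count_matrix(prefix: str) -> CountMatrix:
    import os

    counts = pd.read_csv(f"{prefix}.counts.tsv", sep="\t", index_col="sample")
    sample_meta = feature_meta = None
    if os.path.exists(f"{prefix}.samples.tsv"):
        sample_meta = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col="sample")
    if os.path.exists(f"{prefix}.features.tsv"):
        feature_meta = pd.read_csv(
            f"{prefix}.features.tsv", sep="\t", index_col="feature"
        )
    return CountMatrix(counts, sample_meta, feature_meta)


def write_targets(targets: Iterable[FunctionalTarget], path) -> None:
    rows = [
        (t.target_id, t.og, t.domain, ",".join(t.cazy_families)) for t in targets
    ]
    pd.DataFrame(rows, columns=["target_id", "og", "domain", "cazy"]).to_csv(
        path, sep="\t", index=False
    )


def read_targets(path) -> dict[str, FunctionalTarget]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for r in df.itertuples(index=False):
        fams = tuple(f for f in r.cazy.split(",") if f)
        out[r.target_id] = FunctionalTarget(r.target_id, r.og, r.domain, fams)
    return out
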