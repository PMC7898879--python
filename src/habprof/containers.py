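"""Shared data containers for the profiling pipeline.

The central container is :class:`CountMatrix`: a samples x features table of
non-negative counts (genus SSU counts or gene-family counts) together with
per-sample metadata (habitat label, total read count) and per-feature
metadata (kingdom, taxonomic rank or functional domain).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Samples x features count table with sample and feature metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are feature ids
        (genera or gene families). Entries must be non-negative.
    sample_meta
        DataFrame indexed by sample id. Conventional columns:
        ``habitat`` (str) and ``total_reads`` (int, the denominator used
        for per-sample normalization). Must cover every sample in
        ``counts``.
    feature_meta
        DataFrame indexed by feature id. Conventional columns:
        ``kingdom`` (``"bacteria"`` / ``"fungi"``) and ``rank``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if self.sample_meta is not None:
            missing = self.counts.index.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing samples: {list(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[self.counts.index]
        if self.feature_meta is not None:
            missing = self.counts.columns.difference(self.feature_meta.index)
            if len(missing):
                raise ValueError(f"feature_meta missing features: {list(missing)[:5]}")
            self.feature_meta = self.feature_meta.loc[self.counts.columns]

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def features(self) -> pd.Index:
        return self.counts.columns

    def habitat_of(self) -> pd.Series:
        if self.sample_meta is None or "habitat" not in self.sample_meta:
            raise ValueError("no habitat metadata available")
        return self.sample_meta["habitat"]

    def total_reads(self) -> pd.Series:
        """Per-sample normalization denominator.

        Falls back to the row sum of the count table when no
        ``total_reads`` column is present (i.e. all reads were profiled).
        """
        if self.sample_meta is not None and "total_reads" in self.sample_meta:
            return self.sample_meta["total_reads"]
        return self.counts.sum(axis=1)

    def normalized(self) -> pd.DataFrame:
        """Counts divided by the per-sample total read count."""
        return self.counts.div(self.total_reads(), axis=0)

    def kingdom_features(self, kingdom: str) -> pd.Index:
        if self.feature_meta is None or "kingdom" not in self.feature_meta:
            raise ValueError("no kingdom annotation available")
        return self.features[self.feature_meta["kingdom"] == kingdom]

    def subset_features(self, features) -> "CountMatrix":
        fm = None if self.feature_meta is None else self.feature_meta.loc[features]
        return CountMatrix(self.counts[list(features)], self.sample_meta, fm)
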