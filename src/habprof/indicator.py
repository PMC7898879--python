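"""Indicator genus analysis.

The Dufrene-Legendre indicator value of genus g in habitat h is
IndVal = A x B where A (specificity) is the mean abundance of g in h
divided by the sum of its per-habitat mean abundances and B (fidelity) is
the fraction of h's samples containing g. Each genus is reported for its
argmax habitat; significance comes from free permutation of habitat
labels across samples (add-one p-value) followed by Benjamini-Hochberg
FDR control.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .containers import CountMatrix

__all__ = [
    "indval",
    "permutation_test",
    "bh_fdr",
    "indicator_analysis",
    "indicator_fractions",
]


def _components(x: np.ndarray, codes: np.ndarray, n_habitats: int):
    """A, B and IndVal matrices (habitats x genera) for one labelling."""
    n = x.shape[0]
    group = np.zeros((n_habitats, n))
    group[codes, np.arange(n)] = 1.0
    sizes = group.sum(axis=1, keepdims=True)
    means = (group @ x) / sizes
    colsum = means.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(colsum > 0, means / colsum, 0.0)
    b = (group @ (x > 0)) / sizes
    return a, b, a * b


def indval(counts: pd.DataFrame, habitat_of: pd.Series):
    """Per-habitat specificity A, fidelity B and IndVal = A x B.

    Returns three DataFrames (habitats x genera). Requires at least two
    habitats, each with at least one sample.
    """
    habitat_of = habitat_of.loc[counts.index]
    cats = pd.Categorical(habitat_of)
    if len(cats.categories) < 2:
        raise ValueError("need at least 2 habitats")
    a, b, iv = _components(
        counts.values.astype(float), cats.codes.astype(int), len(cats.categories)
    )
    idx, cols = list(cats.categories), counts.columns
    return (
        pd.DataFrame(a, index=idx, columns=cols),
        pd.DataFrame(b, index=idx, columns=cols),
        pd.DataFrame(iv, index=idx, columns=cols),
    )


def permutation_test(
    counts: pd.DataFrame,
    habitat_of: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-value of the max-habitat IndVal of every genus.

    Habitat labels are freely permuted across samples; the add-one rule
    p = (1 + #{permuted max IndVal >= observed}) / (1 + n_perm) keeps
    p strictly positive.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    habitat_of = habitat_of.loc[counts.index]
    cats = pd.Categorical(habitat_of)
    codes = cats.codes.astype(int)
    x = counts.values.astype(float)
    nh = len(cats.categories)
    _, _, iv = _components(x, codes, nh)
    obs = iv.max(axis=0)
    best = iv.argmax(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, _, piv = _components(x, perm, nh)
        exceed += piv.max(axis=0) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "habitat": np.asarray(cats.categories)[best],
            "indval": obs,
            "p_perm": p,
        },
        index=counts.columns,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return np.asarray(false_discovery_control(p, method="bh"))


def indicator_analysis(
    cm: CountMatrix,
    n_perm: int = 999,
    seed: int = 0,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Full indicator-genus table for a habitat-annotated count matrix.

    Genera with a total count of at most ``min_reads`` across all samples
    are excluded before testing. One row per tested genus: its argmax
    habitat, A, B, IndVal, permutation p-value and BH q-value (plus the
    genus kingdom when annotated).
    """
    habitat_of = cm.habitat_of()
    tested = cm.features[cm.counts.sum(axis=0) > min_reads]
    counts = cm.counts[tested]
    a, b, _ = indval(counts, habitat_of)
    table = permutation_test(counts, habitat_of, n_perm=n_perm, seed=seed)
    table["A"] = [a.loc[h, g] for g, h in table["habitat"].items()]
    table["B"] = [b.loc[h, g] for g, h in table["habitat"].items()]
    table["q_fdr"] = bh_fdr(table["p_perm"].values)
    if cm.feature_meta is not None and "kingdom" in cm.feature_meta:
        table["kingdom"] = cm.feature_meta.loc[tested, "kingdom"]
    table.index.name = "genus"
    return table[
        [c for c in ("kingdom", "habitat", "A", "B", "indval", "p_perm", "q_fdr")
         if c in table.columns]
    ]


def indicator_fractions(
    table: pd.DataFrame,
    totals: Mapping[str, int],
    fdr_threshold: float = 0.3,
    per_habitat: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fractions of significantly habitat-associated genera per kingdom.

    ``totals`` gives the total number of genera per kingdom (the
    denominator, which may exceed the number of genera tested). A genus
    counts as significant when its q-value is strictly below
    ``fdr_threshold``, and counts once, for its argmax habitat. Returns
    the per-(habitat, kingdom) percentage table and the overall per-
    kingdom percentages.
    """
    for kingdom, total in totals.items():
        if total <= 0:
            raise ValueError(f"total for kingdom {kingdom!r} must be positive")
    sig = table[table["q_fdr"] < fdr_threshold]
    kingdoms = sorted(totals)
    overall = pd.Series(
        {
            k: 100.0 * (sig["kingdom"] == k).sum() / totals[k]
            for k in kingdoms
        },
        name="percent_significant",
    )
    rows = []
    if per_habitat:
        for habitat in sorted(table["habitat"].unique()):
            for k in kingdoms:
                n_sig = int(((sig["habitat"] == habitat) & (sig["kingdom"] == k)).sum())
                rows.append(
                    {
                        "habitat": habitat,
                        "kingdom": k,
                        "n_significant": n_sig,
                        "percent": 100.0 * n_sig / totals[k],
                    }
                )
    per_hab = pd.DataFrame(rows, columns=["habitat", "kingdom", "n_significant", "percent"])
    return per_hab, overall
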