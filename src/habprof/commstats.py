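"""Per-sample community statistics.

Bacterial:fungal (B/F) SSU abundance ratio, genus-level Shannon diversity
with a partial-regression correction for sequencing depth, the Hellinger
transformation and Bray-Curtis dissimilarity.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

from .containers import CountMatrix

__all__ = [
    "bf_ratio",
    "shannon",
    "depth_correct",
    "hellinger",
    "bray_curtis",
    "sample_stats",
    "habitat_bf_means",
]


def bf_ratio(bacterial_count: float, fungal_count: float) -> float:
    """Bacterial over fungal SSU count; NaN when the fungal count is zero.

    The NaN sentinel marks samples excluded from downstream habitat means.
    """
    if bacterial_count < 0 or fungal_count < 0:
        raise ValueError("counts must be non-negative")
    if fungal_count == 0:
        return float("nan")
    return bacterial_count / fungal_count


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i, zero-count terms dropped."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("counts must sum to a positive value")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def depth_correct(
    diversities, depths, log_depth: bool = True
) -> np.ndarray:
    """Remove the linear effect of sequencing depth from diversity values.

    Ordinary least squares of H on log10(depth) (or raw depth with
    ``log_depth=False``); returns the residuals shifted by the grand mean
    of H, so corrected values stay on the Shannon scale. With constant
    depth the regression is degenerate and the input is returned
    unchanged.
    """
    h = np.asarray(diversities, dtype=float)
    d = np.asarray(depths, dtype=float)
    if h.shape != d.shape or h.ndim != 1:
        raise ValueError("diversities and depths must be 1-D and equal length")
    if h.size < 3:
        raise ValueError("need at least 3 samples for the depth regression")
    if (d <= 0).any():
        raise ValueError("depths must be positive")
    x = np.log10(d) if log_depth else d
    if np.ptp(x) == 0:
        return h.copy()
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, h, rcond=None)
    residuals = h - design @ coef
    return residuals + h.mean()


def hellinger(matrix) -> pd.DataFrame:
    """Row-wise Hellinger transform: sqrt of relative abundance.

    Every row's sum of squares is 1 afterwards.
    """
    df = pd.DataFrame(matrix, dtype=float)
    sums = df.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every row must have a positive sum")
    return np.sqrt(df.div(sums, axis=0))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("vectors must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("vectors must not both be all-zero")
    return float(_braycurtis(x, y))


def sample_stats(cm: CountMatrix, depths: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-sample statistics table from a genus-level count matrix.

    Columns: bacterial and fungal SSU counts, B/F ratio (NaN when no
    fungal reads), genus-level Shannon index, depth-corrected Shannon and
    total reads. ``depths`` defaults to the per-sample total read count
    recorded in the matrix metadata.
    """
    bact = cm.counts[cm.kingdom_features("bacteria")].sum(axis=1)
    fung = cm.counts[cm.kingdom_features("fungi")].sum(axis=1)
    ratios = bact / fung.replace(0.0, np.nan)
    h = cm.counts.apply(lambda row: shannon(row.values), axis=1)
    total = depths if depths is not None else cm.total_reads()
    stats = pd.DataFrame(
        {
            "bacterial_ssu_count": bact,
            "fungal_ssu_count": fung,
            "bf_ratio": ratios,
            "shannon": h,
            "total_reads": total,
        }
    )
    stats["shannon_depth_corrected"] = depth_correct(
        stats["shannon"].values, stats["total_reads"].values
    )
    return stats


def habitat_bf_means(stats: pd.DataFrame, habitat_of: pd.Series) -> pd.DataFrame:
    """Habitat-level mean B/F ratios.

    Samples with an undefined ratio (no fungal reads) are excluded, not
    imputed; the per-habitat exclusion count is reported alongside the
    mean and its standard error.
    """
    df = stats.join(habitat_of.rename("habitat"))
    out = []
    for habitat, grp in df.groupby("habitat"):
        ratios = grp["bf_ratio"].dropna()
        out.append(
            {
                "habitat": habitat,
                "mean_bf_ratio": ratios.mean() if len(ratios) else np.nan,
                "se_bf_ratio": ratios.sem() if len(ratios) > 1 else np.nan,
                "n_samples": len(grp),
                "n_excluded": int(grp["bf_ratio"].isna().sum()),
            }
        )
    return pd.DataFrame(out).set_index("habitat")
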