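"""Agreement statistics between similarity-derived and empirical results.

A similarity matrix is only a proxy for the empirical item-correlation
matrix; these functions quantify how close the proxy is, both at the matrix
level (correlation of lower triangles) and at the level of downstream fit
indices (medians, cross-method correlations and absolute differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfa_core import CFAFit
from .corpus_io import SquareMatrix

INDEX_NAMES = ("cfi", "tli", "srmr", "rmsea")


@dataclass(frozen=True)
class AgreementReport:
    """Pearson (or Spearman) correlation of the off-diagonal lower triangles."""

    r_lower_triangle: float
    n_pairs: int
    method: str = "pearson"


def lower_triangle_correlation(
    A: SquareMatrix, B: SquareMatrix, method: str = "pearson"
) -> AgreementReport:
    """Correlate the p(p-1)/2 lower-triangle entries of two aligned matrices."""
    if A.axis_ids != B.axis_ids:
        if set(A.axis_ids) != set(B.axis_ids):
            raise ValueError("matrices are labelled with different item ids")
        B = B.reindex(A.axis_ids)
    p = A.p
    if p < 3:
        raise ValueError("need at least 3 items for a meaningful triangle correlation")
    il = np.tril_indices(p, k=-1)
    a, b = A.values[il], B.values[il]
    if method == "pearson":
        r = float(np.corrcoef(a, b)[0, 1])
    elif method == "spearman":
        from scipy.stats import spearmanr

        r = float(spearmanr(a, b).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return AgreementReport(r_lower_triangle=r, n_pairs=len(a), method=method)


@dataclass(frozen=True)
class IndexComparison:
    """Per-index cross-method summary: medians, correlation, |difference| stats.

    Differences are signed first-method-minus-second-method; ``to_frame``
    renders the summary as one row per statistic, one column per index.
    """

    stats: dict[str, dict[str, float]]  # index -> statistic -> value
    n_models: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            "median_a",
            "sd_a",
            "median_b",
            "sd_b",
            "correlation",
            "median_abs_diff",
            "sd_abs_diff",
            "max_abs_diff",
        ]
        return pd.DataFrame(
            {idx: [self.stats[idx][r] for r in rows] for idx in INDEX_NAMES},
            index=rows,
        ).reset_index(names="statistic")


def compare_fit_sets(fits_a: list[CFAFit], fits_b: list[CFAFit]) -> IndexComparison:
    """Summarize agreement of fit indices across two matched lists of fits.

    The lists must hold the same models in the same order (e.g., the same
    battery run on a similarity matrix and on an empirical matrix).
    NaN-valued indices (df = 0 models) are dropped pairwise per index.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError(
            f"fit lists differ in length ({len(fits_a)} vs {len(fits_b)})"
        )
    if not fits_a:
        raise ValueError("empty fit lists")
    stats: dict[str, dict[str, float]] = {}
    for idx in INDEX_NAMES:
        a = np.array([f.indices()[idx] for f in fits_a])
        b = np.array([f.indices()[idx] for f in fits_b])
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        d = a - b
        if len(a) >= 2 and np.std(a) > 0 and np.std(b) > 0:
            corr = float(np.corrcoef(a, b)[0, 1])
        else:
            corr = float("nan")
        stats[idx] = {
            "median_a": float(np.median(a)),
            "sd_a": float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"),
            "median_b": float(np.median(b)),
            "sd_b": float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
            "correlation": corr,
            "median_diff": float(np.median(d)),
            "median_abs_diff": float(np.median(np.abs(d))),
            "sd_abs_diff": float(np.std(np.abs(d), ddof=1)) if len(d) > 1 else float("nan"),
            "max_abs_diff": float(np.max(np.abs(d))),
        }
    return IndexComparison(stats=stats, n_models=len(fits_a))
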