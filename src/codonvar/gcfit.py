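"""Per-codon linear regression of usage against genomic GC fraction.

For each codon an ordinary-least-squares line of usage (%) on GC fraction
(0-1) is fitted across the collection; the slope (percentage points per GC
unit) measures how strongly the codon responds to genome composition. Slopes
are then summarized by the codon's G+C letter count and by its third (wobble)
base. Because every genome's usage vector sums to 100, the 64 slopes must sum
to ~0 on any dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codes import CODONS, gc_count, third_base, STOP_CODONS

__all__ = ["linear_fit", "fit_all_codons", "summarize_slopes"]


def linear_fit(x, y) -> tuple[float, float, float]:
    """OLS fit y = intercept + slope*x; returns (slope, intercept, r).

    Pearson r is defined as 0 (and the slope as 0) when y has zero variance:
    a perfectly flat response is a meaningful outcome here, not an error.
    Constant x or n < 3 raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    return slope, float(ym - slope * xm), float(sxy / np.sqrt(sxx * syy))


def fit_all_codons(matrix: pd.DataFrame, gc) -> pd.DataFrame:
    """Fit usage-vs-GC lines for every codon column of a usage matrix.

    ``gc`` is the per-genome GC fraction aligned with the matrix rows.
    Returns a codon-indexed frame with slope, intercept, r, n; when the fit
    preconditions fail (n < 3 or constant GC) all fits are absent (NaN).
    """
    gc = np.asarray(gc, dtype=float)
    if len(gc) != len(matrix):
        raise ValueError(
            f"matrix has {len(matrix)} rows but {len(gc)} GC values"
        )
    out = pd.DataFrame(
        np.nan,
        index=pd.Index(matrix.columns, name="codon"),
        columns=["slope", "intercept", "r"],
    )
    out["n"] = len(matrix)
    if len(matrix) < 3 or np.ptp(gc) == 0:
        return out
    vals = matrix.to_numpy(dtype=float)
    xc = gc - gc.mean()
    yc = vals - vals.mean(axis=0)
    sxx = float((xc**2).sum())
    sxy = xc @ yc
    syy = (yc**2).sum(axis=0)
    slope = sxy / sxx
    intercept = vals.mean(axis=0) - slope * gc.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(syy > 0, sxy / np.sqrt(sxx * syy), 0.0)
    slope = np.where(syy > 0, slope, 0.0)
    out["slope"], out["intercept"], out["r"] = slope, intercept, r
    return out


def summarize_slopes(fits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Annotate fits with codon composition and group the slopes.

    Returns ``(rows, by_gc_count, by_third_base)``: the per-codon table with
    gc_count, third_base and is_stop columns, plus median/quartile summaries
    of the slope grouped by G+C letter count (0-3) and by wobble base.
    Stop codons are included but flagged.
    """
    rows = fits.copy()
    rows["gc_count"] = [gc_count(c) for c in rows.index]
    rows["third_base"] = [third_base(c) for c in rows.index]
    rows["is_stop"] = [c in STOP_CODONS for c in rows.index]

    def _summary(group_col: str) -> pd.DataFrame:
        g = rows.dropna(subset=["slope"]).groupby(group_col)["slope"]
        return pd.DataFrame(
            {
                "n_codons": g.size(),
                "q25": g.quantile(0.25),
                "median": g.median(),
                "q75": g.quantile(0.75),
            }
        )

    return rows, _summary("gc_count"), _summary("third_base")
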