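"""Per-codon variability of usage across a genome collection.

Two range statistics are computed per codon over the genomes x codons usage
matrix: the sample standard deviation, and Delta 90-10, the distance between
the 90th and 10th percentiles of the usage distribution. Codons occupying a
narrow range ("low variability") are distinguished from those spanning a wide
one ("variable"); the numeric label thresholds are this package's own
construction and are reported alongside the raw statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "usage_sd",
    "percentile",
    "VariabilityRecord",
    "variability_table",
    "sd_fold_changes",
    "histogram",
    "detect_modes",
]


def usage_sd(values) -> float:
    """Sample standard deviation (divisor n-1) of usage percentages."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("standard deviation needs at least 2 genomes")
    return float(np.std(values, ddof=1))


def percentile(values, q: float) -> float:
    """Percentile by linear interpolation between closest ranks.

    Rank position 1 + q(n-1)/100, the common "type 7" estimator (numpy's
    default 'linear' method).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of empty data")
    if not 0 <= q <= 100:
        raise ValueError(f"q must be in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))


@dataclass
class VariabilityRecord:
    codon: str
    n: int
    sd: float
    p10: float
    p90: float
    delta_90_10: float
    label: str


def variability_table(
    matrix: pd.DataFrame, thresholds: tuple[float, float] = (1.0, 3.0)
) -> pd.DataFrame:
    """Per-codon variability statistics over a genomes x codons matrix.

    Columns: n, sd, p10, p90, delta_90_10, label. The label is
    ``low_variability`` when Delta 90-10 < t_low, ``variable`` when it is
    > t_high, else ``intermediate``; thresholds default to (1.0, 3.0)
    percentage points.
    """
    t_low, t_high = thresholds
    if t_low < 0 or t_high < t_low:
        raise ValueError(f"bad thresholds {thresholds}")
    if len(matrix) < 2:
        raise ValueError("variability needs at least 2 genomes")
    vals = matrix.to_numpy(dtype=float)
    sd = np.std(vals, axis=0, ddof=1)
    p10 = np.percentile(vals, 10, axis=0, method="linear")
    p90 = np.percentile(vals, 90, axis=0, method="linear")
    delta = p90 - p10
    label = np.where(
        delta < t_low, "low_variability", np.where(delta > t_high, "variable", "intermediate")
    )
    return pd.DataFrame(
        {
            "n": len(matrix),
            "sd": sd,
            "p10": p10,
            "p90": p90,
            "delta_90_10": delta,
            "label": label,
        },
        index=pd.Index(matrix.columns, name="codon"),
    )


def sd_fold_changes(
    table_all: pd.DataFrame,
    table_heg: pd.DataFrame,
    direction_threshold: float = 1.5,
) -> pd.DataFrame:
    """Fold change of per-codon SD between all-genes and HEG usage.

    fold_change = max(sd_all, sd_heg) / min(sd_all, sd_heg); direction is
    ``decrease_in_heg`` / ``increase_in_heg`` when the fold change reaches
    ``direction_threshold``, else ``none``. A zero SD on either side leaves
    the fold change undefined (NaN, direction ``undefined``).
    """
    if not table_all.index.equals(table_heg.index):
        raise ValueError("tables must cover the same codons in the same order")
    sd_all = table_all["sd"].to_numpy(dtype=float)
    sd_heg = table_heg["sd"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.maximum(sd_all, sd_heg) / np.minimum(sd_all, sd_heg)
    undefined = (sd_all == 0) | (sd_heg == 0)
    fold = np.where(undefined, np.nan, fold)
    direction = np.full(len(fold), "none", dtype=object)
    meets = ~undefined & (fold >= direction_threshold)
    direction[meets & (sd_heg < sd_all)] = "decrease_in_heg"
    direction[meets & (sd_heg > sd_all)] = "increase_in_heg"
    direction[undefined] = "undefined"
    return pd.DataFrame(
        {
            "sd_all": sd_all,
            "sd_heg": sd_heg,
            "fold_change": fold,
            "direction": direction,
        },
        index=table_all.index,
    )


def histogram(values, bin_width: float, origin: float = 0.0) -> list[tuple[float, int]]:
    """Half-open histogram bins [k*w, (k+1)*w) anchored at ``origin``.

    Returns (bin_start, count) for every bin from the first to the last
    occupied one; counts sum to len(values). Empty input gives an empty list.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return []
    k = np.floor((values - origin) / bin_width).astype(int)
    counts = np.bincount(k - k.min())
    return [
        (origin + (k.min() + i) * bin_width, int(c)) for i, c in enumerate(counts)
    ]


def detect_modes(
    hist: list[tuple[float, int]], min_separation_bins: int = 1
) -> list[tuple[float, int]]:
    """Modal bins of a histogram: local maxima with a minimum separation.

    A bin is a local maximum when its count is strictly greater than both
    neighbors (boundary bins compare to their single neighbor). Candidates
    closer than ``min_separation_bins`` bins apart are resolved by keeping
    the higher-count one, ties broken toward the lower bin.
    """
    if not hist:
        return []
    counts = [c for _, c in hist]
    n = len(counts)
    candidates = []
    for i in range(n):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n - 1 else -1
        if counts[i] > left and counts[i] > right:
            candidates.append(i)
    # keep highest peaks first, enforcing the separation; ties -> lower bin
    order = sorted(candidates, key=lambda i: (-counts[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_separation_bins for j in kept):
            kept.append(i)
    return [hist[i] for i in sorted(kept)]
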