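"""Group comparisons between genomes defined by marker-gene presence/absence.

Genomes are stratified by whether a tRNA-modification marker gene (tsaB,
gluQ/GluQRS, tilS, tusE, ...) was detected, and codon usage, GC fraction or
genome size are compared between the strata with rank-based tests:
Wilcoxon-Mann-Whitney for two groups at the stringent alpha = 5e-5, and
Kruskal-Wallis with Dunn's post hoc (Holm-adjusted) for the four-way
tsaB x gluQ design. Tests are two-sided throughout; no across-codon
multiple-testing correction is applied to the two-group battery (Holm is
used only within the four-group pairwise family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.00005
#: combined-n switchover below/at which the rank-sum p is exact (tie-free data)
EXACT_N_MAX = 12

__all__ = [
    "ALPHA",
    "split_by_presence",
    "rank_sum_test",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "compare_all",
    "FourGroupResult",
    "four_group_gc",
    "filter_small_genomes",
]


def split_by_presence(
    values: pd.Series, presence: pd.DataFrame, marker: str
) -> tuple[pd.Series, pd.Series]:
    """Partition per-genome values by a marker's presence boolean."""
    if marker not in presence.columns:
        raise KeyError(f"marker {marker!r} not in presence table")
    missing = values.index.difference(presence.index)
    if len(missing):
        raise KeyError(f"genome {missing[0]!r} missing from presence table")
    flags = presence.loc[values.index, marker].astype(bool)
    return values[flags], values[~flags]


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U of x, p).

    The p-value is exact (distribution enumeration) when the combined sample
    size is at most 12 and the data are tie-free; otherwise the normal
    approximation with midranks, tie correction and continuity correction is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = x.size + y.size <= EXACT_N_MAX and not _has_ties(np.concatenate([x, y]))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if sum(1 for g in groups if g.size > 0) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups: list) -> pd.DataFrame:
    """Dunn's pairwise post hoc z tests on pooled midranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_j)] with the
    tie term T = sum(t^3 - t) / (12(N-1)); two-sided p from the standard
    normal. Returns one row per unordered pair (i < j, 0-based group index).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    pos = 0
    for n in sizes:
        mean_ranks.append(ranks[pos : pos + n].mean())
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        rows.append((i, j, float(z), float(2 * stats.norm.sf(abs(z)))))
    return pd.DataFrame(rows, columns=["i", "j", "z", "p_raw"])


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def compare_all(
    matrix: pd.DataFrame,
    presence: pd.DataFrame,
    markers: list[str],
    responses: list[str] | None = None,
    alpha: float = ALPHA,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Two-group rank-sum tests for every (marker, response) combination.

    ``matrix`` holds one numeric column per response (codon usages, or
    gc_fraction / genome_size_bp from the profile table). Pairs where either
    stratum is smaller than ``min_group_size`` are reported untested
    (tested=False, NaN p); small but tested groups near the threshold carry a
    small_group flag rather than being silently trusted.
    """
    responses = list(matrix.columns) if responses is None else responses
    rows = []
    for marker in markers:
        for resp in responses:
            present, absent = split_by_presence(matrix[resp], presence, marker)
            row = {
                "marker": marker,
                "response": resp,
                "n_present": len(present),
                "n_absent": len(absent),
                "median_present": float(present.median()) if len(present) else np.nan,
                "median_absent": float(absent.median()) if len(absent) else np.nan,
                "tested": False,
                "u_statistic": np.nan,
                "p_two_sided": np.nan,
                "significant": False,
                "small_group": min(len(present), len(absent)) < min_group_size,
            }
            if not row["small_group"]:
                u, p = rank_sum_test(present.to_numpy(), absent.to_numpy())
                row.update(
                    tested=True, u_statistic=u, p_two_sided=p, significant=p < alpha
                )
            rows.append(row)
    return pd.DataFrame(rows)


_GROUP_LABELS = ("both_present", "a_only", "b_only", "neither")


@dataclass
class FourGroupResult:
    """Kruskal-Wallis + Dunn + Holm outcome of a two-marker four-way split."""

    marker_a: str
    marker_b: str
    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    kw_h: float
    kw_p: float
    pairs: pd.DataFrame  # group_a, group_b, z, p_raw, p_holm, significant
    untested_groups: list[str] = field(default_factory=list)


def four_group_gc(
    gc: pd.Series,
    presence: pd.DataFrame,
    marker_a: str = "tsaB_motif1",
    marker_b: str = "gluQRS_motif3",
    alpha: float = ALPHA,
) -> FourGroupResult:
    """Compare a per-genome quantity across the marker_a x marker_b groups.

    Groups: both_present, a_only, b_only, neither. Empty groups leave their
    pairs untested; the test battery runs on the non-empty groups when at
    least two remain.
    """
    for m in (marker_a, marker_b):
        if m not in presence.columns:
            raise KeyError(f"marker {m!r} not in presence table")
    a = presence.loc[gc.index, marker_a].astype(bool)
    b = presence.loc[gc.index, marker_b].astype(bool)
    groups = {
        "both_present": gc[a & b],
        "a_only": gc[a & ~b],
        "b_only": gc[~a & b],
        "neither": gc[~a & ~b],
    }
    sizes = {k: len(v) for k, v in groups.items()}
    medians = {k: (float(v.median()) if len(v) else np.nan) for k, v in groups.items()}
    nonempty = [k for k in _GROUP_LABELS if sizes[k] > 0]
    untested = [k for k in _GROUP_LABELS if sizes[k] == 0]
    if len(nonempty) < 2:
        return FourGroupResult(
            marker_a, marker_b, sizes, medians, np.nan, np.nan,
            pd.DataFrame(
                columns=["group_a", "group_b", "z", "p_raw", "p_holm", "significant"]
            ),
            untested_groups=untested,
        )
    samples = [groups[k].to_numpy(dtype=float) for k in nonempty]
    kw_h, kw_p = kruskal_wallis(samples)
    dunn = dunn_posthoc(samples)
    dunn["group_a"] = [nonempty[i] for i in dunn["i"]]
    dunn["group_b"] = [nonempty[j] for j in dunn["j"]]
    dunn["p_holm"] = holm_adjust(dunn["p_raw"].to_numpy())
    dunn["significant"] = dunn["p_holm"] < alpha
    pairs = dunn[["group_a", "group_b", "z", "p_raw", "p_holm", "significant"]]
    return FourGroupResult(
        marker_a, marker_b, sizes, medians, kw_h, kw_p, pairs,
        untested_groups=untested,
    )


def filter_small_genomes(
    profiles: pd.DataFrame, min_cds: int = 401
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genomes with fewer than ``min_cds`` CDS (default: <= 400 removed).

    Sensitivity filter against the smallest (symbiont-like) genomes, whose
    marker absences may reflect annotation rather than biology.
    """
    keep = profiles["n_cds"] >= min_cds
    return profiles[keep], profiles[~keep]
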