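"""Mann-Whitney group comparisons, fold ratios, and two-study replication.

The Mann-Whitney U test here is permutation-exact for small samples even in
the presence of ties: with combined n <= 20 the null distribution of the
rank-sum statistic is computed over all C(n, n1) group assignments of the
observed midranks (by dynamic programming over doubled midranks, which are
integers), and the two-sided p-value is P(|U - n1*n2/2| >= |u_obs - n1*n2/2|)
under that distribution.  With no ties this reduces to the classical exact
Mann-Whitney distribution.  For larger samples a tie-corrected normal
approximation with continuity correction is used.

False positives are controlled by design rather than by multiple-testing
adjustment: a feature counts as replicated only if it is significant in two
independent studies with the same direction of change.  An optional
Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, StageError
from .peaktable import BIOLOGICAL_GROUPS, FeatureTable

EXACT_MAX_N = 20

#: The six pairwise combinations of the four biological groups, in the order
#: the summary tables report them.
PAIRWISE_COMPARISONS = [
    ("ND_UT", "DM_UT"),
    ("ND_TETA", "DM_TETA"),
    ("ND_UT", "ND_TETA"),
    ("DM_UT", "DM_TETA"),
    ("ND_UT", "DM_TETA"),
    ("ND_TETA", "DM_UT"),
]


def _exact_two_sided_p(pooled: np.ndarray, n1: int) -> tuple[float, float]:
    """Exact (U1, two-sided p) from the tied permutation distribution.

    Midranks of the pooled sample are doubled to integers; the distribution
    of the doubled rank-sum over all n1-subsets is built by DP.
    """
    n = len(pooled)
    n2 = n - n1
    ranks2 = np.rint(2 * sstats.rankdata(pooled)).astype(np.int64)
    r1_2 = int(ranks2[:n1].sum())
    u1 = (r1_2 - n1 * (n1 + 1)) / 2.0

    max_sum = int(ranks2.sum())
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for idx, r in enumerate(ranks2):
        r = int(r)
        top = min(n1, idx + 1)
        for k in range(top, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    counts = dp[n1]
    total = counts.sum()

    # deviation statistic on the doubled scale: |2*U - n1*n2|
    center = n1 * (n1 + 1) + n1 * n2
    sums = np.arange(max_sum + 1)
    dev = np.abs(sums - center)
    dev_obs = abs(r1_2 - center)
    p = counts[dev >= dev_obs].sum() / total
    return u1, float(p)


def _asymptotic_two_sided_p(pooled: np.ndarray, n1: int) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(pooled)
    n2 = n - n1
    ranks = sstats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return u1, float(min(1.0, 2.0 * sstats.norm.sf(z)))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is for the first sample.

    Non-finite values are excluded.  Exact tied-permutation p when the
    combined sample size is at most 20, normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise StageError("Mann-Whitney test needs at least one observation per group")
    pooled = np.concatenate([x, y])
    if len(pooled) <= EXACT_MAX_N:
        return _exact_two_sided_p(pooled, len(x))
    return _asymptotic_two_sided_p(pooled, len(x))


def group_ratio(x, y) -> tuple[float, str]:
    """median(y) / median(x) and its direction ('up' means y above x).

    Returns (nan, 'none') when either central value is non-positive or
    undefined, so a zero-median group never produces a fake fold change.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan"), "none"
    mx, my = float(np.median(x)), float(np.median(y))
    if mx <= 0 or my <= 0:
        return float("nan"), "none"
    ratio = my / mx
    if ratio > 1:
        return ratio, "up"
    if ratio < 1:
        return ratio, "down"
    return ratio, "none"


def differential_features(table: FeatureTable, comparison: tuple, alpha: float = 0.05,
                          p_adjust: str = "none"):
    """Per-feature Mann-Whitney comparison between two groups.

    ``comparison`` is an ordered (group1, group2) pair; the reported ratio is
    group2 central value over group1 (for example DM/ND when comparing
    non-diabetic against diabetic).  Missing values are excluded per feature;
    features with an empty group are skipped and listed.

    Returns ``(results, skipped)``: a DataFrame indexed by feature_id with
    columns u, p, p_adjusted, significant, ratio, direction, n1, n2, and the
    list of skipped feature ids.
    """
    g1, g2 = comparison
    for g in comparison:
        if g not in BIOLOGICAL_GROUPS:
            raise ConfigError(f"unknown group label {g!r}")
    if p_adjust not in ("none", "bh"):
        raise ConfigError("p_adjust must be 'none' or 'bh'")

    rows, skipped = [], []
    for fid in table.intensities.index:
        x = table.group_values(fid, g1)
        y = table.group_values(fid, g2)
        if len(x) == 0 or len(y) == 0:
            skipped.append(fid)
            continue
        u, p = mann_whitney_u(x, y)
        ratio, direction = group_ratio(x, y)
        rows.append((fid, u, p, ratio, direction, len(x), len(y)))
    results = pd.DataFrame(
        rows, columns=["feature_id", "u", "p", "ratio", "direction", "n1", "n2"]
    ).set_index("feature_id")
    if len(results):
        if p_adjust == "bh":
            results["p_adjusted"] = multipletests(results["p"], method="fdr_bh")[1]
        else:
            results["p_adjusted"] = results["p"]
        results["significant"] = results["p_adjusted"] < alpha
    else:
        results["p_adjusted"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
    return results, skipped


def replication_filter(results_study1: pd.DataFrame, results_study2: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Features significant in both studies with the same direction of change.

    Implements the replication rule: p < alpha in each study independently
    and an identical (non-'none') direction.  Output is sorted by the study-1
    p-value, mirroring the replicated-feature tables.
    """
    merged = results_study1.join(results_study2, how="inner",
                                 lsuffix="_study1", rsuffix="_study2")
    keep = (
        (merged["p_study1"] < alpha)
        & (merged["p_study2"] < alpha)
        & (merged["direction_study1"] == merged["direction_study2"])
        & (merged["direction_study1"] != "none")
    )
    out = merged[keep].sort_values("p_study1").copy()
    out["consistent_direction"] = True
    return out


def match_features_across_studies(features1: pd.DataFrame, features2: pd.DataFrame,
                                  tol_ppm: float = 5.0, rt_tol: float = 10.0) -> dict:
    """Greedy nearest-match of features between two runs by m/z (ppm) and rt.

    For real data, where feature ids are run-specific.  Each study-1 feature
    is matched to the closest unclaimed study-2 feature (same ion mode)
    within both tolerances; closeness is the ppm error.  Synthetic data
    shares feature ids across studies and does not need this.
    """
    available = features2.copy()
    mapping: dict = {}
    for fid, row in features1.sort_index().iterrows():
        cand = available[available["ion_mode"] == row["ion_mode"]]
        if cand.empty:
            continue
        ppm = 1e6 * (cand["mz"] - row["mz"]).abs() / row["mz"]
        ok = cand[(ppm <= tol_ppm) & ((cand["rt"] - row["rt"]).abs() <= rt_tol)]
        if ok.empty:
            continue
        best = (1e6 * (ok["mz"] - row["mz"]).abs() / row["mz"]).idxmin()
        mapping[fid] = best
        available = available.drop(index=best)
    return mapping


def comparison_summary(per_study_results: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Counts of significant and replicated features per pairwise comparison.

    ``per_study_results`` maps study_id -> {comparison: results DataFrame}.
    The replicated column can only be smaller than either study's column.
    """
    studies = sorted(per_study_results)
    rows = []
    for comparison in PAIRWISE_COMPARISONS:
        key = f"{comparison[0]}_vs_{comparison[1]}"
        counts = {}
        for sid in studies:
            res = per_study_results[sid].get(comparison)
            counts[f"study{sid}"] = int((res["p"] < alpha).sum()) if res is not None else 0
        res1 = per_study_results[studies[0]].get(comparison)
        res2 = per_study_results[studies[1]].get(comparison) if len(studies) > 1 else None
        if res1 is not None and res2 is not None:
            counts["both_studies"] = len(replication_filter(res1, res2, alpha))
        else:
            counts["both_studies"] = 0
        rows.append({"comparison": key, **counts})
    return pd.DataFrame(rows).set_index("comparison")
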