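"""Study-condition evaluations: the checks that validate the whole pipeline.

Each function here sets up a defined study condition (a synthetic design, a
null, a combinatorial identity), runs the package's own machinery on it, and
returns the measured quantities.  They are shared by the acceptance test
suite and the standalone acceptance script so both report the same numbers.

Brute-force oracles in this module are deliberately independent of the
implementation paths they check: the Mann-Whitney oracle enumerates group
assignments with itertools, the Spearman oracle computes midranks by hand,
and the QA oracle re-applies the detection/RSD rules feature by feature.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import corrnet, qc, univariate
from .annotate import C13_C12_DELTA, assign_charge_state
from .corrnet import CascadeThresholds
from .peaktable import FeatureTable
from .simulate import SyntheticConfig, generate_study

#: Eligible feature counts of the reference correlation analysis (positive
#: and negative ion mode); the pair counts over them are fixed identities.
REFERENCE_FEATURE_COUNTS = {"positive": 3610, "negative": 1983}


# ---------------------------------------------------------------- pair counts

def pair_count_identities() -> dict:
    """Unordered pair counts the correlation stage evaluates per ion mode."""
    return {
        mode: corrnet.n_candidate_pairs(n)
        for mode, n in REFERENCE_FEATURE_COUNTS.items()
    }


# ------------------------------------------------- Mann-Whitney exact oracle

def mann_whitney_permutation_p(x, y) -> tuple:
    """Exhaustive-permutation two-sided Mann-Whitney p (independent oracle).

    Enumerates every assignment of the pooled observations into groups of
    sizes (n1, n2) via itertools.combinations and counts assignments whose U
    deviates from n1*n2/2 at least as much as the observed one.  Midranks are
    computed by hand from the pooled sorted values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    n2 = n - n1

    # hand-rolled midranks: average 1-based positions of tied values
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1

    mu = n1 * n2 / 2.0

    def u_of(idx_tuple) -> float:
        return ranks[list(idx_tuple)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mu) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


def mann_whitney_oracle_deviation(seed: int, n_samples: int = 200) -> float:
    """Max |p_exact - p_permutation| over random small tied samples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        n1 = int(rng.integers(2, 9))
        n2 = int(rng.integers(2, 9))
        # draws from a small integer support guarantee ties
        x = rng.integers(0, 6, size=n1).astype(float)
        y = rng.integers(0, 6, size=n2).astype(float)
        _, p_impl = univariate.mann_whitney_u(x, y)
        _, p_oracle = mann_whitney_permutation_p(x, y)
        worst = max(worst, abs(p_impl - p_oracle))
    return worst


# ---------------------------------------------------------- type-I error null

def _null_config(seed: int, n_features: int) -> SyntheticConfig:
    """Two ten-per-group studies with no differential or correlation structure."""
    return SyntheticConfig(
        n_per_group={
            1: {g: 10 for g in ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA")},
            2: {g: 10 for g in ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA")},
        },
        n_metabolites=n_features,
        features_per_metabolite_probs=(1.0, 0.0, 0.0),
        n_differential=0,
        n_reversal_blocks=0,
        drift_amplitude=0.0,
        noise_cv=0.10,
        missing_rate=0.0,
        seed=seed,
    )


def type_one_error_rates(seed: int, n_features: int = 2000,
                         alpha: float = 0.05) -> dict:
    """Significant fraction and cross-study replication rate on null data."""
    config = _null_config(seed, n_features)
    results = {}
    for sid in (1, 2):
        table, _ = generate_study(config, sid)
        res, _ = univariate.differential_features(table, ("ND_UT", "DM_UT"), alpha=alpha)
        results[sid] = res
    frac_sig = float((results[1]["p"] < alpha).mean())
    replicated = univariate.replication_filter(results[1], results[2], alpha=alpha)
    return {
        "significant_fraction": frac_sig,
        "replication_rate": len(replicated) / len(results[1]),
        "n_features": len(results[1]),
    }


# ------------------------------------------------------- QC-RLSC effectiveness

def qc_correction_effectiveness(seed: int, n_features: int = 200) -> dict:
    """Median QC RSD before/after correction under drift, and the no-drift limit."""
    drift_cfg = SyntheticConfig(
        n_metabolites=n_features, features_per_metabolite_probs=(1.0, 0.0, 0.0),
        n_differential=0, n_reversal_blocks=0,
        drift_amplitude=0.3, noise_cv=0.05, missing_rate=0.0, seed=seed,
    )
    table, _ = generate_study(drift_cfg, 2)
    before = float(qc.qc_rsd_summary(table).median())
    corrected, _ = qc.qc_rlsc_correct(table)
    after = float(qc.qc_rsd_summary(corrected).median())

    clean_cfg = SyntheticConfig(
        n_metabolites=50, features_per_metabolite_probs=(1.0, 0.0, 0.0),
        n_differential=0, n_reversal_blocks=0,
        drift_amplitude=0.0, noise_cv=0.0, missing_rate=0.0, seed=seed,
    )
    clean, _ = generate_study(clean_cfg, 2)
    identity, _ = qc.qc_rlsc_correct(clean)
    raw = clean.intensities.to_numpy(dtype=float)
    out = identity.intensities.to_numpy(dtype=float)
    max_rel_err = float(np.nanmax(np.abs(out - raw) / raw))
    return {
        "median_qc_rsd_before": before,
        "median_qc_rsd_after": after,
        "no_drift_max_relative_error": max_rel_err,
    }


# -------------------------------------------------------- reversal recovery

def _recovery_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_metabolites=30, features_per_metabolite_probs=(1.0, 0.0, 0.0),
        n_differential=0, n_reversal_blocks=1, block_size=12,
        within_block_rho=0.9,
        n_per_group={2: {g: 10 for g in ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA")}},
        drift_amplitude=0.0, noise_cv=0.10, missing_rate=0.0, seed=seed,
    )


def _cascade_on(table: FeatureTable, metabolite_map: dict, seed: int,
                thresholds: CascadeThresholds):
    sets = {
        g: corrnet.group_correlation_matrix(table, g, thresholds, seed=seed)
        for g in ("ND_UT", "DM_UT", "DM_TETA")
    }
    return corrnet.reversal_candidates(
        sets["ND_UT"], sets["DM_UT"], sets["DM_TETA"], thresholds, metabolite_map)


def reversal_block_recovery(seeds) -> dict:
    """Recall of a 12-metabolite reversal block and partner purity, per seed.

    One reversal block (target rank correlation 0.9), ten animals per group;
    recall is the fraction of block features reported as cascade candidates,
    purity the fraction of reported partner links connecting two block
    features (pooled over seeds).
    """
    thresholds = CascadeThresholds()
    recalls = []
    purity_num = purity_den = 0
    for seed in seeds:
        table, truth = generate_study(_recovery_config(seed), 2)
        block = truth.block_features()
        candidates, _ = _cascade_on(table, truth.feature_to_metabolite, seed, thresholds)
        found = {c.feature_id for c in candidates}
        recalls.append(len(found & block) / len(block))
        for cand in candidates:
            for partner in cand.partners:
                purity_den += 1
                if cand.feature_id in block and partner[0] in block:
                    purity_num += 1
    return {
        "recall_per_seed": recalls,
        "mean_recall": float(np.mean(recalls)),
        "min_recall": float(np.min(recalls)),
        "partner_purity": purity_num / purity_den if purity_den else float("nan"),
    }


def reversal_null_specificity(seeds, n_features: int = 50) -> dict:
    """Cascade candidates under a global null of independent features."""
    thresholds = CascadeThresholds()
    zero_seeds = 0
    totals = []
    for seed in seeds:
        config = SyntheticConfig(
            n_metabolites=n_features, features_per_metabolite_probs=(1.0, 0.0, 0.0),
            n_differential=0, n_reversal_blocks=0,
            n_per_group={2: {g: 10 for g in ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA")}},
            drift_amplitude=0.0, noise_cv=0.10, missing_rate=0.0, seed=seed,
        )
        table, truth = generate_study(config, 2)
        candidates, _ = _cascade_on(table, truth.feature_to_metabolite, seed, thresholds)
        totals.append(len(candidates))
        if len(candidates) == 0:
            zero_seeds += 1
    return {"seeds_with_zero_candidates": zero_seeds, "n_seeds": len(list(seeds)),
            "candidates_per_seed": totals}


# ------------------------------------------------------------- charge states

def charge_assignment_accuracy(offsets=(-0.004, 0.0, 0.004), z_values=(1, 2, 3)) -> float:
    """Fraction of perturbed isotope spacings assigned the generating charge."""
    correct = total = 0
    for z in z_values:
        for off in offsets:
            total += 1
            if assign_charge_state([C13_C12_DELTA / z + off]) == z:
                correct += 1
    return correct / total


# ------------------------------------------- Spearman / QA brute-force oracles

def spearman_brute_force(x, y) -> float:
    """Midranks by hand, then the Pearson formula written out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]

    def midranks(v):
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = midranks(x), midranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx ** 2) * np.sum(dy ** 2)))


def spearman_oracle_deviation(seed: int, n_samples: int = 200) -> float:
    """Max |spearman_rho - brute force| over random tied vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        n = int(rng.integers(4, 30))
        x = rng.integers(0, 8, size=n).astype(float)
        y = rng.integers(0, 8, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        worst = max(worst, abs(corrnet.spearman_rho(x, y) - spearman_brute_force(x, y)))
    return worst


def qa_filter_brute_force(table: FeatureTable, detection_threshold: float = 0.60,
                          rsd_threshold: float = 20.0,
                          qc_from_injection: int = 8) -> set:
    """Feature-by-feature recomputation of both QA criteria."""
    entries = table.manifest.entries
    window_ids = [
        sid for sid, row in entries.iterrows()
        if row["group"] == "QC" and row["injection_order"] >= qc_from_injection
    ]
    retained = set()
    for fid in table.intensities.index:
        vals = [table.intensities.at[fid, sid] for sid in window_ids]
        detected = sum(1 for v in vals if pd.notna(v) and v > 0)
        frac = detected / len(window_ids)
        present = [v for v in vals if pd.notna(v)]
        if len(present) < 2:
            continue
        mean = sum(present) / len(present)
        if mean == 0:
            continue
        sd = (sum((v - mean) ** 2 for v in present) / (len(present) - 1)) ** 0.5
        rsd = 100.0 * sd / mean
        if frac > detection_threshold and rsd < rsd_threshold:
            retained.add(fid)
    return retained


def qa_oracle_mismatch(seed: int) -> int:
    """Symmetric difference between qa_filter and its brute-force oracle."""
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(
        n_metabolites=120, n_differential=10, n_reversal_blocks=0,
        drift_amplitude=0.2, noise_cv=float(rng.uniform(0.05, 0.3)),
        missing_rate=0.2, seed=seed,
    )
    table, _ = generate_study(config, 1)
    filtered, _ = qc.qa_filter(table)
    oracle = qa_filter_brute_force(table)
    return len(set(filtered.intensities.index) ^ oracle)
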