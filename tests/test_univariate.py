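"""Mann-Whitney exactness, ratios, and the replication filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabocorr import (
    ConfigError,
    SyntheticConfig,
    differential_features,
    generate_study,
    group_ratio,
    mann_whitney_u,
    replication_filter,
)
from metabocorr.evaluation import (
    mann_whitney_oracle_deviation,
    mann_whitney_permutation_p,
)

from conftest import make_manifest, make_table


def test_fully_separated_small_samples():
    """x < y everywhere with n=3 vs 3: U=0, exact two-sided p = 2/20."""
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1, abs=1e-12)


def test_identical_tied_samples_give_p_one():
    _, p = mann_whitney_u([5, 5, 7, 7], [5, 5, 7, 7])
    assert p == pytest.approx(1.0, abs=1e-9)


def test_exact_p_matches_permutation_oracle_on_tied_samples():
    assert mann_whitney_oracle_deviation(seed=7, n_samples=60) <= 1e-9


def test_large_sample_path_agrees_with_scipy_asymptotics():
    rng = np.random.default_rng(12)
    for _ in range(20):
        x = rng.integers(0, 12, size=15).astype(float)
        y = rng.integers(0, 12, size=14).astype(float) + rng.integers(0, 3)
        _, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


@pytest.mark.parametrize("transform", [np.exp, lambda v: 3 * v - 7, np.cbrt])
def test_p_invariant_under_monotone_transforms(transform):
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 8)
    y = rng.normal(0.5, 1, 6)
    _, p0 = mann_whitney_u(x, y)
    _, p1 = mann_whitney_u(transform(x), transform(y))
    assert p1 == pytest.approx(p0, abs=1e-12)


def test_p_invariant_under_sample_reordering():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 5, 9).astype(float)
    y = rng.integers(0, 5, 7).astype(float)
    u0, p0 = mann_whitney_u(x, y)
    u1, p1 = mann_whitney_u(rng.permutation(x), rng.permutation(y))
    assert (u0, p0) == (u1, p1)


def test_group_ratio_orientation_and_degenerate_cases():
    assert group_ratio([10, 10, 10], [25, 25, 25]) == (2.5, "up")
    assert group_ratio([10, 10, 10], [5, 5, 5]) == (0.5, "down")
    ratio, direction = group_ratio([0, 0, 0], [5, 5, 5])
    assert np.isnan(ratio) and direction == "none"


def test_injected_fold_change_recovered_by_median_ratio():
    """Median DM/ND ratio tracks the injected fold within 25% on average."""
    errors = []
    for seed in range(20):
        config = SyntheticConfig(
            n_metabolites=10, features_per_metabolite_probs=(1.0, 0.0, 0.0),
            n_differential=4, n_reversal_blocks=0, effect_ratio_range=(2.0, 4.0),
            drift_amplitude=0.0, noise_cv=0.10, missing_rate=0.0, seed=seed,
            n_per_group={2: {g: 10 for g in ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA")}},
        )
        table, truth = generate_study(config, 2)
        for fid, mult in truth.differential_features().items():
            ratio, _ = group_ratio(table.group_values(fid, "ND_UT"),
                                   table.group_values(fid, "DM_UT"))
            errors.append(abs(ratio - mult) / mult)
    assert np.mean(errors) < 0.25


def test_all_missing_feature_is_skipped():
    manifest = make_manifest(
        [("Q1", "QC", 1)]
        + [(f"A{i}", "ND_UT", i + 2) for i in range(4)]
        + [(f"B{i}", "DM_UT", i + 6) for i in range(4)]
    )
    data = pd.DataFrame(
        np.vstack([np.ones(9) * 5, np.full(9, np.nan)]),
        index=["present", "absent"], columns=manifest.sample_ids)
    table = make_table(data, manifest)
    results, skipped = differential_features(table, ("ND_UT", "DM_UT"))
    assert "absent" in skipped
    assert list(results.index) == ["present"]


def test_unknown_group_label_rejected(small_study):
    table, _ = small_study
    with pytest.raises(ConfigError):
        differential_features(table, ("ND_UT", "HEALTHY"))


def _fake_results(rows):
    return pd.DataFrame(rows, columns=["feature_id", "p", "direction"]).set_index(
        "feature_id")


def test_replication_requires_both_studies_and_same_direction():
    s1 = _fake_results([("a", 0.01, "up"), ("b", 0.01, "up"), ("c", 0.01, "up"),
                        ("d", 0.2, "up")])
    s2 = _fake_results([("a", 0.2, "up"), ("b", 0.01, "down"), ("c", 0.02, "up"),
                        ("d", 0.01, "up")])
    rep = replication_filter(s1, s2)
    assert list(rep.index) == ["c"]       # a: study-2 ns; b: direction flip; d: study-1 ns
    assert bool(rep["consistent_direction"].all())


def test_replicated_set_is_subset_of_each_study(small_study):
    table, _ = small_study
    config = SyntheticConfig(n_metabolites=24, n_differential=6,
                             n_reversal_blocks=1, block_size=5, seed=11)
    t1, _ = generate_study(config, 1)
    r1, _ = differential_features(t1, ("ND_UT", "DM_UT"))
    r2, _ = differential_features(table, ("ND_UT", "DM_UT"))
    rep = replication_filter(r1, r2)
    sig1 = set(r1.index[r1["p"] < 0.05])
    sig2 = set(r2.index[r2["p"] < 0.05])
    assert set(rep.index) <= sig1 and set(rep.index) <= sig2


def test_injected_differentials_detected_with_high_power():
    """Fold >= 2 at n=10 vs 10 and 10% noise: nearly always significant."""
    detected = total = 0
    for seed in range(20):
        config = SyntheticConfig(
            n_metabolites=12, features_per_metabolite_probs=(1.0, 0.0, 0.0),
            n_differential=4, n_reversal_blocks=0, effect_ratio_range=(2.0, 5.0),
            drift_amplitude=0.0, noise_cv=0.10, missing_rate=0.0, seed=seed,
            n_per_group={2: {g: 10 for g in ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA")}},
        )
        table, truth = generate_study(config, 2)
        results, _ = differential_features(table, ("ND_UT", "DM_UT"))
        for fid in truth.differential_features():
            total += 1
            if results.at[fid, "p"] < 0.05:
                detected += 1
    assert detected / total >= 0.90
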