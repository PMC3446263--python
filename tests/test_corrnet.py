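"""Spearman/bootstrap machinery and the reversal cascade rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabocorr import (
    CascadeThresholds,
    CorrelationSet,
    bootstrap_rho,
    group_correlation_matrix,
    n_candidate_pairs,
    reversal_candidates,
    spearman_rho,
)
from metabocorr.corrnet import pair_passes_cascade
from metabocorr.evaluation import spearman_brute_force, spearman_oracle_deviation

from conftest import make_manifest, make_table


def test_monotone_relationships_give_unit_rho():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)


def test_missing_values_excluded_pairwise():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 4.0, 100.0, 8.0, 10.0]
    assert spearman_rho(x, y) == pytest.approx(1.0)


def test_fewer_than_three_complete_pairs_undefined():
    assert np.isnan(spearman_rho([1, 2, np.nan], [1, np.nan, 2]))


def test_spearman_matches_midrank_pearson_brute_force():
    assert spearman_oracle_deviation(seed=5, n_samples=120) <= 1e-12


@settings(deadline=None, derandomize=True, max_examples=80)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                min_size=3, max_size=25))
def test_spearman_property_matches_oracle_on_arbitrary_tied_data(pairs):
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        assert np.isnan(spearman_rho(x, y))
    else:
        assert spearman_rho(x, y) == pytest.approx(spearman_brute_force(x, y),
                                                   abs=1e-12)


def test_bootstrap_of_monotone_data_is_one_for_every_seed():
    x = np.arange(10.0)
    y = x ** 2
    for seed in range(5):
        rho, n = bootstrap_rho(x, y, seed=seed)
        assert rho == pytest.approx(1.0)
        assert n == 10


def test_bootstrap_below_min_pairs_excluded():
    rho, n = bootstrap_rho([1, 2, 3, 4, 5], [5, 3, 4, 1, 2], min_pairs=6)
    assert np.isnan(rho) and n == 5


def test_bootstrap_is_calibrated_on_bivariate_normal():
    """Median-aggregated bootstrap rho tracks a 0.7 rank correlation at n=10."""
    target_pearson = 2 * np.sin(np.pi * 0.7 / 6)
    rng = np.random.default_rng(0)
    estimates = []
    for seed in range(200):
        z = rng.standard_normal((2, 10))
        x = z[0]
        y = target_pearson * z[0] + np.sqrt(1 - target_pearson ** 2) * z[1]
        rho, _ = bootstrap_rho(x, y, seed=seed)
        estimates.append(rho)
    assert abs(np.mean(estimates) - 0.7) < 0.1


def _corr_table(n_features=4, n_samples=8, missing=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = [(f"S{i}", "ND_UT", i + 2) for i in range(n_samples)] + [("Q", "QC", 1)]
    manifest = make_manifest(rows)
    data = pd.DataFrame(rng.uniform(10, 100, size=(n_features, n_samples + 1)),
                        index=[f"f{i}" for i in range(n_features)],
                        columns=manifest.sample_ids)
    if missing:
        for fid, sids in missing.items():
            data.loc[fid, sids] = np.nan
    return make_table(data, manifest)


def test_group_matrix_enumerates_all_pairs():
    table = _corr_table(n_features=4)
    cs = group_correlation_matrix(table, "ND_UT", seed=0)
    assert len(cs.pairs) == 6 == n_candidate_pairs(4)
    assert all(a != b for a, b in cs.pairs)
    assert all(-1 <= rho <= 1 for rho, _ in cs.pairs.values())


def test_pairs_below_complete_pair_minimum_are_dropped():
    missing = {"f0": [f"S{i}" for i in range(3)]}   # only 5 complete vs f1..f3
    table = _corr_table(n_features=4, missing=missing)
    cs = group_correlation_matrix(table, "ND_UT", seed=0)
    assert len(cs.pairs) == 3                        # pairs among f1,f2,f3 only
    assert all("f0" not in pair for pair in cs.pairs)
    # brute-force completeness count agrees
    vals = table.intensities[table.manifest.group_ids("ND_UT")]
    for a, b in cs.pairs:
        n_complete = int((vals.loc[a].notna() & vals.loc[b].notna()).sum())
        assert n_complete >= 6


def test_result_invariant_to_feature_ordering():
    table = _corr_table(n_features=5, seed=3)
    cs1 = group_correlation_matrix(table, "ND_UT", seed=9)
    reordered = table.subset_features(list(table.intensities.index)[::-1])
    cs2 = group_correlation_matrix(reordered, "ND_UT", seed=9)
    assert cs1.pairs == cs2.pairs


@pytest.mark.parametrize("rhos,expected", [
    ((0.9, 0.1, 0.8), True),     # lost in disease, restored by treatment
    ((0.9, 0.6, 0.8), False),    # change 0.3 <= 0.5
    ((0.6, -0.6, 0.55), True),   # sign switch, change 1.2
    ((0.4, -0.4, 0.9), False),   # control correlation not high
    ((0.9, 0.1, 0.3), False),    # not restored under treatment
])
def test_cascade_threshold_rules(rhos, expected):
    assert pair_passes_cascade(*rhos, CascadeThresholds()) is expected


def _sets_from(pair_rhos):
    """pair_rhos: {(a, b): (rho_nd, rho_dm, rho_dmt)}"""
    out = []
    for k in range(3):
        cs = CorrelationSet(group=["ND_UT", "DM_UT", "DM_TETA"][k])
        cs.pairs = {pair: (rhos[k], 10) for pair, rhos in pair_rhos.items()}
        out.append(cs)
    return out


def test_same_metabolite_pairs_removed_and_degree_counts_metabolites():
    # star around 'hub': 3 partner features, but two map to one metabolite
    pair_rhos = {
        ("hub", "p1"): (0.9, 0.0, 0.9),
        ("hub", "p2"): (0.9, 0.0, 0.9),
        ("hub", "p3"): (0.9, 0.0, 0.9),
        ("hub", "sib"): (0.95, 0.0, 0.95),   # same metabolite as hub -> removed
    }
    met_map = {"hub": "M1", "sib": "M1", "p1": "M2", "p2": "M2", "p3": "M3"}
    thresholds = CascadeThresholds(min_degree=2)
    cands, edges = reversal_candidates(*_sets_from(pair_rhos),
                                       thresholds=thresholds, metabolite_map=met_map)
    by_id = {c.feature_id: c for c in cands}
    assert by_id["hub"].partner_metabolite_count == 2     # M2 and M3, not 3 features
    removed = edges[edges["same_metabolite"]]
    assert len(removed) == 1 and not bool(removed["passes_cascade"].iloc[0])


def test_candidate_sets_shrink_as_thresholds_tighten():
    rng = np.random.default_rng(14)
    pair_rhos = {}
    feats = [f"f{i}" for i in range(12)]
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            pair_rhos[(feats[i], feats[j])] = tuple(rng.uniform(-1, 1, 3))
    loose = CascadeThresholds(high_corr=0.3, delta=0.3, min_degree=1)
    tight_corr = CascadeThresholds(high_corr=0.6, delta=0.3, min_degree=1)
    tight_delta = CascadeThresholds(high_corr=0.3, delta=0.8, min_degree=1)
    high_degree = CascadeThresholds(high_corr=0.3, delta=0.3, min_degree=4)

    def passing(th):
        _, edges = reversal_candidates(*_sets_from(pair_rhos), thresholds=th)
        return set(map(tuple, edges[edges["passes_cascade"]][
            ["feature_a", "feature_b"]].to_numpy()))

    def cand_feats(th):
        cands, _ = reversal_candidates(*_sets_from(pair_rhos), thresholds=th)
        return {c.feature_id for c in cands}

    assert passing(tight_corr) <= passing(loose)
    assert passing(tight_delta) <= passing(loose)
    assert cand_feats(high_degree) <= cand_feats(loose)


def test_disjoint_pair_spaces_rejected():
    a = _sets_from({("x", "y"): (0.9, 0.0, 0.9)})
    b = _sets_from({("u", "v"): (0.9, 0.0, 0.9)})
    with pytest.raises(Exception):
        reversal_candidates(a[0], b[1], b[2])
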