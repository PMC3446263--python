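"""Charge states, ppm matching against brute force, and metabolite grouping."""

import numpy as np
import pytest

from metabocorr import (
    ConfigError,
    ReferenceEntry,
    assign_charge_state,
    group_features_by_metabolite,
    match_metabolites,
)
from metabocorr.annotate import C13_C12_DELTA, DEFAULT_ADDUCTS


class Feat:
    def __init__(self, feature_id, mz, rt=100.0, ion_mode="positive"):
        self.feature_id = feature_id
        self.mz = mz
        self.rt = rt
        self.ion_mode = ion_mode


@pytest.mark.parametrize("z", [1, 2, 3])
def test_isotope_spacing_assigns_generating_charge(z):
    assert assign_charge_state([C13_C12_DELTA / z]) == z


def test_off_grid_spacing_is_unknown():
    assert assign_charge_state([0.40]) is None


def test_charge_robust_across_tolerance_band():
    """Every spacing delta/z + eps with |eps| < tol/2 maps back to z."""
    tol = 0.01
    for z in (1, 2, 3, 4):
        for eps in np.linspace(-tol / 2 + 1e-6, tol / 2 - 1e-6, 9):
            assert assign_charge_state([C13_C12_DELTA / z + eps], tolerance=tol) == z


def test_nonpositive_spacing_rejected():
    with pytest.raises(ConfigError):
        assign_charge_state([-0.5])


PROTON = 1.007276466


def test_zero_tolerance_keeps_only_exact_masses():
    ref = [ReferenceEntry("m1", "exact", 180.063388),
           ReferenceEntry("m2", "near", 180.063388 * (1 + 2e-6))]
    feat = Feat("f", 180.063388 + PROTON)
    rec = match_metabolites(feat, 1, ref, tol_ppm=0.0)
    assert [c[0] for c in rec.candidates] == ["m1"]


def test_rt_window_excludes_candidates():
    ref = [ReferenceEntry("m1", "early", 180.063388, rt_window=(10.0, 50.0))]
    rec = match_metabolites(Feat("f", 180.063388 + PROTON, rt=200.0), 1, ref)
    assert rec.candidates == []
    rec = match_metabolites(Feat("f", 180.063388 + PROTON, rt=30.0), 1, ref)
    assert [c[0] for c in rec.candidates] == ["m1"]


def test_candidates_match_exhaustive_scan_of_reference_and_adducts():
    rng = np.random.default_rng(17)
    ref = [ReferenceEntry(f"m{i}", f"met{i}", float(m))
           for i, m in enumerate(rng.uniform(100, 900, 500))]
    for trial in range(30):
        mode = "positive" if trial % 2 == 0 else "negative"
        feat = Feat(f"f{trial}", float(rng.uniform(80, 950)), ion_mode=mode)
        rec = match_metabolites(feat, None, ref, tol_ppm=5.0)
        expected = set()
        for adduct in DEFAULT_ADDUCTS:
            if adduct.ion_mode != mode:
                continue
            neutral = feat.mz * adduct.charge - adduct.mass_shift
            for entry in ref:
                ppm = 1e6 * (neutral - entry.monoisotopic_mass) / entry.monoisotopic_mass
                if abs(ppm) <= 5.0:
                    expected.add((entry.metabolite_id, adduct.label))
        assert {(c[0], c[1]) for c in rec.candidates} == expected
        assert all(abs(c[2]) <= 5.0 for c in rec.candidates)
        ppms = [abs(c[2]) for c in rec.candidates]
        assert ppms == sorted(ppms)


def test_shrinking_tolerance_never_adds_candidates():
    rng = np.random.default_rng(23)
    ref = [ReferenceEntry(f"m{i}", f"met{i}", float(m))
           for i, m in enumerate(rng.uniform(100, 500, 200))]
    feat = Feat("f", float(rng.uniform(100, 500)))
    previous = None
    for tol in (20.0, 10.0, 5.0, 1.0, 0.0):
        ids = {(c[0], c[1]) for c in match_metabolites(feat, None, ref, tol_ppm=tol).candidates}
        if previous is not None:
            assert ids <= previous
        previous = ids


def test_empty_reference_rejected():
    with pytest.raises(ConfigError):
        match_metabolites(Feat("f", 200.0), 1, [])


def _annotated(fid, mid, ppm=1.0, second=None):
    from metabocorr import AnnotationRecord
    cands = [(mid, "[M+H]+", ppm)]
    if second:
        cands.append(second)
    return AnnotationRecord(fid, 1, cands)


def test_coeluting_features_with_shared_top_candidate_are_grouped():
    recs = [_annotated("a", "glucose"), _annotated("b", "glucose")]
    mapping = group_features_by_metabolite(recs, {"a": 100.0, "b": 102.0})
    assert mapping["a"] == mapping["b"]


def test_non_coeluting_features_split_into_separate_groups():
    recs = [_annotated("a", "glucose"), _annotated("b", "glucose")]
    mapping = group_features_by_metabolite(recs, {"a": 100.0, "b": 130.0})
    assert mapping["a"] != mapping["b"]


def test_ambiguous_and_unannotated_features_are_singletons():
    from metabocorr import AnnotationRecord
    amb = AnnotationRecord("amb", 1, [("m1", "[M+H]+", 2.0), ("m2", "[M+Na]+", 2.0)])
    none = AnnotationRecord("none", None, [])
    mapping = group_features_by_metabolite([amb, none], {"amb": 50.0, "none": 60.0})
    assert mapping["amb"] != mapping["none"]
    assert len(set(mapping.values())) == 2


def test_grouping_is_a_partition():
    rng = np.random.default_rng(31)
    recs, rts = [], {}
    for i in range(40):
        fid = f"f{i}"
        recs.append(_annotated(fid, f"m{i % 7}"))
        rts[fid] = float(rng.uniform(0, 600))
    mapping = group_features_by_metabolite(recs, rts)
    assert set(mapping) == set(rts)          # every feature mapped exactly once


def test_adduct_siblings_recovered_from_reference_masses():
    """Features built as adducts of reference metabolites regroup correctly."""
    rng = np.random.default_rng(41)
    hits = total = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        masses = rng.uniform(150, 800, 25)
        # spread masses apart so annotation is unambiguous at 5 ppm
        masses = np.sort(masses) + np.arange(25) * 0.5
        ref = [ReferenceEntry(f"m{i}", f"met{i}", float(m))
               for i, m in enumerate(masses)]
        adducts = [a for a in DEFAULT_ADDUCTS if a.ion_mode == "positive" and a.charge == 1]
        recs, rts, truth = [], {}, {}
        for i, entry in enumerate(ref):
            rt = float(rng.uniform(60, 600))
            n_feat = int(rng.integers(1, 4))
            for j in range(n_feat):
                adduct = adducts[j % len(adducts)]
                mz = (entry.monoisotopic_mass + adduct.mass_shift) / adduct.charge
                mz *= 1 + rng.uniform(-2e-6, 2e-6)     # 2 ppm mass error
                fid = f"s{seed}_m{i}_f{j}"
                feat = Feat(fid, mz, rt=rt + float(rng.uniform(-1, 1)))
                recs.append(match_metabolites(feat, 1, ref, tol_ppm=5.0))
                rts[fid] = feat.rt
                truth[fid] = entry.metabolite_id
        mapping = group_features_by_metabolite(recs, rts)
        by_met: dict = {}
        for fid, mid in truth.items():
            by_met.setdefault(mid, []).append(fid)
        for mid, fids in by_met.items():
            for fid in fids:
                total += 1
                if mapping[fid] == mapping[fids[0]] and mapping[fid].startswith(mid):
                    hits += 1
    assert hits / total >= 0.95
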