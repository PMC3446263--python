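"""Putative metabolite annotation: charge states, ppm matching, grouping.

A metabolite rarely yields a single LC-MS feature: protonated/sodiated
adducts, multimers and multiply charged species all derive from one neutral
molecule and co-elute.  This module provides the simplified annotation layer
the downstream analysis needs: isotope-spacing charge-state assignment,
adduct-hypothesis neutral-mass reconstruction matched against a
user-supplied reference table within a ppm tolerance (and optional retention
time window), and grouping of co-eluting features that share an unambiguous
top candidate.  The grouping feeds the same-metabolite pair-removal rule of
the correlation cascade.

Annotations are putative (Metabolomics Standards Initiative level 2): a
mass/retention match, never a definitive identification, and all isomer
candidates within tolerance are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Mass difference between 13C and 12C in Da; consecutive isotopologue peaks
#: of a z-charged ion are spaced by this value divided by z.
C13_C12_DELTA = 1.003355

PROTON = 1.007276466


@dataclass(frozen=True)
class Adduct:
    """An ionization hypothesis: m/z = (neutral_mass + mass_shift) / charge."""

    label: str
    ion_mode: str
    charge: int
    mass_shift: float   # total mass added to the neutral molecule, in Da

    def neutral_mass(self, mz: float) -> float:
        return mz * self.charge - self.mass_shift


DEFAULT_ADDUCTS = (
    Adduct("[M+H]+", "positive", 1, PROTON),
    Adduct("[M+Na]+", "positive", 1, 22.989218),
    Adduct("[M+NH4]+", "positive", 1, 18.033823),
    Adduct("[M+2H]2+", "positive", 2, 2 * PROTON),
    Adduct("[M+3H]3+", "positive", 3, 3 * PROTON),
    Adduct("[M-H]-", "negative", 1, -PROTON),
    Adduct("[M+HCOO]-", "negative", 1, 44.998201),
)


@dataclass
class ReferenceEntry:
    """One reference metabolite: name, neutral monoisotopic mass, optional rt window."""

    metabolite_id: str
    name: str
    monoisotopic_mass: float
    rt_window: tuple | None = None   # (low, high) in seconds

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ConfigError(f"{self.metabolite_id}: mass must be positive")
        if self.rt_window is not None and self.rt_window[0] > self.rt_window[1]:
            raise ConfigError(f"{self.metabolite_id}: rt window low > high")


@dataclass
class AnnotationRecord:
    feature_id: str
    charge_state: int | None
    candidates: list = field(default_factory=list)
    # candidates: (metabolite_id, adduct_label, ppm_error) sorted by |ppm_error|

    @property
    def top_candidate(self):
        return self.candidates[0] if self.candidates else None

    def is_ambiguous(self) -> bool:
        """Tie between different metabolites at the best ppm error."""
        if len(self.candidates) < 2:
            return False
        best = abs(self.candidates[0][2])
        tied = {c[0] for c in self.candidates if abs(abs(c[2]) - best) < 1e-9}
        return len(tied) > 1


def assign_charge_state(isotope_mz_spacings, z_max: int = 4,
                        tolerance: float = 0.01) -> int | None:
    """Charge from isotopologue spacing: z minimizing |spacing - delta/z|.

    ``delta`` is the 13C-12C mass difference; a z-charged species shows
    isotope peaks delta/z apart on the m/z axis.  Returns None when no
    z <= z_max fits within ``tolerance`` Da.
    """
    spacings = np.asarray(isotope_mz_spacings, dtype=float)
    if len(spacings) == 0:
        raise ConfigError("need at least one isotope spacing")
    if (spacings <= 0).any():
        raise ConfigError("isotope spacings must be positive")
    spacing = float(np.median(spacings))
    residuals = [(abs(spacing - C13_C12_DELTA / z), z) for z in range(1, z_max + 1)]
    best_res, best_z = min(residuals)
    return best_z if best_res <= tolerance else None


def match_metabolites(feature, charge_state: int | None,
                      reference: list, adducts=DEFAULT_ADDUCTS,
                      tol_ppm: float = 5.0) -> AnnotationRecord:
    """Match one feature against the reference table within a ppm tolerance.

    Every adduct hypothesis consistent with the feature's ion mode (and
    charge state, when known) reconstructs a neutral mass from the measured
    m/z; reference entries within ``tol_ppm`` of that mass — and, when an rt
    window is given, containing the feature's retention time — are candidate
    annotations.  All surviving candidates are reported, sorted by absolute
    ppm error.
    """
    if not reference:
        raise ConfigError("reference table is empty")
    hypotheses = [
        a for a in adducts
        if a.ion_mode == feature.ion_mode
        and (charge_state is None or a.charge == charge_state)
    ]
    candidates = []
    for adduct in hypotheses:
        neutral = adduct.neutral_mass(feature.mz)
        for entry in reference:
            ppm = 1e6 * (neutral - entry.monoisotopic_mass) / entry.monoisotopic_mass
            if abs(ppm) > tol_ppm:
                continue
            if entry.rt_window is not None and not (
                entry.rt_window[0] <= feature.rt <= entry.rt_window[1]
            ):
                continue
            candidates.append((entry.metabolite_id, adduct.label, ppm))
    candidates.sort(key=lambda c: (abs(c[2]), c[0], c[1]))
    return AnnotationRecord(feature.feature_id, charge_state, candidates)


def group_features_by_metabolite(annotations: list, rt_by_feature: dict,
                                 coelution_tol: float = 5.0) -> dict:
    """Partition features into metabolite groups for same-metabolite removal.

    Features sharing an unambiguous top candidate are grouped when they
    co-elute: within each candidate metabolite, features are sorted by
    retention time and split wherever consecutive rts differ by more than
    ``coelution_tol`` seconds.  Ambiguous or unannotated features become
    singletons.  The result maps every feature_id to a group id; it is a
    partition — each feature appears exactly once.
    """
    by_met: dict = {}
    singletons = []
    for rec in annotations:
        if rec.top_candidate is None or rec.is_ambiguous():
            singletons.append(rec.feature_id)
        else:
            by_met.setdefault(rec.top_candidate[0], []).append(rec.feature_id)

    mapping: dict = {}
    for mid, fids in by_met.items():
        fids = sorted(fids, key=lambda f: (rt_by_feature[f], f))
        cluster_idx = 0
        prev_rt = None
        for fid in fids:
            rt = rt_by_feature[fid]
            if prev_rt is not None and rt - prev_rt > coelution_tol:
                cluster_idx += 1
            mapping[fid] = f"{mid}" if cluster_idx == 0 else f"{mid}#{cluster_idx + 1}"
            prev_rt = rt
    for fid in singletons:
        mapping[fid] = f"feature:{fid}"
    return mapping


def read_reference_table(source) -> list:
    """Reference TSV: metabolite_id, name, monoisotopic_mass[, rt_low, rt_high]."""
    df = pd.read_csv(source, sep="\t")
    entries = []
    for _, row in df.iterrows():
        window = None
        if "rt_low" in df.columns and pd.notna(row.get("rt_low")):
            window = (float(row["rt_low"]), float(row["rt_high"]))
        entries.append(ReferenceEntry(
            str(row["metabolite_id"]), str(row["name"]),
            float(row["monoisotopic_mass"]), window,
        ))
    return entries


def annotations_to_frame(annotations: list) -> pd.DataFrame:
    rows = []
    for rec in annotations:
        if not rec.candidates:
            rows.append((rec.feature_id, rec.charge_state, "", "", np.nan))
        for mid, adduct, ppm in rec.candidates:
            rows.append((rec.feature_id, rec.charge_state, mid, adduct, ppm))
    return pd.DataFrame(rows, columns=[
        "feature_id", "charge_state", "metabolite_id", "adduct", "ppm_error",
    ])
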