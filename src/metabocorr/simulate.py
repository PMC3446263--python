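"""Synthetic two-study UPLC-MS serum metabolomics data with known ground truth.

The generator emulates the design this pipeline was built for: two
independent rat studies, each with four biological groups (non-diabetic and
STZ-diabetic, untreated and TETA-treated) plus a pooled quality-control (QC)
sample injected for the first ten injections, then every fifth injection,
and as the final two injections.  On top of clean metabolite abundances it
layers the nuisance structure the pipeline must undo or tolerate:

* **adduct redundancy** — each metabolite emits 1-3 features with
  proportional intensities, so feature-level correlations within a
  metabolite are near 1 by construction;
* **injection-order drift** — a smooth per-feature multiplicative trend
  (random cubic, bounded by ``drift_amplitude``), the phenomenon QC-anchored
  loess correction removes;
* **multiplicative noise** — log-normal with coefficient of variation
  ``noise_cv``;
* **left-censoring** — the lowest ``missing_rate`` fraction of each
  feature's values becomes missing (detection-limit missingness);
* **diabetes effects** — a random subset of metabolites is multiplied by a
  fold change in both diabetic groups;
* **reversal blocks** — blocks of metabolites share a latent factor in the
  non-diabetic groups and in treated diabetics but vary independently in
  untreated diabetics, producing pairwise correlations that are present in
  health, lost in untreated disease, and restored under treatment.  This is
  the correlation-level ground truth the reversal cascade is meant to
  recover.

Within-block rank correlation is targeted on the Spearman scale: for a
bivariate normal latent, rho_spearman = (6/pi) * arcsin(rho_pearson / 2), so
the shared-factor loading is chosen as sqrt(2 * sin(pi * rho_s / 6)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .peaktable import BIOLOGICAL_GROUPS, FeatureTable, SampleManifest

DEFAULT_N_PER_GROUP = {
    1: {"ND_UT": 9, "ND_TETA": 6, "DM_UT": 9, "DM_TETA": 6},
    2: {"ND_UT": 10, "ND_TETA": 10, "DM_UT": 10, "DM_TETA": 10},
}

#: Groups whose reversal-block metabolites share the latent factor.  Untreated
#: diabetics (DM_UT) are the group where the correlation is lost.
CORRELATED_GROUPS = ("ND_UT", "ND_TETA", "DM_TETA")


@dataclass
class SyntheticConfig:
    """Study-design and nuisance parameters for the generator.

    Group sizes default to the real design (study 1: 9/6/9/6 rats; study 2:
    10 per group).  Intensity units are arbitrary peak areas; retention times
    are seconds and m/z values Da/e, drawn uniformly over plausible ranges.
    """

    n_per_group: dict = field(default_factory=lambda: {
        s: dict(g) for s, g in DEFAULT_N_PER_GROUP.items()
    })
    n_metabolites: int = 80
    features_per_metabolite_probs: tuple = (0.5, 0.3, 0.2)  # P(1), P(2), P(3)
    n_differential: int = 15
    effect_ratio_range: tuple = (1.5, 5.0)
    n_reversal_blocks: int = 2
    block_size: int = 6
    within_block_rho: float = 0.9
    drift_amplitude: float = 0.3
    noise_cv: float = 0.10
    missing_rate: float = 0.05
    log_baseline_mean: float = 11.5   # exp(11.5) ~ 1e5 peak-area units
    log_baseline_sd: float = 1.0
    log_biological_sd: float = 0.5    # between-animal spread on the log scale
    ion_mode: str = "positive"
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites <= 0:
            raise ConfigError("n_metabolites must be positive")
        if self.n_differential < 0 or self.n_differential > self.n_metabolites:
            raise ConfigError("n_differential out of range")
        if not (0.5 < self.within_block_rho <= 1.0):
            raise ConfigError("within_block_rho must be in (0.5, 1]")
        if not (0.0 <= self.missing_rate <= 0.5):
            raise ConfigError("missing_rate must be in [0, 0.5]")
        if self.n_reversal_blocks * self.block_size > self.n_metabolites:
            raise ConfigError(
                "infeasible config: n_reversal_blocks * block_size exceeds n_metabolites"
            )
        if self.drift_amplitude < 0 or self.drift_amplitude >= 1:
            raise ConfigError("drift_amplitude must be in [0, 1)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        if not math.isclose(sum(self.features_per_metabolite_probs), 1.0, abs_tol=1e-9):
            raise ConfigError("features_per_metabolite_probs must sum to 1")


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests.

    ``reversal_pairs`` holds unordered feature-id pairs connecting features
    of *distinct* metabolites within the same reversal block — exactly the
    edges the correlation cascade should recover after same-metabolite pair
    removal.
    """

    feature_to_metabolite: dict
    differential_metabolites: dict      # metabolite_id -> fold multiplier on DM groups
    reversal_blocks: list               # list of lists of metabolite_ids
    reversal_pairs: set                 # set of frozenset({fid_a, fid_b})
    drift_curves: pd.DataFrame          # feature_id x sample_id multiplicative drift

    def differential_features(self) -> dict:
        """feature_id -> fold multiplier, expanded from metabolites."""
        return {
            fid: self.differential_metabolites[mid]
            for fid, mid in self.feature_to_metabolite.items()
            if mid in self.differential_metabolites
        }

    def block_features(self) -> set:
        mids = {m for block in self.reversal_blocks for m in block}
        return {f for f, m in self.feature_to_metabolite.items() if m in mids}


def make_injection_sequence(n_biological: int) -> list:
    """Injection schedule: (slot, is_qc) pairs, slots 1-based.

    Ten conditioning/QC injections open the run, a QC occupies every fifth
    slot thereafter (four biological injections between consecutive QCs),
    and the run closes with two consecutive QC injections.
    """
    if n_biological < 1:
        raise ConfigError("n_biological must be >= 1")
    slots = [True] * 10
    remaining = n_biological
    while remaining > 0:
        take = min(4, remaining)
        slots.extend([False] * take)
        remaining -= take
        if remaining > 0:
            slots.append(True)
    slots.extend([True, True])
    return [(i + 1, is_qc) for i, is_qc in enumerate(slots)]


def _spearman_to_pearson(rho_s: float) -> float:
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _drift_curve(rng: np.random.Generator, t: np.ndarray, amplitude: float) -> np.ndarray:
    if amplitude == 0:
        return np.ones_like(t)
    a = rng.uniform(-1.0, 1.0, size=3)
    g = a[0] * t + a[1] * t ** 2 + a[2] * t ** 3
    peak = np.max(np.abs(g))
    if peak == 0:
        return np.ones_like(t)
    return 1.0 + amplitude * g / peak


def _biology_panel(config: SyntheticConfig):
    """The study-independent biological truth, drawn from the config seed only.

    Both studies measure the same biology — the metabolite panel, its adduct
    features, the reversal blocks and the diabetes effects are shared — while
    animals, injection order, drift, noise and censoring are study-specific.
    This is what makes cross-study replication of true effects possible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0B10]))
    n_met = config.n_metabolites
    met_ids = [f"M{i + 1:04d}" for i in range(n_met)]
    log_baseline = rng.normal(config.log_baseline_mean, config.log_baseline_sd, n_met)

    # adduct redundancy: 1-3 features per metabolite, proportional response
    n_feat_per_met = rng.choice([1, 2, 3], size=n_met,
                                p=list(config.features_per_metabolite_probs))
    feature_ids, feat_met_idx, response = [], [], []
    for i, mid in enumerate(met_ids):
        for j in range(n_feat_per_met[i]):
            feature_ids.append(f"{mid}_F{j + 1}")
            feat_met_idx.append(i)
            response.append(1.0 if j == 0 else rng.uniform(0.2, 0.8))

    # reversal blocks, then diabetes effects on the remaining metabolites
    block_pool = rng.permutation(n_met)
    blocks = [
        sorted(block_pool[b * config.block_size:(b + 1) * config.block_size].tolist())
        for b in range(config.n_reversal_blocks)
    ]
    in_block = np.zeros(n_met, dtype=bool)
    for block in blocks:
        in_block[block] = True
    non_block = np.flatnonzero(~in_block)
    diff_pool = non_block if len(non_block) >= config.n_differential else np.arange(n_met)
    diff_idx = rng.choice(diff_pool, size=config.n_differential, replace=False)
    folds = rng.uniform(*config.effect_ratio_range, size=config.n_differential)
    up = rng.random(config.n_differential) < 0.5
    multipliers = np.where(up, folds, 1.0 / folds)
    diff_mult = dict(zip(diff_idx.tolist(), multipliers.tolist()))

    mz = rng.uniform(80.0, 1000.0, len(feature_ids))
    rt = np.repeat(rng.uniform(30.0, 900.0, n_met), n_feat_per_met)
    rt = np.clip(rt + rng.uniform(-1.0, 1.0, len(feature_ids)), 0.0, None)
    return {
        "met_ids": met_ids, "log_baseline": log_baseline,
        "feature_ids": feature_ids, "feat_met_idx": np.asarray(feat_met_idx),
        "response": np.asarray(response), "blocks": blocks,
        "diff_mult": diff_mult, "mz": mz, "rt": rt,
    }


def generate_study(config: SyntheticConfig, study_id: int):
    """Generate one study's feature table (with manifest) and ground truth.

    Deterministic for a fixed (config.seed, study_id).  The biological truth
    is shared between studies (same panel, same differential metabolites,
    same reversal blocks); animals and measurement nuisances are drawn from
    a study-specific stream, so the two studies are independent replicate
    experiments of the same system.
    """
    config.validate()
    if study_id not in config.n_per_group:
        raise ConfigError(f"no group sizes configured for study {study_id}")
    panel = _biology_panel(config)
    met_ids = panel["met_ids"]
    log_baseline = panel["log_baseline"]
    feature_ids = panel["feature_ids"]
    feat_met_idx = panel["feat_met_idx"]
    response = panel["response"]
    blocks = panel["blocks"]
    diff_mult = panel["diff_mult"]
    n_met = config.n_metabolites
    n_feat = len(feature_ids)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, study_id]))

    # loading calibrated so the OBSERVED log-intensities (biological latent
    # plus multiplicative measurement noise) hit the target rank correlation:
    # pearson_obs = b^2 * sigma_bio^2 / (sigma_bio^2 + sigma_noise^2)
    pearson_target = _spearman_to_pearson(config.within_block_rho)
    sigma_noise_sq = math.log(1.0 + config.noise_cv ** 2)
    attenuation = 1.0 + sigma_noise_sq / config.log_biological_sd ** 2
    b_load = math.sqrt(min(1.0, pearson_target * attenuation))

    # biological samples: latent log-abundances per metabolite
    groups, bio_ids = [], []
    for group in BIOLOGICAL_GROUPS:
        n = config.n_per_group[study_id][group]
        for k in range(n):
            bio_ids.append(f"S{study_id}_{group}_{k + 1:02d}")
            groups.append(group)
    n_bio = len(bio_ids)

    log_abund = np.empty((n_met, n_bio))
    for s, group in enumerate(groups):
        eps = rng.standard_normal(n_met)
        z_blocks = rng.standard_normal(config.n_reversal_blocks)
        latent = eps.copy()
        if group in CORRELATED_GROUPS:
            for b, block in enumerate(blocks):
                latent[block] = b_load * z_blocks[b] + math.sqrt(1 - b_load ** 2) * eps[block]
        log_abund[:, s] = log_baseline + config.log_biological_sd * latent
        if group in ("DM_UT", "DM_TETA"):
            for i, mult in diff_mult.items():
                log_abund[i, s] += math.log(mult)

    clean_bio = np.exp(log_abund)[feat_met_idx, :] * response[:, None]   # feature x bio sample
    clean_qc = clean_bio.mean(axis=1)                                    # pooled aliquot

    # injection schedule; biological samples randomised over non-QC slots
    seq = make_injection_sequence(n_bio)
    n_slots = len(seq)
    bio_order = rng.permutation(n_bio)
    sample_ids, sample_groups, col_clean = [], [], []
    qc_count = 0
    bio_cursor = 0
    for slot, is_qc in seq:
        if is_qc:
            qc_count += 1
            sample_ids.append(f"S{study_id}_QC_{qc_count:02d}")
            sample_groups.append("QC")
            col_clean.append(clean_qc)
        else:
            idx = bio_order[bio_cursor]
            bio_cursor += 1
            sample_ids.append(bio_ids[idx])
            sample_groups.append(groups[idx])
            col_clean.append(clean_bio[:, idx])
    clean = np.column_stack(col_clean)   # feature x slot

    t = (np.arange(n_slots)) / max(n_slots - 1, 1)
    drift = np.vstack([_drift_curve(rng, t, config.drift_amplitude) for _ in range(n_feat)])

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        noise = np.exp(rng.normal(0.0, sigma, size=clean.shape) - sigma ** 2 / 2.0)
    else:
        noise = np.ones_like(clean)

    observed = clean * drift * noise

    # detection-limit censoring: the lowest missing_rate fraction of each
    # feature's values is lost
    if config.missing_rate > 0:
        thr = np.quantile(observed, config.missing_rate, axis=1, keepdims=True)
        observed = np.where(observed < thr, np.nan, observed)

    manifest = SampleManifest(pd.DataFrame({
        "study_id": study_id,
        "group": sample_groups,
        "injection_order": [slot for slot, _ in seq],
        "ion_mode": config.ion_mode,
    }, index=pd.Index(sample_ids, name="sample_id")))

    features = pd.DataFrame({
        "mz": panel["mz"],
        "rt": panel["rt"],
        "ion_mode": config.ion_mode,
    }, index=pd.Index(feature_ids, name="feature_id"))

    table = FeatureTable(features, pd.DataFrame(
        observed, index=features.index, columns=sample_ids), manifest)

    fid_by_met = {}
    for fid, i in zip(feature_ids, feat_met_idx):
        fid_by_met.setdefault(met_ids[i], []).append(fid)
    reversal_pairs = set()
    for block in blocks:
        block_mids = [met_ids[i] for i in block]
        for a_pos in range(len(block_mids)):
            for b_pos in range(a_pos + 1, len(block_mids)):
                for fa in fid_by_met[block_mids[a_pos]]:
                    for fb in fid_by_met[block_mids[b_pos]]:
                        reversal_pairs.add(frozenset((fa, fb)))

    truth = GroundTruth(
        feature_to_metabolite={fid: met_ids[i] for fid, i in zip(feature_ids, feat_met_idx)},
        differential_metabolites={met_ids[i]: m for i, m in diff_mult.items()},
        reversal_blocks=[[met_ids[i] for i in block] for block in blocks],
        reversal_pairs=reversal_pairs,
        drift_curves=pd.DataFrame(drift, index=features.index, columns=sample_ids),
    )
    return table, truth


def generate_studies(config: SyntheticConfig) -> dict:
    """Both studies of the replication design: {study_id: (table, truth)}."""
    return {sid: generate_study(config, sid) for sid in sorted(config.n_per_group)}
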