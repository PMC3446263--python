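# Methods

This note documents the models and procedures implemented in `metabocorr`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions a maintainer
would want to audit.

## Data model

A `FeatureTable` holds peak areas (arbitrary units) for metabolic features —
(m/z, retention time) peaks from an LC-MS run — across the injections of one
or more analytical runs, with a `SampleManifest` describing each injection
(study id, group label or QC flag, 1-based injection order, ion mode).
Missingness is a first-class state stored as NaN and written as an empty TSV
cell; it is never conflated with zero at the storage level.  Downstream
conventions differ deliberately: PCA replaces missing by 0 before
autoscaling (the convention of the workflow this package reproduces, kept as
a fidelity choice even though it biases variances of sparsely detected
features), whereas rank tests and correlations exclude missing values
pairwise.

## QC-RLSC and quality assurance

Pooled-QC injections are repeated measurements of identical material, so a
smooth trend in their peak areas over injection order is instrument drift.
Per feature, a robust locally weighted regression (statsmodels `lowess`,
local linear, 3 robustness iterations, default span 0.6 of the QC points) is
fitted to QC intensity versus injection order and linearly interpolated at
every injection; outside the QC order range the nearest fitted value is held
constant, and fitted values are floored at a tiny positive multiple of the
median QC intensity so division is safe.  Corrected values are
`raw / trend × reference` with the per-feature reference defaulting to the
median raw QC intensity, so corrected data stay in peak-area units.  At
least four usable (non-missing, positive) QC points are required; features
below that are dropped with a logged reason.  The span and robustness
settings are declared, configurable choices — the smooth QC-anchored trend
and divide-and-rescale contract is the fixed part, the loess internals are
not.

The QA filter retains a feature only if it is detected (non-missing and
strictly positive) in more than 60% of QC injections with injection order ≥ 8
— the first seven injections condition the column and are excluded — and its
QC relative standard deviation (100·sd/mean over non-missing window QCs) is
below 20%.  Both inequalities are strict.  Each (study, ion mode) run is
corrected and filtered independently; no cross-run normalisation is applied.

## Univariate statistics and replication

Group comparisons use the two-sided Mann–Whitney U test.  For combined
sample sizes up to 20 the p-value is permutation-exact under ties: the null
distribution of the rank sum over all C(n, n1) group assignments of the
observed midranks is computed by dynamic programming over doubled midranks
(integers), and the two-sided p is P(|U − n1·n2/2| ≥ |u_obs − n1·n2/2|).
With no ties this reduces to the classical exact Mann–Whitney distribution;
with ties it is the exact conditional permutation test.  Larger samples use
the tie-corrected normal approximation with continuity correction (verified
against scipy's asymptotic implementation in the tests).

Fold changes are ratios of group medians, consistent with the rank-based
test (means are one flag away if wanted; the choice is documented, not
prescribed).  A zero or undefined median yields an undefined ratio and
direction "none" rather than a fake fold change.

No multiple-testing adjustment is applied by default: the analysis design
controls false positives by requiring replication — p < 0.05 in two
independent studies with an identical direction of change.  Under two
independent nulls the replicated fraction is ≈ α²/2 per direction-consistent
chance agreement, which the acceptance suite measures (≤ 0.005 at α = 0.05).
Benjamini–Hochberg adjustment is available behind a flag.  Features are
matched across studies by shared feature id (always true for synthetic
data); a greedy (m/z ppm, retention-time) matcher is provided for real runs,
where feature ids are run-specific.

## PCA and outlier flagging

PCA operates on zero-imputed, per-feature autoscaled data via SVD;
zero-variance features are dropped and logged.  Component signs are fixed by
making each loading's largest-magnitude entry positive, so score plots are
reproducible across feature orderings.  The low-signal outlier rule
formalises a manual practice (a failed injection shows an anomalously low
total peak area): a biological injection is flagged when its total
non-missing peak area lies more than k = 5 median absolute deviations below
the median biological total.  Flagging is advisory; removal is an explicit
pipeline option (`remove_outliers`), since such calls are run-specific.

## Bootstrapped Spearman correlations and the reversal cascade

Per group, every unordered feature pair with at least `min_pairs = 6`
complete observation pairs gets a Spearman rank correlation (Pearson of
midranks) aggregated as the **median** over `n_boot = 100` with-replacement
resamples of the complete pairs.  Degenerate resamples (fewer than three
distinct sample pairs, or zero rank variance in either margin) are redrawn
up to a fixed budget and otherwise dropped from the aggregate.  Median
aggregation is a robustness choice; only the use of bootstrapping (n = 100)
is fixed by the reproduced workflow, not the aggregate.  The 6-versus-6 rule
is read as: at least six complete pairs in each group entering a compared
correlation — the binding case for the smallest groups in the motivating
design.  Each pair's resampling stream is seeded from a CRC of the sorted
feature-id pair plus the master seed, making results independent of feature
ordering and deterministic across runs.

The cascade keeps a pair when |rho_ND| > 0.5, |rho_ND − rho_DM| > 0.5, and
|rho_DMT| > 0.5 (controls / untreated diabetic / treated diabetic).  The
third condition is an absolute threshold, not a second delta test.  Pairs
whose features map to the same metabolite are removed (unmapped features
count as singleton metabolites), and a feature is reported when its passing
pairs span at least `min_degree = 10` different partner metabolites —
counting metabolites, not features, so adduct redundancy cannot inflate a
hub.  The full pair space is O(F²); 2,000 features (≈ 2M pairs) is the
intended desk-scale ceiling.

### What small groups can and cannot support

With n = 10 samples per group, the sample Spearman correlation of truly
uncorrelated features has standard deviation ≈ 1/3, and the estimator of a
population rank correlation of 0.9 has expectation ≈ 0.85.  The delta
condition therefore fails whenever the untreated-diabetic rho fluctuates
above ≈ 0.35, which happens for roughly 15% of truly reversed pairs; the
three conditions jointly hold for ≈ 80% of them.  Consequently a feature
inside a 12-metabolite reversal block (11 possible partners) passes the
degree-10 filter only ≈ 35–50% of the time, and *complete* per-dataset
recovery of a block is not achievable at these group sizes — no noise
setting changes this, because the binding randomness is the correlation
estimator itself.  What the cascade does deliver at this scale, and what the
acceptance suite asserts, is high specificity (zero candidates under a
global null in ≥ 9 of 10 datasets at 50 features) and high partner purity
(> 90% of reported partner links connect two block features).  The degree
filter trades recall for precision by design.

## Annotation

Charge states come from isotopologue spacing: z ∈ {1..4} minimising
|spacing − Δ/z| with Δ = 1.003355 Da (¹³C−¹²C), unknown if the best residual
exceeds 0.01 Da.  Neutral masses are reconstructed per adduct hypothesis
([M+H]⁺, [M+Na]⁺, [M+NH₄]⁺, [M+2H]²⁺, [M+3H]³⁺ positive; [M−H]⁻, [M+HCOO]⁻
negative; configurable) and matched against a user-supplied reference table
within ±5 ppm, with optional retention-time windows; all surviving isomer
candidates are reported, sorted by absolute ppm error.  Annotation is
putative (MSI level 2) only.  Features sharing an unambiguous top candidate
are grouped when they co-elute (consecutive retention times within 5 s, a
declared default); ambiguous or unannotated features are singletons, so the
grouping is a partition.  On synthetic data the ground-truth
feature→metabolite map bypasses mass matching, so correlation-network
results are not hostage to annotation accuracy.

## Synthetic-data generator

The generator emulates the two-study, four-group design: study 1 with
9/6/9/6 animals (controls and diabetics, untreated and treated), study 2
with 10 per group; pooled-QC injections as the first ten, every fifth
thereafter, and the final two; biological samples randomised over the
remaining slots.

The biological truth — metabolite panel (log-normal baselines, log-mean 11.5
≈ 10⁵ area units, log-sd 1.0), 1–3 adduct features per metabolite with
proportional response factors, the differential metabolites with fold
changes drawn from [1.5, 5] in a random direction, and the reversal blocks —
is drawn from the config seed alone and shared by both studies; animals,
injection order, drift, noise and censoring come from per-study streams.
Both properties matter: shared biology makes cross-study replication of true
effects possible, independent nuisances make it meaningful.

Per sample, metabolite log-abundances are the baseline plus a biological
deviate (log-sd 0.5).  Reversal-block metabolites share a per-sample latent
factor in the non-diabetic groups and in treated diabetics but vary
independently in untreated diabetics.  The factor loading is calibrated so
the *observed* data (after measurement noise) hit the configured within-block
Spearman correlation, via rho_pearson = 2·sin(π·rho_s/6) and a
noise-attenuation correction.  Diabetes folds multiply both diabetic groups.
Every feature is then scaled by a smooth per-feature drift curve (random
cubic in normalised injection index, max fractional deviation
`drift_amplitude`, default 0.3 — drift shape is unconstrained by the
reproduced workflow beyond smoothness), by log-normal multiplicative noise
(`noise_cv`, default 0.10), and the lowest `missing_rate` (default 0.05)
fraction of each feature's values is censored, emulating detection limits.
QC injections carry the per-feature mean of the clean biological signal
(a pooled aliquot) under the same drift and noise.

Not emulated: chromatographic peak shapes, isotope envelopes as signals,
retention-time shifts between runs, matrix effects beyond multiplicative
drift/noise, batch structure within a run, and missingness mechanisms other
than left-censoring.  Passing recovery tests on this generator therefore
demonstrates the statistical machinery under a clean version of the assumed
data-generating process, not robustness to every artefact of real LC-MS
data.

## Numerical choices and degenerate inputs

* Exact Mann–Whitney cutoff at combined n = 20; DP over doubled midranks
  keeps all arithmetic integral until the final division.
* Identical samples give p = 1; an empty group after missing removal skips
  the feature with a logged reason.
* Loess trends are clipped positive; constant QC series reproduce the
  constant exactly, so no-drift data are corrected to themselves (relative
  error < 1e-9, asserted).
* Spearman needs ≥ 3 complete pairs and non-degenerate ranks, else NaN.
* QA RSD with fewer than two non-missing window QCs is undefined and the
  feature fails.
* Problem sizes in tests and the acceptance evaluations (tens of metabolites
  for correlation scenarios, 2,000 features for null calibration, 10
  replicate seeds) are chosen to estimate each property with comfortable
  margins at desk scale.

## Pipeline

`run_pipeline` chains the stages per (study, ion mode) run — correction, QA,
PCA and outlier flags, six pairwise comparisons — then the cross-study
replication filter, then the correlation cascade on the study with larger
group sizes (study 2 by default, configurable).  Positive and negative ion
modes are processed as separate runs and combined only in reporting.  Stage
counts (features in, QA-retained, significant, replicated) are recorded in a
machine-readable summary and must form a monotone funnel; every dropped
feature carries a reason.  All randomness derives from one master seed, and
QA verdicts on a fixed input are seed-independent.
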