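"""End-to-end orchestration of the analysis stages.

Stage order per (study, ion mode) run: QC-RLSC drift correction -> QC-based
QA filter -> PCA overview and low-signal outlier flagging -> the six pairwise
Mann-Whitney comparisons.  Across studies: the replication filter.  On the
study with the larger group sizes (study 2 by default): the bootstrapped
Spearman correlation matrices for the control, untreated-diabetic and
treated-diabetic groups and the reversal cascade.

Every stage's feature counts are recorded in a machine-readable summary so
the monotone funnel (input >= QA-retained >= significant >= replicated) can
be audited.  All randomness derives from a single master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import corrnet, multivariate, qc, univariate
from .corrnet import CascadeThresholds
from .errors import ConfigError
from .peaktable import FeatureTable, read_feature_table, write_feature_table
from .simulate import SyntheticConfig, generate_studies


@dataclass
class PipelineConfig:
    """All stage parameters plus either a synthetic config or input paths."""

    synthetic: SyntheticConfig | None = None
    input_paths: dict = field(default_factory=dict)   # study_id -> (table, manifest)
    span: float = 0.6
    detection_threshold: float = 0.60
    rsd_threshold: float = 20.0
    qc_from_injection: int = 8
    alpha: float = 0.05
    outlier_k: float = 5.0
    remove_outliers: bool = False
    thresholds: CascadeThresholds = field(default_factory=CascadeThresholds)
    correlation_study: int = 2
    correlation_groups: tuple = ("ND_UT", "DM_UT", "DM_TETA")
    run_qc: bool = True
    run_pca: bool = True
    run_stats: bool = True
    run_corrnet: bool = True
    seed: int = 0
    outdir: str | None = None


def _write(df: pd.DataFrame, outdir: Path | None, name: str, **kwargs) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, sep="\t", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; return the machine-readable run summary."""
    outdir = None
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        studies = generate_studies(config.synthetic)
        tables = {sid: tbl for sid, (tbl, _) in studies.items()}
        truths = {sid: truth for sid, (_, truth) in studies.items()}
    elif config.input_paths:
        tables = {
            sid: read_feature_table(tp, mp)
            for sid, (tp, mp) in config.input_paths.items()
        }
        truths = {}
    else:
        raise ConfigError("pipeline needs a synthetic config or input paths")

    summary: dict = {"studies": {}, "alpha": config.alpha, "seed": config.seed}
    per_study_results: dict = {}
    processed: dict = {}

    for sid, table in sorted(tables.items()):
        counts = {"features_in": table.n_features, "injections": table.n_samples}
        schedule = table.manifest.entries.sort_values("injection_order")["group"].tolist()
        counts["qc_injections"] = schedule.count("QC")

        if config.run_qc:
            corrected, dropped = qc.qc_rlsc_correct(table, span=config.span)
            counts["uncorrectable"] = len(dropped)
            filtered, report = qc.qa_filter(
                corrected,
                detection_threshold=config.detection_threshold,
                rsd_threshold=config.rsd_threshold,
                qc_from_injection=config.qc_from_injection,
            )
            counts["qa_retained"] = report.n_retained
            counts["qa_removed"] = report.n_removed
            _write(report.metrics, outdir, f"study{sid}_qa_report.tsv",
                   index_label="feature_id")
            if outdir is not None:
                write_feature_table(filtered, outdir / f"study{sid}_corrected.tsv")
                (outdir / f"study{sid}_dropped.txt").write_text(
                    "".join(f"{fid}\t{why}\n" for fid, why in dropped))
        else:
            filtered = table
            counts["qa_retained"] = table.n_features

        flagged = []
        if config.run_pca:
            pca = multivariate.pca_scores(filtered)
            flagged = multivariate.flag_outliers(filtered, k=config.outlier_k)
            counts["pca_explained_pc1"] = float(pca.explained_variance_fraction[0])
            counts["outliers_flagged"] = len(flagged)
            _write(pca.scores, outdir, f"study{sid}_pca_scores.tsv",
                   index_label="sample_id")
            if outdir is not None:
                (outdir / f"study{sid}_outliers.txt").write_text(
                    "".join(f"{sid_}\t{why}\n" for sid_, why in flagged))
        if config.remove_outliers and flagged:
            keep = [s for s in filtered.intensities.columns
                    if s not in {f[0] for f in flagged}]
            filtered = filtered.subset_samples(keep)
            counts["injections_after_outlier_removal"] = filtered.n_samples

        if config.run_stats:
            comp_results = {}
            sig_counts = {}
            for comparison in univariate.PAIRWISE_COMPARISONS:
                res, skipped = univariate.differential_features(
                    filtered, comparison, alpha=config.alpha)
                comp_results[comparison] = res
                key = f"{comparison[0]}_vs_{comparison[1]}"
                sig_counts[key] = int((res["p"] < config.alpha).sum())
                _write(res, outdir, f"study{sid}_{key}.tsv", index_label="feature_id")
            per_study_results[sid] = comp_results
            counts["significant"] = sig_counts

        processed[sid] = filtered
        summary["studies"][str(sid)] = counts

    if config.run_stats and len(per_study_results) >= 2:
        table1 = univariate.comparison_summary(per_study_results, alpha=config.alpha)
        _write(table1, outdir, "comparison_summary.tsv")
        summary["comparison_summary"] = {
            k: v for k, v in table1.to_dict(orient="index").items()
        }
        sids = sorted(per_study_results)
        replicated = {}
        for comparison in univariate.PAIRWISE_COMPARISONS:
            rep = univariate.replication_filter(
                per_study_results[sids[0]][comparison],
                per_study_results[sids[1]][comparison],
                alpha=config.alpha,
            )
            key = f"{comparison[0]}_vs_{comparison[1]}"
            replicated[key] = len(rep)
            _write(rep, outdir, f"replicated_{key}.tsv", index_label="feature_id")
        summary["replicated"] = replicated

    if config.run_corrnet:
        sid = config.correlation_study
        if sid not in processed:
            raise ConfigError(f"correlation study {sid} not among inputs")
        ftab = processed[sid]
        met_map = {}
        if truths.get(sid) is not None:
            met_map = {
                f: m for f, m in truths[sid].feature_to_metabolite.items()
                if f in set(ftab.intensities.index)
            }
        sets = {
            g: corrnet.group_correlation_matrix(
                ftab, g, thresholds=config.thresholds, seed=config.seed)
            for g in config.correlation_groups
        }
        g_nd, g_dm, g_dmt = config.correlation_groups
        candidates, edges = corrnet.reversal_candidates(
            sets[g_nd], sets[g_dm], sets[g_dmt],
            thresholds=config.thresholds, metabolite_map=met_map,
        )
        summary["correlation"] = {
            "study": sid,
            "eligible_features": ftab.n_features,
            "candidate_pairs": corrnet.n_candidate_pairs(ftab.n_features),
            "pairs_evaluated": int(len(edges)),
            "pairs_passing_cascade": int(edges["passes_cascade"].sum()),
            "candidate_features": len(candidates),
        }
        _write(edges, outdir, "reversal_edges.tsv", index=False)
        cand_df = pd.DataFrame(
            [(c.feature_id, c.partner_metabolite_count) for c in candidates],
            columns=["feature_id", "partner_metabolite_count"],
        )
        _write(cand_df, outdir, "reversal_candidates.tsv", index=False)

    if outdir is not None:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
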