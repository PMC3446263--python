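#!/usr/bin/env python
"""PCA score overview per study and low-total-signal outlier flags.

Checks the two qualitative expectations of a well-behaved run: pooled-QC
injections cluster tightly relative to biological samples, and the diabetic /
non-diabetic contrast dominates the leading component when strong effects are
present.  Writes score tables and, when matplotlib is available, a PC1-PC2
scatter per study.
"""

import argparse
from pathlib import Path

import numpy as np

from metabocorr import flag_outliers, pca_scores, read_feature_table

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=str, default="results/data")
parser.add_argument("--qadir", type=str, default="results")
parser.add_argument("--outdir", type=str, default="results")
args = parser.parse_args()

data, qa, out = Path(args.datadir), Path(args.qadir), Path(args.outdir)
out.mkdir(parents=True, exist_ok=True)

for sid in (1, 2):
    table = read_feature_table(qa / f"study{sid}_qa_filtered.tsv",
                               data / f"study{sid}_manifest.tsv")
    result = pca_scores(table)
    result.scores.to_csv(out / f"study{sid}_pca_scores.tsv", sep="\t",
                         index_label="sample_id")
    evf = ", ".join(f"{f:.1%}" for f in result.explained_variance_fraction)
    scores = result.scores[["PC1", "PC2"]]
    qc_ids = table.manifest.group_ids("QC")
    bio_ids = table.manifest.biological_ids()
    qc_disp = np.linalg.norm(scores.loc[qc_ids] - scores.loc[qc_ids].mean(), axis=1).mean()
    bio_disp = np.linalg.norm(scores.loc[bio_ids] - scores.loc[bio_ids].mean(), axis=1).mean()
    flagged = flag_outliers(table)
    print(f"study {sid}: explained variance {evf}; QC dispersion "
          f"{qc_disp:.2f} vs biological {bio_disp:.2f} in PC1-PC2; "
          f"{len(flagged)} low-signal outliers flagged")
    for sample, why in flagged:
        print(f"  outlier {sample}: {why}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        continue
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = table.manifest.entries["group"]
    for group, marker in [("ND_UT", "o"), ("ND_TETA", "s"), ("DM_UT", "^"),
                          ("DM_TETA", "v"), ("QC", "x")]:
        ids = groups.index[groups == group]
        ax.scatter(result.scores.loc[ids, "PC1"], result.scores.loc[ids, "PC2"],
                   marker=marker, label=group, s=25)
    ax.set_xlabel("PC1"); ax.set_ylabel("PC2"); ax.legend(fontsize=7)
    fig.tight_layout()
    figdir = Path("scratch/figures")
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / f"study{sid}_pca.png", dpi=120)
    plt.close(fig)
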