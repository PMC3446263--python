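#!/usr/bin/env python
"""Generate the two synthetic studies and write their tables + ground truth.

Emulates the study design the pipeline targets: two independent runs, four
biological groups (study 1: 9/6/9/6 animals, study 2: 10 per group), pooled
QC injections (ten leading, every fifth, two trailing), smooth injection-order
drift, multiplicative noise, detection-limit missingness, adduct redundancy,
diabetes fold changes, and treatment-restored correlation blocks.
"""

import argparse
from pathlib import Path

import pandas as pd

from metabocorr import SyntheticConfig, generate_studies, write_feature_table, write_manifest

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=str, default="results/data")
args = parser.parse_args()

out = Path(args.outdir)
out.mkdir(parents=True, exist_ok=True)
config = SyntheticConfig(seed=args.seed)

for sid, (table, truth) in generate_studies(config).items():
    write_feature_table(table, out / f"study{sid}_table.tsv")
    write_manifest(table.manifest, out / f"study{sid}_manifest.tsv")
    pd.DataFrame(sorted(truth.feature_to_metabolite.items()),
                 columns=["feature_id", "metabolite_id"]).to_csv(
        out / f"study{sid}_feature_map.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.differential_metabolites.items()),
                 columns=["metabolite_id", "fold_multiplier"]).to_csv(
        out / f"study{sid}_true_differential.tsv", sep="\t", index=False)
    pd.DataFrame([(b, mid) for b, block in enumerate(truth.reversal_blocks)
                  for mid in block],
                 columns=["block", "metabolite_id"]).to_csv(
        out / f"study{sid}_true_blocks.tsv", sep="\t", index=False)
    n_qc = int(table.manifest.is_qc().sum())
    n_missing = int(table.missing_mask().to_numpy().sum())
    print(f"study {sid}: {table.n_features} features x {table.n_samples} injections "
          f"({n_qc} QCs), {n_missing} missing cells, "
          f"{len(truth.differential_metabolites)} differential metabolites, "
          f"{len(truth.reversal_blocks)} reversal blocks")
print(f"wrote tables to {out}")
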