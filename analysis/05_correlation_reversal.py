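#!/usr/bin/env python
"""Bootstrapped Spearman correlation matrices and the reversal cascade.

Run on study 2 (the study with ten animals per group): per-group bootstrap
Spearman over all feature pairs with at least six complete observation pairs,
then the three-condition filter — high |rho| in controls, a >0.5 change in
untreated diabetics, high |rho| again under treatment — same-metabolite pair
removal, and the ten-different-partner-metabolites degree filter.  Compares
the candidate features against the generator's reversal-block ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from metabocorr import CascadeThresholds, n_candidate_pairs, read_feature_table
from metabocorr.corrnet import group_correlation_matrix, reversal_candidates

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=str, default="results/data")
parser.add_argument("--qadir", type=str, default="results")
parser.add_argument("--outdir", type=str, default="results")
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--min-degree", type=int, default=4,
                    help="partner-metabolite degree cutoff (default sized to "
                    "the 6-metabolite blocks the generator injects)")
args = parser.parse_args()

data, qa, out = Path(args.datadir), Path(args.qadir), Path(args.outdir)
out.mkdir(parents=True, exist_ok=True)

table = read_feature_table(qa / "study2_qa_filtered.tsv",
                           data / "study2_manifest.tsv")
fmap = pd.read_csv(data / "study2_feature_map.tsv", sep="\t")
met_map = dict(zip(fmap["feature_id"], fmap["metabolite_id"]))

thresholds = CascadeThresholds(min_degree=args.min_degree)
print(f"{table.n_features} features -> {n_candidate_pairs(table.n_features)} "
      f"candidate pairs per group")

sets = {g: group_correlation_matrix(table, g, thresholds, seed=args.seed)
        for g in ("ND_UT", "DM_UT", "DM_TETA")}
for g, cs in sets.items():
    print(f"  {g}: {len(cs.pairs)} pairs with >= {thresholds.min_pairs} complete obs")

candidates, edges = reversal_candidates(
    sets["ND_UT"], sets["DM_UT"], sets["DM_TETA"], thresholds, met_map)
edges.to_csv(out / "reversal_edges.tsv", sep="\t", index=False)
pd.DataFrame([(c.feature_id, c.partner_metabolite_count) for c in candidates],
             columns=["feature_id", "partner_metabolite_count"]).to_csv(
    out / "reversal_candidates.tsv", sep="\t", index=False)

n_pass = int(edges["passes_cascade"].sum())
print(f"{n_pass} pairs pass the cascade; {len(candidates)} features have "
      f">= {thresholds.min_degree} different partner metabolites")

blocks = pd.read_csv(data / "study2_true_blocks.tsv", sep="\t")
block_mids = set(blocks["metabolite_id"])
block_fids = {f for f, m in met_map.items() if m in block_mids}
found = {c.feature_id for c in candidates}
recall = len(found & block_fids) / len(block_fids & set(table.intensities.index))
partner_links = [(c.feature_id in block_fids and p[0] in block_fids)
                 for c in candidates for p in c.partners]
purity = sum(partner_links) / len(partner_links) if partner_links else float("nan")
print(f"recall of true reversal-block features: {recall:.0%}; "
      f"{purity:.0%} of reported partner links connect two block features")
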