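"""Differential expression of nascent RNA between stimulated and control
replicates, plus replicate-correlation QC.

Genes are called induced/repressed at |fold| >= 1.5 and FDR < 0.05 from
the exact pooled binomial test on size-factor-normalised counts.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py")
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from stat5targets.expression_response import call_degs, replicate_correlation

dataset = common.study()
degs = call_degs(dataset.counts)
degs.to_csv(common.RESULTS / "degs.tsv", sep="\t")

n_ind = int((degs["call"] == "induced").sum())
n_rep = int((degs["call"] == "repressed").sum())
truth = dataset.truth.gene_direction
correct = sum(
    1 for g, d in truth.items() if d != "unchanged" and degs.loc[g, "call"] == d
)
planted = sum(1 for d in truth.values() if d != "unchanged")
print(f"{n_ind} genes induced, {n_rep} repressed (of {len(degs)})")
print(f"planted DEGs recovered: {correct}/{planted}")
top = degs[degs["call"] == "induced"].nlargest(3, "fold_change")
print("strongest induced genes:")
for g, row in top.iterrows():
    print(f"  {g}: fold {row.fold_change:.1f}, FDR {row.fdr:.2g} "
          f"(planted fold {dataset.truth.gene_fold[g]:.1f})")
r = replicate_correlation(dataset.counts)
print(f"replicate Spearman r: EPO+ {r['EPO+']:.3f}, EPO- {r['EPO-']:.3f}")
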