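"""Annotate every ChIP peak with its nearest TSS and feature class.

Promoters are defined as 1 kb upstream to 100 nt downstream of a TSS;
peaks inside gene bodies split into UTR/CDS/intron; peaks within 50 kb
of a gene body are distal, the rest intergenic.  The resulting class
fractions are the pie-chart numbers of the study design this emulates.
"""

import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py")
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from stat5targets.peak_annotation import annotate_peaks, annotation_table

dataset = common.study()
annotated, fractions = annotate_peaks(
    dataset.peak_sets["pSTAT5"], dataset.genome.genes
)
table = annotation_table(annotated)
table.to_csv(common.RESULTS / "peak_annotation.tsv", sep="\t", index=False)
(common.RESULTS / "class_fractions.json").write_text(
    json.dumps(fractions, indent=1, sort_keys=True)
)

recovered = sum(
    row.feature == dataset.truth.peak_class[row.peak_name]
    for row in table.itertuples()
)
print(f"annotated {len(table)} peaks")
for cls, frac in sorted(fractions.items(), key=lambda kv: -kv[1]):
    print(f"  {cls:<11} {100 * frac:5.1f} %")
print(f"planted classes recovered: {recovered}/{len(table)}")
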