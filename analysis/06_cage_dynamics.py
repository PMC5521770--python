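"""RLE-normalise the CAGE tag time courses and classify response dynamics.

Regions whose maximal fold over t=0 stays below 2 are unresponsive;
responders peaking at or before 60 min are immediate, later peaks are
delayed — separating fast direct targets from slower secondary waves.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py")
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from stat5targets.expression_response import classify_cage_dynamics

dataset = common.study()
dynamics = classify_cage_dynamics(dataset.cage)
dynamics.to_csv(common.RESULTS / "cage_dynamics.tsv", sep="\t")

print(dynamics["call"].value_counts().to_string())
truth = dataset.truth.region_dynamics
ok = sum(dynamics.loc[r, "call"] == cls for r, cls in truth.items())
resp = [(r, cls) for r, cls in truth.items() if cls != "unresponsive"]
resp_ok = sum(dynamics.loc[r, "call"] == cls for r, cls in resp)
print(f"planted dynamics recovered: {ok}/{len(truth)} "
      f"(responsive only: {resp_ok}/{len(resp)})")
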