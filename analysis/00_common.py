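"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same seeded synthetic study (cheap, fully
deterministic) rather than passing files between steps, and writes its
tables under results/.
"""

from pathlib import Path

from stat5targets import synthetic_data as sd

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study():
    RESULTS.mkdir(exist_ok=True)
    return sd.simulate(sd.SimulationConfig(seed=SEED))
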