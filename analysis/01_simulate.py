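#!/usr/bin/env python
"""Generate the synthetic structure-activity study data.

Emits a raw assay table (replicated measurements, mixed units, alternate
SMILES encodings), the ground-truth activity metadata, and a 200-compound
screening library, all under results/study/.
"""
from pathlib import Path

from qsarscreen.config import RunConfig
from qsarscreen.pipeline import run_simulate

CONFIG = Path(__file__).parent / "study_config.yaml"

if __name__ == "__main__":
    cfg = RunConfig.load(CONFIG)
    paths = run_simulate(cfg)
    print(f"synthetic study written (seed={cfg.seed}):")
    for name, path in paths.items():
        print(f"  {path}")
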