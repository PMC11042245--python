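#!/usr/bin/env python
"""Map the curated chemical space with t-SNE on the fingerprint matrix.

Writes planar coordinates (CSV) and a scatter coloured by pChEMBL; with the
two-family generator the plot shows two clusters, the high-activity one
sharing a common core scaffold.
"""
from pathlib import Path

from qsarscreen.config import RunConfig
from qsarscreen.pipeline import run_explore

CONFIG = Path(__file__).parent / "study_config.yaml"

if __name__ == "__main__":
    cfg = RunConfig.load(CONFIG)
    paths = run_explore(cfg)
    print(f"t-SNE map written: {paths['tsne.png']} "
          f"(perplexity={cfg.tsne_perplexity}, seed-derived init)")
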