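#!/usr/bin/env python
"""Curate the raw assay table into a pChEMBL-labelled compound set.

Converts each measurement to a molar concentration and then to pChEMBL,
deduplicates by canonical SMILES, and averages replicate measurements on the
log scale.  Prints the row-level accounting and the resulting activity
distribution.
"""
import json
from pathlib import Path

from qsarscreen.config import RunConfig
from qsarscreen.io import read_curated_csv
from qsarscreen.pipeline import run_curate

CONFIG = Path(__file__).parent / "study_config.yaml"

if __name__ == "__main__":
    cfg = RunConfig.load(CONFIG)
    raw = Path(cfg.output_dir) / "raw_records.csv"
    paths = run_curate(cfg, str(raw))
    log = json.loads(Path(paths["curation_log.json"]).read_text())
    rows = read_curated_csv(paths["curated.csv"])
    actives = sum(r["active"] for r in rows)
    pchembl = [r["pchembl"] for r in rows]
    print(f"curated {log['n_records']} records -> {log['n_compounds']} compounds "
          f"({log['n_rejected']} rejected: {log['reject_reasons']})")
    print(f"pChEMBL range {min(pchembl):.2f}-{max(pchembl):.2f}; "
          f"{actives}/{len(rows)} active at threshold {cfg.activity_threshold} "
          f"({100 * actives / len(rows):.0f}%)")
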