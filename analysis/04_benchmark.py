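#!/usr/bin/env python
"""Benchmark ten regressors under seeded 5-fold nested cross-validation.

Each model's hyperparameters are chosen by grid search with 3-fold inner CV
on the training folds only; the champion (highest mean test R-squared, ties by
lowest mean test RMSE) is refit on the full curated set and saved for
screening.
"""
from pathlib import Path

from qsarscreen.config import RunConfig
from qsarscreen.pipeline import run_bench

CONFIG = Path(__file__).parent / "study_config.yaml"

if __name__ == "__main__":
    cfg = RunConfig.load(CONFIG)
    result = run_bench(cfg)
    table = result["table"]
    print(f"{'model':30s} {'test R2':>12s} {'test RMSE':>12s}")
    for rec in table.to_records():
        if "error" in rec:
            print(f"{rec['model']:30s} failed: {rec['error']}")
            continue
        print(f"{rec['model']:30s} {rec['test_r2_mean']:.3f} ({rec['test_r2_std']:.4f})"
              f" {rec['test_rmse_mean']:.3f} ({rec['test_rmse_std']:.4f})")
    print(f"champion: {table.champion} -> {Path(cfg.output_dir) / 'champion.joblib'}")
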