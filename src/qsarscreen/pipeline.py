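"""High-level pipeline stages shared by the CLI and the analysis scripts.

Each stage reads/writes plain files under a run directory and returns the
paths it wrote.  A ``manifest.json`` accumulates every artifact together with
the configuration fingerprint, so any output can be traced to the exact
settings (and master seed) that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import bench as bench_mod
from . import curation as cur
from . import explore as explore_mod
from . import io as qio
from . import screen as screen_mod
from . import synthetic as syn
from . import validate as val
from .bench import ModelHandle, ModelSpec, derive_seed
from .config import RunConfig
from .fingerprints import fingerprint_matrix


def _manifest_add(cfg: RunConfig, out_dir: Path, artifacts: list[str]) -> None:
    path = out_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config": cfg.to_dict(),
        "artifacts": {},
    }
    for a in artifacts:
        manifest["artifacts"][a] = cfg.fingerprint()
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_simulate(cfg: RunConfig) -> dict[str, str]:
    """Generate a synthetic raw assay table, ground truth, and a library."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = syn.SyntheticSpec(
        n_compounds=cfg.synthetic_n,
        noise_sd=cfg.synthetic_noise_sd,
        active_fraction=cfg.synthetic_active_fraction,
        activity_threshold=cfg.activity_threshold,
    )
    dataset = syn.generate_dataset(spec, seed=derive_seed(cfg.seed, "dataset"))
    records = syn.generate_raw_records(
        dataset,
        replicate_lambda=0.5,
        jitter_sd=0.05,
        alternate_smiles=True,
        seed=derive_seed(cfg.seed, "records"),
    )
    qio.write_csv(
        out / "raw_records.csv",
        (
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles,
                "endpoint_type": r.endpoint_type,
                "qualifier": r.qualifier,
                "value": r.value,
                "unit": r.unit,
            }
            for r in records
        ),
    )
    qio.write_json(
        out / "ground_truth.json",
        {
            "config_fingerprint": cfg.fingerprint(),
            "compounds": {
                c.structure_key: {
                    "pchembl": c.pchembl,
                    "scaffold_family": c.scaffold_family,
                    "deterministic_pchembl": c.deterministic_pchembl,
                }
                for c in dataset
            },
        },
    )
    library, truth = syn.generate_library(
        spec, n=200, overlap_fraction_with_actives=0.5,
        seed=derive_seed(cfg.seed, "library"),
    )
    (out / "library.smi").write_text("\n".join(library) + "\n")
    qio.write_json(out / "library_truth.json", truth)
    paths = ["raw_records.csv", "ground_truth.json", "library.smi", "library_truth.json"]
    _manifest_add(cfg, out, paths)
    return {p: str(out / p) for p in paths}


def run_curate(
    cfg: RunConfig, input_csv: str, column_map: dict | None = None
) -> dict[str, str]:
    """Raw activity table -> curated pChEMBL dataset + curation log."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(input_csv) as fh:
        records, parse_rejects = cur.parse_activity_table(fh, column_map)
    compounds, log = cur.curate(records, cfg.curation_config())
    qio.write_csv(out / "curated.csv", cur.compounds_to_rows(compounds))
    qio.write_json(
        out / "curation_log.json",
        {
            "config_fingerprint": cfg.fingerprint(),
            "n_parse_rejects": len(parse_rejects),
            **log.summary(),
        },
    )
    _manifest_add(cfg, out, ["curated.csv", "curation_log.json"])
    return {
        "curated.csv": str(out / "curated.csv"),
        "curation_log.json": str(out / "curation_log.json"),
    }


def _load_curated(cfg: RunConfig, curated_csv: str | None = None):
    path = curated_csv or str(Path(cfg.output_dir) / "curated.csv")
    rows = qio.read_curated_csv(path)
    keys = [r["structure_key"] for r in rows]
    y = np.array([r["pchembl"] for r in rows])
    matrix, failures = fingerprint_matrix(keys, cfg.fingerprint_config())
    if failures:
        raise ValueError(f"unparseable curated structures: {failures[:5]}")
    return keys, y, matrix


def run_explore(cfg: RunConfig, curated_csv: str | None = None) -> dict[str, str]:
    """t-SNE embedding of the curated set, coloured by pChEMBL."""
    out = Path(cfg.output_dir)
    keys, y, matrix = _load_curated(cfg, curated_csv)
    emb = explore_mod.tsne_embed(
        matrix,
        perplexity=cfg.tsne_perplexity,
        seed=derive_seed(cfg.seed, "tsne"),
        n_iterations=cfg.tsne_iterations,
    )
    qio.write_csv(
        out / "tsne_coords.csv",
        (
            {"structure_key": k, "x": float(c[0]), "y": float(c[1])}
            for k, c in zip(emb.ids, emb.coords)
        ),
    )
    explore_mod.plot_embedding(
        emb, dict(zip(keys, y)), str(out / "tsne.png")
    )
    _manifest_add(cfg, out, ["tsne_coords.csv", "tsne.png"])
    return {"tsne_coords.csv": str(out / "tsne_coords.csv"), "tsne.png": str(out / "tsne.png")}


def run_bench(cfg: RunConfig, curated_csv: str | None = None) -> dict:
    """Ten-model nested-CV benchmark; fits and saves the champion."""
    out = Path(cfg.output_dir)
    keys, y, matrix = _load_curated(cfg, curated_csv)
    X = matrix.matrix.astype(float)
    specs = [
        ModelSpec(name=n, grid=cfg.model_grids.get(n, {}))
        for n in bench_mod.MODEL_NAMES
    ]
    table = bench_mod.benchmark(
        X, y, specs, k=cfg.cv_k, inner_k=cfg.cv_inner_k,
        seed=derive_seed(cfg.seed, "bench"),
    )
    qio.write_csv(out / "benchmark.csv", table.to_records())
    champion_spec = next(s for s in specs if s.name == table.champion)
    handle = bench_mod.fit_final(
        X, y, champion_spec,
        seed=derive_seed(cfg.seed, "final"),
        fingerprint_config=cfg.fingerprint_config(),
        training_keys=keys,
        inner_k=cfg.cv_inner_k,
    )
    handle.save(str(out / "champion.joblib"))
    qio.write_json(
        out / "champion.json",
        {
            "config_fingerprint": cfg.fingerprint(),
            "champion": table.champion,
            "params": handle.params,
        },
    )
    _manifest_add(cfg, out, ["benchmark.csv", "champion.joblib", "champion.json"])
    return {"table": table, "handle": handle, "benchmark.csv": str(out / "benchmark.csv")}


def run_validate(cfg: RunConfig, curated_csv: str | None = None) -> dict:
    """90/10 reshuffle, rebuild the champion on 90%, screen the reserved 10%."""
    out = Path(cfg.output_dir)
    keys, y, matrix = _load_curated(cfg, curated_csv)
    labels = dict(zip(keys, y))
    train_keys, reserved_keys = val.reshuffle_split(
        keys, cfg.train_fraction, seed=derive_seed(cfg.seed, "reshuffle")
    )
    idx = {k: i for i, k in enumerate(keys)}
    X = matrix.matrix.astype(float)
    tr = [idx[k] for k in train_keys]
    table = bench_mod.benchmark(
        X[tr], y[tr],
        k=cfg.cv_k, inner_k=cfg.cv_inner_k,
        seed=derive_seed(cfg.seed, "revalidate"),
    )
    champion_spec = ModelSpec(name=table.champion, grid=cfg.model_grids.get(table.champion, {}))
    handle = bench_mod.fit_final(
        X[tr], y[tr], champion_spec,
        seed=derive_seed(cfg.seed, "refit"),
        fingerprint_config=cfg.fingerprint_config(),
        training_keys=train_keys,
        inner_k=cfg.cv_inner_k,
    )
    report = val.simulated_screen(
        handle, {k: labels[k] for k in reserved_keys}, cfg.activity_threshold
    )
    qio.write_json(
        out / "validation.json",
        {"config_fingerprint": cfg.fingerprint(), "champion": table.champion,
         **report.summary()},
    )
    qio.write_csv(out / "validation_table.csv", report.table)
    _manifest_add(cfg, out, ["validation.json", "validation_table.csv"])
    return {"report": report, "champion": table.champion, "handle": handle}


def run_screen(
    cfg: RunConfig,
    library_path: str | None = None,
    model_path: str | None = None,
) -> dict:
    """Score a library with the saved champion and rank hits with novelty."""
    out = Path(cfg.output_dir)
    library_path = library_path or str(out / "library.smi")
    model_path = model_path or str(out / "champion.joblib")
    handle = ModelHandle.load(model_path)
    if handle.fingerprint_config != cfg.fingerprint_config():
        raise ValueError(
            "fingerprint config mismatch between model and run config"
        )
    smiles = qio.read_library(library_path)
    preds = screen_mod.score_library(handle, smiles, source_library=Path(library_path).name)
    train_matrix, _ = fingerprint_matrix(handle.training_keys, handle.fingerprint_config)
    report = screen_mod.rank_hits(
        preds,
        train_matrix,
        mode=cfg.screening_mode,
        threshold=cfg.screening_threshold,
        k=cfg.screening_top_k,
    )
    qio.write_csv(
        out / "screening_report.csv",
        report.to_records(),
        fieldnames=[
            "rank", "structure_key", "predicted_pchembl",
            "novelty_tanimoto", "nearest_training_id", "source_library",
        ],
    )
    qio.write_json(
        out / "screening_summary.json",
        {
            "config_fingerprint": cfg.fingerprint(),
            "mode": report.mode,
            "threshold": report.threshold,
            "k": report.k,
            "n_scored": report.n_scored,
            "n_hits": len(report.hits),
            "n_parse_failures": len(preds.failures),
            "ranking_rule": report.ranking_rule,
        },
    )
    _manifest_add(cfg, out, ["screening_report.csv", "screening_summary.json"])
    return {"report": report, "screening_report.csv": str(out / "screening_report.csv")}
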