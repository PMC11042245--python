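"""Library screening: score, classify hits, rank, annotate novelty.

A fitted model scores every parseable structure in a library; hits are either
all compounds predicted at or above the pChEMBL threshold (default 7,
inclusive) or the top-K by predicted value regardless of threshold — the two
triage modes used in practice for small focused libraries and very large
collections respectively.  Each hit carries a novelty annotation: its maximum
Tanimoto similarity to the training set and the nearest training compound,
so chemically new hits are visible at a glance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bench import ModelHandle
from .curation import canonical_key
from .fingerprints import (
    FingerprintMatrix,
    fingerprint_matrix,
    max_train_similarity,
    morgan_fingerprint,
)


@dataclass
class LibraryPredictions:
    """Per-structure predictions plus the rows that failed to parse."""

    keys: list[str]  # canonical, deduplicated, input order of first sighting
    predicted: np.ndarray
    failures: list[tuple[str, str]]
    source_library: str = ""


def score_library(
    handle: ModelHandle,
    smiles_list: list[str],
    source_library: str = "",
) -> LibraryPredictions:
    """Predict pChEMBL for every parseable, deduplicated library structure.

    Structures are canonicalised first; duplicate molecules collapse onto one
    key.  Invalid SMILES are logged as failures, never fatal.
    """
    keys: list[str] = []
    seen: set[str] = set()
    failures: list[tuple[str, str]] = []
    for smi in smiles_list:
        try:
            key = canonical_key(smi)
        except ValueError as exc:
            failures.append((smi, str(exc)))
            continue
        if key not in seen:
            seen.add(key)
            keys.append(key)
    if not keys:
        raise ValueError("no parseable structure in library")
    matrix, fp_failures = fingerprint_matrix(keys, handle.fingerprint_config)
    failures.extend(fp_failures)
    preds = handle.predict(matrix.matrix.astype(float))
    return LibraryPredictions(
        keys=list(matrix.ids),
        predicted=preds,
        failures=failures,
        source_library=source_library,
    )


@dataclass(frozen=True)
class ScreeningHit:
    structure_key: str
    predicted_pchembl: float
    rank: int  # 1-based, dense over the sorted order
    novelty_tanimoto: float
    nearest_training_id: str
    source_library: str = ""


@dataclass
class ScreeningReport:
    """Ranked hits with the settings that produced them."""

    hits: list[ScreeningHit]
    mode: str
    threshold: float
    k: int | None
    n_scored: int
    ranking_rule: str = (
        "predicted pChEMBL descending; ties by structure_key ascending; "
        "dense 1..n ranks"
    )

    def to_records(self) -> list[dict]:
        return [
            {
                "rank": h.rank,
                "structure_key": h.structure_key,
                "predicted_pchembl": h.predicted_pchembl,
                "novelty_tanimoto": h.novelty_tanimoto,
                "nearest_training_id": h.nearest_training_id,
                "source_library": h.source_library,
            }
            for h in self.hits
        ]


def rank_hits(
    predictions: LibraryPredictions,
    train_matrix: FingerprintMatrix,
    mode: str = "threshold",
    threshold: float = 7.0,
    k: int = 200,
) -> ScreeningReport:
    """Rank scored compounds into a screening report.

    threshold mode keeps every compound predicted >= threshold (inclusive);
    top_k mode keeps the k best by predicted value with no threshold.  The
    sort is predicted value descending with ties broken by ascending
    structure key, so reports are deterministic; increasing k only appends.
    """
    if mode not in {"threshold", "top_k"}:
        raise ValueError(f"unknown ranking mode {mode!r}")
    if mode == "top_k" and k <= 0:
        raise ValueError("k must be positive")
    if len(predictions.keys) == 0:
        raise ValueError("no predictions to rank")

    order = sorted(
        range(len(predictions.keys)),
        key=lambda i: (-predictions.predicted[i], predictions.keys[i]),
    )
    if mode == "threshold":
        selected = [i for i in order if predictions.predicted[i] >= threshold]
    else:
        selected = order[:k]

    hits = []
    for rank, i in enumerate(selected, start=1):
        fp = morgan_fingerprint(predictions.keys[i], train_matrix.config)
        sim, nearest = max_train_similarity(fp, train_matrix)
        hits.append(
            ScreeningHit(
                structure_key=predictions.keys[i],
                predicted_pchembl=float(predictions.predicted[i]),
                rank=rank,
                novelty_tanimoto=sim,
                nearest_training_id=nearest,
                source_library=predictions.source_library,
            )
        )
    return ScreeningReport(
        hits=hits,
        mode=mode,
        threshold=threshold,
        k=k if mode == "top_k" else None,
        n_scored=len(predictions.keys),
    )
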