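"""Simulated virtual-screening validation.

Models are rebuilt on a reshuffled 90% of the curated dataset and asked to
"screen" the reserved 10% (and optionally an external labelled set): every
evaluation compound gets a predicted pChEMBL, compounds predicted at or above
the activity threshold are the screen's hits, and the report counts how many
truly active compounds the screen recovered, alongside the largest absolute
prediction error.  Because the evaluation compounds never touch model
construction, this quantifies generalisation to unseen molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bench import ModelHandle
from .curation import label_active
from .fingerprints import fingerprint_matrix


def reshuffle_split(
    keys: list[str], train_fraction: float = 0.9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded shuffle, then split into (train, reserved) sets.

    train size = floor(train_fraction * n), reserved takes the remainder —
    375 compounds at fraction 0.9 split 337/38.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(keys)
    if n < 10:
        raise ValueError("need at least 10 compounds to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.floor(train_fraction * n)
    train = [keys[i] for i in order[:n_train]]
    reserved = [keys[i] for i in order[n_train:]]
    return train, reserved


@dataclass
class EvalReport:
    """Outcome of one simulated screen on a labelled evaluation set."""

    n_eval: int
    n_true_active: int
    n_predicted_hits: int
    n_recovered_actives: int
    recall_of_actives: float  # recovered / true actives
    precision_of_hits: float  # recovered / predicted hits
    max_abs_error: float
    threshold: float
    table: list[dict] = field(default_factory=list)  # per-compound rows

    def summary(self) -> dict:
        return {
            "n_eval": self.n_eval,
            "n_true_active": self.n_true_active,
            "n_predicted_hits": self.n_predicted_hits,
            "n_recovered_actives": self.n_recovered_actives,
            "recall_of_actives": self.recall_of_actives,
            "precision_of_hits": self.precision_of_hits,
            "max_abs_error": self.max_abs_error,
            "threshold": self.threshold,
        }


def simulated_screen(
    handle: ModelHandle,
    eval_labels: dict[str, float],
    threshold: float = 7.0,
) -> EvalReport:
    """Screen a labelled evaluation set with a fitted model.

    eval_labels maps structure key -> actual pChEMBL.  The evaluation keys
    must be disjoint from the model's training keys (checked; overlap is an
    error naming the offenders).  A predicted hit is predicted pChEMBL >=
    threshold (inclusive); a recovered active is a predicted hit that is also
    truly active.
    """
    if not eval_labels:
        raise ValueError("empty evaluation set")
    overlap = sorted(set(eval_labels) & set(handle.training_keys))
    if overlap:
        raise ValueError(f"evaluation compounds seen in training: {overlap[:5]}")

    keys = sorted(eval_labels)  # row-order invariance by construction
    matrix, failures = fingerprint_matrix(keys, handle.fingerprint_config)
    if failures:
        raise ValueError(f"unparseable evaluation structures: {failures[:5]}")
    preds = handle.predict(matrix.matrix.astype(float))

    table = []
    n_true = n_hits = n_recovered = 0
    max_err = 0.0
    for key, pred in zip(matrix.ids, preds):
        actual = float(eval_labels[key])
        is_active = bool(label_active(actual, threshold))
        is_hit = bool(label_active(float(pred), threshold))
        n_true += is_active
        n_hits += is_hit
        n_recovered += is_active and is_hit
        max_err = max(max_err, abs(actual - float(pred)))
        table.append(
            {
                "structure_key": key,
                "actual_pchembl": actual,
                "predicted_pchembl": float(pred),
                "abs_error": abs(actual - float(pred)),
                "true_active": bool(is_active),
                "predicted_hit": bool(is_hit),
            }
        )
    return EvalReport(
        n_eval=len(keys),
        n_true_active=n_true,
        n_predicted_hits=n_hits,
        n_recovered_actives=n_recovered,
        recall_of_actives=n_recovered / n_true if n_true else float("nan"),
        precision_of_hits=n_recovered / n_hits if n_hits else float("nan"),
        max_abs_error=max_err,
        threshold=threshold,
        table=table,
    )
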