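"""Chemical-space exploration: 2-D t-SNE embedding of fingerprint matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .fingerprints import FingerprintMatrix


@dataclass
class Embedding2D:
    """Planar embedding with the parameters needed to reproduce it."""

    ids: list[str]
    coords: np.ndarray  # shape (n, 2)
    perplexity: float
    seed: int
    n_iterations: int
    metric: str


def tsne_embed(
    matrix: FingerprintMatrix,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iterations: int = 1000,
    metric: str = "euclidean",
) -> Embedding2D:
    """Embed a fingerprint matrix into the plane with seeded t-SNE.

    Euclidean distance on the 0/1 vectors is the default; ``metric="jaccard"``
    switches to Tanimoto distance.  Perplexity must be below the number of
    rows; the effective perplexity is capped at (n_rows - 1) / 3, the usual
    guidance for small datasets.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("t-SNE needs at least 3 rows")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n_rows {n}")
    perplexity = min(perplexity, max(1.0, (n - 1) / 3))
    X = matrix.matrix.astype(np.float64)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        max_iter=n_iterations,
        init="pca" if metric == "euclidean" else "random",
        metric=metric,
    )
    coords = tsne.fit_transform(X)
    return Embedding2D(
        ids=list(matrix.ids),
        coords=np.asarray(coords, dtype=float),
        perplexity=perplexity,
        seed=seed,
        n_iterations=n_iterations,
        metric=metric,
    )


def plot_embedding(
    embedding: Embedding2D,
    colour_values: dict[str, float],
    path: str,
    colour_label: str = "pChEMBL",
) -> str:
    """Scatter the embedding coloured by a continuous value (e.g. pChEMBL)."""
    if len(embedding.ids) == 0:
        raise ValueError("empty embedding")
    missing = [i for i in embedding.ids if i not in colour_values]
    if missing:
        raise ValueError(f"colour values missing for ids: {missing[:5]}")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = [colour_values[i] for i in embedding.ids]
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        embedding.coords[:, 0], embedding.coords[:, 1], c=values, cmap="viridis", s=18
    )
    fig.colorbar(sc, ax=ax, label=colour_label)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(
        f"chemical space (perplexity={embedding.perplexity:g}, seed={embedding.seed})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
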