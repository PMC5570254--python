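"""Nonlinear 2D embedding of signature vectors (Barnes-Hut t-SNE).

The embedding is only an intermediate coordinate system: density
clustering runs on it and the report plots it. A PCA pre-reduction to at
most 50 dimensions is applied first, standard practice for Barnes-Hut
t-SNE on high-dimensional compositional features. With a fixed seed the
coordinates are fully reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


@dataclass
class Embedding2D:
    ids: list[str]
    coords: np.ndarray  # n x 2
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {i: (float(x), float(y)) for i, (x, y) in zip(self.ids, self.coords)}


def embed_2d(
    features: np.ndarray,
    ids: list[str] | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
    pre_reduce: int = 50,
    theta: float = 0.5,
    n_iter: int = 1000,
) -> Embedding2D:
    """Embed feature vectors into 2D with Barnes-Hut t-SNE.

    Perplexity is clamped to (n - 1) / 3 with a warning when too large
    for the point count. ``pre_reduce`` caps the linear pre-reduction
    dimension (0 disables it).

    Raises
    ------
    ValueError
        If fewer than 4 points are given.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 4:
        raise ValueError(f"too few points to embed ({n} < 4)")
    if ids is None:
        ids = [str(i) for i in range(n)]

    max_perp = (n - 1) / 3.0
    if perplexity >= max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} points; "
            f"clamped to {max_perp:.2f}",
            stacklevel=2,
        )
        perplexity = max_perp * 0.999  # strict inequality required downstream

    X = features
    if pre_reduce and features.shape[1] > pre_reduce:
        k = min(pre_reduce, n, features.shape[1])
        X = PCA(n_components=k, svd_solver="full", random_state=seed).fit_transform(
            features
        )

    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        angle=theta,
        max_iter=max(n_iter, 250),
        init="pca",
        method="barnes_hut",
    )
    coords = tsne.fit_transform(X)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return Embedding2D(
        ids=list(ids),
        coords=np.asarray(coords, dtype=float),
        params={
            "perplexity": perplexity,
            "seed": seed,
            "pre_reduce": pre_reduce,
            "theta": theta,
            "n_iter": n_iter,
        },
    )


def write_coordinates_tsv(
    emb: Embedding2D, roles: dict[str, str], path: str
) -> None:
    with open(path, "w") as out:
        out.write("sequence_id\tx\ty\trole\n")
        for rid, (x, y) in zip(emb.ids, emb.coords):
            out.write(f"{rid}\t{x:.6f}\t{y:.6f}\t{roles.get(rid, '')}\n")
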