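"""Two-dimensional embedding of per-molecule replicate STR vectors.

Each molecule is represented by the vector of its replicate STR values with
the minimum and maximum removed as outliers (six replicates yield a
four-dimensional vector). t-SNE maps these vectors to the plane; molecules
of a jointly activated cascade share a rate and cluster together.
Coordinates carry no absolute meaning — only the relative topology (cluster
membership and separation) is interpretable, which ``cluster_separation``
quantifies as a mean silhouette coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score


@dataclass(frozen=True)
class StrVector:
    """Replicate STR values of one molecule (post-trim)."""

    molecule_id: str
    values: np.ndarray
    condition: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def trim_minmax(values) -> np.ndarray:
    """Remove exactly one minimal and one maximal element.

    Ties are resolved by removing a single instance of each; the multiset of
    the remaining values is preserved, and the median of an even-length
    input is unchanged.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need at least 4 values to trim min and max, got {len(x)}")
    keep = np.ones(len(x), dtype=bool)
    keep[np.argmin(x)] = False
    # argmax over still-kept entries so min == max inputs drop two elements
    masked = np.where(keep, x, -np.inf)
    keep[np.argmax(masked)] = False
    return x[keep]


def embed_str_vectors(
    vectors: list[StrVector],
    perplexity: float = 5.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> dict[str, tuple[float, float]]:
    """t-SNE embedding of the molecules' STR vectors into 2-D.

    Deterministic for a fixed seed and library version. Requires at least 3
    vectors of equal length and perplexity < number of vectors.
    """
    if len(vectors) < 3:
        raise ValueError(f"need at least 3 vectors to embed, got {len(vectors)}")
    lengths = {len(v.values) for v in vectors}
    if len(lengths) > 1:
        raise ValueError(f"all STR vectors must have equal length, got lengths {lengths}")
    if perplexity >= len(vectors):
        raise ValueError("perplexity must be smaller than the number of vectors")
    X = np.vstack([v.values for v in vectors])
    if np.allclose(X, X[0], rtol=0.0, atol=1e-12 * max(1.0, np.abs(X).max())):
        # degenerate input: all vectors identical, every pairwise distance is
        # zero, and the only faithful 2-D layout is a single point (the
        # underlying optimizer cannot handle zero input variance)
        return {v.molecule_id: (0.0, 0.0) for v in vectors}
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = tsne.fit_transform(X)
    return {v.molecule_id: (float(x), float(y)) for v, (x, y) in zip(vectors, coords)}


def cluster_separation(coords, labels) -> float:
    """Mean silhouette coefficient of the embedded points under the given
    labels, in [-1, 1]; higher means better-separated clusters.

    Labels with a single point are excluded with a warning; degenerate
    inputs (all points coincident, or fewer than 2 usable labels) score 0.
    """
    pts = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if len(pts) != len(labels):
        raise ValueError("coords and labels must have equal length")
    uniq, counts = np.unique(labels, return_counts=True)
    singletons = uniq[counts < 2]
    if len(singletons):
        warnings.warn(
            f"excluding single-point labels from separation score: {list(singletons)}",
            stacklevel=2,
        )
        keep = ~np.isin(labels, singletons)
        pts, labels = pts[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        return 0.0
    if np.allclose(pts, pts[0], atol=1e-12):
        return 0.0
    return float(silhouette_score(pts, labels))
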