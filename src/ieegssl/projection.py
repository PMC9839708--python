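"""2-D neighbor-embedding projection of autoencoder embeddings for expert review.

Projections are a review aid only: no pipeline decision consumes the 2-D
coordinates (this module is imported by nothing else in the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import BINARY_CLASS_NAMES, CLASS_NAMES, UNLABELED

__all__ = ["Projection2D", "project_2d", "render_scatter"]


class ProjectionError(ValueError):
    pass


@dataclass
class Projection2D:
    coords: np.ndarray           # (M, 2)
    segment_ids: list[str]
    seed: int
    params: dict = field(default_factory=dict)


def project_2d(embeddings: np.ndarray, seed: int = 0, n_neighbors: int = 15,
               min_dist: float = 0.1, segment_ids: list[str] | None = None) -> Projection2D:
    """UMAP projection to 2-D; deterministic for a fixed seed."""
    import umap  # deferred: numba-backed import is slow

    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    m = embeddings.shape[0]
    if m < n_neighbors + 1:
        raise ProjectionError(f"{m} points are too few for n_neighbors={n_neighbors}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=int(seed))
    coords = np.asarray(reducer.fit_transform(embeddings), dtype=np.float64)
    if segment_ids is None:
        segment_ids = [str(i) for i in range(m)]
    return Projection2D(coords=coords, segment_ids=list(segment_ids), seed=int(seed),
                        params={"n_neighbors": n_neighbors, "min_dist": min_dist})


def legend_entries(labels: np.ndarray, mode: str = "multiclass") -> list[str]:
    """Legend strings in class-code order for the classes present in ``labels``."""
    names = BINARY_CLASS_NAMES if mode == "binary" else CLASS_NAMES
    entries = [f"{code}-{names[code]}" for code in sorted(names) if (labels == code).any()]
    if (np.asarray(labels) == UNLABELED).any():
        entries.append("unlabeled")
    return entries


def render_scatter(projection: Projection2D, labels: np.ndarray, path: str,
                   mode: str = "multiclass", title: str = "") -> str:
    """Scatter the projection with one color per class and a class-ordered legend.

    ``mode='multiclass'`` uses the 4-class legend (0-power line noise ...);
    ``mode='binary'`` the pseudo-prospective legend (0-physiological, 1-IED).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    if labels.shape[0] != projection.coords.shape[0]:
        raise ProjectionError("labels must align with projection coords")
    names = BINARY_CLASS_NAMES if mode == "binary" else CLASS_NAMES
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab10")
    for code in sorted(names):
        mask = labels == code
        if not mask.any():
            continue
        ax.scatter(projection.coords[mask, 0], projection.coords[mask, 1],
                   s=6, color=cmap(code), label=f"{code}-{names[code]}")
    unl = labels == UNLABELED
    if unl.any():
        ax.scatter(projection.coords[unl, 0], projection.coords[unl, 1],
                   s=6, color="lightgray", label="unlabeled")
    ax.legend(markerscale=2, fontsize=8)
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    if title:
        ax.set_title(title)
    try:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    except OSError as exc:
        raise ProjectionError(f"cannot write figure to {path!r}: {exc}") from exc
    finally:
        plt.close(fig)
    return path
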