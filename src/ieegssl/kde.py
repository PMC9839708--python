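"""Per-class kernel-density classification of embeddings (Naive-Bayes form).

Each class's density over the D-dimensional embedding space is estimated as a
product of univariate Gaussian kernels — one bandwidth per dimension by
Silverman's rule — from the N labeled embeddings in that class.  A query is
assigned to the class with the highest prior-weighted density; with equal N
per class and uniform priors this is the maximum-density rule.

The axis-aligned product kernel is the operational reading of the Naive-Bayes
framing: dimensions are treated as conditionally independent given the class,
which sidesteps estimating a full 128-D joint density from tens of points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["ClassKDE", "KDEClassifier", "fit_kde", "log_density", "classify"]

_LOG_2PI = float(np.log(2.0 * np.pi))


class KDEError(ValueError):
    pass


@dataclass
class ClassKDE:
    """Gaussian product-kernel density for one class: stored points + per-dim bandwidths."""

    class_code: int
    points: np.ndarray      # (N, D)
    bandwidths: np.ndarray  # (D,)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.bandwidths = np.asarray(self.bandwidths, dtype=np.float64)
        if self.points.shape[0] < 1:
            raise KDEError(f"class {self.class_code}: needs at least one training point")
        if self.bandwidths.shape != (self.points.shape[1],):
            raise KDEError("one bandwidth per dimension required")
        if not (self.bandwidths > 0).all():
            raise KDEError("bandwidths must be positive")

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def _silverman_bandwidths(points: np.ndarray, eps_bw: float) -> np.ndarray:
    """h_d = 0.9 * min(sigma_d, IQR_d / 1.34) * N^(-1/5), floored at eps_bw.

    Quantiles use the nearest-rank convention; degenerate dimensions (zero
    spread) fall to the floor.
    """
    n = points.shape[0]
    sigma = points.std(axis=0)  # population std
    q75 = np.percentile(points, 75, axis=0, method="nearest")
    q25 = np.percentile(points, 25, axis=0, method="nearest")
    spread = np.minimum(sigma, (q75 - q25) / 1.34)
    return np.maximum(0.9 * spread * n ** (-1.0 / 5.0), eps_bw)


def fit_kde(labeled_embeddings: dict[int, np.ndarray], eps_bw: float = 1e-3,
            priors: dict[int, float] | None = None,
            bandwidth_mode: str = "per_dim") -> "KDEClassifier":
    """Fit one ClassKDE per class from a class -> (N, D) embedding mapping.

    ``bandwidth_mode='shared'`` replaces the per-dimension bandwidths of each
    class by their mean (a single scalar scale per class).
    """
    if not labeled_embeddings:
        raise KDEError("no classes supplied")
    kdes: dict[int, ClassKDE] = {}
    dim = None
    for code in sorted(labeled_embeddings):
        pts = np.atleast_2d(np.asarray(labeled_embeddings[code], dtype=np.float64))
        if pts.size == 0 or pts.shape[0] == 0:
            raise KDEError(f"class {code} has zero labeled embeddings")
        if dim is None:
            dim = pts.shape[1]
        elif pts.shape[1] != dim:
            raise KDEError(f"class {code}: dimension {pts.shape[1]} != {dim}")
        bw = _silverman_bandwidths(pts, eps_bw)
        if bandwidth_mode == "shared":
            bw = np.full_like(bw, bw.mean())
        elif bandwidth_mode != "per_dim":
            raise KDEError(f"unknown bandwidth_mode {bandwidth_mode!r}")
        kdes[code] = ClassKDE(code, pts, bw)
    codes = sorted(kdes)
    if priors is None:
        pri = np.full(len(codes), 1.0 / len(codes))
    else:
        pri = np.array([priors[c] for c in codes], dtype=np.float64)
        if (pri < 0).any() or not np.isclose(pri.sum(), 1.0):
            raise KDEError("priors must be nonnegative and sum to 1")
        pri = pri / pri.sum()
    return KDEClassifier(kdes=kdes, priors=pri)


def log_density(kde: ClassKDE, x: np.ndarray) -> float:
    """log of the product-kernel density at x, via log-sum-exp over training points."""
    return float(_log_density_batch(kde, np.atleast_2d(x))[0])


def _log_density_batch(kde: ClassKDE, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != kde.dim:
        raise KDEError(f"query dimension {X.shape[1]} != KDE dimension {kde.dim}")
    h = kde.bandwidths
    # (M, N) matrix of per-point Gaussian log-kernels
    z = (X[:, None, :] - kde.points[None, :, :]) / h
    log_kernels = -0.5 * (z * z).sum(axis=2) - np.log(h).sum() - 0.5 * kde.dim * _LOG_2PI
    return logsumexp(log_kernels, axis=1) - np.log(kde.points.shape[0])


@dataclass
class KDEClassifier:
    """One ClassKDE per class plus class priors (uniform by default)."""

    kdes: dict[int, ClassKDE]
    priors: np.ndarray

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=np.float64)
        dims = {k.dim for k in self.kdes.values()}
        if len(dims) != 1:
            raise KDEError("all class KDEs must share one dimensionality")
        if len(self.priors) != len(self.kdes):
            raise KDEError("one prior per class required")

    @property
    def classes(self) -> list[int]:
        return sorted(self.kdes)

    @property
    def dim(self) -> int:
        return next(iter(self.kdes.values())).dim

    def posterior_batch(self, X: np.ndarray) -> np.ndarray:
        """(M, C) posterior matrix, columns ordered by ascending class code."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        log_post = np.column_stack([
            _log_density_batch(self.kdes[c], X) + np.log(p)
            for c, p in zip(self.classes, self.priors)
        ])
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        return np.exp(log_post)

    def predict_batch(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(predicted class codes, posterior matrix); ties go to the lowest code."""
        post = self.posterior_batch(X)
        codes = np.asarray(self.classes)
        return codes[np.argmax(post, axis=1)], post


def classify(clf: KDEClassifier, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Classify one embedding: (argmax-posterior class, posterior vector)."""
    codes, post = clf.predict_batch(np.atleast_2d(x))
    return int(codes[0]), post[0]
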