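"""Latent-space machinery for attribute discovery and controlled walks.

A style-based generator modulates synthesis through per-layer style
vectors y = A w + b, where w is a latent code in the intermediate space
W and (A, b) is a learned affine map.  The operations here are the
desk-scale parts of that pipeline:

* :func:`style_vector` — the affine style transform itself.
* :func:`sefa_directions` — closed-form semantic factorization: the top
  eigenvectors of M = sum_i A_i^T A_i are the latent directions along
  which the generator output varies most; walking along them changes
  one semantic factor (debris level, inflammation, vascular pattern...).
* :func:`latent_walk` — codes w_i = w_base - alpha_i * a with alpha on a
  linear grid over [A, B]; step 2 over intervals within [0, 50] is a
  practical default for capsule-endoscopy attributes.
* :func:`frechet_distance` / :func:`fit_feature_stats` — the Fréchet
  distance between Gaussian fits of feature sets, the usual
  generated-vs-real distribution metric (the deep feature extractor is a
  pluggable preprocessing step).
* :func:`label_pathology_attributes` — mark an attribute as pathology
  relevant when any of its walk samples lands within a radius of an
  expert-chosen prototype in an (injected) embedding space.
* :func:`make_planted_generator` — a toy generator with a planted
  spectrum and a disk rasterizer, so factorization, walks and labeling
  can be exercised and tested end to end without any trained model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError

_PSD_TOL = 1e-6


@dataclass(frozen=True)
class AffineStyleMap:
    """One layer's learned affine transform y = A w + b (A is m x d)."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
            raise ValidationError(f"A must be a 2-D m x d matrix, got shape {A.shape}")
        if b.shape != (A.shape[0],):
            raise ValidationError(
                f"b must have length m = {A.shape[0]}, got shape {b.shape}"
            )
        if not (np.isfinite(A).all() and np.isfinite(b).all()):
            raise ValidationError("A and b must be finite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @property
    def style_dim(self) -> int:
        return self.A.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.A.shape[1]


@dataclass(frozen=True)
class AttributeDirection:
    """A unit latent direction with its variation strength."""

    a: np.ndarray
    eigenvalue: float
    rank: int
    pathology_relevant: bool | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValidationError("attribute direction must be a unit vector")
        if self.eigenvalue < 0:
            raise ValidationError("eigenvalue must be nonnegative")
        object.__setattr__(self, "a", a)


@dataclass(frozen=True)
class WalkSpec:
    """A linear walk w_i = w_base - alpha_i * a, alpha in [lo, hi]."""

    w_base: np.ndarray
    direction: AttributeDirection
    interval: tuple[float, float] = (0.0, 50.0)
    alpha_step: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if lo > hi:
            raise ValidationError(f"interval bounds must satisfy lo <= hi, got {self.interval}")
        if self.alpha_step <= 0:
            raise ValidationError(f"alpha_step must be positive, got {self.alpha_step}")
        w = np.asarray(self.w_base, dtype=float)
        if w.shape != self.direction.a.shape:
            raise ValidationError(
                f"w_base (shape {w.shape}) and direction (shape "
                f"{self.direction.a.shape}) must agree"
            )
        object.__setattr__(self, "w_base", w)


@dataclass(frozen=True)
class FeatureStats:
    """Gaussian moments (mean, covariance) of a feature set."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if cov.shape != (mean.size, mean.size):
            raise ValidationError(
                f"covariance shape {cov.shape} does not match mean length {mean.size}"
            )
        if np.abs(cov - cov.T).max() > 1e-8:
            raise ValidationError("covariance must be symmetric within 1e-8")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", (cov + cov.T) / 2.0)


def style_vector(style_map: AffineStyleMap, w: np.ndarray) -> np.ndarray:
    """Apply the affine style transform: y = A w + b."""
    w = np.asarray(w, dtype=float)
    if w.shape != (style_map.latent_dim,):
        raise ValidationError(
            f"latent code must have length d = {style_map.latent_dim}, "
            f"got shape {w.shape}"
        )
    return style_map.A @ w + style_map.b


def sefa_directions(
    maps: AffineStyleMap | Iterable[AffineStyleMap], j: int
) -> list[AttributeDirection]:
    """Closed-form semantic factorization of one or more style maps.

    Stacks the maps' rows — eigen-decomposes M = sum_i A_i^T A_i — and
    returns the top-``j`` unit eigenvectors as attribute directions,
    eigenvalues sorted descending.  Each direction's sign is fixed so
    its largest-magnitude component is positive, giving reproducible
    walk orientations.
    """
    if isinstance(maps, AffineStyleMap):
        maps = [maps]
    maps = list(maps)
    if not maps:
        raise ValidationError("need at least one AffineStyleMap")
    d = maps[0].latent_dim
    if any(m.latent_dim != d for m in maps):
        raise ValidationError("all style maps must share the latent dimension d")
    if not 1 <= j <= d:
        raise ValidationError(f"j must lie in [1, d] = [1, {d}], got {j}")

    M = np.zeros((d, d))
    for m in maps:
        M += m.A.T @ m.A
    eigvals, eigvecs = np.linalg.eigh(M)  # ascending
    order = np.argsort(eigvals)[::-1][:j]

    out = []
    for rank, idx in enumerate(order, start=1):
        v = eigvecs[:, idx]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        out.append(
            AttributeDirection(
                a=v / np.linalg.norm(v),
                eigenvalue=float(max(eigvals[idx], 0.0)),
                rank=rank,
            )
        )
    return out


def latent_walk(spec: WalkSpec) -> list[np.ndarray]:
    """Latent codes along an attribute direction, in increasing alpha.

    alpha takes the values lo, lo + step, ... up to and including every
    value <= hi; a zero-length interval yields the single base code.
    """
    lo, hi = spec.interval
    n_steps = int(np.floor((hi - lo) / spec.alpha_step + 1e-12))
    alphas = lo + spec.alpha_step * np.arange(n_steps + 1)
    return [spec.w_base - alpha * spec.direction.a for alpha in alphas]


def fit_feature_stats(features: np.ndarray) -> FeatureStats:
    """Sample mean and covariance (denominator n - 1) of feature vectors."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 feature vectors to fit moments")
    cov = np.cov(X, rowvar=False, ddof=1)
    return FeatureStats(mean=X.mean(axis=0), covariance=np.atleast_2d(cov))


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigen-decomposition, eigenvalues
    clamped at zero (tolerance _PSD_TOL for genuine negativity)."""
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < -_PSD_TOL * max(1.0, abs(vals.max())):
        raise ValidationError(
            f"covariance is not PSD within tolerance (min eigenvalue {vals.min():.3g})"
        )
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(p: FeatureStats, q: FeatureStats) -> float:
    """Fréchet distance between two Gaussian feature distributions.

    d^2 = ||mu_p - mu_q||^2 + Tr(Sigma_p + Sigma_q - 2 (Sigma_p Sigma_q)^{1/2})

    The cross term is computed as Tr sqrt(S_p^{1/2} Sigma_q S_p^{1/2}),
    a symmetric PSD reformulation of the matrix square root; tiny
    negative residue from floating point is clamped at zero, with a
    warning if it exceeds tolerance.
    """
    if p.mean.shape != q.mean.shape:
        raise ValidationError(
            f"dimension mismatch: {p.mean.shape} vs {q.mean.shape}"
        )
    sqrt_p = _psd_sqrt(p.covariance)
    _psd_sqrt(q.covariance)  # validates PSD-ness of q
    inner = sqrt_p @ q.covariance @ sqrt_p
    vals = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    tr_sqrt = float(np.sqrt(vals).sum())

    diff = p.mean - q.mean
    d2 = float(diff @ diff + np.trace(p.covariance) + np.trace(q.covariance)
               - 2.0 * tr_sqrt)
    if d2 < 0.0:
        if d2 < -_PSD_TOL:
            warnings.warn(
                f"Fréchet distance numerically negative ({d2:.3g}); clamped to 0",
                stacklevel=2,
            )
        d2 = 0.0
    return d2


def label_pathology_attributes(
    walk_points: Mapping[str, np.ndarray],
    prototypes: np.ndarray,
    radius: float,
) -> dict[str, bool]:
    """Flag attributes whose walks approach a disease prototype.

    ``walk_points`` maps an attribute name to the embedded positions of
    its walk samples; an attribute is pathology relevant iff any sample
    lies within Euclidean distance ``radius`` of any prototype.  The
    embedding itself (e.g. t-SNE seeded with prototype images) is an
    injected preprocessing step.
    """
    if radius <= 0:
        raise ValidationError(f"radius must be positive, got {radius}")
    protos = np.atleast_2d(np.asarray(prototypes, dtype=float))
    if protos.size == 0:
        raise ValidationError("at least one prototype point is required")

    flags: dict[str, bool] = {}
    for name, pts in walk_points.items():
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if pts.shape[1] != protos.shape[1]:
            raise ValidationError(
                f"attribute {name!r}: embedding dimension {pts.shape[1]} does "
                f"not match prototypes ({protos.shape[1]})"
            )
        flags[name] = bool((cdist(pts, protos) <= radius).any())
    return flags


def _orthonormal(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """n x k matrix with orthonormal columns (QR of a Gaussian draw)."""
    q, r = np.linalg.qr(rng.standard_normal((n, k)))
    return q * np.sign(np.diag(r))  # fix QR sign ambiguity for determinism


def make_planted_generator(
    d: int,
    m: int,
    spectrum: Sequence[float],
    seed: int,
    raster_size: int = 64,
) -> tuple[AffineStyleMap, Callable[[np.ndarray], np.ndarray], np.ndarray]:
    """Toy generator with known factors: A = U diag(spectrum) V^T.

    Returns ``(style_map, rasterize, planted_directions)`` where
    ``planted_directions`` are the columns of V (the ground-truth
    attribute directions that factorization should recover) and
    ``rasterize`` maps a style vector to a square grayscale raster whose
    disk radius, interior intensity and ring texture are monotone in the
    first three style coordinates — so a walk along a planted direction
    produces a visibly monotone image sequence, the desk-scale analogue
    of attribute-conditional generation.
    """
    spec = np.asarray(spectrum, dtype=float)
    if spec.ndim != 1 or len(spec) < 1 or len(spec) > min(d, m):
        raise ValidationError(
            f"spectrum length must lie in [1, min(d, m)] = [1, {min(d, m)}]"
        )
    if np.any(spec <= 0) or np.any(np.diff(spec) >= 0):
        raise ValidationError("spectrum must be strictly decreasing positives")

    rng = np.random.default_rng(seed)
    r = len(spec)
    U = _orthonormal(m, r, rng)
    V = _orthonormal(d, r, rng)
    style_map = AffineStyleMap(A=(U * spec) @ V.T, b=np.zeros(m))

    yy, xx = np.mgrid[0:raster_size, 0:raster_size]
    center = (raster_size - 1) / 2.0
    rad_grid = np.hypot(xx - center, yy - center)

    def rasterize(y: np.ndarray) -> np.ndarray:
        """Style vector -> uint8 grayscale raster (disk on black)."""
        y = np.asarray(y, dtype=float)
        if y.shape != (m,):
            raise ValidationError(f"style vector must have length m = {m}")
        squash = lambda v: 1.0 / (1.0 + np.exp(-v))
        radius = (0.08 + 0.36 * squash(y[0])) * raster_size
        intensity = 80.0 + 175.0 * squash(y[1] if m > 1 else 0.0)
        ripple = 0.5 * squash(y[2] if m > 2 else 0.0)
        disk = rad_grid <= radius
        texture = 1.0 - ripple * (0.5 + 0.5 * np.cos(rad_grid))
        img = np.zeros((raster_size, raster_size))
        img[disk] = intensity * texture[disk]
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return style_map, rasterize, V


def disk_radius(raster: np.ndarray) -> float:
    """Measured disk radius of a planted-generator raster (max distance
    of a lit pixel from the raster centre); 0 for an all-dark raster."""
    lit = np.argwhere(raster > 0)
    if len(lit) == 0:
        return 0.0
    center = (np.asarray(raster.shape, dtype=float) - 1) / 2.0
    return float(np.max(np.hypot(*(lit - center).T)))
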