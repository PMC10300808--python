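"""Ordinary and generalized Procrustes analysis for landmark configurations.

Superimposition removes position, orientation and (optionally) size:
pairwise alignment is the classical least-squares similarity fit with the
rotation obtained from an SVD of the cross-covariance matrix (Kabsch), with
the determinant correction that forbids improper rotations (reflections).
Generalized Procrustes analysis (GPA) iterates alignment of every shape to
the running mean until the mean stabilises; the mean shape is kept at unit
centroid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkSet

__all__ = [
    "Shape",
    "SimilarityTransform",
    "ShapeEnsemble",
    "centroid_size",
    "align_pair",
    "procrustes_distance",
    "gpa_mean",
]


def _as_points(shape: "Shape | LandmarkSet | np.ndarray") -> np.ndarray:
    if isinstance(shape, Shape):
        return shape.points
    if isinstance(shape, LandmarkSet):
        return shape.points
    return np.asarray(shape, dtype=float)


def centroid_size(lm: "LandmarkSet | Shape | np.ndarray") -> float:
    """Root sum of squared distances of the landmarks from their centroid."""
    pts = _as_points(lm)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


@dataclass(frozen=True)
class Shape:
    """A landmark configuration as geometry only (identity stripped)."""

    points: np.ndarray  # (k, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))

    @classmethod
    def from_landmarks(cls, lm: LandmarkSet) -> "Shape":
        return cls(points=lm.points.copy())

    @property
    def centroid_size(self) -> float:
        return centroid_size(self.points)

    def normalized(self) -> "Shape":
        """Centered at the origin and scaled to unit centroid size."""
        pts = self.points - self.points.mean(axis=0)
        size = np.sqrt((pts**2).sum())
        if size == 0:
            raise ValueError("degenerate shape: zero centroid size")
        return Shape(pts / size)


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * rotation @ x + translation, with a proper rotation."""

    rotation: np.ndarray  # (3, 3), det = +1
    scale: float
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation is improper (det != +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=np.eye(3), scale=1.0, translation=np.zeros(3))


@dataclass
class ShapeEnsemble:
    """A superimposed group of shapes plus its Procrustes mean shape."""

    shapes: list[Shape]
    mean_shape: Shape
    group_label: str = ""
    iterations: int = 0
    converged: bool = False
    specimen_ids: list[str] = field(default_factory=list)


def _check_configuration(pts: np.ndarray, what: str) -> None:
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, abs(centered).max())) < 2:
        raise ValueError(f"{what}: landmarks are collinear (rank-deficient)")


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R maximising trace(R @ A.T @ B) plus the corrected
    singular values of the cross-covariance (for the scale factor)."""
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    s_corr = s * np.array([1.0, 1.0, d])
    return R, s_corr


def align_pair(
    source: "Shape | LandmarkSet | np.ndarray",
    target: "Shape | LandmarkSet | np.ndarray",
    allow_scale: bool = True,
) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity (or rigid) fit of ``source`` onto ``target``.

    Returns the optimal transform and the root-mean-square landmark misfit
    after applying it.  Reflections are never returned: the SVD solution is
    corrected to a proper rotation, so a mirrored target yields a proper
    rotation with non-zero residual.
    """
    A = _as_points(source)
    B = _as_points(target)
    if A.shape != B.shape:
        raise ValueError(f"landmark count mismatch: {A.shape} vs {B.shape}")
    _check_configuration(A, "source")
    _check_configuration(B, "target")

    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mu_a, B - mu_b
    R, s_corr = _optimal_rotation(Ac, Bc)
    scale = float(s_corr.sum() / (Ac**2).sum()) if allow_scale else 1.0
    if scale <= 0:
        raise ValueError("optimal scale is non-positive (degenerate configuration)")
    t = mu_b - scale * R @ mu_a
    T = SimilarityTransform(rotation=R, scale=scale, translation=t)
    resid = T.apply(A) - B
    rms = float(np.sqrt((resid**2).sum() / A.shape[0]))
    return T, rms


def procrustes_distance(
    a: "Shape | LandmarkSet | np.ndarray", b: "Shape | LandmarkSet | np.ndarray"
) -> float:
    """Symmetric full-Procrustes RMS misfit between two configurations.

    Both configurations are centered and scaled to unit centroid size, then
    optimally rotated and scaled onto each other; the residual reduces to
    sqrt(1 - (sum of corrected singular values)^2) / sqrt(k), which is
    symmetric in the two arguments by construction.
    """
    A = Shape(_as_points(a)).normalized().points
    B = Shape(_as_points(b)).normalized().points
    if A.shape != B.shape:
        raise ValueError(f"landmark count mismatch: {A.shape} vs {B.shape}")
    _, s_corr = _optimal_rotation(A, B)
    ssq = max(0.0, 1.0 - float(s_corr.sum()) ** 2)
    return float(np.sqrt(ssq / A.shape[0]))


def gpa_mean(
    shapes: "list[Shape] | list[LandmarkSet]",
    tol: float = 1e-8,
    max_iter: int = 100,
    group_label: str = "",
    scale_per_iteration: bool = False,
) -> ShapeEnsemble:
    """Generalized Procrustes analysis: superimpose all shapes, return mean.

    Every shape is first centered and normalized to unit centroid size; each
    iteration aligns all shapes to the current mean (rotation only by
    default, full similarity when ``scale_per_iteration``), recomputes the
    mean and renormalizes it to unit centroid size, until the mean moves by
    less than ``tol`` in Procrustes distance.  The initial reference is the
    first shape in input order; the invariance tests guard against order
    sensitivity.
    """
    if len(shapes) < 2:
        raise ValueError("GPA requires at least two shapes")
    specimen_ids = [
        s.specimen_id if isinstance(s, LandmarkSet) else "" for s in shapes
    ]
    pts = [Shape(_as_points(s)).normalized().points for s in shapes]
    k = pts[0].shape[0]
    for p in pts:
        if p.shape != (k, 3):
            raise ValueError("all shapes must share landmark count and order")

    mean = pts[0]
    converged = False
    iterations = 0
    aligned = pts
    for iterations in range(1, max_iter + 1):
        new_aligned = []
        for p in aligned:
            T, _ = align_pair(p, mean, allow_scale=scale_per_iteration)
            q = T.apply(p)
            if scale_per_iteration:
                q = Shape(q).normalized().points
            new_aligned.append(q)
        aligned = new_aligned
        new_mean = Shape(np.mean(aligned, axis=0)).normalized().points
        moved = procrustes_distance(new_mean, mean)
        mean = new_mean
        if moved < tol:
            converged = True
            break

    return ShapeEnsemble(
        shapes=[Shape(p) for p in aligned],
        mean_shape=Shape(mean),
        group_label=group_label,
        iterations=iterations,
        converged=converged,
        specimen_ids=specimen_ids,
    )
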