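"""3D thin-plate-spline interpolation and landmark-driven mesh morphing.

A TPS maps one landmark configuration exactly onto another (at zero
regularisation) and extends that map smoothly to all of space, which lets a
full skull mesh follow its 18 landmarks onto a target mean shape.  The map
is f(x) = c + B x + sum_i w_i U(|x - s_i|) with the 3D biharmonic kernel
U(r) = -r by default (the sign convention only flips the solved weights; +r
is available).  The weights satisfy the usual side conditions: they have no
affine component, i.e. the weight columns are orthogonal to [1 | source
points].

Morphing a millimetre-scale mesh toward a unit-size Procrustes mean shape
directly would collapse it, so the target configuration is first
similarity-aligned (rotation, translation, scale) onto the template's own
landmarks; the morph then changes only shape, never gross size or pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LANDMARK_NAMES, LandmarkSet
from .registration import Shape, align_pair

__all__ = [
    "TPSTransform",
    "TriangleMesh",
    "tps_solve",
    "tps_apply",
    "bending_energy",
    "morph_template",
]


@dataclass
class TriangleMesh:
    """A triangle surface with optional named-landmark annotations.

    ``landmark_map`` carries each landmark either as a vertex index (the
    landmark lies on the mesh) or as a free 3D point near the surface;
    landmarks are never snapped to vertices.
    """

    vertices: np.ndarray  # (m, 3) mm
    faces: np.ndarray     # (f, 3) vertex indices
    landmark_map: dict[str, "int | np.ndarray"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    def landmark_points(self) -> np.ndarray:
        """The 18 landmark positions in scheme order, from the annotation map."""
        missing = [n for n in LANDMARK_NAMES if n not in self.landmark_map]
        if missing:
            raise ValueError("mesh is missing landmark annotations: " + ", ".join(missing))
        pts = []
        for name in LANDMARK_NAMES:
            ref = self.landmark_map[name]
            if isinstance(ref, (int, np.integer)):
                pts.append(self.vertices[int(ref)])
            else:
                pts.append(np.asarray(ref, dtype=float))
        return np.stack(pts)


@dataclass(frozen=True)
class TPSTransform:
    """A solved 3D thin-plate-spline map from source to target landmarks."""

    source_points: np.ndarray   # (n, 3)
    affine_matrix: np.ndarray   # (3, 3)
    affine_offset: np.ndarray   # (3,)
    kernel_weights: np.ndarray  # (n, 3)
    kernel: str = "minus_r"
    regularization: float = 0.0


def _kernel_matrix(r: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "minus_r":
        return -r
    if kernel == "r":
        return r
    raise ValueError(f"unknown TPS kernel {kernel!r}")


def tps_solve(
    source: np.ndarray,
    target: np.ndarray,
    lam: float = 0.0,
    kernel: str = "minus_r",
) -> TPSTransform:
    """Solve the bordered TPS system for weights and affine part.

    Solves [[K + lam*I, P], [P.T, 0]] [W; A] = [Y; 0] where K is the kernel
    matrix over the source points and P = [1 | X].  Requires n >= 5
    non-coplanar source points so the affine part is determined; with
    lam = 0 the map interpolates each target point exactly.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"source must be n x 3, got {X.shape}")
    if X.shape != Y.shape:
        raise ValueError(f"source/target shape mismatch: {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 5:
        raise ValueError("TPS in 3D needs at least 5 control points")
    if lam < 0:
        raise ValueError("regularization must be non-negative")

    P = np.hstack([np.ones((n, 1)), X])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, abs(X).max())) < 4:
        raise ValueError("source points are coplanar: affine part is rank-deficient")

    r = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    K = _kernel_matrix(r, kernel)
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K + lam * np.eye(n)
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = Y
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate TPS system: {exc}") from exc
    W = sol[:n]
    A = sol[n:]
    return TPSTransform(
        source_points=X.copy(),
        affine_offset=A[0].copy(),
        affine_matrix=A[1:].T.copy(),
        kernel_weights=W,
        kernel=kernel,
        regularization=float(lam),
    )


def tps_apply(T: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the TPS map at arbitrary points (vectorised, O(m*n))."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts[:, None, :] - T.source_points[None, :, :], axis=2)
    U = _kernel_matrix(r, T.kernel)
    out = T.affine_offset + pts @ T.affine_matrix.T + U @ T.kernel_weights
    return out if np.asarray(points).ndim == 2 else out[0]


def bending_energy(T: TPSTransform) -> float:
    """Magnitude of the TPS bending-energy quadratic form trace(W.T K W)."""
    r = np.linalg.norm(
        T.source_points[:, None, :] - T.source_points[None, :, :], axis=2
    )
    K = _kernel_matrix(r, T.kernel)
    return float(abs(np.trace(T.kernel_weights.T @ K @ T.kernel_weights)))


def morph_template(
    mesh: TriangleMesh,
    template_landmarks: "LandmarkSet | np.ndarray | None" = None,
    target_mean: "Shape | np.ndarray | None" = None,
    lam: float = 0.0,
    kernel: str = "minus_r",
) -> TriangleMesh:
    """Morph a template mesh so its landmarks meet a target mean shape.

    The target mean (typically a unit-size Procrustes mean) is first
    similarity-aligned to the template's own landmark configuration, so the
    morph preserves the template's scale and pose; a TPS from the template
    landmarks to the aligned targets then transports every mesh vertex.
    Topology is untouched: the face list and vertex count are preserved.
    """
    if template_landmarks is None:
        src = mesh.landmark_points()
    elif isinstance(template_landmarks, LandmarkSet):
        src = template_landmarks.points
    else:
        src = np.asarray(template_landmarks, dtype=float)
    if target_mean is None:
        raise ValueError("target_mean is required")
    tgt = target_mean.points if isinstance(target_mean, Shape) else np.asarray(
        target_mean, dtype=float
    )
    if tgt.shape != src.shape:
        raise ValueError(f"landmark count mismatch: {tgt.shape} vs {src.shape}")

    T_align, _ = align_pair(tgt, src, allow_scale=True)
    tgt_in_template_frame = T_align.apply(tgt)

    T = tps_solve(src, tgt_in_template_frame, lam=lam, kernel=kernel)
    new_vertices = tps_apply(T, mesh.vertices)
    new_map: dict[str, int | np.ndarray] = {}
    for name, ref in mesh.landmark_map.items():
        if isinstance(ref, (int, np.integer)):
            new_map[name] = int(ref)
        else:
            new_map[name] = tps_apply(T, np.asarray(ref, dtype=float))
    return TriangleMesh(vertices=new_vertices, faces=mesh.faces.copy(), landmark_map=new_map)
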