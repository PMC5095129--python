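"""Normalisation of digitised open SAM contours.

A contour is an ordered open polyline tracing the meristem outline from one
basal end, over the apex, to the other basal end (μm, y-up).  The pipeline
mirrors standard open-outline morphometrics: orient so the next leaf
primordium (P0) is on a fixed side, thin to equally arc-length-spaced
pseudo-landmarks, then superimpose the population by generalised Procrustes
analysis (GPA) with landmark-index correspondence.

Reflections are never allowed in the rotation step: left/right asymmetry is a
real biological signal handled explicitly by :func:`orient_contour`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Contour",
    "AlignedContourSet",
    "resample_contour",
    "orient_contour",
    "procrustes_align",
]

ORIENTATIONS = ("p0_left", "p0_right", "unknown")


@dataclass(frozen=True)
class Contour:
    """An ordered open 2-D outline of a shoot apex (coordinates in μm, y-up)."""

    points: np.ndarray
    contour_id: str = ""
    is_open: bool = True
    orientation: str = "unknown"
    #: skip the distinct-consecutive-points check (reconstructed/degenerate shapes)
    check: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("contour needs an (n >= 2, 2) point array")
        if self.check and np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive contour points must be distinct")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centroid_size(self) -> float:
        """Square root of summed squared distances to the centroid (μm)."""
        c = self.points - self.centroid()
        return float(np.sqrt(np.sum(c**2)))


@dataclass
class AlignedContourSet:
    """Result of GPA: superimposed pseudo-landmark configurations.

    ``landmarks`` has shape (n_shapes, n_points, 2); every shape is centred at
    the origin and, when scaling was applied, has unit centroid size.
    ``centroid_sizes`` keeps the original sizes in μm so size is never lost.
    ``sse_history`` records the summed squared deviation from the mean after
    each GPA iteration (monotonically non-increasing).
    """

    landmarks: np.ndarray
    ids: list[str]
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    converged: bool
    iterations: int
    with_scaling: bool
    sse_history: list[float] = field(default_factory=list)

    @property
    def n_shapes(self) -> int:
        return self.landmarks.shape[0]

    @property
    def n_points(self) -> int:
        return self.landmarks.shape[1]


def _arc_lengths(pts: np.ndarray) -> np.ndarray:
    seg = np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_contour(contour: Contour, n_points: int = 800) -> Contour:
    """Thin/resample a contour to ``n_points`` equally arc-length-spaced pseudo-landmarks.

    Endpoints are preserved exactly; interior points are linear interpolations
    along the input polyline at equal arc-length spacing.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    s = _arc_lengths(contour.points)
    total = s[-1]
    if total <= 0:
        raise ValueError("contour has zero total length")
    target = np.linspace(0.0, total, n_points)
    x = np.interp(target, s, contour.points[:, 0])
    y = np.interp(target, s, contour.points[:, 1])
    pts = np.column_stack([x, y])
    pts[0] = contour.points[0]
    pts[-1] = contour.points[-1]
    return replace(contour, points=pts)


def orient_contour(contour: Contour, target: str) -> Contour:
    """Mirror a contour about the vertical axis through its centroid if needed.

    No-op when the contour already has ``target`` orientation.  On mirroring,
    x-coordinates are negated about the centroid and the point order is
    reversed so traversal still runs base → apex → base in the same rotational
    sense.
    """
    if target not in ("p0_left", "p0_right"):
        raise ValueError("target orientation must be 'p0_left' or 'p0_right'")
    if contour.orientation == "unknown":
        raise ValueError(
            f"contour {contour.contour_id!r} has unknown orientation; "
            "set the orientation flag before orienting"
        )
    if contour.orientation == target:
        return contour
    cx = contour.centroid()[0]
    pts = contour.points.copy()
    pts[:, 0] = 2.0 * cx - pts[:, 0]
    pts = pts[::-1]
    return replace(contour, points=pts, orientation=target)


def _optimal_rotations(shapes: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Batch of proper rotations (det = +1) aligning each shape onto ``mean``."""
    # cross-covariance per shape: (n, 2, 2)
    A = np.einsum("npi,pj->nij", shapes, mean)
    U, _, Vt = np.linalg.svd(A)
    det = np.linalg.det(U @ Vt)
    # flip the smallest singular direction where a reflection would be optimal
    D = np.repeat(np.eye(2)[None], shapes.shape[0], axis=0)
    D[:, 1, 1] = np.sign(det)
    return U @ D @ Vt


def procrustes_align(
    contours: list[Contour] | np.ndarray,
    with_scaling: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedContourSet:
    """Generalised Procrustes analysis with landmark-index correspondence.

    Each configuration is centred (and scaled to unit centroid size when
    ``with_scaling``), then iteratively rotated onto the current mean shape by
    the optimal *proper* rotation (reflections forbidden); the mean is updated
    until it changes by less than ``tol`` (RMS) or ``max_iter`` is reached.
    """
    if isinstance(contours, np.ndarray):
        shapes = np.asarray(contours, dtype=float).copy()
        ids = [str(i) for i in range(shapes.shape[0])]
    else:
        if len(contours) < 2:
            raise ValueError("need at least 2 contours to align")
        n_pts = {c.n_points for c in contours}
        if len(n_pts) != 1:
            raise ValueError(f"all contours must share one point count, got {sorted(n_pts)}")
        shapes = np.stack([c.points for c in contours]).astype(float)
        ids = [c.contour_id for c in contours]
    if shapes.shape[0] < 2:
        raise ValueError("need at least 2 shapes to align")

    shapes -= shapes.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(shapes**2, axis=(1, 2)))
    if np.any(sizes <= 0):
        raise ValueError("degenerate zero-size configuration")
    if with_scaling:
        shapes /= sizes[:, None, None]

    mean = shapes[0].copy()
    converged = False
    sse_history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        R = _optimal_rotations(shapes, mean)
        shapes = np.einsum("npi,nij->npj", shapes, R)
        new_mean = shapes.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        sse_history.append(float(np.sum((shapes - new_mean[None]) ** 2)))
        delta = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations", stacklevel=2)

    return AlignedContourSet(
        landmarks=shapes,
        ids=ids,
        centroid_sizes=sizes,
        mean_shape=mean,
        converged=converged,
        iterations=it,
        with_scaling=with_scaling,
        sse_history=sse_history,
    )
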