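"""Discrete-cosine-transform shape descriptors for open contours, with PCA.

After Procrustes alignment each contour is a pair of coordinate signals
(x_0..x_{N-1}) and (y_0..y_{N-1}) over the pseudo-landmark index.  Each signal
is transformed by the orthonormal DCT-II; harmonics k = 1..n_harmonics are
retained (k = 0 carries the mean and is ~0 for centred shapes, so it is
dropped).  The per-shape feature vector is the concatenation
[coeff_x, coeff_y] (length 24 at the default 12 harmonics).

PCA is an eigen-decomposition of the covariance of the column-centred,
*unscaled* coefficient matrix — coefficients share units, and per-column
standardisation would distort the harmonic energy ordering.  PC signs are
fixed deterministically: the largest-|loading| entry of each PC is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct as _dct, idct as _idct

from .contours import AlignedContourSet, Contour

__all__ = [
    "DctCoefficients",
    "ShapePcSpace",
    "dct_transform",
    "inverse_dct",
    "shape_pca",
    "reconstruct_at_pc",
]


@dataclass(frozen=True)
class DctCoefficients:
    """Retained DCT-II harmonics (k = 1..n_harmonics) of one shape's x and y signals."""

    shape_id: str
    coeff_x: np.ndarray
    coeff_y: np.ndarray
    n_harmonics: int
    n_points: int

    def __post_init__(self) -> None:
        cx = np.asarray(self.coeff_x, dtype=float)
        cy = np.asarray(self.coeff_y, dtype=float)
        if cx.shape != (self.n_harmonics,) or cy.shape != (self.n_harmonics,):
            raise ValueError("coeff_x/coeff_y must have length n_harmonics")
        if not (np.all(np.isfinite(cx)) and np.all(np.isfinite(cy))):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coeff_x", cx)
        object.__setattr__(self, "coeff_y", cy)

    @property
    def vector(self) -> np.ndarray:
        """Concatenated feature vector [coeff_x, coeff_y]."""
        return np.concatenate([self.coeff_x, self.coeff_y])


@dataclass
class ShapePcSpace:
    """PCA over DCT coefficient vectors.

    ``scores`` is (n_shapes, n_pcs), ``loadings`` (n_pcs, 2*n_harmonics) with
    orthonormal rows, ``explained_fraction`` the per-PC share of total
    coefficient variance, ``mean_coeffs`` the column means of the coefficient
    matrix.  ``pc_sign_convention`` records, per PC, the loading index whose
    positivity fixed the sign.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    mean_coeffs: np.ndarray
    n_harmonics: int
    n_points: int
    ids: list[str]
    pc_sign_convention: dict[int, int]

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]

    def score_sd(self, pc: int) -> float:
        return float(np.std(self.scores[:, pc], ddof=1))


def dct_transform(aligned: AlignedContourSet, n_harmonics: int = 12) -> list[DctCoefficients]:
    """Orthonormal DCT-II of each aligned shape's x and y signals, truncated.

    Harmonics k = 1..n_harmonics are kept for each coordinate independently.
    """
    n_points = aligned.n_points
    if n_harmonics >= n_points:
        raise ValueError(f"n_harmonics ({n_harmonics}) must be < n_points ({n_points})")
    out = []
    coeffs = _dct(aligned.landmarks, type=2, norm="ortho", axis=1)
    for i in range(aligned.n_shapes):
        out.append(
            DctCoefficients(
                shape_id=aligned.ids[i],
                coeff_x=coeffs[i, 1 : n_harmonics + 1, 0],
                coeff_y=coeffs[i, 1 : n_harmonics + 1, 1],
                n_harmonics=n_harmonics,
                n_points=n_points,
            )
        )
    return out


def _inverse_vector(vec: np.ndarray, n_harmonics: int, n_points: int) -> np.ndarray:
    """Inverse truncated orthonormal DCT-II of a [coeff_x, coeff_y] vector -> (n, 2)."""
    full = np.zeros((n_points, 2))
    full[1 : n_harmonics + 1, 0] = vec[:n_harmonics]
    full[1 : n_harmonics + 1, 1] = vec[n_harmonics:]
    return _idct(full, type=2, norm="ortho", axis=0)


def inverse_dct(coeffs: DctCoefficients, n_points: int | None = None) -> Contour:
    """Reconstruct a centred open contour from retained harmonics."""
    n = coeffs.n_points if n_points is None else n_points
    if n < 2:
        raise ValueError("n_points must be >= 2")
    pts = _inverse_vector(coeffs.vector, coeffs.n_harmonics, n)
    return Contour(points=pts, contour_id=coeffs.shape_id, orientation="unknown", check=False)


def shape_pca(coeff_list: list[DctCoefficients]) -> ShapePcSpace:
    """PCA of the (n_shapes × 2·n_harmonics) coefficient matrix.

    Eigen-decomposition of the covariance of the column-centred, unscaled
    matrix via SVD.  All PCs up to the matrix rank bound are retained;
    explained fractions are non-increasing and sum to 1.
    """
    if len(coeff_list) < 3:
        raise ValueError("shape PCA needs at least 3 shapes")
    n_h = {c.n_harmonics for c in coeff_list}
    if len(n_h) != 1:
        raise ValueError("all coefficient sets must share n_harmonics")
    n_harmonics = n_h.pop()

    X = np.stack([c.vector for c in coeff_list])
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]

    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)

    scores = U * s
    loadings = Vt
    sign_convention: dict[int, int] = {}
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(loadings[k])))
        sign_convention[k] = j
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]

    return ShapePcSpace(
        scores=scores,
        loadings=loadings,
        explained_fraction=explained,
        mean_coeffs=mean,
        n_harmonics=n_harmonics,
        n_points=coeff_list[0].n_points,
        ids=[c.shape_id for c in coeff_list],
        pc_sign_convention=sign_convention,
    )


def reconstruct_at_pc(
    space: ShapePcSpace,
    pc: int,
    sd_multiples: list[float],
    n_points: int | None = None,
) -> list[Contour]:
    """Expected shapes along one PC at given multiples of its score SD.

    Inverse-DCT of ``mean_coeffs + m · sd(score_pc) · loading_pc`` for each
    multiple ``m``; ``m = 0`` returns the mean shape.
    """
    if not 0 <= pc < space.n_pcs:
        raise ValueError(f"pc {pc} outside retained PCs (0..{space.n_pcs - 1})")
    n = space.n_points if n_points is None else n_points
    sd = space.score_sd(pc)
    out = []
    for m in sd_multiples:
        vec = space.mean_coeffs + m * sd * space.loadings[pc]
        pts = _inverse_vector(vec, space.n_harmonics, n)
        out.append(
            Contour(points=pts, contour_id=f"pc{pc + 1}_{m:+g}sd", orientation="unknown", check=False)
        )
    return out
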