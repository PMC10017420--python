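"""Thin-plate-spline warps from sparse landmark correspondences.

Standard 2D TPS with kernel U(r) = r^2 log r: the warp is an affine part
plus a weighted sum of kernels centred on the control points, solved from
the square system

    [K + lam*I  P] [w]   [v]
    [P^T        0] [a] = [0]

per output coordinate, where K_ij = U(|p_i - p_j|) and P = [1, x, y].
lam = 0 interpolates the control points exactly; lam > 0 trades landmark
fidelity for bending-energy smoothness (useful with noisy matches). Pure
affine correspondences yield zero kernel weights, so affine motion is
reproduced exactly everywhere for any lam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DegenerateConfigurationError, InvalidParameterError

__all__ = ["WarpModel", "fit_tps", "tps_kernel"]


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, r**2 * np.log(r), 0.0)
    return out


@dataclass
class WarpModel:
    """Fitted TPS mapping source-plane points to target-plane points."""

    control_points: np.ndarray  # (N, 2) source landmarks
    affine: np.ndarray  # (3, 2): rows [const, x-coef, y-coef] per output dim
    weights: np.ndarray  # (N, 2) kernel weights per output dim
    lam: float

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map (M, 2) source-plane points through the warp."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts[:, None, :] - self.control_points[None, :, :]
        K = tps_kernel(np.sqrt((d**2).sum(-1)))
        out = (
            self.affine[0][None, :]
            + pts @ self.affine[1:]
            + K @ self.weights
        )
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.transform(points)


def fit_tps(src: np.ndarray, dst: np.ndarray, lam: float = 0.0) -> WarpModel:
    """Fit a TPS warp sending ``src`` landmarks to ``dst``.

    Requires >= 3 non-collinear source points. With lam = 0 the fitted
    warp passes through every correspondence exactly.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
        raise InvalidParameterError("src and dst must both be (N, 2)")
    n = len(src)
    if n < 3:
        raise DegenerateConfigurationError("need at least 3 correspondences")
    if lam < 0:
        raise InvalidParameterError("lam must be >= 0")
    centered = src - src.mean(axis=0)
    # collinearity check via the singular values of the centred cloud
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("control points are collinear")

    d = src[:, None, :] - src[None, :, :]
    K = tps_kernel(np.sqrt((d**2).sum(-1))) + lam * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as e:
        raise DegenerateConfigurationError(f"singular TPS system: {e}") from e
    return WarpModel(
        control_points=src.copy(),
        affine=sol[n:],
        weights=sol[:n],
        lam=float(lam),
    )
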