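"""Comparison reconstructions: temporal-total-variation least squares,
low-rank-plus-sparse decomposition, and the zero-filled adjoint."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spiralcine.gridding import GriddedKSpace, coil_combine
from spiralcine.operators import MeasurementOperator, centered_ifft2
from spiralcine.synthetic import CineImage
from spiralcine.dps import ReconResult


@dataclass(frozen=True)
class TTVConfig:
    lambda_t: float = 1e-3
    n_iters: int = 100
    tol: float = 1e-7
    step: float = 1.0
    backtrack: float = 0.5
    circular: bool = True

    def __post_init__(self):
        if self.lambda_t < 0 or self.n_iters < 1:
            raise ValueError("invalid TTVConfig")


@dataclass(frozen=True)
class LRSConfig:
    lambda_L: float = 1e-2
    lambda_S: float = 1e-3
    n_iters: int = 100
    tol: float = 1e-7
    step: float = 1.0

    def __post_init__(self):
        if self.lambda_L < 0 or self.lambda_S < 0 or self.n_iters < 1:
            raise ValueError("invalid LRSConfig")


# ----------------------------------------------------------------------------
# 1D total-variation prox (temporal axis), circular or linear boundary
# ----------------------------------------------------------------------------


def tv1d_prox(v: np.ndarray, lam: float, circular: bool = True,
              max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """prox of lam * sum |x_{f+1} - x_f| along axis 0, vectorized.

    Solved on the dual: min_u 1/2 ||v - D^T u||^2 with the box/ball
    constraint |u| <= lam, by FISTA projected gradient (L = ||D D^T|| <= 4).
    Works for real and complex data; for complex data the constraint is the
    complex modulus ball.
    """
    if lam == 0:
        return v.copy()
    f = v.shape[0]
    n_con = f if circular else f - 1
    if n_con < 1:
        return v.copy()

    def D(x):  # forward difference
        d = np.roll(x, -1, axis=0) - x
        return d if circular else d[:-1]

    def Dt(u):  # adjoint
        if circular:
            return np.roll(u, 1, axis=0) - u
        up = np.concatenate([np.zeros_like(u[:1]), u])
        un = np.concatenate([u, np.zeros_like(u[:1])])
        return up - un

    u = np.zeros((n_con,) + v.shape[1:], dtype=v.dtype)
    w = u.copy()
    t_mom = 1.0
    step = 0.25
    x = v.copy()
    for _ in range(max_iter):
        grad = -D(v - Dt(w))
        u_new = w - step * grad
        mag = np.abs(u_new)
        scale = np.minimum(1.0, lam / np.maximum(mag, 1e-300))
        u_new = u_new * scale
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
        w = u_new + ((t_mom - 1) / t_new) * (u_new - u)
        du = np.max(np.abs(u_new - u)) if u.size else 0.0
        u, t_mom = u_new, t_new
        x = v - Dt(u)
        if du < tol * max(lam, 1.0):
            break
    return x


def tv1d_value(x: np.ndarray, circular: bool = True) -> float:
    d = np.roll(x, -1, axis=0) - x
    if not circular:
        d = d[:-1]
    return float(np.sum(np.abs(d)))


# ----------------------------------------------------------------------------
# TTV
# ----------------------------------------------------------------------------


def recon_ttv(y: GriddedKSpace, A: MeasurementOperator,
              config: TTVConfig = TTVConfig()) -> ReconResult:
    """Proximal-gradient minimization of 1/2||Ax-y||^2 + lam * TV_t(x)."""
    if y.n_frames < 2:
        raise ValueError("TTV needs at least 2 frames")
    yd = y.data
    lam = config.lambda_t

    def data_obj(x):
        r = A.forward(x) - yd
        return 0.5 * float(np.sum(np.abs(r) ** 2))

    def objective(x):
        return data_obj(x) + lam * tv1d_value(x, config.circular)

    x = A.adjoint(yd)
    obj = objective(x)
    history = [obj]
    tau = config.step
    for it in range(config.n_iters):
        grad = A.adjoint(A.forward(x) - yd)
        accepted = False
        tau_try = tau
        for _ in range(30):
            x_new = tv1d_prox(x - tau_try * grad, lam * tau_try, config.circular)
            obj_new = objective(x_new)
            if obj_new <= obj + 1e-12 * max(abs(obj), 1.0):
                accepted = True
                break
            tau_try *= config.backtrack
        if not accepted:
            break
        rel = abs(obj - obj_new) / max(abs(obj), 1e-12)
        x, obj, tau = x_new, obj_new, tau_try
        history.append(obj)
        if not np.isfinite(obj):
            raise FloatingPointError("TTV diverged")
        if rel < config.tol:
            break
    return ReconResult(
        x_hat=CineImage(x),
        residual_log=np.asarray(history),
        provenance={"method": "ttv", "lambda_t": lam, "n_iters": len(history) - 1},
    )


# ----------------------------------------------------------------------------
# LRS
# ----------------------------------------------------------------------------


def svt(matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Singular-value soft thresholding U (S - thr)_+ V^H."""
    u, s, vh = np.linalg.svd(matrix, full_matrices=False)
    s = np.maximum(s - threshold, 0.0)
    return (u * s) @ vh


def nuclear_norm(matrix: np.ndarray) -> float:
    return float(np.sum(np.linalg.svd(matrix, compute_uv=False)))


def _tfft(x: np.ndarray) -> np.ndarray:
    return np.fft.fft(x, axis=0, norm="ortho")


def _itfft(k: np.ndarray) -> np.ndarray:
    return np.fft.ifft(k, axis=0, norm="ortho")


def soft_threshold(x: np.ndarray, threshold: float) -> np.ndarray:
    mag = np.abs(x)
    return np.where(mag > 0, x * np.maximum(mag - threshold, 0.0) / np.maximum(mag, 1e-300), 0)


def recon_lrs(y: GriddedKSpace, A: MeasurementOperator,
              config: LRSConfig = LRSConfig()) -> ReconResult:
    """Iterative soft-thresholding L+S decomposition (Casorati low rank +
    temporal-Fourier sparsity), x = L + S at output."""
    if y.n_frames < 2:
        raise ValueError("LRS needs at least 2 frames")
    yd = y.data
    nf, g = y.n_frames, A.grid_size

    def casorati(x):
        return x.reshape(nf, g * g)

    def objective(L, S):
        r = A.forward(L + S) - yd
        val = 0.5 * float(np.sum(np.abs(r) ** 2))
        val += config.lambda_L * nuclear_norm(casorati(L))
        val += config.lambda_S * float(np.sum(np.abs(_tfft(S))))
        return val

    M = A.adjoint(yd)
    L = M.copy()
    S = np.zeros_like(M)
    history = [objective(L, S)]
    for it in range(config.n_iters):
        L = svt(casorati(M - S), config.lambda_L * config.step).reshape(nf, g, g)
        S = _itfft(soft_threshold(_tfft(M - L), config.lambda_S * config.step))
        resid = A.adjoint(A.forward(L + S) - yd)
        M = L + S - config.step * resid
        obj = objective(L, S)
        history.append(obj)
        if not np.isfinite(obj):
            raise FloatingPointError("LRS diverged")
        if abs(history[-2] - obj) < config.tol * max(abs(history[-2]), 1e-12):
            break
    x = L + S
    return ReconResult(
        x_hat=CineImage(x),
        residual_log=np.asarray(history),
        provenance={
            "method": "lrs",
            "lambda_L": config.lambda_L,
            "lambda_S": config.lambda_S,
            "n_iters": len(history) - 1,
        },
    )


# ----------------------------------------------------------------------------


def recon_zero_filled(y: GriddedKSpace, A: MeasurementOperator) -> ReconResult:
    """Coil-combined adjoint of the masked data (lower-bound comparator)."""
    imgs = centered_ifft2(y.data * y.mask[:, None])
    x = coil_combine(imgs, A.maps)
    return ReconResult(
        x_hat=x,
        residual_log=np.empty(0),
        provenance={"method": "zero_filled"},
    )
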