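"""GRAPPA operator gridding (GROG), occupancy masks, coil-map estimation
and coil combination.

Conventions: k-space grids are centered (DC at index grid_size//2),
coordinates are cycles/FOV in [-0.5, 0.5), grid cell spacing 1/grid_size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spiralcine.synthetic import CineImage, CoilMaps
from spiralcine.spiral import SpiralKSpace

EPS_FLOOR_FRACTION = 1e-8


@dataclass
class GrogKernels:
    """Unit-cell shift operators along kx and ky with cached eigensystems."""

    Gx: np.ndarray
    Gy: np.ndarray
    calib_source: str = ""

    def __post_init__(self) -> None:
        self.Gx = np.asarray(self.Gx, dtype=np.complex128)
        self.Gy = np.asarray(self.Gy, dtype=np.complex128)
        if self.Gx.shape != self.Gy.shape or self.Gx.shape[0] != self.Gx.shape[1]:
            raise ValueError("Gx/Gy must be square matrices of equal size")
        self._eig = {}

    @property
    def n_coils(self) -> int:
        return self.Gx.shape[0]

    def _eigensystem(self, axis: str):
        if axis not in self._eig:
            G = self.Gx if axis == "x" else self.Gy
            w, v = np.linalg.eig(G)
            try:
                vinv = np.linalg.inv(v)
            except np.linalg.LinAlgError:
                vinv = np.linalg.pinv(v)
            self._eig[axis] = (w, v, vinv)
        return self._eig[axis]

    def fractional_power(self, axis: str, delta: float) -> np.ndarray:
        """G^delta via the eigendecomposition (principal branch)."""
        if delta == 0:
            return np.eye(self.n_coils, dtype=np.complex128)
        w, v, vinv = self._eigensystem(axis)
        return (v * np.power(w.astype(np.complex128), delta)) @ vinv

    def shift_operator(self, dx: float, dy: float) -> np.ndarray:
        return self.fractional_power("x", dx) @ self.fractional_power("y", dy)


@dataclass
class GriddedKSpace:
    """Cartesian-grid k-space after GROG with occupancy mask and hit counts."""

    data: np.ndarray  # (n_frames, n_coils, g, g) complex
    mask: np.ndarray  # (n_frames, g, g) in {0,1}
    weight: np.ndarray = None  # (n_frames, g, g) accumulation counts

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.mask = np.asarray(self.mask)
        if self.data.ndim != 4 or self.mask.ndim != 3:
            raise ValueError("GriddedKSpace expects (F,C,g,g) data and (F,g,g) mask")
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask must be binary")
        if np.any(self.data * (1 - self.mask[:, None]) != 0):
            raise ValueError("data must be zero where mask is zero")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_size(self) -> int:
        return self.data.shape[-1]


@dataclass
class SamplingMask:
    """Binary per-frame occupancy shared across coils."""

    mask: np.ndarray  # (n_frames, g, g)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("mask must have shape (n_frames, g, g)")
        if np.any(self.mask.reshape(self.mask.shape[0], -1).sum(axis=1) == 0):
            raise ValueError("each frame must have at least one sampled cell")


# ----------------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------------


def calibrate_grog(calib_data: np.ndarray, calib_mask: np.ndarray | None = None,
                   calib_source: str = "temporal-average grid") -> GrogKernels:
    """Fit unit-shift GRAPPA operators from a Cartesian calibration grid.

    ``calib_data`` is (n_coils, g, g); for each axis all filled neighbor
    pairs (k, k+1cell) enter a least-squares fit target = G @ source.
    """
    calib_data = np.asarray(calib_data, dtype=np.complex128)
    if calib_data.ndim != 3:
        raise ValueError("calibration data must be (n_coils, g, g)")
    nc = calib_data.shape[0]
    if calib_mask is None:
        calib_mask = np.all(calib_data != 0, axis=0)
    calib_mask = calib_mask.astype(bool)

    kernels = []
    for axis in (1, 0):  # x = last axis shift, y = first axis shift of the (ky,kx) grid
        pair = calib_mask & np.roll(calib_mask, -1, axis=axis)
        # exclude wrap-around pairs
        if axis == 1:
            pair[:, -1] = False
        else:
            pair[-1, :] = False
        src_idx = np.where(pair)
        if src_idx[0].size < nc:
            raise ValueError(
                "rank-deficient GROG calibration: need more filled neighbor pairs"
            )
        src = calib_data[:, src_idx[0], src_idx[1]]  # (nc, npairs)
        if axis == 1:
            tgt = calib_data[:, src_idx[0], src_idx[1] + 1]
        else:
            tgt = calib_data[:, src_idx[0] + 1, src_idx[1]]
        # solve G src = tgt  ->  G = tgt src^H (src src^H)^-1
        gram = src @ src.conj().T
        rhs = tgt @ src.conj().T
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "rank-deficient GROG calibration: need more calibration data"
            )
        kernels.append(rhs @ np.linalg.inv(gram))
    Gx, Gy = kernels
    return GrogKernels(Gx=Gx, Gy=Gy, calib_source=calib_source)


# ----------------------------------------------------------------------------
# gridding
# ----------------------------------------------------------------------------


def nearest_cell(coords: np.ndarray, grid_size: int) -> tuple:
    """Nearest grid indices and fractional offsets (in cells) for coords.

    Returns (iy, ix, dy, dx) where the grid point is k=(i - g//2)/g and
    delta = gridpoint - sample in cell units, |delta| <= 0.5.
    """
    u = coords * grid_size + grid_size // 2  # continuous index (ux, uy)
    idx = np.round(u).astype(int)
    delta = idx - u
    if np.any((idx < 0) | (idx >= grid_size)):
        raise ValueError("sample rounds outside the k-space grid")
    if np.any(np.abs(delta) > 0.5 + 1e-9):
        raise ValueError("GROG shift exceeds half a cell (bug guard)")
    return idx[:, 1], idx[:, 0], delta[:, 1], delta[:, 0]


def _fractional_shift_apply(
    kernels: GrogKernels, axis: str, deltas: np.ndarray, vecs: np.ndarray
) -> np.ndarray:
    """Apply G_axis^delta_j to column j of vecs, exactly, via eigensystem.

    vecs is (nc, ns); deltas is (ns,).  G^d = V diag(w^d) V^-1 with
    per-sample eigenvalue powers, fully vectorized.
    """
    w, v, vinv = kernels._eigensystem(axis)
    t = vinv @ vecs  # (nc, ns) in eigenbasis
    powers = np.power(w[:, None].astype(np.complex128), deltas[None, :])
    return v @ (powers * t)


def grog_grid(
    ksp: SpiralKSpace, kernels: GrogKernels, grid_size: int
) -> GriddedKSpace:
    """Shift every non-Cartesian sample to its nearest grid cell via GROG.

    Each sample's coil vector is multiplied by Gx^dx Gy^dy (fractional cell
    offsets, |delta| <= 0.5) and accumulated; multiple hits on a cell are
    averaged and the occupancy defines the sampling mask.
    """
    nc = ksp.n_coils
    if nc != kernels.n_coils:
        raise ValueError("coil count mismatch between data and kernels")
    g = grid_size
    nf = ksp.n_frames
    data = np.zeros((nf, nc, g, g), dtype=np.complex128)
    weight = np.zeros((nf, g, g))

    for f in range(nf):
        iy, ix, dy, dx = nearest_cell(ksp.coords[f], g)
        vecs = ksp.samples[f]  # (nc, ns)
        shifted = _fractional_shift_apply(kernels, "x", dx, vecs)
        shifted = _fractional_shift_apply(kernels, "y", dy, shifted)
        np.add.at(data[f], (slice(None), iy, ix), shifted)
        np.add.at(weight[f], (iy, ix), 1.0)

    hit = weight > 0
    data[:, :, :, :] = np.where(hit[:, None], data / np.maximum(weight[:, None], 1), 0)
    return GriddedKSpace(data=data, mask=hit.astype(np.uint8), weight=weight)


def masks_from_schedule(
    traj, schedule: list, grid_size: int
) -> SamplingMask:
    """Occupancy masks implied by rounding scheduled arm coordinates."""
    masks = np.zeros((len(schedule), grid_size, grid_size), dtype=np.uint8)
    for f, arms in enumerate(schedule):
        coords = traj.arm_coords[np.asarray(arms)].reshape(-1, 2)
        iy, ix, _, _ = nearest_cell(coords, grid_size)
        masks[f, iy, ix] = 1
    return SamplingMask(mask=masks)


# ----------------------------------------------------------------------------
# coil maps and combination
# ----------------------------------------------------------------------------


def _centered_ifft2(k: np.ndarray) -> np.ndarray:
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def estimate_coil_maps(
    avg_ksp: np.ndarray,
    calib_size: int = 24,
    kernel_size: int = 6,
    subspace_threshold: float = 0.02,
    eig_threshold: float = 0.9,
) -> CoilMaps:
    """ESPIRiT-style coil-sensitivity estimation from averaged k-space.

    Builds the block-Hankel calibration matrix from the central
    ``calib_size`` square, keeps the dominant singular subspace, transforms
    the kernels to image space and returns the leading per-pixel eigenvector
    masked by an eigenvalue support threshold.  Maps satisfy RSS <= 1.
    """
    avg_ksp = np.asarray(avg_ksp, dtype=np.complex128)
    nc, g, _ = avg_ksp.shape
    c0 = g // 2 - calib_size // 2
    calib = avg_ksp[:, c0 : c0 + calib_size, c0 : c0 + calib_size]
    if np.any(np.all(calib == 0, axis=0)):
        raise ValueError("calibration region contains empty cells")

    k = kernel_size
    nblk = calib_size - k + 1
    # block-Hankel: rows are sliding k x k x nc patches
    Amat = np.empty((nblk * nblk, k * k * nc), dtype=np.complex128)
    r = 0
    for i in range(nblk):
        for j in range(nblk):
            Amat[r] = calib[:, i : i + k, j : j + k].reshape(-1)
            r += 1
    _, s, vh = np.linalg.svd(Amat, full_matrices=False)
    nkeep = int(np.sum(s >= subspace_threshold * s[0]))
    nkeep = max(nkeep, 1)
    # rows of vh are the conjugated null/parallel-space kernels in the
    # orientation the image-domain transform needs directly
    kernels = vh[:nkeep].reshape(nkeep, nc, k, k)

    # image-space kernels: zero-pad centrally, inverse FFT; scaling chosen
    # so support eigenvalues are ~1
    pad = np.zeros((nkeep, nc, g, g), dtype=np.complex128)
    p0 = g // 2 - k // 2
    pad[:, :, p0 : p0 + k, p0 : p0 + k] = kernels
    imgk = _centered_ifft2(pad) * (g / k)

    # per-pixel leading eigenvector of G^H G with G = imgk[:, :, y, x]
    Gpix = imgk.transpose(2, 3, 0, 1).reshape(g * g, nkeep, nc)
    GhG = np.einsum("pkc,pkd->pcd", Gpix.conj(), Gpix)
    w, v = np.linalg.eigh(GhG)
    lead = v[:, :, -1]
    lam = w[:, -1].real
    maps = lead.reshape(g, g, nc).transpose(2, 0, 1).conj()
    support = (lam >= eig_threshold).reshape(g, g)
    maps = maps * support[None]
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps = np.where(rss[None] > 0, maps / np.maximum(rss[None], 1e-12), 0)
    return CoilMaps(maps, calibration_origin="estimated")


def coil_combine(coil_images: np.ndarray, maps: CoilMaps) -> CineImage:
    """SENSE-style combination x = sum_c conj(S_c) x_c / max(RSS^2, eps)."""
    coil_images = np.asarray(coil_images, dtype=np.complex128)
    if coil_images.ndim == 3:
        coil_images = coil_images[None]
    if coil_images.shape[1] != maps.n_coils:
        raise ValueError("coil count mismatch")
    rss2 = np.sum(np.abs(maps.data) ** 2, axis=0)
    floor = EPS_FLOOR_FRACTION * max(rss2.max(), 1e-300)
    num = np.sum(maps.data.conj()[None] * coil_images, axis=1)
    return CineImage(num / np.maximum(rss2, floor)[None])
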