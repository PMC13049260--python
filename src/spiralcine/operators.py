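"""The Cartesian measurement operator A = M F S, its adjoint, crop
embedding/extraction and the temporal-average reconstruction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spiralcine.synthetic import CineImage, CoilMaps
from spiralcine.gridding import GriddedKSpace, SamplingMask, coil_combine


def centered_fft2(img: np.ndarray) -> np.ndarray:
    """Unitary centered 2D FFT over the last two axes."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def centered_ifft2(k: np.ndarray) -> np.ndarray:
    """Unitary centered 2D inverse FFT over the last two axes."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


@dataclass
class MeasurementOperator:
    """A = M F S on the full Cartesian grid, with crop bookkeeping.

    ``periphery`` is the frame-constant full-FOV complex image used to fill
    the region outside the central model crop before data consistency.
    """

    maps: CoilMaps
    mask: SamplingMask
    grid_size: int
    crop_size: int
    periphery: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.maps.data.shape[-1] != self.grid_size:
            raise ValueError("coil maps do not match grid_size")
        if self.mask.mask.shape[-1] != self.grid_size:
            raise ValueError("mask does not match grid_size")
        if self.crop_size > self.grid_size:
            raise ValueError("crop_size must not exceed grid_size")

    @property
    def n_frames(self) -> int:
        return self.mask.mask.shape[0]

    @property
    def n_coils(self) -> int:
        return self.maps.n_coils

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, frames: slice | None = None) -> np.ndarray:
        """Apply M F S to x of shape (n_frames, g, g); returns (F, C, g, g)."""
        x = np.asarray(x)
        m = self.mask.mask if frames is None else self.mask.mask[frames]
        if x.shape[0] != m.shape[0] or x.shape[-1] != self.grid_size:
            raise ValueError("shape mismatch in forward")
        coil = self.maps.data[None] * x[:, None]
        return m[:, None] * centered_fft2(coil)

    def adjoint(self, y: np.ndarray, frames: slice | None = None) -> np.ndarray:
        """Apply S^H F^-1 M to y of shape (F, C, g, g); returns (F, g, g)."""
        y = np.asarray(y)
        m = self.mask.mask if frames is None else self.mask.mask[frames]
        if y.shape[0] != m.shape[0] or y.shape[-1] != self.grid_size:
            raise ValueError("shape mismatch in adjoint")
        img = centered_ifft2(m[:, None] * y)
        return np.sum(self.maps.data.conj()[None] * img, axis=1)


def forward(A: MeasurementOperator, x: CineImage) -> GriddedKSpace:
    """Noiseless application of the forward model to a cine series."""
    y = A.forward(x.data)
    return GriddedKSpace(data=y, mask=A.mask.mask.astype(np.uint8))


def adjoint(A: MeasurementOperator, y: GriddedKSpace | np.ndarray) -> CineImage:
    data = y.data if isinstance(y, GriddedKSpace) else np.asarray(y)
    return CineImage(A.adjoint(data))


# ----------------------------------------------------------------------------
# crop embedding
# ----------------------------------------------------------------------------


def crop_bounds(grid_size: int, crop_size: int) -> tuple:
    lo = (grid_size - crop_size) // 2
    return lo, lo + crop_size


def extract_crop(x_full: np.ndarray, crop_size: int) -> np.ndarray:
    """Centered crop over the last two axes."""
    g = x_full.shape[-1]
    lo, hi = crop_bounds(g, crop_size)
    return x_full[..., lo:hi, lo:hi]


def embed_crop(x_crop: np.ndarray, periphery: np.ndarray) -> np.ndarray:
    """Place the crop at the center of the frozen periphery image.

    ``periphery`` is (g, g) or (n_frames, g, g); ``x_crop`` is
    (n_frames, c, c).  ``extract_crop`` is the exact left inverse.
    """
    x_crop = np.asarray(x_crop)
    periphery = np.asarray(periphery)
    g = periphery.shape[-1]
    c = x_crop.shape[-1]
    if c > g:
        raise ValueError("crop larger than grid")
    nf = x_crop.shape[0]
    if periphery.ndim == 2:
        full = np.broadcast_to(periphery, (nf, g, g)).copy()
    else:
        full = periphery.copy()
    lo, hi = crop_bounds(g, c)
    full[..., lo:hi, lo:hi] = x_crop
    return full


# ----------------------------------------------------------------------------
# temporal average
# ----------------------------------------------------------------------------


def temporal_average_kspace(y: GriddedKSpace) -> tuple:
    """Cellwise mean of sampled k-space cells across frames + union mask."""
    msum = y.mask.sum(axis=0)
    union = (msum > 0).astype(np.uint8)
    avg = y.data.sum(axis=0) / np.maximum(msum, 1)[None]
    avg *= union[None]
    return avg, union


def temporal_average_recon(y: GriddedKSpace, A: MeasurementOperator) -> CineImage:
    """Static coil-combined image from frame-averaged k-space, replicated.

    Cells never sampled in any frame stay zero.
    """
    if y.n_frames < 1:
        raise ValueError("need at least one frame")
    avg, _ = temporal_average_kspace(y)
    imgs = centered_ifft2(avg)  # (nc, g, g)
    combined = coil_combine(imgs[None], A.maps).data[0]
    rep = np.broadcast_to(combined, (y.n_frames,) + combined.shape).copy()
    return CineImage(rep)
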