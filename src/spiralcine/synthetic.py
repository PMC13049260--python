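"""Seeded dynamic cardiac phantom, coil sensitivities and normalization.

The phantom is a hard-edged shape family (contracting myocardial annulus,
blood pool, chest-wall ellipses, rotating papillary features) confined to a
central crop of the full field of view, with a static low-amplitude
background elsewhere.  Hard edges keep the annulus-area oracle exact to a
pixel-boundary tolerance and provide sharp structures for sharpness
assessment downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

# nominal shape intensities (magnitude); chosen distinct so tests can
# identify structures by value
MYO_INTENSITY = 0.55
BLOOD_INTENSITY = 1.0
PAPILLARY_INTENSITY = 0.25
CHEST_INTENSITY = 0.35
BACKGROUND_INTENSITY = 0.08


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic cine generator.

    All lengths are in pixels of the full field of view; the anatomy is
    confined to the central ``crop_size`` square.
    """

    grid_size: int = 512
    crop_size: int = 304
    n_frames_per_cycle: int = 20
    n_cycles: int = 1
    contraction_amplitude: float = 0.3
    rr_jitter: float = 0.0
    breathing_amplitude: float = 0.0
    n_coils: int = 24
    noise_sigma: float = 0.0
    edge_smoothing: float = 1.0  # Gaussian sigma (px) keeping shapes band-limited
    seed: int = 0
    frame_duration: float = 13 * 48e-3 / 13  # 13 arms x TR(=48/13 ms) = 48 ms

    def validate(self) -> None:
        if self.crop_size > self.grid_size:
            raise ValueError("crop_size must not exceed grid_size")
        if not (2 <= self.n_frames_per_cycle <= 1000):
            raise ValueError("n_frames_per_cycle outside [2, 1000]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not (0 <= self.contraction_amplitude < 1):
            raise ValueError("contraction_amplitude must be in [0, 1)")
        for name in ("rr_jitter", "breathing_amplitude", "noise_sigma", "edge_smoothing"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")


@dataclass
class CineImage:
    """Complex dynamic image series of shape (n_frames, n, m)."""

    data: np.ndarray
    frame_duration: float = 48e-3
    norm_scale: float = 1.0
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CineImage.data must have shape (n_frames, n, m)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CineImage.data contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "CineImage":
        return CineImage(
            self.data.copy(),
            frame_duration=self.frame_duration,
            norm_scale=self.norm_scale,
            is_normalized=self.is_normalized,
        )


@dataclass
class CoilMaps:
    """Complex coil sensitivities of shape (n_coils, n, m)."""

    data: np.ndarray
    calibration_origin: str = "ground_truth"  # or "estimated"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CoilMaps.data must have shape (n_coils, n, m)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CoilMaps.data contains non-finite values")
        if self.calibration_origin not in ("ground_truth", "estimated"):
            raise ValueError("calibration_origin must be ground_truth|estimated")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.data) ** 2, axis=0))


# ----------------------------------------------------------------------------
# phantom geometry
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class _Geometry:
    """Analytic geometry of one phantom realization (crop-relative units)."""

    outer_radius: float
    inner_radius_rest: float
    papillary_radius: float
    papillary_orbit: float
    chest_axes: tuple
    chest_center: tuple


def _geometry(config: PhantomConfig) -> _Geometry:
    c = config.crop_size
    return _Geometry(
        outer_radius=0.22 * c,
        inner_radius_rest=0.14 * c,
        papillary_radius=0.02 * c,
        papillary_orbit=0.08 * c,
        chest_axes=(0.42 * c, 0.38 * c),
        chest_center=(0.0, 0.0),
    )


def cycle_phase(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Cardiac phase in [0,1) per frame, with per-cycle lognormal RR jitter."""
    n_total = config.n_frames_per_cycle * config.n_cycles
    if config.rr_jitter > 0:
        periods = config.n_frames_per_cycle * rng.lognormal(
            mean=0.0, sigma=config.rr_jitter, size=config.n_cycles + 1
        )
    else:
        periods = np.full(config.n_cycles + 1, float(config.n_frames_per_cycle))
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n_total, dtype=float)
    phase = np.empty(n_total)
    for i, ti in enumerate(t):
        j = int(np.searchsorted(boundaries, ti, side="right")) - 1
        j = min(j, len(periods) - 1)
        phase[i] = (ti - boundaries[j]) / periods[j]
    return phase % 1.0


def contraction_curve(phase: np.ndarray, amplitude: float) -> np.ndarray:
    """Fractional inner-radius reduction over the cycle (0 at phase 0)."""
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def inner_radius(config: PhantomConfig, phase: np.ndarray) -> np.ndarray:
    """Analytic inner radius of the myocardial annulus per frame (pixels)."""
    geo = _geometry(config)
    return geo.inner_radius_rest * (
        1.0 - contraction_curve(np.asarray(phase, float), config.contraction_amplitude)
    )


def annulus_radii(config: PhantomConfig, phase: np.ndarray) -> tuple:
    """(inner, outer) myocardial annulus radii in pixels for given phases."""
    geo = _geometry(config)
    r_in = inner_radius(config, phase)
    return r_in, np.full_like(np.asarray(r_in, float), geo.outer_radius)


def _substreams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_phantom(config: PhantomConfig) -> CineImage:
    """Generate a complex dynamic cardiac phantom.

    Dynamic content (annulus contraction, papillary rotation, breathing
    translation) stays inside the central ``crop_size`` window; the
    background outside the crop is static.
    """
    config.validate()
    rng_rr, rng_phase, _ = _substreams(config.seed, 3)
    g, c = config.grid_size, config.crop_size
    geo = _geometry(config)
    phase = cycle_phase(config, rng_rr)
    n_total = phase.size

    yy, xx = np.meshgrid(
        np.arange(g) - g / 2.0, np.arange(g) - g / 2.0, indexing="ij"
    )

    # static background over the full FOV (faint smooth blob), frame-constant
    bg = BACKGROUND_INTENSITY * np.exp(-((xx / (0.45 * g)) ** 2 + (yy / (0.5 * g)) ** 2))

    # smooth static low-order spatial phase so complex handling is exercised
    a = rng_phase.uniform(-1.0, 1.0, size=4)
    phi = 0.5 * (a[0] + a[1] * xx / g + a[2] * yy / g + a[3] * xx * yy / g**2)
    phase_map = np.exp(1j * phi)

    r_in = inner_radius(config, phase)
    r_out = geo.outer_radius

    # breathing translation; bounded so anatomy stays within the crop
    max_extent = max(geo.chest_axes) + config.breathing_amplitude
    if max_extent >= c / 2.0 - 1:
        raise ValueError("breathing_amplitude pushes anatomy outside the crop")
    t = np.arange(n_total, dtype=float)
    breath_period = 5.0 * config.n_frames_per_cycle  # breathing slower than the heart
    dy = config.breathing_amplitude * np.sin(2 * np.pi * t / breath_period)
    dx = 0.4 * config.breathing_amplitude * np.sin(2 * np.pi * t / breath_period + 0.7)

    frames = np.empty((n_total, g, g), dtype=np.complex128)
    n_pap = 3
    for f in range(n_total):
        cy, cx = dy[f], dx[f]
        ry, rx = yy - cy, xx - cx
        rho2 = rx**2 + ry**2

        img = bg.copy()
        # chest-wall ellipse ring (static shape, translated by breathing only)
        ex, ey = geo.chest_axes
        ell = (rx / ex) ** 2 + (ry / ey) ** 2
        img[(ell <= 1.0) & (ell >= 0.82)] = CHEST_INTENSITY

        # blood pool then annulus (annulus drawn last between r_in and r_out)
        img[rho2 <= r_in[f] ** 2] = BLOOD_INTENSITY
        ring = (rho2 >= r_in[f] ** 2) & (rho2 <= r_out**2)
        img[ring] = MYO_INTENSITY

        # papillary features orbiting inside the blood pool; motion is tied
        # to cardiac contraction so zero-amplitude configs are fully static
        theta0 = 2 * np.pi * phase[f] if config.contraction_amplitude > 0 else 0.0
        orbit = min(geo.papillary_orbit, max(r_in[f] - geo.papillary_radius - 1, 0.0))
        for p in range(n_pap):
            ang = theta0 + 2 * np.pi * p / n_pap
            py = cy + orbit * np.sin(ang)
            px = cx + orbit * np.cos(ang)
            pap = (xx - px) ** 2 + (yy - py) ** 2 <= geo.papillary_radius**2
            img[pap] = PAPILLARY_INTENSITY

        if config.edge_smoothing > 0:
            # slight band-limiting so the spiral Nyquist disc carries
            # essentially all signal energy (edges stay ~1 px sharp)
            img = gaussian_filter(img, config.edge_smoothing, mode="nearest")
        frames[f] = img * phase_map

    # enforce exact confinement of dynamic content: outside the central crop
    # every frame equals the static frame-0 periphery
    lo = (g - c) // 2
    hi = lo + c
    outside = np.ones((g, g), dtype=bool)
    outside[lo:hi, lo:hi] = False
    frames[:, outside] = frames[0, outside]

    return CineImage(frames, frame_duration=config.frame_duration)


def generate_coil_maps(config: PhantomConfig, mode: str = "ring") -> CoilMaps:
    """Generate smooth complex coil sensitivity maps.

    ``mode='ring'`` places Gaussian-falloff coils on a circle around the FOV
    with a smooth low-order complex phase; ``mode='uniform'`` returns
    all-ones maps (useful for single-coil tests).
    """
    config.validate()
    if mode not in ("ring", "uniform"):
        raise ValueError("mode must be 'ring' or 'uniform'")
    g, nc = config.grid_size, config.n_coils
    if mode == "uniform":
        return CoilMaps(np.ones((nc, g, g), dtype=np.complex128))

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    yy, xx = np.meshgrid(
        np.arange(g) - g / 2.0, np.arange(g) - g / 2.0, indexing="ij"
    )
    radius = 0.55 * g
    width = 0.6 * g
    maps = np.empty((nc, g, g), dtype=np.complex128)
    angles = 2 * np.pi * np.arange(nc) / nc + rng.uniform(0, 2 * np.pi)
    for c in range(nc):
        cy = radius * np.sin(angles[c])
        cx = radius * np.cos(angles[c])
        mag = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2)))
        b = rng.uniform(-1, 1, size=3)
        ph = b[0] + 2.0 * (b[1] * (xx - cx) + b[2] * (yy - cy)) / g
        maps[c] = mag * np.exp(1j * ph)
    # scale so RSS is O(1) without flattening the spatial profile
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss.max()
    return CoilMaps(maps, calibration_origin="ground_truth")


def normalize_series(x: CineImage) -> CineImage:
    """Divide the series by the maximum magnitude; records the divisor."""
    scale = float(np.max(np.abs(x.data)))
    if scale <= 0:
        raise ValueError("cannot normalize an all-zero series")
    out = x.copy()
    out.data = x.data / scale
    out.norm_scale = scale * x.norm_scale
    out.is_normalized = True
    return out


def denormalize_series(x: CineImage) -> CineImage:
    """Invert :func:`normalize_series` exactly."""
    out = x.copy()
    out.data = x.data * x.norm_scale
    out.norm_scale = 1.0
    out.is_normalized = False
    return out
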