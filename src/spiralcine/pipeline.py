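"""Desk-scale synthetic experiment orchestration.

Wires the full chain — phantom, spiral acquisition, GROG, gating/binning,
prior training, DPS and baseline reconstruction, metrics — at configurable
(small) sizes.  Used by the CLI, the acceptance tests and the acceptance
script so they all run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spiralcine import gridding
from spiralcine.baselines import recon_zero_filled
from spiralcine.dps import DPSConfig, reconstruct
from spiralcine.gridding import (
    GriddedKSpace,
    GrogKernels,
    SamplingMask,
    calibrate_grog,
    coil_combine,
    grog_grid,
)
from spiralcine.operators import (
    MeasurementOperator,
    centered_ifft2,
    temporal_average_recon,
)
from spiralcine.prior import ScoreModelConfig, TrainResult, clip_stream, train
from spiralcine.spiral import (
    SpiralKSpace,
    SpiralTrajectory,
    bin_segmented_cine,
    dc_gate,
    frame_arm_schedule,
    make_spiral_trajectory,
    sample_kspace,
    thin_arm_schedule,
)
from spiralcine.synthetic import CineImage, CoilMaps, PhantomConfig, generate_coil_maps, generate_phantom


@dataclass(frozen=True)
class ExperimentConfig:
    """Scaled-down analog of the acquisition/reconstruction study."""

    grid_size: int = 96
    crop_size: int = 64
    n_frames_per_cycle: int = 6
    n_cycles: int = 1
    n_coils: int = 6
    noise_sigma: float = 2e-4
    contraction_amplitude: float = 0.35
    n_arms_full: int = 104
    n_arms_frame: int = 13
    rotation_states: int = 8
    rotation_period_frames: int = 1
    samples_per_arm: int | None = None
    seed: int = 0

    def phantom_config(self, **overrides) -> PhantomConfig:
        kw = dict(
            grid_size=self.grid_size,
            crop_size=self.crop_size,
            n_frames_per_cycle=self.n_frames_per_cycle,
            n_cycles=self.n_cycles,
            contraction_amplitude=self.contraction_amplitude,
            n_coils=self.n_coils,
            noise_sigma=self.noise_sigma,
            seed=self.seed,
        )
        kw.update(overrides)
        return PhantomConfig(**kw)


@dataclass
class World:
    """One simulated subject: ground truth, coils, trajectory."""

    config: ExperimentConfig
    phantom: CineImage
    maps: CoilMaps
    traj: SpiralTrajectory


def build_world(cfg: ExperimentConfig, **phantom_overrides) -> World:
    pcfg = cfg.phantom_config(**phantom_overrides)
    phantom = generate_phantom(pcfg)
    maps = generate_coil_maps(pcfg)
    traj = make_spiral_trajectory(
        n_arms_full=cfg.n_arms_full,
        samples_per_arm=cfg.samples_per_arm,
        grid_size=cfg.grid_size,
        n_arms_frame=cfg.n_arms_frame,
        rotation_states=cfg.rotation_states,
        rotation_period_frames=cfg.rotation_period_frames,
    )
    return World(config=cfg, phantom=phantom, maps=maps, traj=traj)


# ----------------------------------------------------------------------------
# acquisition + gridding
# ----------------------------------------------------------------------------


def nn_grid_average(ksp: SpiralKSpace, grid_size: int) -> tuple:
    """Temporally-averaged nearest-neighbor (convolution) gridded estimate.

    Used as the GROG calibration source: all frames' samples are deposited
    on their nearest cells without coil-mixing and averaged.
    """
    nc = ksp.n_coils
    acc = np.zeros((nc, grid_size, grid_size), dtype=np.complex128)
    cnt = np.zeros((grid_size, grid_size))
    for f in range(ksp.n_frames):
        iy, ix, _, _ = gridding.nearest_cell(ksp.coords[f], grid_size)
        np.add.at(acc, (slice(None), iy, ix), ksp.samples[f])
        np.add.at(cnt, (iy, ix), 1.0)
    filled = cnt > 0
    acc = np.where(filled[None], acc / np.maximum(cnt[None], 1), 0)
    return acc, filled


def acquire(
    world: World, n_frames: int, seed_offset: int = 0, thin: int | None = None
) -> tuple:
    """Sample spiral k-space for the first ``n_frames`` phantom frames.

    ``thin`` keeps every ``thin``-th arm of each frame (2 -> the 7-arm
    variant).  Returns (SpiralKSpace, schedule).
    """
    cfg = world.config
    schedule = frame_arm_schedule(world.traj, n_frames)
    if thin is not None:
        schedule = thin_arm_schedule(schedule, thin)
    cine = CineImage(
        world.phantom.data[:n_frames], frame_duration=world.phantom.frame_duration
    )
    ksp = sample_kspace(
        cine,
        world.maps,
        world.traj,
        schedule,
        noise_sigma=cfg.noise_sigma,
        seed=cfg.seed + 101 + seed_offset,
    )
    return ksp, schedule


def grog_calibrate(world: World, ksp: SpiralKSpace) -> GrogKernels:
    calib, filled = nn_grid_average(ksp, world.config.grid_size)
    return calibrate_grog(calib, filled, calib_source="temporal-average NN grid")


def grid_frames(world: World, ksp: SpiralKSpace, kernels: GrogKernels) -> GriddedKSpace:
    return grog_grid(ksp, kernels, world.config.grid_size)


def operator_for(world: World, gridded: GriddedKSpace) -> MeasurementOperator:
    return MeasurementOperator(
        maps=world.maps,
        mask=SamplingMask(mask=gridded.mask.astype(np.uint8)),
        grid_size=world.config.grid_size,
        crop_size=world.config.crop_size,
    )


# ----------------------------------------------------------------------------
# segmented cine
# ----------------------------------------------------------------------------


def segmented_reference(
    world_seg: World, kernels: GrogKernels | None = None
) -> dict:
    """Simulate a multi-cycle acquisition, gate, bin and grid it.

    The world must contain several cycles with
    rotation_period_frames == n_frames_per_cycle so every phase accumulates
    all rotation states.  Returns the binned gridded k-space, the per-phase
    ground-truth frame mapping and diagnostics.
    """
    cfg = world_seg.config
    n_frames = cfg.n_frames_per_cycle * cfg.n_cycles
    ksp, schedule = acquire(world_seg, n_frames)
    gating = dc_gate(
        ksp.dc_signal,
        n_phases=cfg.n_frames_per_cycle,
        arms_per_frame=cfg.n_arms_frame,
    )
    binned = bin_segmented_cine(ksp, gating)
    if kernels is None:
        kernels = grog_calibrate(world_seg, ksp)
    gridded = grid_frames(world_seg, binned, kernels)

    # map each phase to the dominant ground-truth cycle-frame it came from
    spa = cfg.n_arms_frame
    frame_of_arm = np.repeat(np.arange(n_frames), spa)
    phase_to_frame = np.zeros(cfg.n_frames_per_cycle, dtype=int)
    for p in range(cfg.n_frames_per_cycle):
        arms = np.where(gating.phase_assignment == p)[0]
        cyc_frames = frame_of_arm[arms] % cfg.n_frames_per_cycle
        vals, counts = np.unique(cyc_frames, return_counts=True)
        phase_to_frame[p] = int(vals[np.argmax(counts)])
    return {
        "kspace": ksp,
        "gating": gating,
        "binned": binned,
        "gridded": gridded,
        "kernels": kernels,
        "phase_to_frame": phase_to_frame,
    }


def segmented_recon(world: World, gridded: GriddedKSpace) -> CineImage:
    """Direct inverse-FFT + coil combination of fully binned k-space."""
    imgs = centered_ifft2(gridded.data * gridded.mask[:, None])
    return coil_combine(imgs, world.maps)


# ----------------------------------------------------------------------------
# prior training at desk scale
# ----------------------------------------------------------------------------


def training_set(
    cfg: ExperimentConfig, n_series: int = 8, base_seed: int = 1000
) -> list:
    """Ground-truth cine series with varied seeds and contraction amplitudes."""
    out = []
    rng = np.random.default_rng(base_seed)
    for i in range(n_series):
        amp = float(rng.uniform(0.2, 0.45))
        pcfg = cfg.phantom_config(
            seed=base_seed + i, contraction_amplitude=amp, n_cycles=1
        )
        out.append(generate_phantom(pcfg))
    return out


def train_desk_prior(
    cfg: ExperimentConfig,
    n_steps: int = 600,
    n_series: int = 8,
    base: int = 16,
    temporal: bool = True,
    dtype: str = "float32",
    seed: int = 0,
    lr: float = 1e-3,
    train_crop: int | None = None,
) -> TrainResult:
    """Train a tiny prior on phantom clips.

    ``train_crop`` (default half the reconstruction crop, min 32) keeps the
    per-step cost low; the fully convolutional network applies unchanged at
    the larger reconstruction crop.  The noise schedule is tied to the
    reconstruction crop so inference sees matched sigma levels.
    """
    if train_crop is None:
        train_crop = min(cfg.crop_size, max(32, cfg.crop_size // 2))
    model_cfg = ScoreModelConfig(
        base_channels=base,
        channel_multipliers=(1, 2),
        n_frames_train=cfg.n_frames_per_cycle,
        crop_size=train_crop,
        sigma_max=50.0 * cfg.crop_size / 304.0,
        temporal_layers=temporal,
        dtype=dtype,
    )
    cine_set = training_set(cfg, n_series=n_series, base_seed=1000 + seed)
    stream = clip_stream(cine_set, model_cfg, seed=seed)
    return train(model_cfg, stream, n_steps=n_steps, lr=lr, seed=seed)


# ----------------------------------------------------------------------------
# full reconstruction comparison
# ----------------------------------------------------------------------------


def realtime_experiment(
    cfg: ExperimentConfig,
    prior: TrainResult,
    n_frames: int | None = None,
    dps: DPSConfig | None = None,
    thin: int | None = None,
) -> dict:
    """Acquire real-time frames, reconstruct with DPS / zero-filled /
    temporal-average, and return everything needed for metric comparison."""
    world = build_world(cfg)
    nf = n_frames or cfg.n_frames_per_cycle * cfg.n_cycles
    ksp, schedule = acquire(world, nf, thin=thin)
    kernels = grog_calibrate(world, ksp)
    gridded = grid_frames(world, ksp, kernels)
    A = operator_for(world, gridded)

    model = prior.ema_model()
    sde = prior.config.sde()
    if dps is None:
        dps = DPSConfig(n_steps=40, t_start=0.4, zeta=1.0, blocks=nf, seed=cfg.seed)
    result_dps = reconstruct(gridded, A, model, sde, dps)
    result_zf = recon_zero_filled(gridded, A)
    avg = temporal_average_recon(gridded, A)
    return {
        "world": world,
        "kspace": ksp,
        "schedule": schedule,
        "gridded": gridded,
        "A": A,
        "dps": result_dps,
        "zero_filled": result_zf,
        "temporal_average": avg,
        "reference": CineImage(world.phantom.data[:nf]),
    }
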