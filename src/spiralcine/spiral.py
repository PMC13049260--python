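"""Spiral trajectories, the frame rotation scheme, non-Cartesian sampling
and DC self-gated retrospective binning into segmented cine."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from spiralcine.synthetic import CineImage, CoilMaps


@dataclass
class SpiralTrajectory:
    """Equiangular Archimedean spiral arms in cycles/FOV, |k| < 0.5.

    ``arm_coords[i]`` has shape (samples_per_arm, 2) ordered (kx, ky); arm i
    is the base arm rotated by 2*pi*i/n_arms_full.
    """

    arm_coords: np.ndarray  # (n_arms_full, samples_per_arm, 2)
    n_arms_full: int = 104
    n_arms_frame: int = 13
    rotation_period_frames: int = 10
    rotation_states: int = 8

    def __post_init__(self) -> None:
        if self.n_arms_full != self.n_arms_frame * self.rotation_states:
            raise ValueError("n_arms_full must equal n_arms_frame * rotation_states")
        if np.max(np.abs(self.arm_coords)) >= 0.5:
            raise ValueError("trajectory coordinates must satisfy |k| < 0.5")

    @property
    def samples_per_arm(self) -> int:
        return self.arm_coords.shape[1]


@dataclass
class SpiralKSpace:
    """Per-frame non-Cartesian multi-coil samples.

    ``samples[f]`` is (n_coils, ns_f) and ``coords[f]`` is (ns_f, 2); frames
    may hold different numbers of arms after retrospective binning, hence
    list storage.  ``arm_ids[f]`` records which trajectory arms contributed
    (one id per arm block of ``samples_per_arm`` samples).
    """

    samples: list
    coords: list
    arm_ids: list
    samples_per_arm: int
    dc_signal: np.ndarray = None  # complex, one value per acquired arm
    frame_duration: float = 48e-3

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.coords):
            raise ValueError("samples/coords frame count mismatch")
        for s, c in zip(self.samples, self.coords):
            if s.shape[1] != c.shape[0]:
                raise ValueError("samples/coords shape mismatch within a frame")
            if not (np.all(np.isfinite(s)) and np.all(np.isfinite(c))):
                raise ValueError("non-finite k-space data")

    @property
    def n_frames(self) -> int:
        return len(self.samples)

    @property
    def n_coils(self) -> int:
        return self.samples[0].shape[0]


@dataclass
class GatingResult:
    """Cycle triggers and cardiac-phase bin per acquired arm."""

    trigger_indices: np.ndarray
    phase_assignment: np.ndarray  # -1 for rejected arms
    n_phases: int
    rejected_arms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.trigger_indices)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("triggers must be strictly increasing")
        accepted = self.phase_assignment[self.phase_assignment >= 0]
        if accepted.size and accepted.max() >= self.n_phases:
            raise ValueError("phase assignment out of range")


# ----------------------------------------------------------------------------
# trajectory
# ----------------------------------------------------------------------------


def make_spiral_trajectory(
    n_arms_full: int = 104,
    samples_per_arm: int | None = None,
    grid_size: int = 512,
    n_arms_frame: int | None = None,
    rotation_states: int | None = None,
    rotation_period_frames: int = 10,
) -> SpiralTrajectory:
    """Uniform-pitch Archimedean arms meeting Nyquist at the grid edge.

    The base arm runs from k=0 to the edge with the number of turns chosen
    so that the interleaved set of ``n_arms_full`` arms has radial gaps of
    at most one grid cell (1/grid_size cycles/FOV).
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    if n_arms_full < 1:
        raise ValueError("n_arms_full must be >= 1")
    r_max = 0.5 - 1.0 / grid_size
    n_turns = max(1, int(np.ceil(r_max * grid_size / n_arms_full)))
    if samples_per_arm is None:
        # ~1.5 samples per traversed grid cell of arc length
        arc_cells = np.pi * n_turns * r_max * grid_size
        samples_per_arm = int(np.ceil(1.5 * arc_cells)) + 1
    if samples_per_arm < 2:
        raise ValueError("samples_per_arm must be >= 2")

    # equal-arc-length parametrization of the Archimedean curve
    # (ds^2 = dr^2 + r^2 dtheta^2): dense radially near the center, dense
    # azimuthally at the edge, so gridded occupancy has no density holes
    tf = np.linspace(0.0, 1.0, max(20 * samples_per_arm, 2000))
    rf = r_max * tf
    thf = 2 * np.pi * n_turns * tf
    seg = np.sqrt(np.diff(rf) ** 2 + (0.5 * (rf[1:] + rf[:-1]) * np.diff(thf)) ** 2)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arclen[-1], samples_per_arm)
    s = np.interp(targets, arclen, tf)
    radius = r_max * s
    theta = 2 * np.pi * n_turns * s
    offsets = 2 * np.pi * np.arange(n_arms_full) / n_arms_full
    ang = theta[None, :] + offsets[:, None]
    coords = np.stack(
        [radius[None, :] * np.cos(ang), radius[None, :] * np.sin(ang)], axis=-1
    )

    if rotation_states is None:
        for cand in (8, 4, 2, 1):
            if n_arms_full % cand == 0:
                rotation_states = cand
                break
    if n_arms_frame is None:
        n_arms_frame = n_arms_full // rotation_states
    return SpiralTrajectory(
        arm_coords=coords,
        n_arms_full=n_arms_full,
        n_arms_frame=n_arms_frame,
        rotation_period_frames=rotation_period_frames,
        rotation_states=rotation_states,
    )


def frame_arm_schedule(traj: SpiralTrajectory, n_frames: int) -> list:
    """Arm-index set per frame under the interleaved rotation scheme.

    Frame f uses arms {r(f) + k*rotation_states} with rotation state
    r(f) = floor(f / rotation_period_frames) mod rotation_states, so the
    union over all states is the full equidistant arm set and each frame's
    arms are equiangular with spacing 2*pi/n_arms_frame.
    """
    schedule = []
    for f in range(n_frames):
        r = (f // traj.rotation_period_frames) % traj.rotation_states
        arms = r + traj.rotation_states * np.arange(traj.n_arms_frame)
        schedule.append(arms)
    return schedule


def thin_arm_schedule(schedule: list, keep_every: int = 2) -> list:
    """Keep every ``keep_every``-th arm of each frame (7 of 13 for 2)."""
    return [np.asarray(arms)[::keep_every] for arms in schedule]


# ----------------------------------------------------------------------------
# non-Cartesian sampling
# ----------------------------------------------------------------------------


def ndft2(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Non-uniform DFT of a (possibly batched) image at coords (ns, 2).

    Matches the unitary centered DFT on grid frequencies: pixel coordinates
    are centered at the array midpoint and the result is scaled by 1/sqrt(N).
    Accepts image of shape (..., n, m); returns (..., ns).
    """
    n, m = image.shape[-2:]
    py = np.arange(n) - n // 2
    px = np.arange(m) - m // 2
    ky = coords[:, 1][:, None]
    kx = coords[:, 0][:, None]
    ey = np.exp(-2j * np.pi * ky * py[None, :])  # (ns, n)
    ex = np.exp(-2j * np.pi * kx * px[None, :])  # (ns, m)
    # sum_p x[y,x] ey[k,y] ex[k,x]  — contract x first, then y
    tmp = image @ ex.T  # (..., n, ns)
    out = np.einsum("...ns,sn->...s", tmp, ey)
    return out / np.sqrt(n * m)


def sample_kspace(
    x: CineImage,
    maps: CoilMaps,
    traj: SpiralTrajectory,
    schedule: list,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SpiralKSpace:
    """Simulate multi-coil spiral sampling of a cine series.

    Per frame and coil, evaluates the non-uniform Fourier transform of
    S_c * x_f at the scheduled arm coordinates and adds i.i.d. complex
    Gaussian noise.  The first sample of each arm (k=0) forms the DC
    navigator signal (coil average).
    """
    if x.data.shape[-2:] != maps.data.shape[-2:]:
        raise ValueError("image and coil map grids differ")
    if len(schedule) != x.n_frames:
        raise ValueError("schedule length must equal the number of frames")
    rng = np.random.default_rng(seed)
    nc = maps.n_coils
    spa = traj.samples_per_arm

    samples, coords_out, arm_ids, dc = [], [], [], []
    for f, arms in enumerate(schedule):
        arms = np.asarray(arms)
        coords = traj.arm_coords[arms].reshape(-1, 2)
        coil_imgs = maps.data * x.data[f][None]  # (nc, n, m)
        y = ndft2(coil_imgs, coords)  # (nc, ns)
        if noise_sigma > 0:
            y = y + noise_sigma * (
                rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
            )
        samples.append(y)
        coords_out.append(coords)
        arm_ids.append(arms)
        dc.append(y[:, ::spa].mean(axis=0))  # first sample of each arm
    return SpiralKSpace(
        samples=samples,
        coords=coords_out,
        arm_ids=arm_ids,
        samples_per_arm=spa,
        dc_signal=np.concatenate(dc),
        frame_duration=x.frame_duration,
    )


def dc_navigator_signal(
    config, arms_per_frame: int = 13, rng: np.random.Generator | None = None
) -> tuple:
    """Arm-rate DC navigator from the phantom's analytic cycle curve.

    The frame-snapshot simulation yields a navigator that is piecewise
    constant over the arms of one frame; this helper instead evaluates the
    total-signal surrogate at per-arm time resolution, returning the complex
    navigator and the ground-truth trigger arm indices (cycle starts).
    """
    from spiralcine.synthetic import cycle_phase, contraction_curve
    from dataclasses import replace

    if rng is None:
        rng = np.random.default_rng(config.seed + 9)
    fine = replace(config, n_frames_per_cycle=config.n_frames_per_cycle * arms_per_frame)
    phase = cycle_phase(fine, rng)
    # total image signal shrinks as the blood pool contracts
    dc = 1.0 - 0.35 * contraction_curve(phase, max(config.contraction_amplitude, 1e-3))
    wraps = np.where(np.diff(phase) < -0.5)[0] + 1
    triggers = np.concatenate([[0], wraps])
    return dc.astype(np.complex128), triggers


# ----------------------------------------------------------------------------
# DC gating and retrospective binning
# ----------------------------------------------------------------------------


def dc_gate(
    dc_signal: np.ndarray,
    n_phases: int,
    arms_per_frame: int = 13,
    detrend_window: int | None = None,
    min_cycle_arms: int | None = None,
) -> GatingResult:
    """Detect cardiac cycles from the DC navigator and bin arms by phase.

    The magnitude is detrended by a moving average and triggers are picked
    as prominent local maxima (prominence 0.5x interquartile range); each
    arm inside an RR interval gets a phase bin by linear position. Arms
    before the first or after the last trigger are rejected.
    """
    m = np.abs(np.asarray(dc_signal, dtype=np.complex128))
    n = m.size
    if detrend_window is None:
        # match the detrend window to the dominant period (autocorrelation)
        z = m - m.mean()
        ac = np.correlate(z, z, mode="full")[n - 1 :]
        lo = max(2, arms_per_frame)
        hi = max(lo + 2, n // 2)
        seg = ac[lo:hi]
        ac_peaks, _ = find_peaks(seg)
        if ac_peaks.size:
            period = lo + int(ac_peaks[np.argmax(seg[ac_peaks])])
        else:
            period = lo + int(np.argmax(seg))
        detrend_window = max(5, period) | 1
    kernel = np.ones(detrend_window) / detrend_window
    trend = np.convolve(np.pad(m, detrend_window // 2, mode="edge"), kernel, "valid")[:n]
    d = m - trend
    # short symmetric smoothing disambiguates plateaued (frame-constant) peaks
    sw = max(3, arms_per_frame) | 1
    d = np.convolve(np.pad(d, sw // 2, mode="edge"), np.ones(sw) / sw, "valid")[:n]
    q75, q25 = np.percentile(d, [75, 25])
    prominence = 0.5 * (q75 - q25)
    if min_cycle_arms is None:
        min_cycle_arms = max(2, int(0.6 * (detrend_window - 1)) or 2)
    peaks, _ = find_peaks(d, prominence=prominence, distance=min_cycle_arms)
    if peaks.size < 2:
        raise ValueError("cannot gate: fewer than 2 triggers detected")

    phase = np.full(n, -1, dtype=int)
    for t0, t1 in zip(peaks[:-1], peaks[1:]):
        idx = np.arange(t0, t1)
        phase[idx] = np.minimum(
            (n_phases * (idx - t0)) // (t1 - t0), n_phases - 1
        )
    rejected = np.where(phase < 0)[0]
    return GatingResult(
        trigger_indices=peaks,
        phase_assignment=phase,
        n_phases=n_phases,
        rejected_arms=rejected,
    )


def bin_segmented_cine(ksp: SpiralKSpace, gating: GatingResult) -> SpiralKSpace:
    """Regroup acquired arms into one frame per cardiac phase.

    Arms assigned to the same phase across cycles are unioned; repeated
    acquisitions of the same trajectory arm within a phase are averaged.
    """
    spa = ksp.samples_per_arm
    nc = ksp.n_coils
    # flatten acquisition order: global arm index g -> (frame, slot)
    frame_of, slot_of = [], []
    for f, arms in enumerate(ksp.arm_ids):
        frame_of.extend([f] * len(arms))
        slot_of.extend(range(len(arms)))
    n_arms_total = len(frame_of)
    if gating.phase_assignment.size != n_arms_total:
        raise ValueError("gating covers a different number of arms than acquired")

    samples, coords, arm_ids = [], [], []
    for p in range(gating.n_phases):
        acc: dict = {}
        for g_idx in np.where(gating.phase_assignment == p)[0]:
            f, a = frame_of[g_idx], slot_of[g_idx]
            arm_id = int(ksp.arm_ids[f][a])
            sl = slice(a * spa, (a + 1) * spa)
            entry = acc.setdefault(
                arm_id, [np.zeros((nc, spa), np.complex128), ksp.coords[f][sl], 0]
            )
            entry[0] += ksp.samples[f][:, sl]
            entry[2] += 1
        if not acc:
            raise ValueError(f"empty phase bin {p}: no arms assigned")
        ids = sorted(acc)
        samples.append(np.concatenate([acc[i][0] / acc[i][2] for i in ids], axis=1))
        coords.append(np.concatenate([acc[i][1] for i in ids], axis=0))
        arm_ids.append(np.asarray(ids))
    return SpiralKSpace(
        samples=samples,
        coords=coords,
        arm_ids=arm_ids,
        samples_per_arm=spa,
        dc_signal=None,
        frame_duration=ksp.frame_duration,
    )
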