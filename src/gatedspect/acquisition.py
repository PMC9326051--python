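"""Continuous-rotation dual-head acquisition simulation.

A dual-head camera (heads opposed at 180 degrees, H-mode) rotates slowly and
continuously: every 0.125 s each head advances 0.5 degrees and records one
binned projection frame, so one rotation takes 90 s (720 frames per head)
and four rotations cover the 6 min study.  Each frame is tagged with the
cardiac gate (8 per 1 s heartbeat) and respiratory gate (5 per 5 s breath)
of its start time.

Photon transport is not simulated.  Scatter is emulated: a broad Gaussian
share of the primary projection is added to the main energy window
(126-154 keV) and the same contribution, divided by the dual-energy-window
(DEW) multiplier k = 0.5, forms the scatter window (100-125 keV), so the
standard DEW estimate  main - k * scatter  returns the primary in
expectation.  Poisson noise is drawn per bin per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .kinetics import TissueTACSet
from .phantom import AIR, BACKGROUND, BLOOD, LIVER, LUNG, MYOCARDIUM, PhantomState
from .projector import FWHM_TO_SIGMA, BlurModel, ParallelProjector

N_CARDIAC_GATES = 8
N_RESP_GATES = 5


@dataclass(frozen=True)
class DetectorModel:
    """Camera geometry, response and emulation parameters."""

    hole_diameter: float = 1.5       # mm
    hole_length: float = 35.0        # mm
    septal_thickness: float = 0.2    # mm (unused: septal penetration ignored)
    intrinsic_fwhm: float = 2.5      # mm
    radius_of_rotation: float = 320.0  # mm
    bin_size: float = 4.4            # mm
    n_bins: tuple[int, int] = (64, 64)
    main_window_kev: tuple[float, float] = (126.0, 154.0)
    scatter_window_kev: tuple[float, float] = (100.0, 125.0)
    dew_k: float = 0.5
    scatter_fraction: float = 0.3
    scatter_kernel_fwhm: float = 40.0  # mm
    #: counts per (mCi/ml * mm * s); calibrated once so that the reference
    #: case's last-minute main-window total is about 2.1e6 on the desk grid.
    sensitivity_scale: float = 1.0
    n_blur_groups: int = 6

    def __post_init__(self):
        if min(self.hole_diameter, self.hole_length, self.radius_of_rotation) <= 0:
            raise ValueError("collimator geometry must be positive")
        if not 0 < self.dew_k <= 1:
            raise ValueError("dew_k must lie in (0, 1]")
        if not 0 <= self.scatter_fraction < 1:
            raise ValueError("scatter_fraction must lie in [0, 1)")

    def blur_model(self) -> BlurModel:
        return BlurModel(
            self.intrinsic_fwhm, self.hole_diameter, self.hole_length, self.radius_of_rotation
        )


@dataclass
class AcquisitionSchedule:
    """Frame times, head angles and gate tags of a continuous acquisition."""

    dt: float
    dtheta: float
    n_rotations: int
    n_heads: int
    t_start: np.ndarray       # (n_frames,)
    head_angles: np.ndarray   # (n_frames, n_heads) degrees
    cardiac_gate: np.ndarray  # (n_frames,)
    resp_gate: np.ndarray     # (n_frames,)

    @property
    def n_frames(self) -> int:
        return self.t_start.size

    @property
    def frames_per_rotation(self) -> int:
        return int(round(360.0 / self.dtheta))

    @property
    def rotation_period(self) -> float:
        return self.frames_per_rotation * self.dt

    @property
    def total_duration(self) -> float:
        return self.n_rotations * self.rotation_period


@dataclass
class AcquisitionFrame:
    """One binned projection view of one head in one energy window."""

    counts: np.ndarray
    window: str          # "main" | "scatter" | "corrected"
    head: int            # 1-based
    frame_index: int
    angle: float         # degrees
    t_start: float
    cardiac_gate: int
    resp_gate: int

    @property
    def gate(self) -> tuple[int, int]:
        return (self.cardiac_gate, self.resp_gate)


def gate_of_time(
    t: float | np.ndarray,
    cardiac_period: float = 1.0,
    resp_period: float = 5.0,
    n_cardiac: int = N_CARDIAC_GATES,
    n_resp: int = N_RESP_GATES,
):
    """Cardiac/respiratory gate of time ``t`` (left-closed sub-intervals)."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    q = np.floor((t % cardiac_period) / (cardiac_period / n_cardiac)).astype(int) + 1
    r = np.floor((t % resp_period) / (resp_period / n_resp)).astype(int) + 1
    q = np.minimum(q, n_cardiac)
    r = np.minimum(r, n_resp)
    if q.ndim == 0:
        return int(q), int(r)
    return q, r


def build_schedule(
    dt: float = 0.125,
    dtheta: float = 0.5,
    n_rotations: int = 4,
    cardiac_period: float = 1.0,
    resp_period: float = 5.0,
    n_heads: int = 2,
    start_angle: float = 0.0,
) -> AcquisitionSchedule:
    """Continuous-rotation schedule with gate tags.

    Head 2 is opposed at 180 degrees (H-mode).
    """
    if dt <= 0 or dtheta <= 0:
        raise ValueError("dt and dtheta must be positive")
    fpr = 360.0 / dtheta
    if abs(fpr - round(fpr)) > 1e-9:
        raise ValueError("360 must be an integral number of angle increments")
    n_frames = int(round(fpr)) * n_rotations
    idx = np.arange(n_frames)
    t = idx * dt
    head1 = (start_angle + idx * dtheta) % 360.0
    angles = np.stack([(head1 + 180.0 * h) % 360.0 for h in range(n_heads)], axis=1)
    q, r = gate_of_time(t, cardiac_period, resp_period)
    return AcquisitionSchedule(
        dt=dt,
        dtheta=dtheta,
        n_rotations=n_rotations,
        n_heads=n_heads,
        t_start=t,
        head_angles=angles,
        cardiac_gate=q,
        resp_gate=r,
    )


_PROJECTOR_CACHE: dict[tuple, ParallelProjector] = {}


def get_projector(
    vol_shape: tuple[int, int, int],
    voxel_size: float,
    detector: DetectorModel,
    blur: bool = True,
) -> ParallelProjector:
    """Shared projector instance for a (volume, detector) geometry."""
    key = (tuple(vol_shape), float(voxel_size), detector.n_bins, blur,
           detector.intrinsic_fwhm, detector.hole_diameter, detector.hole_length,
           detector.radius_of_rotation, detector.n_blur_groups)
    proj = _PROJECTOR_CACHE.get(key)
    if proj is None:
        proj = ParallelProjector(
            vol_shape,
            voxel_size,
            detector.n_bins,
            blur=detector.blur_model() if blur else None,
            n_blur_groups=detector.n_blur_groups,
        )
        _PROJECTOR_CACHE[key] = proj
    return proj


def forward_project(
    activity: np.ndarray,
    mu_map: np.ndarray | None,
    angle_deg: float,
    detector: DetectorModel,
    voxel_size: float,
    dt: float = 1.0,
    blur: bool = True,
) -> np.ndarray:
    """Expected (noise-free) projection of an activity volume at one angle.

    Attenuated line integrals with depth-dependent response, scaled by
    ``sensitivity_scale * dt``.
    """
    if mu_map is not None and mu_map.shape != activity.shape:
        raise ValueError("activity and attenuation grids differ")
    proj = get_projector(activity.shape, voxel_size, detector, blur=blur)
    att = None if mu_map is None else proj.attenuation_factors(mu_map, angle_deg)
    return proj.forward(activity, angle_deg, att) * detector.sensitivity_scale * dt


def emulate_scatter(
    primary: np.ndarray,
    scatter_fraction: float,
    kernel_fwhm_mm: float,
    bin_size: float,
    dew_k: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected main- and scatter-window projections from a primary one.

    scatter-in-main = fraction * broad Gaussian blur of the primary (the blur
    is reflective, hence count-preserving); the scatter window holds the same
    contribution divided by ``dew_k``, making the DEW estimate unbiased.
    """
    if not 0 <= scatter_fraction < 1:
        raise ValueError("scatter_fraction must lie in [0, 1)")
    if scatter_fraction == 0:
        return primary.copy(), np.zeros_like(primary)
    sigma = kernel_fwhm_mm * FWHM_TO_SIGMA / bin_size
    scatter_main = scatter_fraction * ndimage.gaussian_filter(primary, sigma, mode="reflect")
    return primary + scatter_main, scatter_main / dew_k


def dew_correct(
    main: np.ndarray, scatter: np.ndarray, dew_k: float = 0.5
) -> tuple[np.ndarray, int]:
    """DEW scatter correction: max(0, main - k * scatter).

    Returns the corrected frame and the number of zero-clipped bins.
    """
    if main.shape != scatter.shape:
        raise ValueError("main and scatter frames must share shape")
    est = main - dew_k * scatter
    clipped = int(np.count_nonzero(est < 0))
    return np.maximum(est, 0.0), clipped


@dataclass
class AcquisitionRun:
    """All frames of one simulated acquisition (counts or expectations)."""

    schedule: AcquisitionSchedule
    detector: DetectorModel
    main: np.ndarray      # (n_frames, n_heads, n_u, n_v)
    scatter: np.ndarray   # same shape
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def frames(self, window: str = "main"):
        data = {"main": self.main, "scatter": self.scatter}[window]
        sched = self.schedule
        for i in range(sched.n_frames):
            for h in range(sched.n_heads):
                yield AcquisitionFrame(
                    counts=data[i, h],
                    window=window,
                    head=h + 1,
                    frame_index=i,
                    angle=float(sched.head_angles[i, h]),
                    t_start=float(sched.t_start[i]),
                    cardiac_gate=int(sched.cardiac_gate[i]),
                    resp_gate=int(sched.resp_gate[i]),
                )

    def corrected_frames(self):
        """DEW-corrected frames (main - k * scatter, clipped at zero)."""
        sched = self.schedule
        k = self.detector.dew_k
        for i in range(sched.n_frames):
            for h in range(sched.n_heads):
                corr, _ = dew_correct(self.main[i, h].astype(np.float64),
                                      self.scatter[i, h].astype(np.float64), k)
                yield AcquisitionFrame(
                    counts=corr,
                    window="corrected",
                    head=h + 1,
                    frame_index=i,
                    angle=float(sched.head_angles[i, h]),
                    t_start=float(sched.t_start[i]),
                    cardiac_gate=int(sched.cardiac_gate[i]),
                    resp_gate=int(sched.resp_gate[i]),
                )


def paint_activity(
    labels: np.ndarray, tacset: TissueTACSet, time_index: int
) -> np.ndarray:
    """Assign each labeled voxel its tissue concentration at one time sample.

    Lungs carry background activity (the four-group reduction); air is cold.
    """
    values = tacset.at_index(time_index)
    lut = np.zeros(6, dtype=np.float64)
    lut[BACKGROUND] = values["background"]
    lut[LUNG] = values["background"]
    lut[LIVER] = values["liver"]
    lut[BLOOD] = values["blood"]
    lut[MYOCARDIUM] = values["myocardium"]
    lut[AIR] = 0.0
    return lut[labels]


def expected_projections(
    states_by_gate: dict[tuple[int, int], PhantomState],
    tacset: TissueTACSet,
    schedule: AcquisitionSchedule,
    detector: DetectorModel,
    progress: bool = False,
) -> AcquisitionRun:
    """Noise-free expected main/scatter-window projections for every frame."""
    some_state = next(iter(states_by_gate.values()))
    proj = get_projector(some_state.labels.shape, some_state.voxel_size, detector)
    nu, nv = detector.n_bins
    n_frames, n_heads = schedule.n_frames, schedule.n_heads
    main = np.zeros((n_frames, n_heads, nu, nv), dtype=np.float32)
    scat = np.zeros_like(main)
    tac_dt = float(tacset.times[1] - tacset.times[0])
    for i in range(n_frames):
        gate = (int(schedule.cardiac_gate[i]), int(schedule.resp_gate[i]))
        state = states_by_gate.get(gate)
        if state is None:
            raise KeyError(f"no phantom state for gate {gate}")
        ti = int(round(float(schedule.t_start[i]) / tac_dt))
        act = paint_activity(state.labels, tacset, ti)
        for h in range(n_heads):
            angle = float(schedule.head_angles[i, h])
            att = proj.attenuation_factors(state.mu_map, angle)
            primary = (
                proj.forward(act, angle, att) * detector.sensitivity_scale * schedule.dt
            )
            m, s = emulate_scatter(
                primary,
                detector.scatter_fraction,
                detector.scatter_kernel_fwhm,
                detector.bin_size,
                detector.dew_k,
            )
            main[i, h] = m
            scat[i, h] = s
    return AcquisitionRun(schedule, detector, main, scat, seed=None, meta={"expected": True})


def sample_counts(expected: AcquisitionRun, seed: int) -> AcquisitionRun:
    """Draw Poisson counts from an expected-projection run."""
    rng = np.random.default_rng(seed)
    main = rng.poisson(np.asarray(expected.main, dtype=np.float64)).astype(np.int32)
    scat = rng.poisson(np.asarray(expected.scatter, dtype=np.float64)).astype(np.int32)
    return AcquisitionRun(
        expected.schedule, expected.detector, main, scat, seed=seed, meta={"expected": False}
    )


def simulate_acquisition(
    states_by_gate: dict[tuple[int, int], PhantomState],
    tacset: TissueTACSet,
    schedule: AcquisitionSchedule,
    detector: DetectorModel,
    seed: int,
) -> AcquisitionRun:
    """Full acquisition simulation: expectation painting + Poisson sampling."""
    return sample_counts(
        expected_projections(states_by_gate, tacset, schedule, detector), seed
    )


# ---------------------------------------------------------------------------
# HDF5 persistence


def write_run(run: AcquisitionRun, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("main", data=run.main, compression="gzip", compression_opts=4)
        f.create_dataset("scatter", data=run.scatter, compression="gzip", compression_opts=4)
        sched = run.schedule
        f.create_dataset("t_start", data=sched.t_start)
        f.create_dataset("head_angles", data=sched.head_angles)
        f.create_dataset("cardiac_gate", data=sched.cardiac_gate)
        f.create_dataset("resp_gate", data=sched.resp_gate)
        f.attrs["dt"] = sched.dt
        f.attrs["dtheta"] = sched.dtheta
        f.attrs["n_rotations"] = sched.n_rotations
        f.attrs["n_heads"] = sched.n_heads
        f.attrs["seed"] = -1 if run.seed is None else run.seed
        f.attrs["sensitivity_scale"] = run.detector.sensitivity_scale


def read_run(path: str | Path, detector: DetectorModel | None = None) -> AcquisitionRun:
    with h5py.File(path, "r") as f:
        schedule = AcquisitionSchedule(
            dt=float(f.attrs["dt"]),
            dtheta=float(f.attrs["dtheta"]),
            n_rotations=int(f.attrs["n_rotations"]),
            n_heads=int(f.attrs["n_heads"]),
            t_start=f["t_start"][:],
            head_angles=f["head_angles"][:],
            cardiac_gate=f["cardiac_gate"][:],
            resp_gate=f["resp_gate"][:],
        )
        det = detector or DetectorModel(sensitivity_scale=float(f.attrs["sensitivity_scale"]))
        seed = int(f.attrs["seed"])
        return AcquisitionRun(
            schedule,
            det,
            f["main"][:],
            f["scatter"][:],
            seed=None if seed < 0 else seed,
        )
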