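"""Deformable cardiac-torso phantom.

A simplified analytic torso built from ellipsoidal organs: a prolate
ellipsoidal left-ventricular (LV) myocardial shell with a blood-pool cavity,
a half-ellipsoidal liver, two low-density lungs and an elliptical-cylinder
body of soft tissue.  The phantom beats and breathes: the LV shell contracts
radially from end-diastole (ED) to end-systole (ES) with its wall volume
conserved (the wall thickens at systole), and the whole heart plus liver
translate along the inferior-superior axis with a raised-cosine diaphragm
displacement while the anterior-posterior (AP) body extent expands in phase.

Both motions are discretized into 8 cardiac sub-phases per heartbeat and 5
heartbeats per respiratory cycle, giving 40 motion states per 5 s breathing
cycle.  Each state carries a matched 140 keV attenuation map so that
downstream projection and reconstruction can use gate-specific attenuation.

Axes: index 0 = left-right (x), index 1 = anterior-posterior (y),
index 2 = inferior-superior (z, superior positive).  All physical
coordinates are in mm and are centered on the grid center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

# Tissue label codes, shared across the package.
AIR = 0
BACKGROUND = 1
LUNG = 2
LIVER = 3
BLOOD = 4
MYOCARDIUM = 5

LABEL_NAMES = {
    AIR: "air",
    BACKGROUND: "background",
    LUNG: "lung",
    LIVER: "liver",
    BLOOD: "blood",
    MYOCARDIUM: "myocardium",
}

#: Narrow-beam linear attenuation at 140 keV (Tc-99m), cm^-1.  Soft tissue,
#: blood, myocardium and liver are treated as water-equivalent.
MU_TABLE_140KEV = {
    AIR: 0.0,
    BACKGROUND: 0.155,
    LUNG: 0.045,
    LIVER: 0.155,
    BLOOD: 0.155,
    MYOCARDIUM: 0.155,
}

N_CARDIAC_GATES = 8
N_RESP_GATES = 5


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and motion parameters of the torso phantom.

    Lengths are mm, times are seconds.  The default grid is the desk-scale
    4.4 mm grid (90 x 60 x 55); ``full_resolution()`` returns the 2.2 mm
    (180 x 120 x 110) variant with identical physical geometry.
    """

    grid_dims: tuple[int, int, int] = (90, 60, 55)
    voxel_size: float = 4.4
    cardiac_period: float = 1.0
    resp_period: float = 5.0
    ed_to_es: float = 0.325
    #: increase of the AP body *extent* (diameter) at full inhalation, mm
    ap_expansion: float = 12.0
    #: peak inferior-superior diaphragm displacement of heart and liver, mm
    diaphragm_amp: float = 20.0
    #: fraction by which the endocardial semi-axes shrink at end-systole
    contraction_fraction: float = 0.25
    lv_center: tuple[float, float, float] = (-35.0, 10.0, 20.0)
    lv_endo_axes: tuple[float, float, float] = (24.0, 24.0, 38.0)
    lv_epi_axes: tuple[float, float, float] = (36.0, 36.0, 50.0)
    wall_mode: str = "uniform"  # "uniform" | "non-uniform"
    thin_sector_center_deg: float = 135.0
    thin_sector_width_deg: float = 60.0
    thin_fraction: float = 0.4
    body_axes: tuple[float, float] = (135.0, 95.0)
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-72.0, -12.0, 30.0),
        (72.0, -12.0, 30.0),
    )
    lung_axes: tuple[float, float, float] = (36.0, 48.0, 70.0)
    liver_center: tuple[float, float, float] = (48.0, 5.0, -58.0)
    liver_axes: tuple[float, float, float] = (62.0, 58.0, 52.0)
    mu_table: dict = field(default_factory=lambda: dict(MU_TABLE_140KEV))

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0 < self.ed_to_es < self.cardiac_period:
            raise ValueError("ed_to_es must lie strictly inside the cardiac period")
        if self.diaphragm_amp < 0:
            raise ValueError("diaphragm_amp must be nonnegative")
        frame = self.cardiac_period / N_CARDIAC_GATES
        for period in (self.cardiac_period, self.resp_period):
            n = period / frame
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    "cardiac and respiratory periods must be integer multiples "
                    f"of the {frame} s frame duration"
                )
        if self.wall_mode not in ("uniform", "non-uniform"):
            raise ValueError(f"unknown wall_mode {self.wall_mode!r}")
        if not all(e < p for e, p in zip(self.lv_endo_axes, self.lv_epi_axes)):
            raise ValueError("endocardial semi-axes must lie inside the epicardium")

    def full_resolution(self) -> "PhantomConfig":
        """The 2.2 mm / 180x120x110 variant of this configuration."""
        return replace(self, grid_dims=(180, 120, 110), voxel_size=2.2)

    @property
    def frame_duration(self) -> float:
        return self.cardiac_period / N_CARDIAC_GATES


@dataclass
class PhantomState:
    """One of the 40 cardiac-respiratory motion states.

    ``labels`` is an integer volume of tissue codes; ``mu_map`` the matched
    140 keV attenuation map in cm^-1 on the same grid.
    """

    labels: np.ndarray
    mu_map: np.ndarray
    cardiac_gate: int
    resp_gate: int
    voxel_size: float

    @property
    def state_index(self) -> int:
        return (self.resp_gate - 1) * N_CARDIAC_GATES + self.cardiac_gate


def _grids(config: PhantomConfig):
    nx, ny, nz = config.grid_dims
    h = config.voxel_size
    x = (np.arange(nx) - (nx - 1) / 2) * h
    y = (np.arange(ny) - (ny - 1) / 2) * h
    z = (np.arange(nz) - (nz - 1) / 2) * h
    return np.meshgrid(x, y, z, indexing="ij")


def respiratory_displacement(t: float | np.ndarray, config: PhantomConfig) -> float | np.ndarray:
    """Raised-cosine inferior-superior displacement, mm.

    Zero at end-exhale (t = 0), peaks at ``diaphragm_amp`` mid-cycle.
    """
    return config.diaphragm_amp * (1 - np.cos(2 * np.pi * np.asarray(t) / config.resp_period)) / 2


def contraction_phase(t_c: float, config: PhantomConfig) -> float:
    """Contraction fraction in [0, 1]: 0 at ED, 1 at ES.

    Piecewise linear: rises over [0, ed_to_es], relaxes over the rest of the
    heartbeat.
    """
    t_c = float(t_c) % config.cardiac_period
    if t_c <= config.ed_to_es:
        return t_c / config.ed_to_es
    return (config.cardiac_period - t_c) / (config.cardiac_period - config.ed_to_es)


def _ellipsoid_volume(axes) -> float:
    a, b, c = axes
    return 4.0 / 3.0 * np.pi * a * b * c


def cardiac_axes(t_c: float, config: PhantomConfig):
    """Endo/epi semi-axes at cardiac-cycle time ``t_c``.

    The endocardium shrinks radially by ``contraction_fraction`` at ES; the
    epicardium is rescaled so the shell (wall) volume is conserved, which
    thickens the wall at systole.
    """
    c = contraction_phase(t_c, config)
    scale_endo = 1.0 - c * config.contraction_fraction
    endo = np.asarray(config.lv_endo_axes) * scale_endo
    v_endo0 = _ellipsoid_volume(config.lv_endo_axes)
    v_epi0 = _ellipsoid_volume(config.lv_epi_axes)
    v_wall = v_epi0 - v_endo0
    g = ((_ellipsoid_volume(endo) + v_wall) / v_epi0) ** (1.0 / 3.0)
    epi = np.asarray(config.lv_epi_axes) * g
    if not np.all(endo < epi):
        raise ValueError("degenerate LV geometry: endocardium reached the epicardium")
    return endo, epi


def generate_state(config: PhantomConfig, q: int, r: int) -> PhantomState:
    """Build the phantom state for cardiac gate ``q`` and respiratory gate ``r``.

    Motion is evaluated at the gate midpoints: t_c = (q - 1/2) / 8 of the
    heartbeat and t_r = (r - 1/2) / 5 of the breathing cycle.
    """
    if not 1 <= q <= N_CARDIAC_GATES:
        raise ValueError(f"cardiac gate {q} out of range 1..{N_CARDIAC_GATES}")
    if not 1 <= r <= N_RESP_GATES:
        raise ValueError(f"respiratory gate {r} out of range 1..{N_RESP_GATES}")

    t_c = (q - 0.5) * config.cardiac_period / N_CARDIAC_GATES
    t_r = (r - 0.5) * config.resp_period / N_RESP_GATES
    disp = float(respiratory_displacement(t_r, config))
    breath = disp / config.diaphragm_amp if config.diaphragm_amp > 0 else (
        (1 - np.cos(2 * np.pi * t_r / config.resp_period)) / 2
    )

    X, Y, Z = _grids(config)
    labels = np.zeros(config.grid_dims, dtype=np.uint8)

    # Body: elliptical cylinder, AP semi-axis grows by ap_expansion/2 at peak.
    bx, by = config.body_axes
    by_t = by + 0.5 * config.ap_expansion * breath
    body = (X / bx) ** 2 + (Y / by_t) ** 2 <= 1.0
    labels[body] = BACKGROUND

    for cx, cy, cz in config.lung_centers:
        lung = (
            ((X - cx) / config.lung_axes[0]) ** 2
            + ((Y - cy) / config.lung_axes[1]) ** 2
            + ((Z - cz) / config.lung_axes[2]) ** 2
        ) <= 1.0
        labels[lung & body] = LUNG

    # Liver: inferior half-ellipsoid, translated with the diaphragm.
    lx, ly, lz = config.liver_center
    lz = lz + disp
    liver = (
        ((X - lx) / config.liver_axes[0]) ** 2
        + ((Y - ly) / config.liver_axes[1]) ** 2
        + ((Z - lz) / config.liver_axes[2]) ** 2
    ) <= 1.0
    labels[liver & (Z <= lz) & body] = LIVER

    # Heart: deformed shell + cavity, translated with the diaphragm.
    endo, epi = cardiac_axes(t_c, config)
    hx, hy, hz = config.lv_center
    hz = hz + disp
    dx, dy, dz = X - hx, Y - hy, Z - hz
    f_epi = (dx / epi[0]) ** 2 + (dy / epi[1]) ** 2 + (dz / epi[2]) ** 2
    f_endo = (dx / endo[0]) ** 2 + (dy / endo[1]) ** 2 + (dz / endo[2]) ** 2
    myo = (f_epi <= 1.0) & (f_endo > 1.0)
    cavity = f_endo <= 1.0

    if config.wall_mode == "non-uniform":
        # A thinned angular sector: the wall keeps (1 - thin_fraction) of its
        # local thickness, the freed inner band joins the cavity.
        azimuth = np.degrees(np.arctan2(dy, dx + np.zeros_like(dy)))
        delta = (azimuth - config.thin_sector_center_deg + 180.0) % 360.0 - 180.0
        sector = np.abs(delta) <= config.thin_sector_width_deg / 2
        endo_thin = endo + config.thin_fraction * (epi - endo)
        f_thin = (dx / endo_thin[0]) ** 2 + (dy / endo_thin[1]) ** 2 + (dz / endo_thin[2]) ** 2
        myo = myo & ~(sector & (f_thin <= 1.0))
        cavity = cavity | (sector & (f_thin <= 1.0) & (f_epi <= 1.0))

    labels[cavity & body] = BLOOD
    labels[myo & body] = MYOCARDIUM

    mu_map = attenuation_map(labels, config.mu_table)
    return PhantomState(labels, mu_map, q, r, config.voxel_size)


def generate_sequence(config: PhantomConfig) -> list[PhantomState]:
    """All 40 states in time order: 8 cardiac gates x 5 heartbeats per cycle."""
    return [
        generate_state(config, q, r)
        for r in range(1, N_RESP_GATES + 1)
        for q in range(1, N_CARDIAC_GATES + 1)
    ]


def states_by_gate(states: list[PhantomState]) -> dict[tuple[int, int], PhantomState]:
    return {(s.cardiac_gate, s.resp_gate): s for s in states}


def attenuation_map(labels: np.ndarray, mu_table: dict) -> np.ndarray:
    """Voxelwise lookup of linear attenuation (cm^-1) from tissue labels."""
    codes = np.unique(labels)
    unknown = [int(c) for c in codes if int(c) not in mu_table]
    if unknown:
        raise KeyError(f"labels {unknown} missing from the attenuation table")
    lut = np.zeros(int(max(mu_table)) + 1, dtype=np.float64)
    for code, mu in mu_table.items():
        lut[code] = mu
    return lut[labels]


def lv_center(labels: np.ndarray, voxel_size: float) -> np.ndarray:
    """Centroid of the myocardium label in centered physical coordinates, mm."""
    idx = np.argwhere(labels == MYOCARDIUM)
    if idx.size == 0:
        raise ValueError("myocardium label is empty")
    center = (np.asarray(labels.shape) - 1) / 2
    return (idx.mean(axis=0) - center) * voxel_size


def tissue_volumes_ml(labels: np.ndarray, voxel_size: float) -> dict[str, float]:
    """Volume of each tissue group in ml."""
    vox_ml = (voxel_size / 10.0) ** 3
    return {
        name: float(np.count_nonzero(labels == code) * vox_ml)
        for code, name in LABEL_NAMES.items()
        if code != AIR
    }


# ---------------------------------------------------------------------------
# NIfTI persistence


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def write_state(state: PhantomState, directory: str | Path) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"state_{state.state_index:02d}"
    aff = _affine(state.voxel_size)
    nib.save(nib.Nifti1Image(state.labels.astype(np.uint8), aff), directory / f"{stem}_labels.nii")
    nib.save(nib.Nifti1Image(state.mu_map.astype(np.float32), aff), directory / f"{stem}_mu.nii")
    return {
        "state_index": state.state_index,
        "cardiac_gate": state.cardiac_gate,
        "resp_gate": state.resp_gate,
        "labels": f"{stem}_labels.nii",
        "mu": f"{stem}_mu.nii",
    }


def write_sequence(states: list[PhantomState], directory: str | Path) -> Path:
    directory = Path(directory)
    manifest = {
        "voxel_size": states[0].voxel_size,
        "states": [write_state(s, directory) for s in states],
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_sequence(directory: str | Path) -> list[PhantomState]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    states = []
    for entry in manifest["states"]:
        labels = np.asarray(nib.load(directory / entry["labels"]).dataobj).astype(np.uint8)
        mu = np.asarray(nib.load(directory / entry["mu"]).dataobj).astype(np.float64)
        states.append(
            PhantomState(labels, mu, entry["cardiac_gate"], entry["resp_gate"], manifest["voxel_size"])
        )
    return states
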