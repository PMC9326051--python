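"""Small 2D reconstruction toys shared by the recon and acceptance tests."""

import numpy as np

from gatedspect.acquisition import DetectorModel
from gatedspect.gating import GatedSinogram, GateViews
from gatedspect.recon import BSplineBasis, GateSystemMatrix, build_gate_system_matrix


def toy_detector(n_u=24, blur=True):
    return DetectorModel(
        n_bins=(n_u, 1),
        sensitivity_scale=1.0,
        scatter_fraction=0.0,
        intrinsic_fwhm=2.5 if blur else 1e-6,
        radius_of_rotation=120.0,
        n_blur_groups=3,
    )


def disc_volume(n=16, center=(0.0, 0.0), radius=5.0, value=3.0):
    c = (n - 1) / 2
    xx, yy = np.meshgrid(np.arange(n) - c - center[0], np.arange(n) - c - center[1], indexing="ij")
    return np.where(xx**2 + yy**2 <= radius**2, value, 0.0)[:, :, None]


def toy_mu(n=16, level=0.01):
    """Uniform weak attenuation; also serves as the support mask (mu > 0)."""
    return np.full((n, n, 1), level)


def simulate_gate(
    matrix: GateSystemMatrix,
    basis: BSplineBasis,
    activity_of_t,
    times,
    angles,
    rng=None,
):
    """Noise-free (or Poisson) views of a time-varying activity at given
    (time, angle) pairs, using the same operator as the reconstruction."""
    counts = []
    for t, a in zip(times, angles):
        y = matrix.forward(activity_of_t(t), matrix.angle_index(a))
        if rng is not None:
            y = rng.poisson(y).astype(float)
        counts.append(y)
    views = GateViews(
        gate=matrix.gate,
        counts=np.stack(counts),
        heads=np.ones(len(times), dtype=int),
        angles=np.asarray(angles, dtype=float),
        frame_indices=np.arange(len(times)),
        t_start=np.asarray(times, dtype=float),
    )
    return GatedSinogram(gates={matrix.gate: views})


def full_sampling(times_grid, angles_grid):
    """Every angle visited at every time (a fully sampled toy schedule)."""
    tt, aa = np.meshgrid(times_grid, angles_grid, indexing="ij")
    return tt.ravel(), aa.ravel()
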