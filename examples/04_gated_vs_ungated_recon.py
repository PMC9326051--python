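"""Gated vs ungated reconstruction of a moving object (2-D toy).

A small disc alternates between two positions (two "gates").  Reconstructing
each gate with its own system matrix resolves a sharp disc at each position;
pooling all frames into one ungated reconstruction smears the activity
across both.  The printed spatial spread (second moment along the motion
axis) quantifies the blur the gating removes.
"""

import numpy as np

from gatedspect import recon
from gatedspect.acquisition import AcquisitionFrame, DetectorModel
from gatedspect.gating import GatedSinogram, GateViews

det = DetectorModel(n_bins=(24, 1), sensitivity_scale=1.0, scatter_fraction=0.0,
                    radius_of_rotation=120.0, n_blur_groups=3)
mu = np.full((16, 16, 1), 0.05)
basis = recon.build_bspline_basis(knot_times=[], domain=(0.0, 1.0), order=0)
angles = np.arange(0, 360, 12.0)


def disc(cx):
    xx, yy = np.meshgrid(np.arange(16) - 7.5 - cx, np.arange(16) - 7.5, indexing="ij")
    return np.where(xx**2 + yy**2 <= 16, 3.0, 0.0)[:, :, None]


mats, gate_views, all_frames = {}, {}, []
for g, cx in ((1, -3.0), (2, 3.0)):
    mat = recon.build_gate_system_matrix((g, 1), angles, mu, det, 4.4, frame_dt=1.0)
    counts = np.stack([mat.forward(disc(cx), i) for i in range(angles.size)])
    views = GateViews((g, 1), counts, np.ones(angles.size, int), angles,
                      np.arange(angles.size), np.full(angles.size, 0.5))
    mats[(g, 1)], gate_views[(g, 1)] = mat, views
    all_frames += [AcquisitionFrame(counts[j], "corrected", 1, j, float(angles[j]),
                                    0.5, g, 1) for j in range(angles.size)]

gated = recon.mlem_spatiotemporal(GatedSinogram(gates=gate_views), mats, basis, n_iter=30)
ungated = recon.recon_ungated_4d(all_frames, mu, basis, det, 4.4, n_iter=30, frame_dt=1.0)


def spread(vol):
    prof = np.clip(vol[:, :, 0], 0, None).sum(axis=1)
    xs = np.arange(prof.size)
    m = (prof * xs).sum() / prof.sum()
    return np.sqrt((prof * (xs - m) ** 2).sum() / prof.sum())


print(f"spatial spread along motion axis: gated {spread(gated.evaluate((1, 1), 0.5)):.2f} px, "
      f"ungated {spread(ungated.evaluate((0, 0), 0.5)):.2f} px")
print("The ungated image mixes both positions of the disc; the gated one is")
print("sharper because each gate's data are reconstructed with its own geometry.")
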