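"""Continuous dual-head acquisition and cardiac-respiratory gating.

Builds the rotation schedule (0.5 degrees per 0.125 s frame), simulates a
short gate-tagged acquisition on a coarse phantom, and bins the frames by
gate: every one of the 40 gates collects exactly 18 views per rotation per
head, 20 degrees apart, and binning conserves counts exactly.
"""

import numpy as np

from gatedspect import acquisition as acq
from gatedspect import gating, kinetics, phantom

sched = acq.build_schedule()
print(f"schedule: {sched.frames_per_rotation} frames/rotation/head, "
      f"rotation period {sched.rotation_period:.0f} s, "
      f"total {sched.total_duration:.0f} s over {sched.n_rotations} rotations")

config = phantom.PhantomConfig(grid_dims=(48, 32, 28), voxel_size=8.8)
states = phantom.states_by_gate(phantom.generate_sequence(config))
tacs = kinetics.assemble_tacset(case=1)
detector = acq.DetectorModel(n_bins=(32, 28), sensitivity_scale=33.4)
one_rotation = acq.build_schedule(n_rotations=1)
run = acq.simulate_acquisition(states, tacs, one_rotation, detector, seed=7)

gs = gating.bin_by_gate(run.corrected_frames())
views = sorted(set(gs.view_counts().values()))
angles = gating.gate_angle_coverage(gs, (1, 1))
print(f"{gs.n_gates} gates, views per gate (1 rotation, 2 heads): {views}")
print(f"gate (1,1) angular coverage: {angles.size} angles, "
      f"spacing {np.diff(angles)[0]:.0f} degrees")
total_before = float(np.sum([f.counts.sum() for f in run.corrected_frames()]))
print(f"counts conserved by gating: {gs.total_counts():.0f} vs {total_before:.0f}")
print("Slow continuous rotation still samples every motion state: each gate")
print("sees a sparse but evenly spread subset of angles.")
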