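"""Regrouping of continuously acquired frames into per-gate projection sets.

Because the 0.125 s frame duration equals the cardiac sub-phase duration and
the rotation period (90 s) is a multiple of the respiratory period (5 s),
frames never straddle a gate boundary and every (cardiac, respiratory) gate
receives exactly 18 views per rotation per head, spaced 20 degrees apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np

from .acquisition import AcquisitionFrame

N_GATES = 40


@dataclass
class GateViews:
    """All views binned into one (cardiac, respiratory) gate."""

    gate: tuple[int, int]
    counts: np.ndarray        # (n_views, n_u, n_v)
    heads: np.ndarray         # (n_views,)
    angles: np.ndarray        # (n_views,) degrees
    frame_indices: np.ndarray
    t_start: np.ndarray

    @property
    def n_views(self) -> int:
        return self.counts.shape[0]


@dataclass
class GatedSinogram:
    """Frames partitioned by gate; the reconstruction input."""

    gates: dict[tuple[int, int], GateViews] = field(default_factory=dict)

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    def total_counts(self) -> float:
        return float(sum(v.counts.sum() for v in self.gates.values()))

    def view_counts(self) -> dict[tuple[int, int], int]:
        return {g: v.n_views for g, v in self.gates.items()}


def bin_by_gate(frames: Iterable[AcquisitionFrame]) -> GatedSinogram:
    """Partition frames by (cardiac, respiratory) gate tag.

    Counts are carried over exactly (no reweighting); each frame lands in
    exactly one gate.
    """
    buckets: dict[tuple[int, int], list[AcquisitionFrame]] = {}
    for fr in frames:
        if fr.cardiac_gate is None or fr.resp_gate is None:
            raise ValueError(f"frame {fr.frame_index} carries no gate tag")
        buckets.setdefault(fr.gate, []).append(fr)
    gs = GatedSinogram()
    for gate, items in buckets.items():
        gs.gates[gate] = GateViews(
            gate=gate,
            counts=np.stack([np.asarray(f.counts, dtype=np.float64) for f in items]),
            heads=np.array([f.head for f in items]),
            angles=np.array([f.angle for f in items]),
            frame_indices=np.array([f.frame_index for f in items]),
            t_start=np.array([f.t_start for f in items]),
        )
    return gs


def gate_angle_coverage(gs: GatedSinogram, gate: tuple[int, int]) -> np.ndarray:
    """Sorted unique head angles (mod 360) contributing to one gate."""
    if gate not in gs.gates:
        raise KeyError(f"gate {gate} not present")
    return np.unique(np.round(gs.gates[gate].angles % 360.0, 6))


def write_gated(gs: GatedSinogram, path: str | Path) -> None:
    with h5py.File(path, "a") as f:
        if "gated" in f:
            del f["gated"]
        root = f.create_group("gated")
        for (q, r), views in gs.gates.items():
            grp = root.create_group(f"q{q}_r{r}")
            grp.create_dataset("counts", data=views.counts, compression="gzip")
            grp.create_dataset("heads", data=views.heads)
            grp.create_dataset("angles", data=views.angles)
            grp.create_dataset("frame_indices", data=views.frame_indices)
            grp.create_dataset("t_start", data=views.t_start)


def read_gated(path: str | Path) -> GatedSinogram:
    gs = GatedSinogram()
    with h5py.File(path, "r") as f:
        for name, grp in f["gated"].items():
            q, r = (int(s[1:]) for s in name.split("_"))
            gs.gates[(q, r)] = GateViews(
                gate=(q, r),
                counts=grp["counts"][:],
                heads=grp["heads"][:],
                angles=grp["angles"][:],
                frame_indices=grp["frame_indices"][:],
                t_start=grp["t_start"][:],
            )
    return gs
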