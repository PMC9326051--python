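"""Image-quality metrics for the gated dynamic reconstructions.

Mean Stabilized Activity (MSA) is the myocardial-ROI mean of the
reconstructed activity averaged over evaluation times in the stabilization
window (the last minute of the study, by default).  SNR divides MSA by the
spatial standard deviation of the time-averaged activity over the ROI;
Bias is the percent deviation of MSA from the ground-truth myocardial
concentration averaged over the same window.  The ROI is the ground-truth
myocardium label of the gate, eroded by one voxel to limit edge
partial-volume effects (falling back to the full label if the wall is too
thin to survive erosion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .phantom import MYOCARDIUM, PhantomState
from .recon import GatedDynamicImage, postfilter

DEFAULT_WINDOW = (300.0, 360.0)
DEFAULT_N_TIMES = 13


@dataclass
class MetricsReport:
    case: int | None
    gate: tuple[int, int]
    msa: float
    snr: float
    bias_percent: float
    n_roi_voxels: int
    snr_flagged_infinite: bool = False


def myocardium_roi(state: PhantomState, erode: int = 1) -> np.ndarray:
    """Ground-truth myocardial ROI, eroded to avoid edge voxels."""
    roi = state.labels == MYOCARDIUM
    if erode > 0:
        eroded = ndimage.binary_erosion(roi, iterations=erode)
        if eroded.any():
            roi = eroded
    return roi


def _window_volumes(
    img: GatedDynamicImage,
    gate: tuple[int, int],
    window: tuple[float, float],
    n_times: int = DEFAULT_N_TIMES,
    filter_fwhm_mm: float | None = None,
) -> np.ndarray:
    times = np.linspace(window[0], window[1], n_times)
    vols = np.stack([img.evaluate(gate, float(t)) for t in times])
    if filter_fwhm_mm is not None:
        vols = postfilter(vols, img.voxel_size, fwhm_mm=filter_fwhm_mm)
    return vols


def compute_msa(
    img: GatedDynamicImage,
    roi_myo: np.ndarray,
    gate: tuple[int, int],
    window: tuple[float, float] = DEFAULT_WINDOW,
    n_times: int = DEFAULT_N_TIMES,
    filter_fwhm_mm: float | None = None,
) -> float:
    """ROI- and time-mean activity over the stabilization window."""
    if not np.any(roi_myo):
        raise ValueError("empty ROI")
    vols = _window_volumes(img, gate, window, n_times, filter_fwhm_mm)
    return float(vols[:, roi_myo].mean())


def compute_snr(
    img: GatedDynamicImage,
    roi_myo: np.ndarray,
    gate: tuple[int, int],
    window: tuple[float, float] = DEFAULT_WINDOW,
    n_times: int = DEFAULT_N_TIMES,
    filter_fwhm_mm: float | None = None,
) -> tuple[float, bool]:
    """MSA over the spatial SD of time-averaged activity in the ROI.

    Returns (snr, flagged_infinite).
    """
    if not np.any(roi_myo):
        raise ValueError("empty ROI")
    vols = _window_volumes(img, gate, window, n_times, filter_fwhm_mm)
    time_avg = vols.mean(axis=0)
    sd = float(time_avg[roi_myo].std())
    msa = float(vols[:, roi_myo].mean())
    if sd == 0.0:
        return float("inf"), True
    return msa / sd, False


def compute_bias(
    img: GatedDynamicImage,
    truth_times: np.ndarray,
    truth_tac: np.ndarray,
    roi_myo: np.ndarray,
    gate: tuple[int, int],
    window: tuple[float, float] = DEFAULT_WINDOW,
    n_times: int = DEFAULT_N_TIMES,
    filter_fwhm_mm: float | None = None,
) -> float:
    """Percent deviation of MSA from the ground-truth window-mean activity."""
    sel = (truth_times >= window[0]) & (truth_times <= window[1])
    truth_mean = float(np.mean(truth_tac[sel]))
    if truth_mean == 0:
        raise ValueError("ground-truth window mean is zero")
    msa = compute_msa(img, roi_myo, gate, window, n_times, filter_fwhm_mm)
    return 100.0 * (msa - truth_mean) / truth_mean


def displacement_trace(
    img: GatedDynamicImage,
    lv_regions: dict[tuple[int, int], np.ndarray],
    resp_gates=range(1, 6),
    cardiac_gate: int = 1,
    t_eval: float = 330.0,
    reference_gate: int = 1,
) -> np.ndarray:
    """Inferior-superior LV displacement per respiratory gate, mm.

    For each respiratory gate the activity-weighted axial centroid inside
    that gate's LV region mask is compared to the end-exhale gate's.
    ``lv_regions`` maps gates to generous LV masks (e.g. the ground-truth
    myocardium+cavity dilated a little), which makes segmentation
    deterministic.
    """
    centroids = {}
    for r in resp_gates:
        gate = (cardiac_gate, r)
        mask = lv_regions[gate]
        if not np.any(mask):
            raise ValueError(f"empty LV region for gate {gate}")
        vol = np.clip(img.evaluate(gate, t_eval), 0, None) * mask
        total = float(vol.sum())
        if total == 0:
            raise ValueError(f"no reconstructed activity in LV region of gate {gate}")
        zz = np.arange(vol.shape[2])
        zc = float((vol.sum(axis=(0, 1)) * zz).sum() / total)
        centroids[r] = zc * img.voxel_size
    ref = centroids[reference_gate]
    return np.array([centroids[r] - ref for r in resp_gates])


def compare_msa_ttest(sample_a, sample_b) -> float:
    """Two-sample two-tailed t-test p-value between per-seed MSA lists."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 replicates per sample")
    if np.array_equal(a, b) and np.ptp(a) == 0:
        return 1.0
    return float(stats.ttest_ind(a, b).pvalue)
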