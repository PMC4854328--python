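"""Reconstruction quality metrics and scan-time arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import PartialVolumeMaps

__all__ = ["EvaluationReport", "evaluate_rmse", "scan_time_efficiency"]


@dataclass
class EvaluationReport:
    """Overall and per-tissue RMSE plus difference maps.

    The ground truth is scaled to unit mean over the brain mask and the
    reconstruction magnitude is scaled by the same factor, so RMSE values
    are fractions of the mean brain signal.  Tissue masks are the partial
    volume maps thresholded strictly (PV > threshold); a tissue with an
    empty mask reports NaN, not zero.
    """

    rmse: float
    rmse_tissue: dict[str, float]
    difference: np.ndarray
    threshold: float
    slice_mean_wm: np.ndarray = field(default_factory=lambda: np.array([]))


def evaluate_rmse(
    recon: np.ndarray,
    truth: np.ndarray,
    pv: PartialVolumeMaps,
    threshold: float = 0.8,
    brain_threshold: float = 0.5,
    match_scale: bool = True,
) -> EvaluationReport:
    """RMSE of a reconstruction against ground truth, overall and per tissue.

    With ``match_scale`` (default) the reconstruction is brought to the
    truth's intensity scale by matching mean magnitude over the brain mask
    — reconstructions carry an arbitrary global scale (profile
    normalization conventions differ between methods), and RMSE should
    measure structure, not that scale.  Disable it to compare images
    already on a common scale.
    """
    recon = np.abs(np.asarray(recon)).astype(float)
    truth = np.abs(np.asarray(truth)).astype(float)
    if recon.shape != truth.shape:
        raise ValueError("reconstruction and truth must share a grid")
    brain = pv.brain_mask(brain_threshold)
    scale = 1.0 / truth[brain].mean()
    truth_n = truth * scale
    if match_scale:
        recon_n = recon / recon[brain].mean()
    else:
        recon_n = recon * scale
    diff = recon_n - truth_n

    def rms(mask):
        if not np.any(mask):
            return float("nan")
        return float(np.sqrt(np.mean(diff[mask] ** 2)))

    rmse_tissue = {t: rms(pv.tissue_mask(t, threshold)) for t in ("WM", "GM", "CSF")}
    wm_mask = pv.tissue_mask("WM", threshold)
    nz = recon.shape[2]
    slice_mean = np.full(nz, np.nan)
    for z in range(nz):
        m = wm_mask[:, :, z]
        if np.any(m):
            slice_mean[z] = recon_n[:, :, z][m].mean()
    return EvaluationReport(
        rmse=rms(brain),
        rmse_tissue=rmse_tissue,
        difference=diff,
        threshold=threshold,
        slice_mean_wm=slice_mean,
    )


def scan_time_efficiency(extra_kz_fraction: float) -> float:
    """Scan-time efficiency given the fractional excess of kz encodings.

    The ideal acquisition spends one kz encoding per reconstructed slice;
    slab-boundary corrections need overlap/oversampling, i.e. a fraction
    ``f`` more encodings, giving efficiency ``1 / (1 + f)``.  With 0.4x
    more encodings this is 1/1.4 = 71.4%.
    """
    if extra_kz_fraction < 0:
        raise ValueError("extra fraction must be >= 0")
    return 100.0 / (1.0 + extra_kz_fraction)
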