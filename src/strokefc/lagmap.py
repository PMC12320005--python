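"""Voxelwise hemodynamic lag maps and the hemispheric QC gate.

Pipeline: band-pass the BOLD series (0.009-0.09 Hz, zero-phase
Butterworth), build a gray-matter reference signal excluding the lesion,
then for each voxel find the integer shift in +/- ``max_shift_trs`` TRs
that maximizes the overlapping-sample Pearson cross-correlation with the
reference (optionally refined below the TR by parabolic interpolation).
Subjects whose mean lag in the affected hemisphere exceeds 1 s are
flagged for exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from strokefc.io_core import SubjectContext, VolumeImage, assert_same_grid

__all__ = ["LagMap", "bandpass", "gm_reference", "voxel_lag", "compute_lagmap"]


@dataclass
class LagMap:
    """Voxelwise lag estimates plus hemispheric QC summary."""

    lag_s: VolumeImage                 # seconds, NaN outside analysis mask
    peak_xcorr: VolumeImage
    mean_lag_affected_s: float
    mean_lag_unaffected_s: float
    mean_abs_lag_affected_s: float
    mean_abs_lag_unaffected_s: float
    excluded: bool
    max_shift_trs: int = 4
    exclusion_thresh_s: float = 1.0

    def qc_dict(self) -> dict:
        return {
            "mean_lag_affected_s": self.mean_lag_affected_s,
            "mean_lag_unaffected_s": self.mean_lag_unaffected_s,
            "mean_abs_lag_affected_s": self.mean_abs_lag_affected_s,
            "mean_abs_lag_unaffected_s": self.mean_abs_lag_unaffected_s,
            "excluded": bool(self.excluded),
            "max_shift_trs": self.max_shift_trs,
            "exclusion_thresh_s": self.exclusion_thresh_s,
        }

    def write_qc(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.qc_dict(), fh, indent=2)
        return path


def bandpass(bold: VolumeImage, low_hz: float = 0.009,
             high_hz: float = 0.09, order: int = 2) -> VolumeImage:
    """Zero-phase Butterworth band-pass per voxel; output is demeaned."""
    if bold.tr_s is None:
        raise ValueError("band-pass requires a 4D volume with tr_s")
    nyquist = 0.5 / bold.tr_s
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for TR={bold.tr_s}s "
            f"(Nyquist {nyquist:.3f} Hz)")
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                           fs=1.0 / bold.tr_s, output="sos")
    data = bold.data.astype(float)
    data = data - data.mean(axis=-1, keepdims=True)
    filtered = sp_signal.sosfiltfilt(sos, data, axis=-1)
    return bold.with_data(filtered, name=f"{bold.name}_bandpassed")


def gm_reference(bold_filtered: VolumeImage, gm_prob: VolumeImage,
                 lesion_mask: VolumeImage, gm_thresh: float = 0.5) -> np.ndarray:
    """Mean series over gray-matter voxels outside the lesion."""
    mask = (gm_prob.data >= gm_thresh) & ~lesion_mask.as_mask()
    if not mask.any():
        raise ValueError("gray-matter compartment (excluding lesion) is empty")
    return bold_filtered.data[mask].mean(axis=0)


def _lagged_correlations(data: np.ndarray, ref: np.ndarray,
                         max_shift: int) -> np.ndarray:
    """Pearson r at integer shifts -max_shift..+max_shift for (V, T) data.

    Positive shift = voxel series lags (is delayed relative to) the
    reference. Overlapping samples only, re-standardized per shift.
    """
    n_t = data.shape[-1]
    if n_t <= 2 * max_shift + 2:
        raise ValueError(f"series too short (T={n_t}) for +/-{max_shift} shifts")
    shifts = np.arange(-max_shift, max_shift + 1)
    out = np.empty(data.shape[:-1] + (len(shifts),))
    for i, k in enumerate(shifts):
        if k >= 0:
            x = data[..., k:]
            y = ref[: n_t - k]
        else:
            x = data[..., :n_t + k]
            y = ref[-k:]
        xm = x - x.mean(axis=-1, keepdims=True)
        ym = y - y.mean()
        num = xm @ ym
        den = np.sqrt((xm ** 2).sum(axis=-1) * (ym ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            out[..., i] = num / den
    return out


def _refine_peak(corrs: np.ndarray, peak_idx: np.ndarray,
                 max_shift: int) -> np.ndarray:
    """Parabolic sub-sample interpolation around the integer peak."""
    shifts = peak_idx.astype(float) - max_shift
    interior = (peak_idx > 0) & (peak_idx < corrs.shape[-1] - 1)
    idx = np.nonzero(interior)[0]
    if idx.size:
        j = peak_idx[idx]
        rm1 = corrs[idx, j - 1]
        r0 = corrs[idx, j]
        rp1 = corrs[idx, j + 1]
        denom = rm1 - 2 * r0 + rp1
        delta = np.zeros_like(r0)
        ok = np.abs(denom) > 1e-12
        delta[ok] = 0.5 * (rm1[ok] - rp1[ok]) / denom[ok]
        delta = np.clip(delta, -0.5, 0.5)
        shifts[idx] += delta
    return np.clip(shifts, -max_shift, max_shift)


def voxel_lag(ts: np.ndarray, ref: np.ndarray, tr_s: float,
              max_shift_trs: int = 4, subsample: bool = True
              ) -> tuple[float, float]:
    """Lag (seconds) and peak correlation of one series vs a reference.

    Positive lag means ``ts`` is delayed relative to ``ref``. Returns
    (nan, nan) for zero-variance input.
    """
    ts = np.asarray(ts, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if ts.std() == 0 or ref.std() == 0:
        return float("nan"), float("nan")
    corrs = _lagged_correlations(ts[None, :], ref, max_shift_trs)[0]
    j = int(np.nanargmax(corrs))
    peak_r = float(corrs[j])
    if subsample:
        shift = _refine_peak(corrs[None, :], np.array([j]), max_shift_trs)[0]
    else:
        shift = j - max_shift_trs
    return float(shift * tr_s), peak_r


def compute_lagmap(bold: VolumeImage, ctx: SubjectContext,
                   analysis_mask: VolumeImage | None = None,
                   max_shift_trs: int = 4, exclusion_thresh_s: float = 1.0,
                   subsample: bool = True, gm_thresh: float = 0.5,
                   low_hz: float = 0.009, high_hz: float = 0.09,
                   use_abs_for_exclusion: bool = False) -> LagMap:
    """Voxelwise lag map over the analysis mask plus hemispheric QC.

    The default analysis mask is gray matter (``gm_prob >= gm_thresh``)
    excluding the lesion. Hemispheres are split at the mid-sagittal world
    plane (x = grid-center x under the image affine); the affected side
    comes from ``ctx.affected_side``. The ``excluded`` verdict applies
    the threshold to the affected hemisphere's mean lag (signed by
    default, absolute with ``use_abs_for_exclusion``).
    """
    assert_same_grid(bold, ctx.brain_mask)
    lesion = ctx.lesion_mask.as_mask()
    if analysis_mask is None:
        amask = (ctx.gm_prob.data >= gm_thresh) & ~lesion & ctx.brain_mask.as_mask()
    else:
        amask = analysis_mask.as_mask()
    if not amask.any():
        raise ValueError("empty lag analysis mask")

    filtered = bandpass(bold, low_hz=low_hz, high_hz=high_hz)
    ref = gm_reference(filtered, ctx.gm_prob, ctx.lesion_mask, gm_thresh)

    vox = np.argwhere(amask)
    data = filtered.data[amask]
    corrs = _lagged_correlations(data, ref, max_shift_trs)
    valid = ~np.isnan(corrs).any(axis=-1)
    peak_idx = np.zeros(len(data), dtype=int)
    peak_idx[valid] = np.argmax(corrs[valid], axis=-1)
    if subsample:
        shift = _refine_peak(corrs[valid], peak_idx[valid], max_shift_trs)
    else:
        shift = (peak_idx[valid] - max_shift_trs).astype(float)

    lag_vol = np.full(bold.shape3d, np.nan)
    peak_vol = np.full(bold.shape3d, np.nan)
    vv = vox[valid]
    lag_vol[vv[:, 0], vv[:, 1], vv[:, 2]] = shift * bold.tr_s
    peak_vol[vv[:, 0], vv[:, 1], vv[:, 2]] = corrs[valid, peak_idx[valid]]

    # hemisphere split in world coordinates along x
    nx = bold.shape3d[0]
    ii = np.arange(nx)
    world_x_axis = bold.affine[0, 0] * ii + bold.affine[0, 3]
    center_x = world_x_axis.mean()
    world_x = bold.affine[0, 0] * vv[:, 0] + bold.affine[0, 3] \
        + bold.affine[0, 1] * vv[:, 1] + bold.affine[0, 2] * vv[:, 2]
    left = world_x < center_x
    lags = shift * bold.tr_s
    sides = {"left": lags[left], "right": lags[~left]}
    for name, vals in sides.items():
        if vals.size == 0:
            raise ValueError(f"no analysis voxels in {name} hemisphere")
    aff = ctx.affected_side
    unaff = "right" if aff == "left" else "left"
    mean_aff = float(np.mean(sides[aff]))
    mean_unaff = float(np.mean(sides[unaff]))
    mean_abs_aff = float(np.mean(np.abs(sides[aff])))
    mean_abs_unaff = float(np.mean(np.abs(sides[unaff])))
    gate = mean_abs_aff if use_abs_for_exclusion else mean_aff
    excluded = bool(gate > exclusion_thresh_s)

    return LagMap(
        lag_s=bold.with_data(lag_vol, name="lag_s"),
        peak_xcorr=bold.with_data(peak_vol, name="peak_xcorr"),
        mean_lag_affected_s=mean_aff,
        mean_lag_unaffected_s=mean_unaff,
        mean_abs_lag_affected_s=mean_abs_aff,
        mean_abs_lag_unaffected_s=mean_abs_unaff,
        excluded=excluded,
        max_shift_trs=max_shift_trs,
        exclusion_thresh_s=exclusion_thresh_s,
    )
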