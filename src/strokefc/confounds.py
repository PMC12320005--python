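"""Nuisance-regressor computation.

Covers the full regressor menu the denoising pipelines draw from:
motion expansion, framewise displacement (Power and Jenkinson), DVARS,
motion-outlier flags, tissue/global mean signals (with lesion-aware
variants), anatomical CompCor, lesion-overlap ICA regressors, and the
discrete-cosine drift basis.

Conventions (all configurable):

* temporal derivative = backward difference with 0 imputed at t=0;
* standardized DVARS = raw DVARS divided by its within-run median;
* motion-outlier thresholds use strict inequality (0.5 mm FD / 1.5
  standardized DVARS);
* tissue probability maps binarized at 0.99 and a 1-voxel-dilated GM
  mask subtracted before CompCor;
* ICA component maps z-scored, binarized at |z| >= 2, flagged as noise
  when the suprathreshold extent overlaps the lesion by >= 5%
  (component-referenced fraction; inclusive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from strokefc.io_core import ConfoundsTable, SubjectContext, VolumeImage

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseMasks", "IcaResult",
    "expand_regressors", "framewise_displacement_power",
    "framewise_displacement_jenkinson", "dvars", "flag_motion_outliers",
    "make_noise_masks", "mean_signals", "acompcor", "lesion_ica",
    "cosine_drift", "compute_confounds",
]


@dataclass
class NoiseMasks:
    """Binary CSF / WM / combined noise masks for anatomical CompCor."""

    csf_mask: VolumeImage
    wm_mask: VolumeImage
    combined_mask: VolumeImage
    whole_brain_mask: VolumeImage
    variant: str  # "standard" | "lesion_adjusted"


@dataclass
class IcaResult:
    """Spatial ICA decomposition with per-component lesion-overlap flags."""

    n_components: int
    spatial_maps_z: np.ndarray        # (k, V) z-scored maps over in-brain voxels
    mixing: np.ndarray                # (T, k) component time courses
    lesion_overlap: np.ndarray        # (k,) overlap fraction in [0, 1]
    noise_flags: np.ndarray           # (k,) bool
    brain_index: np.ndarray           # (V, 3) voxel coords of the in-brain columns
    shape: tuple[int, int, int]
    seed: int
    overlap_threshold: float = 0.05
    zmap_threshold: float = 2.0

    @property
    def flagged_mixing(self) -> np.ndarray:
        """Time courses of flagged (noise) components, shape (T, n_flagged)."""
        return self.mixing[:, self.noise_flags]

    def spatial_volume(self, comp: int, affine: np.ndarray) -> VolumeImage:
        vol = np.zeros(self.shape)
        vol[self.brain_index[:, 0], self.brain_index[:, 1],
            self.brain_index[:, 2]] = self.spatial_maps_z[comp]
        return VolumeImage(vol, affine, name=f"ica_component_{comp:02d}")


# ---------------------------------------------------------------------------
# Regressor expansion / motion summaries


def expand_regressors(cols: pd.DataFrame) -> pd.DataFrame:
    """Expand T x k columns to T x 4k: [x, dx, x^2, dx^2].

    dx is the backward difference with 0 at the first row.
    """
    df = pd.DataFrame(cols)
    if len(df) < 2:
        raise ValueError("need at least 2 time points to form derivatives")
    out: dict[str, np.ndarray] = {}
    for name in df.columns:
        x = df[name].to_numpy(dtype=float)
        dx = np.diff(x, prepend=x[0])  # first entry 0
        out[name] = x
        out[f"{name}_derivative1"] = dx
        out[f"{name}_power2"] = x ** 2
        out[f"{name}_derivative1_power2"] = dx ** 2
    # order: all x, all dx, all x^2, all dx^2 (group blocks)
    ordered = (
        list(df.columns)
        + [f"{c}_derivative1" for c in df.columns]
        + [f"{c}_power2" for c in df.columns]
        + [f"{c}_derivative1_power2" for c in df.columns]
    )
    return pd.DataFrame(out)[ordered]


def _check_motion(motion: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got {arr.shape}")
    return arr


def framewise_displacement_power(motion, head_radius_mm: float = 50.0) -> np.ndarray:
    """FD following the absolute-sum-of-relative-motions formulation.

    FD[t] = sum |d trans| + R * sum |d rot|; FD[0] = 0. Rotations in rad.
    """
    arr = _check_motion(motion)
    d = np.diff(arr, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def _rigid_affine(params: np.ndarray) -> np.ndarray:
    """4x4 rigid-body affine from (tx, ty, tz, rx, ry, rz); R = Rz @ Ry @ Rx."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rz @ Ry @ Rx
    M[:3, 3] = (tx, ty, tz)
    return M


def framewise_displacement_jenkinson(motion, head_radius_mm: float = 50.0) -> np.ndarray:
    """FD as RMS displacement between consecutive rigid-body affines.

    For the relative transform ``M = M_t @ inv(M_{t-1})`` with rotation
    block ``A = R - I`` and translation ``b``, the mean-square displacement
    of points uniformly distributed in a ball of radius R centered on the
    rotation origin is ``R^2/5 * tr(A^T A) + ||b||^2``; FD is its square
    root. FD[0] = 0.
    """
    arr = _check_motion(motion)
    n_t = len(arr)
    fd = np.zeros(n_t)
    prev = _rigid_affine(arr[0])
    for t in range(1, n_t):
        cur = _rigid_affine(arr[t])
        rel = cur @ np.linalg.inv(prev)
        A = rel[:3, :3] - np.eye(3)
        b = rel[:3, 3]
        fd[t] = np.sqrt(head_radius_mm ** 2 / 5.0 * np.trace(A.T @ A) + b @ b)
        prev = cur
    return fd


def dvars(bold: VolumeImage, brain_mask: VolumeImage) -> tuple[np.ndarray, np.ndarray]:
    """Raw and standardized DVARS.

    raw[t] = RMS over mask voxels of the frame-to-frame difference, raw[0]=0;
    standardized = raw / median(raw[1:]) so a typical frame scores 1.
    """
    mask = brain_mask.as_mask()
    if not mask.any():
        raise ValueError("empty brain mask for DVARS")
    data = bold.data[mask]  # (V, T)
    diff = np.diff(data, axis=1)
    raw = np.sqrt(np.mean(diff ** 2, axis=0))
    raw = np.concatenate([[0.0], raw])
    scale = np.median(raw[1:])
    std = raw / scale if scale > 0 else np.zeros_like(raw)
    return raw, std


def flag_motion_outliers(fd: np.ndarray, dvars_std: np.ndarray,
                         fd_thresh: float = 0.5,
                         dvars_thresh: float = 1.5) -> np.ndarray:
    """Frames with FD > fd_thresh mm OR standardized DVARS > dvars_thresh."""
    fd = np.asarray(fd, dtype=float)
    dvars_std = np.asarray(dvars_std, dtype=float)
    if fd.shape != dvars_std.shape:
        raise ValueError(f"length mismatch: fd {fd.shape} vs dvars {dvars_std.shape}")
    return (fd > fd_thresh) | (dvars_std > dvars_thresh)


# ---------------------------------------------------------------------------
# Noise masks & mean signals


def make_noise_masks(ctx: SubjectContext, variant: str = "standard",
                     prob_thresh: float = 0.99, gm_dilation_vox: int = 1,
                     gm_prob_thresh: float = 0.5) -> NoiseMasks:
    """Binary CSF/WM/combined masks for anatomical CompCor.

    ``standard``: probability maps thresholded at ``prob_thresh``, then a
    dilated gray-matter mask is subtracted so no voxel with a GM fraction
    contributes. ``lesion_adjusted``: lesion voxels are additionally forced
    into the CSF mask, removed from the WM mask, and exempted from the
    GM-dilation exclusion.
    """
    if variant not in ("standard", "lesion_adjusted"):
        raise ValueError(f"unknown variant {variant!r}")
    brain = ctx.brain_mask.as_mask()
    lesion = ctx.lesion_mask.as_mask()
    csf = (ctx.csf_prob.data >= prob_thresh) & brain
    wm = (ctx.wm_prob.data >= prob_thresh) & brain
    gm = ctx.gm_prob.data >= gm_prob_thresh
    if gm_dilation_vox > 0:
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        gm_excl = ndimage.binary_dilation(gm, structure=struct,
                                          iterations=gm_dilation_vox)
    else:
        gm_excl = gm.copy()
    if variant == "lesion_adjusted":
        gm_excl = gm_excl & ~lesion
        csf = (csf & ~gm_excl) | lesion
        wm = wm & ~gm_excl & ~lesion
    else:
        csf = csf & ~gm_excl
        wm = wm & ~gm_excl
    for name, m in (("CSF", csf), ("WM", wm)):
        if not m.any():
            raise ValueError(
                f"{name} noise mask is empty under variant={variant!r}; "
                f"relax prob_thresh (currently {prob_thresh}) or gm_dilation"
            )
    aff = ctx.brain_mask.affine

    def _vol(m, name):
        return VolumeImage(m.astype(np.int16), aff, name=name)

    return NoiseMasks(
        csf_mask=_vol(csf, f"csf_mask_{variant}"),
        wm_mask=_vol(wm, f"wm_mask_{variant}"),
        combined_mask=_vol(csf | wm, f"combined_mask_{variant}"),
        whole_brain_mask=_vol(brain, "brain_mask"),
        variant=variant,
    )


def _mask_mean(bold_data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return bold_data[mask].mean(axis=0)


def mean_signals(bold: VolumeImage, ctx: SubjectContext,
                 variant: str = "standard",
                 noise_masks: NoiseMasks | None = None) -> pd.DataFrame:
    """Tissue-compartment mean time series.

    Always emits ``global_signal``, ``wm``, ``csf`` (unweighted voxel means
    over whole brain and the variant's noise masks). Under
    ``lesion_adjusted`` each compartment additionally gets
    ``*_excl_lesion`` and, when the compartment intersects the lesion,
    ``*_lesion`` columns; the plain column doubles as the
    including-lesion signal.
    """
    masks = noise_masks or make_noise_masks(ctx, variant)
    brain = ctx.brain_mask.as_mask()
    lesion = ctx.lesion_mask.as_mask()
    compartments = {
        "global_signal": brain,
        "csf": masks.csf_mask.as_mask(),
        "wm": masks.wm_mask.as_mask(),
    }
    out: dict[str, np.ndarray] = {}
    for name, mask in compartments.items():
        if not mask.any():
            raise ValueError(f"empty mask for {name}")
        out[name] = _mask_mean(bold.data, mask)
        if variant == "lesion_adjusted":
            excl = mask & ~lesion
            if not excl.any():
                raise ValueError(f"{name} mask has no voxels outside the lesion")
            out[f"{name}_excl_lesion"] = _mask_mean(bold.data, excl)
            within = mask & lesion
            if within.any():
                out[f"{name}_lesion"] = _mask_mean(bold.data, within)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# aCompCor


def cosine_drift(n_volumes: int, tr_s: float, cutoff_s: float = 128.0) -> pd.DataFrame:
    """Unit-norm discrete cosine drift basis with periods >= cutoff_s.

    Column j (1-based) is cos(pi * j * (2t+1) / (2T)); the number of
    columns is floor(2 * T * tr / cutoff).
    """
    duration = n_volumes * tr_s
    order = int(np.floor(2 * duration / cutoff_s))
    if duration <= cutoff_s:
        order = 0
    if order < 1:
        warnings.warn(
            f"run duration {duration:.0f}s shorter than cutoff {cutoff_s:.0f}s; "
            "no cosine drift columns", stacklevel=2)
        return pd.DataFrame(index=range(n_volumes))
    t = np.arange(n_volumes)
    cols = {}
    for j in range(1, order + 1):
        basis = np.cos(np.pi * j * (2 * t + 1) / (2 * n_volumes))
        cols[f"cosine{j:02d}"] = basis / np.linalg.norm(basis)
    return pd.DataFrame(cols)


def _residualize_cosine(data: np.ndarray, n_volumes: int, tr_s: float,
                        cutoff_s: float) -> np.ndarray:
    """Project out intercept + cosine drift from (V, T) data."""
    drift = cosine_drift(n_volumes, tr_s, cutoff_s)
    design = np.column_stack([np.ones(n_volumes)] + (
        [drift.to_numpy()] if drift.shape[1] else []))
    beta, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return data - (design @ beta).T


def acompcor(bold: VolumeImage, mask: VolumeImage,
             highpass_cutoff_s: float = 128.0,
             var_explained: float = 0.5) -> pd.DataFrame:
    """Anatomical CompCor components from a noise mask.

    Voxel series are cosine-high-pass residualized and variance
    normalized; the smallest number of leading principal components whose
    cumulative explained variance reaches ``var_explained`` is returned,
    each scaled to unit variance, in singular-value order.
    """
    m = mask.as_mask()
    if not m.any():
        raise ValueError("empty CompCor mask")
    data = bold.data[m].astype(float)  # (V, T)
    n_t = data.shape[1]
    data = _residualize_cosine(data, n_t, bold.tr_s, highpass_cutoff_s)
    sd = data.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all mask voxels have zero variance after filtering")
    data = data[keep] / sd[keep, None]
    # PCA over time: SVD of (T, V) matrix
    u, s, _ = np.linalg.svd(data.T, full_matrices=False)
    var = s ** 2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, var_explained) + 1)
    comps = u[:, :k]
    comps = comps / comps.std(axis=0)
    return pd.DataFrame(
        comps, columns=[f"a_comp_cor_{i:02d}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# Lesion ICA


def lesion_ica(bold: VolumeImage, brain_mask: VolumeImage,
               lesion_mask: VolumeImage, n_components: int | None = None,
               overlap_threshold: float = 0.05, zmap_threshold: float = 2.0,
               seed: int = 0, overlap_reference: str = "component",
               max_iter: int = 1000) -> IcaResult:
    """Spatial ICA with lesion-overlap noise flagging.

    Components whose z-scored spatial map, binarized at
    ``|z| >= zmap_threshold``, overlaps the lesion by at least
    ``overlap_threshold`` are flagged as noise; their mixing time courses
    are the lesion-ICA confound columns. The overlap denominator is the
    component's suprathreshold extent (``overlap_reference="component"``)
    or the lesion (``"lesion"``).
    """
    brain = brain_mask.as_mask()
    lesion = lesion_mask.as_mask()
    if not lesion.any():
        raise ValueError("empty lesion mask; lesion ICA undefined")
    if overlap_reference not in ("component", "lesion"):
        raise ValueError(f"unknown overlap_reference {overlap_reference!r}")
    n_t = bold.n_volumes
    if n_components is None:
        n_components = min(20, n_t // 5)
    if n_components > n_t // 2:
        raise ValueError(f"n_components={n_components} exceeds T/2={n_t // 2}")
    brain_index = np.argwhere(brain)
    data = bold.data[brain].astype(float)          # (V, T)
    data = data - data.mean(axis=1, keepdims=True)

    sources = mixing = None
    last_err: Exception | None = None
    for attempt in range(3):
        ica = FastICA(n_components=n_components, random_state=seed + attempt,
                      max_iter=max_iter, whiten="unit-variance")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                sources = ica.fit_transform(data)  # (V, k) spatial maps
            except Exception as exc:               # pragma: no cover - rare
                last_err = exc
                continue
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            last_err = RuntimeError(f"FastICA failed to converge (seed {seed + attempt})")
            sources = None
            continue
        mixing = ica.mixing_  # (T, k) time courses
        break
    if sources is None or mixing is None:
        raise RuntimeError(f"lesion ICA failed after 3 seeds: {last_err}")

    k = sources.shape[1]
    lesion_in_brain = lesion[brain]
    zmaps = np.empty((k, sources.shape[0]))
    overlap = np.zeros(k)
    for c in range(k):
        s = sources[:, c]
        z = (s - s.mean()) / s.std()
        zmaps[c] = z
        supra = np.abs(z) >= zmap_threshold
        if overlap_reference == "component":
            denom = supra.sum()
            overlap[c] = (supra & lesion_in_brain).sum() / denom if denom else 0.0
        else:
            overlap[c] = (supra & lesion_in_brain).sum() / lesion_in_brain.sum()
    flags = overlap >= overlap_threshold
    # unit-variance time courses so downstream scaling is uniform
    mix = mixing / mixing.std(axis=0)
    return IcaResult(
        n_components=k, spatial_maps_z=zmaps, mixing=mix,
        lesion_overlap=overlap, noise_flags=flags, brain_index=brain_index,
        shape=bold.shape3d, seed=seed,
        overlap_threshold=overlap_threshold, zmap_threshold=zmap_threshold,
    )


# ---------------------------------------------------------------------------
# Full confounds assembly


def compute_confounds(bold: VolumeImage, ctx: SubjectContext,
                      variant: str = "standard",
                      with_lesion_ica: bool = False,
                      highpass_cutoff_s: float = 128.0,
                      compcor_var_explained: float = 0.5,
                      ica_seed: int = 0,
                      n_ica_components: int | None = None) -> ConfoundsTable:
    """Assemble the full confounds table one pipeline variant needs.

    Groups: motion24, gs4, wm, csf, compcor, cosine, fd, dvars, outliers
    and (when requested) ica_lesion.
    """
    masks = make_noise_masks(ctx, variant)
    frames: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}

    motion24 = expand_regressors(ctx.motion)
    frames.append(motion24)
    groups["motion24"] = list(motion24.columns)

    signals = mean_signals(bold, ctx, variant, noise_masks=masks)
    gs4 = expand_regressors(signals[["global_signal"]])
    wm4 = expand_regressors(signals[["wm"]])
    csf4 = expand_regressors(signals[["csf"]])
    frames += [gs4, wm4, csf4]
    groups["gs4"] = list(gs4.columns)
    groups["wm"] = list(wm4.columns)
    groups["csf"] = list(csf4.columns)
    extra = signals.drop(columns=["global_signal", "wm", "csf"])
    if extra.shape[1]:
        frames.append(extra)
        groups["lesion_signals"] = list(extra.columns)

    compcor = acompcor(bold, masks.combined_mask,
                       highpass_cutoff_s=highpass_cutoff_s,
                       var_explained=compcor_var_explained)
    frames.append(compcor)
    groups["compcor"] = list(compcor.columns)

    drift = cosine_drift(bold.n_volumes, bold.tr_s, highpass_cutoff_s)
    if drift.shape[1]:
        frames.append(drift)
    groups["cosine"] = list(drift.columns)

    if with_lesion_ica:
        ica = lesion_ica(bold, ctx.brain_mask, ctx.lesion_mask,
                         n_components=n_ica_components, seed=ica_seed)
        flagged = ica.flagged_mixing
        cols = [f"ica_lesion_{i:02d}" for i in range(flagged.shape[1])]
        if cols:
            frames.append(pd.DataFrame(flagged, columns=cols))
        else:
            logger.info("no ICA component met the lesion-overlap criterion; "
                        "ica_lesion group is empty")
        groups["ica_lesion"] = cols

    fd_power = framewise_displacement_power(ctx.motion)
    fd_jenk = framewise_displacement_jenkinson(ctx.motion)
    raw_dvars, std_dvars = dvars(bold, ctx.brain_mask)
    outliers = flag_motion_outliers(fd_power, std_dvars)
    qc = pd.DataFrame({
        "framewise_displacement": fd_power,
        "fd_jenkinson": fd_jenk,
        "dvars": raw_dvars,
        "std_dvars": std_dvars,
        "motion_outlier": outliers.astype(float),
    })
    frames.append(qc)
    groups["fd"] = ["framewise_displacement", "fd_jenkinson"]
    groups["dvars"] = ["dvars", "std_dvars"]
    groups["outliers"] = ["motion_outlier"]

    table = pd.concat(frames, axis=1)
    return ConfoundsTable(table, groups)
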