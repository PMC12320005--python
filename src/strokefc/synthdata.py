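"""Synthetic stroke subjects with known ground truth.

Each generated subject mimics the derivatives a preprocessing pipeline
would hand downstream: a network-structured 4D BOLD series, tissue
probability maps, a binary lesion whose voxels carry a shared artifact
time course (optionally bled into remote "contaminated" regions), a
voxelwise hemodynamic lag field injected by circular temporal shift, and
rigid-body motion traces.

Construction notes
------------------
* Latent signals are synthesized directly in the Fourier domain with
  support restricted to the analysis band (0.009-0.09 Hz by default), so
  a circular shift is an exact delay and discrete lag recovery is exact
  in the noise-free case.
* Within-network structure: every region series is
  ``sqrt(r_within) * network_latent + sqrt(1 - r_within) * private_latent``
  which targets pairwise correlation ``r_within`` inside a network and 0
  across networks.
* Lesions are grown voxel-by-voxel (nearest voxels to a center), so a
  requested voxel count is met exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from strokefc.io_core import (
    SubjectContext,
    VolumeImage,
    write_confounds,
    write_sidecar,
    write_volume,
)

__all__ = ["SynthParams", "SynthTruth", "generate_subject", "generate_cohort",
           "write_subject_dir"]


@dataclass
class SynthParams:
    """Knobs for one synthetic subject."""

    shape: tuple[int, int, int] = (24, 24, 12)
    n_volumes: int = 150
    tr_s: float = 2.0
    n_regions: int = 20
    n_networks: int = 4
    r_within: float = 0.6
    lesion_n_voxels: int = 40
    lesion_side: str = "left"
    lesion_in_gm: bool = True  # confine lesion to the GM shell (cortical stroke)
    artifact_amplitude: float = 1.0
    n_contaminated_regions: int = 0
    contamination_amplitude: float | None = None  # defaults to artifact_amplitude
    lag_values_trs: Sequence[int] = (0,)
    lag_zero_frac: float | None = None  # probability mass on lag 0; rest uniform
    global_amplitude: float = 0.0  # variance fraction of a shared GM-wide signal
    signal_band_hz: tuple[float, float] = (0.009, 0.09)
    motion_scale_mm: float = 0.02
    noise_sd: float = 0.5
    voxel_size_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions % self.n_networks:
            raise ValueError("n_regions must be a multiple of n_networks")
        if self.lesion_side not in ("left", "right"):
            raise ValueError("lesion_side must be 'left' or 'right'")
        max_lag = max(abs(int(v)) for v in self.lag_values_trs)
        if max_lag > 4:
            raise ValueError(f"lag {max_lag} TRs outside the +/-4 TR search window")
        if not 0 <= self.r_within < 1:
            raise ValueError("r_within must be in [0, 1)")


@dataclass
class SynthTruth:
    """Ground truth emitted alongside a synthetic subject."""

    region_networks: dict[int, str]
    lesion_voxels: np.ndarray            # (n, 3) int voxel indices
    artifact: np.ndarray                 # (T,) shared artifact time course
    lag_field_s: np.ndarray              # 3D, NaN outside GM
    contaminated_regions: list[int]
    region_signals: pd.DataFrame         # clean per-region series, T x R
    seed: int = 0


def _bandlimited_noise(rng: np.random.Generator, n_t: int, tr_s: float,
                       band_hz: tuple[float, float], size: int = 1) -> np.ndarray:
    """Unit-variance real signals with spectral support confined to band_hz.

    Returns array of shape (size, n_t).
    """
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not keep.any():
        raise ValueError(f"band {band_hz} empty for T={n_t}, TR={tr_s}")
    spec = np.zeros((size, freqs.size), dtype=complex)
    n_keep = int(keep.sum())
    spec[:, keep] = rng.standard_normal((size, n_keep)) + 1j * rng.standard_normal(
        (size, n_keep)
    )
    sig = np.fft.irfft(spec, n=n_t, axis=1)
    sig -= sig.mean(axis=1, keepdims=True)
    sig /= sig.std(axis=1, keepdims=True)
    return sig


def _head_geometry(shape: tuple[int, int, int], voxel_mm: float):
    """Ellipsoidal head model: normalized radius rho, affine with x midline at 0."""
    nx, ny, nz = shape
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(shape) * 0.46
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    rho = np.sqrt(
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -center * voxel_mm  # world origin at head center
    return rho, affine


def _tissue_maps(rho: np.ndarray):
    """Crisp radial tissue shells: WM core, GM shell, CSF rim."""
    brain = rho <= 1.0
    wm = rho <= 0.55
    gm = (rho > 0.55) & (rho <= 0.85)
    csf = (rho > 0.85) & brain
    return brain, gm.astype(float), wm.astype(float), csf.astype(float)


def _parcellate(gm_mask: np.ndarray, n_regions: int) -> np.ndarray:
    """Deterministic wedge parcellation of the GM shell.

    GM voxels are ordered by (z-half, azimuthal angle) and chunked into
    n_regions nearly equal contiguous wedges; labels are 1..n_regions.
    """
    atlas = np.zeros(gm_mask.shape, dtype=np.int32)
    idx = np.argwhere(gm_mask)
    center = (np.array(gm_mask.shape) - 1) / 2.0
    angle = np.arctan2(idx[:, 1] - center[1], idx[:, 0] - center[0])
    zhalf = (idx[:, 2] >= center[2]).astype(int)
    order = np.lexsort((idx[:, 2], angle, zhalf))
    chunks = np.array_split(order, n_regions)
    for label, chunk in enumerate(chunks, start=1):
        vox = idx[chunk]
        atlas[vox[:, 0], vox[:, 1], vox[:, 2]] = label
    return atlas


def _grow_lesion(eligible: np.ndarray, center_vox: np.ndarray,
                 n_voxels: int) -> np.ndarray:
    """Return the n_voxels eligible voxel indices closest to center_vox."""
    idx = np.argwhere(eligible)
    if len(idx) < n_voxels:
        raise ValueError(
            f"lesion of {n_voxels} voxels exceeds eligible tissue ({len(idx)} voxels)"
        )
    d2 = np.sum((idx - center_vox) ** 2, axis=1)
    pick = np.argsort(d2, kind="stable")[:n_voxels]
    return idx[pick]


def generate_subject(params: SynthParams):
    """Generate one synthetic subject.

    Returns
    -------
    bold : VolumeImage
        4D series.
    ctx : SubjectContext
        Masks, affected side, motion.
    atlas : VolumeImage
        Integer label image (0 = background).
    networks : pandas.DataFrame
        Columns ``region``, ``network``.
    truth : SynthTruth
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_t = p.n_volumes

    rho, affine = _head_geometry(p.shape, p.voxel_size_mm)
    brain, gm, wm, csf = _tissue_maps(rho)
    atlas_data = _parcellate(gm > 0, p.n_regions)

    per_net = p.n_regions // p.n_networks
    region_networks = {
        r: f"Net{(r - 1) // per_net + 1}" for r in range(1, p.n_regions + 1)
    }

    # --- latent signals (band-limited, unit variance) ---
    net_latents = _bandlimited_noise(rng, n_t, p.tr_s, p.signal_band_hz,
                                     size=p.n_networks)
    private = _bandlimited_noise(rng, n_t, p.tr_s, p.signal_band_hz,
                                 size=p.n_regions)
    w = np.sqrt(p.r_within)
    global_latent = _bandlimited_noise(rng, n_t, p.tr_s, p.signal_band_hz, size=1)[0]
    wg = np.sqrt(p.global_amplitude)
    region_signals = np.empty((p.n_regions, n_t))
    for r in range(p.n_regions):
        net = (r // per_net)
        local = w * net_latents[net] + np.sqrt(1 - p.r_within) * private[r]
        local /= local.std()
        region_signals[r] = wg * global_latent + np.sqrt(1 - p.global_amplitude) * local
        region_signals[r] /= region_signals[r].std()

    artifact = _bandlimited_noise(rng, n_t, p.tr_s, p.signal_band_hz, size=1)[0]

    # --- lesion placement: inside brain tissue (GM or WM) on the requested side ---
    midline = (p.shape[0] - 1) / 2.0
    side_ok = (np.arange(p.shape[0]) < midline if p.lesion_side == "left"
               else np.arange(p.shape[0]) > midline)
    tissue_ok = (gm > 0) if p.lesion_in_gm else (brain & (rho <= 0.9))
    eligible = tissue_ok & side_ok[:, None, None]
    # deterministic center: in the GM shell on the affected side, mid y/z,
    # so lesions overlap atlas regions
    cx = int(round(p.shape[0] * (0.17 if p.lesion_side == "left" else 0.83)))
    center_vox = np.array([cx, p.shape[1] // 2, p.shape[2] // 2])
    lesion_idx = _grow_lesion(eligible, center_vox, p.lesion_n_voxels)
    lesion = np.zeros(p.shape, dtype=np.int16)
    lesion[lesion_idx[:, 0], lesion_idx[:, 1], lesion_idx[:, 2]] = 1

    # --- contaminated remote regions: farthest regions from the lesion ---
    contam_amp = (p.contamination_amplitude if p.contamination_amplitude is not None
                  else p.artifact_amplitude)
    contaminated: list[int] = []
    if p.n_contaminated_regions:
        centroids = np.array([
            np.argwhere(atlas_data == r).mean(axis=0) for r in range(1, p.n_regions + 1)
        ])
        d = np.linalg.norm(centroids - center_vox, axis=1)
        far = np.argsort(d)[::-1][: p.n_contaminated_regions]
        contaminated = sorted(int(r + 1) for r in far)

    # --- per-voxel lag assignment over GM (seconds; NaN elsewhere) ---
    lag_choices = np.asarray(sorted(set(int(v) for v in p.lag_values_trs)))
    lag_field = np.full(p.shape, np.nan)
    gm_idx = np.argwhere(gm > 0)
    if p.lag_zero_frac is not None and len(lag_choices) > 1:
        if 0 not in lag_choices:
            raise ValueError("lag_zero_frac requires 0 in lag_values_trs")
        probs = np.full(len(lag_choices),
                        (1 - p.lag_zero_frac) / (len(lag_choices) - 1))
        probs[lag_choices == 0] = p.lag_zero_frac
        gm_lags = rng.choice(lag_choices, size=len(gm_idx), p=probs)
    else:
        gm_lags = lag_choices[rng.integers(0, len(lag_choices), size=len(gm_idx))]
    lag_field[gm_idx[:, 0], gm_idx[:, 1], gm_idx[:, 2]] = gm_lags * p.tr_s

    # --- assemble BOLD ---
    bold_data = np.zeros(p.shape + (n_t,), dtype=np.float64)
    lesion_bool = lesion.astype(bool)
    for shift in lag_choices:
        sel = gm_lags == shift
        if not sel.any():
            continue
        vox = gm_idx[sel]
        labels = atlas_data[vox[:, 0], vox[:, 1], vox[:, 2]]
        shifted = np.roll(region_signals, shift, axis=1)  # +shift = delayed
        bold_data[vox[:, 0], vox[:, 1], vox[:, 2], :] = shifted[labels - 1]
    for r in contaminated:
        reg = atlas_data == r
        bold_data[reg] += contam_amp * artifact
    # lesioned tissue: no neural signal, only the artifact
    bold_data[lesion_bool] = p.artifact_amplitude * artifact
    noise = rng.standard_normal(bold_data.shape) * p.noise_sd
    bold_data += noise
    bold_data[~brain] = 0.0
    bold_data[brain] += 100.0  # baseline offset

    motion = np.cumsum(
        rng.standard_normal((n_t, 6)) * p.motion_scale_mm, axis=0
    )
    motion[:, 3:] *= 0.01  # rotations in rad, ~1/100 of translation scale
    motion_df = pd.DataFrame(motion, columns=list(SubjectContext.MOTION_COLUMNS))

    bold = VolumeImage(bold_data, affine, tr_s=p.tr_s, name="bold")
    ctx = SubjectContext(
        brain_mask=VolumeImage(brain.astype(np.int16), affine, name="brain_mask"),
        gm_prob=VolumeImage(gm, affine, name="gm_prob"),
        wm_prob=VolumeImage(wm, affine, name="wm_prob"),
        csf_prob=VolumeImage(csf, affine, name="csf_prob"),
        lesion_mask=VolumeImage(lesion, affine, name="lesion_mask"),
        affected_side=p.lesion_side,
        motion=motion_df,
    )
    atlas = VolumeImage(atlas_data, affine, name="atlas")
    networks = pd.DataFrame(
        {"region": list(region_networks), "network": list(region_networks.values())}
    )
    truth = SynthTruth(
        region_networks=region_networks,
        lesion_voxels=lesion_idx,
        artifact=artifact,
        lag_field_s=lag_field,
        contaminated_regions=contaminated,
        region_signals=pd.DataFrame(
            region_signals.T, columns=[f"region_{r}" for r in range(1, p.n_regions + 1)]
        ),
        seed=p.seed,
    )
    return bold, ctx, atlas, networks, truth


def generate_cohort(n_subjects: int, params_ranges: dict | None = None,
                    seed: int = 0, out_dir: str | Path | None = None,
                    base_params: SynthParams | None = None):
    """Generate a cohort of subjects with varied lesion sizes.

    ``params_ranges`` may contain ``lesion_n_voxels`` as either an explicit
    list of sizes (cycled over subjects) or a ``(lo, hi)`` tuple from which
    n_subjects sizes are log-spaced. Other SynthParams fields given as
    scalars are applied to every subject.

    Returns ``(subjects, manifest)`` where subjects is a list of
    generate_subject tuples and manifest a DataFrame; if ``out_dir`` is
    given, each subject directory plus ``manifest.tsv`` is written there.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params_ranges = dict(params_ranges or {})
    sizes_spec = params_ranges.pop("lesion_n_voxels", (10, 200))
    if isinstance(sizes_spec, (tuple,)) and len(sizes_spec) == 2:
        lo, hi = sizes_spec
        if hi < lo or lo < 1:
            raise ValueError(f"invalid lesion size range {sizes_spec}")
        sizes = np.unique(
            np.round(np.geomspace(lo, hi, n_subjects)).astype(int)
        )
        sizes = np.resize(sizes, n_subjects)
    else:
        sizes = list(sizes_spec)
        if not sizes:
            raise ValueError("empty lesion size list")
        sizes = [int(sizes[i % len(sizes)]) for i in range(n_subjects)]

    base = base_params or SynthParams()
    subjects = []
    rows = []
    for i in range(n_subjects):
        fields = {**base.__dict__, **params_ranges}
        fields["lesion_n_voxels"] = int(sizes[i])
        fields["seed"] = seed * 100_003 + i
        p = SynthParams(**fields)
        subj = generate_subject(p)
        subjects.append(subj)
        _, ctx, _, _, truth = subj
        rows.append({
            "subject": f"sub-{i + 1:03d}",
            "seed": p.seed,
            "lesion_n_voxels": int(ctx.lesion_mask.data.sum()),
            "affected_side": p.lesion_side,
            "n_contaminated_regions": len(truth.contaminated_regions),
        })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for row, subj in zip(rows, subjects):
            write_subject_dir(*subj, out_dir / row["subject"])
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return subjects, manifest


def write_subject_dir(bold: VolumeImage, ctx: SubjectContext, atlas: VolumeImage,
                      networks: pd.DataFrame, truth: SynthTruth,
                      subject_dir: str | Path) -> Path:
    """Write a subject as an fMRIPrep-derivative-like directory (NIfTI/TSV/JSON)."""
    d = Path(subject_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(bold, d / "bold.nii")
    write_volume(ctx.brain_mask, d / "brain_mask.nii")
    write_volume(ctx.gm_prob, d / "gm_prob.nii")
    write_volume(ctx.wm_prob, d / "wm_prob.nii")
    write_volume(ctx.csf_prob, d / "csf_prob.nii")
    write_volume(ctx.lesion_mask, d / "lesion_mask.nii")
    write_volume(atlas, d / "atlas.nii")
    ctx.motion.to_csv(d / "motion.tsv", sep="\t", index=False)
    networks.to_csv(d / "networks.tsv", sep="\t", index=False)
    write_sidecar({"tr_s": bold.tr_s, "affected_side": ctx.affected_side},
                  d / "subject.json")
    with open(d / "truth.json", "w") as fh:
        json.dump({
            "contaminated_regions": truth.contaminated_regions,
            "n_lesion_voxels": int(len(truth.lesion_voxels)),
            "seed": truth.seed,
        }, fh, indent=2)
    return d
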