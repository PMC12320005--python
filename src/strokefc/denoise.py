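"""Pipeline design matrices and confound regression.

Three presets mirror the evaluated denoising strategies:

* ``CompCorGS`` — standard tissue masks; global signal, 24-parameter
  motion, WM/CSF signals (each with derivative/quadratic expansion) and
  anatomical CompCor components.
* ``CompCorLesionGS`` — identical regressor menu but all tissue masks are
  lesion-adjusted (lesion folded into CSF, excluded elsewhere).
* ``ICLesionCompCorGS`` — CompCorLesionGS plus the lesion-overlap ICA
  time courses; when no component is flagged the design collapses to
  CompCorLesionGS exactly.

All confounds are removed simultaneously in a single least-squares
regression; low-frequency drift is handled by the cosine columns inside
the design rather than by a separate temporal filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strokefc.io_core import ConfoundsTable, SubjectContext, VolumeImage

logger = logging.getLogger(__name__)

__all__ = ["PipelineSpec", "DesignMatrix", "PIPELINES", "build_design",
           "regress_out", "denoise_bold", "denoise_series"]

RANK_TOL = 1e-8


@dataclass(frozen=True)
class PipelineSpec:
    """Which regressor groups a denoising pipeline includes."""

    name: str
    mask_variant: str                      # standard | lesion_adjusted
    groups: tuple[str, ...]                # confound groups beyond intercept
    include_gsr: bool = True
    use_lesion_ica: bool = False

    def active_groups(self) -> tuple[str, ...]:
        gs = self.groups if self.include_gsr else tuple(
            g for g in self.groups if g != "gs4")
        return gs

    def without_gsr(self) -> "PipelineSpec":
        return PipelineSpec(self.name + "-noGS", self.mask_variant, self.groups,
                            include_gsr=False, use_lesion_ica=self.use_lesion_ica)


_BASE_GROUPS = ("cosine", "motion24", "gs4", "wm", "csf", "compcor")

PIPELINES: dict[str, PipelineSpec] = {
    "CompCorGS": PipelineSpec("CompCorGS", "standard", _BASE_GROUPS),
    "CompCorLesionGS": PipelineSpec("CompCorLesionGS", "lesion_adjusted",
                                    _BASE_GROUPS),
    "ICLesionCompCorGS": PipelineSpec(
        "ICLesionCompCorGS", "lesion_adjusted", _BASE_GROUPS + ("ica_lesion",),
        use_lesion_ica=True),
}


@dataclass
class DesignMatrix:
    """T x p design with column names and group provenance."""

    matrix: np.ndarray
    names: list[str]
    provenance: dict[str, str]  # column name -> group

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def _prune_collinear(matrix: np.ndarray, names: list[str],
                     tol: float = RANK_TOL) -> tuple[np.ndarray, list[str]]:
    """Greedy rank pruning: drop columns in the span of earlier ones."""
    kept_cols: list[np.ndarray] = []
    kept_names: list[str] = []
    basis: list[np.ndarray] = []
    dropped: list[str] = []
    for j, name in enumerate(names):
        col = matrix[:, j].astype(float)
        resid = col.copy()
        for q in basis:
            resid = resid - (q @ resid) * q
        norm = np.linalg.norm(resid)
        ref = np.linalg.norm(col)
        if ref == 0 or norm <= tol * max(ref, 1.0):
            dropped.append(name)
            continue
        basis.append(resid / norm)
        kept_cols.append(col)
        kept_names.append(name)
    if dropped:
        logger.warning("dropped collinear design columns: %s", dropped)
    return np.column_stack(kept_cols), kept_names


def build_design(spec: PipelineSpec, confounds: ConfoundsTable) -> DesignMatrix:
    """Assemble the design matrix for one pipeline.

    Columns: intercept, then each active group in a fixed order. A
    missing ``ica_lesion`` group is an error only for ICA pipelines; an
    *empty* group (no flagged components) is valid and logged.
    """
    n_t = confounds.n_frames
    cols = [np.ones(n_t)]
    names = ["intercept"]
    prov = {"intercept": "intercept"}
    for grp in spec.active_groups():
        if not confounds.has_group(grp):
            if grp == "ica_lesion":
                raise ValueError(
                    "confounds table lacks the ica_lesion group; compute "
                    "confounds with with_lesion_ica=True for ICA pipelines")
            raise ValueError(f"confounds table lacks required group {grp!r}")
        sub = confounds.group(grp)
        if grp == "ica_lesion" and sub.shape[1] == 0:
            logger.info("%s: empty ICA-lesion group; design equals the "
                        "non-ICA variant", spec.name)
        for c in sub.columns:
            cols.append(sub[c].to_numpy(dtype=float))
            names.append(c)
            prov[c] = grp
    matrix = np.column_stack(cols)
    matrix, kept = _prune_collinear(matrix, names)
    prov = {n: prov[n] for n in kept}
    return DesignMatrix(matrix=matrix, names=kept, provenance=prov)


def regress_out(signals: np.ndarray | pd.DataFrame,
                design: DesignMatrix) -> np.ndarray:
    """Least-squares residuals of signals (T x m) against the design."""
    y = np.asarray(signals, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    x = design.matrix
    if x.shape[1] >= x.shape[0]:
        raise ValueError(
            f"design has p={x.shape[1]} columns for only T={x.shape[0]} frames")
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"T mismatch: signals {y.shape[0]} vs design {x.shape[0]}")
    # QR projection: numerically orthogonal residuals even for poorly
    # scaled designs (e.g. squared motion terms)
    norms = np.linalg.norm(x, axis=0)
    if np.any(norms == 0):
        raise ValueError("design matrix contains a zero column")
    q, r = np.linalg.qr(x / norms)
    if np.min(np.abs(np.diag(r))) < 1e-10:
        raise ValueError("design matrix rank-deficient after pruning")
    resid = y - q @ (q.T @ y)
    return resid[:, 0] if squeeze else resid


def denoise_series(series: pd.DataFrame, spec: PipelineSpec,
                   confounds: ConfoundsTable) -> pd.DataFrame:
    """Confound-regress a table of (ROI) time series."""
    design = build_design(spec, confounds)
    resid = regress_out(series.to_numpy(dtype=float), design)
    return pd.DataFrame(resid, columns=series.columns, index=series.index)


def denoise_bold(bold: VolumeImage, ctx: SubjectContext, spec: PipelineSpec,
                 confounds: ConfoundsTable) -> VolumeImage:
    """Voxelwise confound regression; NaN outside the brain mask."""
    design = build_design(spec, confounds)
    mask = ctx.brain_mask.as_mask()
    data = bold.data.astype(float)
    if data.shape[-1] != design.matrix.shape[0]:
        raise ValueError("BOLD length does not match confounds length")
    out = np.full(data.shape, np.nan)
    resid = regress_out(data[mask].T, design)
    out[mask] = resid.T
    return bold.with_data(out, name=f"{bold.name}_{spec.name}")
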