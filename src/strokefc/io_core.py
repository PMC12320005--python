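"""Core domain types and file I/O.

Volumes are NIfTI-1/2 via nibabel; tabular data is BIDS-derivatives-style
TSV (tab separator, ``n/a`` for missing). No resampling is performed:
all images belonging to one subject must already live on a single grid.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AFFINE_ATOL = 1e-4

__all__ = [
    "VolumeImage",
    "SubjectContext",
    "ConfoundsTable",
    "read_volume",
    "write_volume",
    "read_confounds",
    "write_confounds",
    "assert_same_grid",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Raised when images expected to share a voxel grid do not."""


@dataclass
class VolumeImage:
    """A 3D or 4D voxel grid with its affine and (for 4D) repetition time.

    Parameters
    ----------
    data : ndarray
        ``(X, Y, Z)`` or ``(X, Y, Z, T)`` array.
    affine : ndarray
        4x4 voxel-to-world transform.
    tr_s : float, optional
        Repetition time in seconds. Required for 4D data.
    name : str, optional
        Human-readable tag used in error messages.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float | None = None
    name: str = "volume"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"{self.name}: expected 3D or 4D data, got ndim={self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape[:3]):
            raise ValueError(f"{self.name}: all spatial dims must be >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError(f"{self.name}: affine must be 4x4")
        if self.is_4d:
            if self.tr_s is None or self.tr_s <= 0:
                raise ValueError(
                    f"{self.name}: 4D volume requires a positive tr_s "
                    f"(got {self.tr_s})"
                )

    @property
    def is_4d(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3] if self.is_4d else 1

    def with_data(self, data: np.ndarray, name: str | None = None) -> "VolumeImage":
        """New image on the same grid (and TR, if still 4D)."""
        data = np.asarray(data)
        tr = self.tr_s if data.ndim == 4 else None
        return VolumeImage(data, self.affine.copy(), tr_s=tr, name=name or self.name)

    def as_mask(self) -> np.ndarray:
        """Return boolean mask, validating {0,1} values."""
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{self.name}: mask is not {{0,1}}-valued")
        return self.data.astype(bool)


@dataclass
class SubjectContext:
    """Masks and metadata a single subject needs downstream."""

    brain_mask: VolumeImage
    gm_prob: VolumeImage
    wm_prob: VolumeImage
    csf_prob: VolumeImage
    lesion_mask: VolumeImage
    affected_side: str
    motion: pd.DataFrame

    MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected_side must be left/right, got {self.affected_side!r}")
        assert_same_grid(
            self.brain_mask, self.gm_prob, self.wm_prob, self.csf_prob, self.lesion_mask
        )
        for prob in (self.gm_prob, self.wm_prob, self.csf_prob):
            if prob.data.min() < 0 or prob.data.max() > 1:
                raise ValueError(f"{prob.name}: probability map outside [0, 1]")
        brain = self.brain_mask.as_mask()
        lesion = self.lesion_mask.as_mask()
        if np.any(lesion & ~brain):
            n_out = int(np.sum(lesion & ~brain))
            raise ValueError(f"lesion_mask has {n_out} voxels outside brain_mask")
        missing = [c for c in self.MOTION_COLUMNS if c not in self.motion.columns]
        if missing:
            raise ValueError(f"motion table missing columns: {missing}")


class ConfoundsTable:
    """Named nuisance time series of a common length T, with column groups."""

    def __init__(self, data: pd.DataFrame | Mapping[str, Sequence[float]],
                 groups: Mapping[str, Sequence[str]] | None = None):
        df = pd.DataFrame(data)
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate confound column names: {dupes}")
        self._df = df.astype(float)
        self._groups: dict[str, list[str]] = {
            k: list(v) for k, v in (groups or {}).items()
        }
        self._validate()

    def _validate(self) -> None:
        if self._df.isna().any().any():
            bad = self._df.columns[self._df.isna().any()].tolist()
            raise ValueError(f"NaN in confound columns {bad}; impute before building")
        for grp, cols in self._groups.items():
            missing = [c for c in cols if c not in self._df.columns]
            if missing:
                raise ValueError(f"group {grp!r} references missing columns {missing}")

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def n_frames(self) -> int:
        return len(self._df)

    @property
    def columns(self) -> list[str]:
        return list(self._df.columns)

    @property
    def groups(self) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self._groups.items()}

    def group(self, name: str) -> pd.DataFrame:
        if name not in self._groups:
            raise KeyError(f"no confound group {name!r}; have {sorted(self._groups)}")
        return self._df[self._groups[name]]

    def has_group(self, name: str) -> bool:
        return name in self._groups

    def add(self, columns: pd.DataFrame, group: str | None = None) -> "ConfoundsTable":
        """Return a new table with extra columns appended (and optionally grouped)."""
        merged = pd.concat([self._df, columns.astype(float)], axis=1)
        groups = self.groups
        if group is not None:
            groups.setdefault(group, [])
            groups[group] = groups[group] + list(columns.columns)
        return ConfoundsTable(merged, groups)

    def __getitem__(self, col: str) -> np.ndarray:
        return self._df[col].to_numpy()

    def __contains__(self, col: str) -> bool:
        return col in self._df.columns


# ---------------------------------------------------------------------------
# Volume I/O


def read_volume(path: str | Path, name: str | None = None,
                allow_nan: bool = False) -> VolumeImage:
    """Read a NIfTI file into a :class:`VolumeImage`.

    TR is taken from the header pixdim for 4D images; a 4D file with a
    zero TR in its header is rejected. NaN voxels are rejected unless
    ``allow_nan`` is set (derived maps such as denoised BOLD or lag maps
    use NaN outside the brain).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad magic
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asarray(img.dataobj)
    if not allow_nan:
        n_nan = int(np.count_nonzero(np.isnan(data)))
        if n_nan:
            raise ValueError(f"{path}: {n_nan} NaN voxels in input volume")
    tr = None
    if data.ndim == 4:
        tr = float(img.header.get_zooms()[3])
        if tr <= 0:
            raise ValueError(f"{path}: 4D volume with non-positive TR in header")
    return VolumeImage(data, img.affine, tr_s=tr, name=name or path.name)


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    """Write a :class:`VolumeImage` as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    if vol.is_4d:
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr_s
        img.header.set_zooms(zooms)
        img.header["xyzt_units"] = 10  # mm + sec
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Tabular I/O

#: column-name prefixes whose missing first-row cells are imputed to 0
_DERIVATIVE_HINTS = ("derivative", "_derivative1", "framewise", "dvars")


def read_confounds(path: str | Path) -> ConfoundsTable:
    """Read a tab-separated confounds table (``n/a`` = missing).

    Missing cells are imputed to 0 with a logged warning — the only
    expected missing entries are first-row derivative values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such confounds file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate column names")
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if df.isna().any().any():
        n_missing = int(df.isna().sum().sum())
        logger.warning("%s: imputing %d missing cells to 0", path, n_missing)
        warnings.warn(f"{path}: imputed {n_missing} 'n/a' cells to 0", stacklevel=2)
        df = df.fillna(0.0)
    return ConfoundsTable(df)


def write_confounds(table: ConfoundsTable | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.frame if isinstance(table, ConfoundsTable) else table
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.10g")
    return path


def read_motion(path: str | Path) -> pd.DataFrame:
    """Read a 6-column rigid-body motion TSV (translations mm, rotations rad)."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"]).fillna(0.0)
    missing = [c for c in SubjectContext.MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: motion table missing columns {missing}")
    return df[list(SubjectContext.MOTION_COLUMNS)].astype(float)


def read_network_lookup(path: str | Path) -> pd.DataFrame:
    """Read a region->network TSV with columns ``region`` and ``network``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("region", "network"):
        if col not in df.columns:
            raise ValueError(f"{path}: lookup must have a {col!r} column")
    df["region"] = df["region"].astype(int)
    return df


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_sidecar(meta: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dict(meta), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Grid validation


def assert_same_grid(*images: VolumeImage, atol: float = AFFINE_ATOL) -> None:
    """Raise :class:`GridMismatchError` unless all images share shape + affine.

    Affines may differ by up to ``atol`` per entry.
    """
    if len(images) < 2:
        return
    ref = images[0]
    offenders: list[str] = []
    for img in images[1:]:
        if img.shape3d != ref.shape3d:
            offenders.append(f"{img.name} shape {img.shape3d} != {ref.shape3d}")
        elif not np.allclose(img.affine, ref.affine, atol=atol, rtol=0):
            offenders.append(f"{img.name} affine differs from {ref.name}")
    if offenders:
        raise GridMismatchError(
            "images not on a common grid: " + "; ".join(offenders)
        )


def load_subject_dir(subject_dir: str | Path) -> tuple[VolumeImage, SubjectContext]:
    """Load a subject directory written by :mod:`strokefc.synthdata` (or an
    equivalently laid-out derivatives folder).

    Expected files: ``bold.nii``, ``brain_mask.nii``, ``gm_prob.nii``,
    ``wm_prob.nii``, ``csf_prob.nii``, ``lesion_mask.nii``, ``motion.tsv``,
    ``subject.json`` (keys ``tr_s``, ``affected_side``).
    """
    d = Path(subject_dir)
    meta = read_sidecar(d / "subject.json")
    bold = read_volume(d / "bold.nii", name="bold")
    if bold.tr_s is None or abs(bold.tr_s - meta["tr_s"]) > 1e-6:
        bold = VolumeImage(bold.data, bold.affine, tr_s=float(meta["tr_s"]), name="bold")
    ctx = SubjectContext(
        brain_mask=read_volume(d / "brain_mask.nii", name="brain_mask"),
        gm_prob=read_volume(d / "gm_prob.nii", name="gm_prob"),
        wm_prob=read_volume(d / "wm_prob.nii", name="wm_prob"),
        csf_prob=read_volume(d / "csf_prob.nii", name="csf_prob"),
        lesion_mask=read_volume(d / "lesion_mask.nii", name="lesion_mask"),
        affected_side=meta["affected_side"],
        motion=read_motion(d / "motion.tsv"),
    )
    assert_same_grid(bold, ctx.brain_mask)
    return bold, ctx
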