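"""Parcellation, Ledoit-Wolf functional connectivity, seed-to-voxel maps."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from strokefc.io_core import VolumeImage, assert_same_grid

logger = logging.getLogger(__name__)

__all__ = ["AtlasSpec", "ConnectivityMatrix", "extract_roi_series",
           "ledoit_wolf_correlation", "sample_correlation", "seed_to_voxel"]


@dataclass
class AtlasSpec:
    """Integer label image (0 = background) plus a region->network lookup."""

    label_img: VolumeImage
    networks: pd.DataFrame  # columns: region, network

    def __post_init__(self) -> None:
        labels = self.label_img.data
        if not np.issubdtype(np.asarray(labels).dtype, np.number):
            raise ValueError("atlas labels must be numeric")
        if np.any(labels != np.round(labels)):
            raise ValueError("atlas labels must be integers")
        present = set(int(v) for v in np.unique(labels) if v != 0)
        known = set(int(r) for r in self.networks["region"])
        missing = sorted(present - known)
        if missing:
            raise ValueError(f"atlas regions without a network entry: {missing}")

    @property
    def region_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.label_img.data) if v != 0)

    @property
    def network_of(self) -> dict[int, str]:
        return dict(zip(self.networks["region"].astype(int),
                        self.networks["network"].astype(str)))

    def region_voxel_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.label_img.data, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts) if l != 0}


@dataclass
class ConnectivityMatrix:
    """R x R symmetric Pearson-correlation matrix bound to atlas labels."""

    matrix: np.ndarray
    region_ids: list[int]
    network_labels: list[str]
    estimator: str  # "ledoit_wolf" | "sample"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        r = m.shape[0]
        if m.shape != (r, r):
            raise ValueError("connectivity matrix must be square")
        if len(self.region_ids) != r or len(self.network_labels) != r:
            raise ValueError("labels do not match matrix size")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("connectivity matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError("connectivity diagonal must be 1")
        if m.min() < -1 - 1e-9 or m.max() > 1 + 1e-9:
            raise ValueError("correlations outside [-1, 1]")
        self.matrix = m

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.region_ids,
                            columns=self.region_ids)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index_label="region")
        return path


def extract_roi_series(bold: VolumeImage, atlas: AtlasSpec,
                       brain_mask: VolumeImage | None = None) -> pd.DataFrame:
    """Mean BOLD time series per atlas region, T x R.

    Regions wholly outside the brain mask are dropped with a warning;
    regions absent from the label image raise.
    """
    assert_same_grid(bold, atlas.label_img)
    labels = atlas.label_img.data.astype(int)
    restrict = brain_mask.as_mask() if brain_mask is not None else None
    out: dict[int, np.ndarray] = {}
    dropped: list[int] = []
    empty: list[int] = []
    for rid in sorted(set(int(r) for r in atlas.networks["region"])):
        region = labels == rid
        if not region.any():
            empty.append(rid)
            continue
        if restrict is not None:
            region = region & restrict
            if not region.any():
                dropped.append(rid)
                continue
        out[rid] = bold.data[region].mean(axis=0)
    if empty:
        raise ValueError(f"regions missing from label image: {empty}")
    if dropped:
        warnings.warn(f"regions wholly outside brain mask dropped: {dropped}",
                      stacklevel=2)
    return pd.DataFrame(out)


def _standardize(series: pd.DataFrame) -> np.ndarray:
    x = series.to_numpy(dtype=float)
    sd = x.std(axis=0)
    constant = [str(c) for c, s in zip(series.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant time series for regions: {constant}")
    return (x - x.mean(axis=0)) / sd


def _finalize(cov: np.ndarray, series: pd.DataFrame, estimator: str,
              networks: dict[int, str] | None) -> ConnectivityMatrix:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    region_ids = [int(c) for c in series.columns]
    nets = ([networks.get(r, "unknown") for r in region_ids] if networks
            else ["unknown"] * len(region_ids))
    return ConnectivityMatrix(matrix=corr, region_ids=region_ids,
                              network_labels=nets, estimator=estimator)


def ledoit_wolf_correlation(series: pd.DataFrame,
                            networks: dict[int, str] | None = None
                            ) -> ConnectivityMatrix:
    """Pearson correlation via Ledoit-Wolf shrinkage of the covariance of
    standardized columns, renormalized to unit diagonal."""
    if len(series) < 3:
        raise ValueError("need at least 3 time points")
    x = _standardize(series)
    lw = LedoitWolf(assume_centered=True).fit(x)
    return _finalize(lw.covariance_, series, "ledoit_wolf", networks)


def sample_correlation(series: pd.DataFrame,
                       networks: dict[int, str] | None = None
                       ) -> ConnectivityMatrix:
    """Plain sample Pearson correlation (oracle / comparison estimator)."""
    x = _standardize(series)
    cov = (x.T @ x) / len(x)
    return _finalize(cov, series, "sample", networks)


def seed_to_voxel(denoised_bold: VolumeImage, seed_mask: VolumeImage,
                  brain_mask: VolumeImage) -> VolumeImage:
    """Pearson r between the seed-mean series and every in-brain voxel."""
    assert_same_grid(denoised_bold, seed_mask, brain_mask)
    seed = seed_mask.as_mask()
    brain = brain_mask.as_mask()
    if not seed.any():
        raise ValueError("empty seed mask")
    seed_ts = np.nanmean(denoised_bold.data[seed], axis=0)
    if np.nanstd(seed_ts) == 0:
        raise ValueError("zero-variance seed signal")
    data = denoised_bold.data[brain]
    xm = data - data.mean(axis=1, keepdims=True)
    ym = seed_ts - seed_ts.mean()
    num = xm @ ym
    den = np.sqrt((xm ** 2).sum(axis=1) * (ym ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r = np.clip(r, -1.0, 1.0)
    out = np.full(denoised_bold.shape3d, np.nan)
    out[brain] = r
    return VolumeImage(out, denoised_bold.affine, name="seed_to_voxel_r")
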