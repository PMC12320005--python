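"""Connectivity-evaluation statistics.

* positive / negative mean strength of lesion-overlapping regions
  (sum of positive resp. negative edges to all other regions, averaged
  over the lesion regions);
* FCC — the rank-sum Z statistic contrasting within-network against
  between-network edge values (higher = clearer network structure);
* Q — Newman modularity of the positive-weight graph under the best of
  several Louvain partitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from strokefc.connectivity import AtlasSpec, ConnectivityMatrix
from strokefc.io_core import VolumeImage, assert_same_grid

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "lesion_overlap_regions", "mean_strength",
           "fcc", "modularity_q", "compute_report", "compare_pipelines"]


@dataclass
class MetricsReport:
    """Evaluation metrics for one (subject, pipeline) connectivity matrix."""

    pipeline: str
    lesion_regions: dict[int, float]       # region id -> overlap fraction
    positive_mean_strength: float
    negative_mean_strength: float
    fcc_z: float
    q_value: float | None
    n_regions: int
    n_networks: int
    subject: str = ""

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "pipeline": self.pipeline,
            "lesion_regions": {str(k): v for k, v in self.lesion_regions.items()},
            "positive_mean_strength": self.positive_mean_strength,
            "negative_mean_strength": self.negative_mean_strength,
            "fcc_z": self.fcc_z,
            "q_value": self.q_value,
            "n_regions": self.n_regions,
            "n_networks": self.n_networks,
        }


def lesion_overlap_regions(atlas: AtlasSpec, lesion_mask: VolumeImage,
                           min_overlap_frac: float = 0.0) -> dict[int, float]:
    """Atlas regions overlapping the lesion.

    Returns ``{region_id: |region ∩ lesion| / |region|}`` for regions
    whose fraction strictly exceeds ``min_overlap_frac`` (so the default
    keeps any nonzero overlap).
    """
    assert_same_grid(atlas.label_img, lesion_mask)
    lesion = lesion_mask.as_mask()
    if not lesion.any():
        warnings.warn("empty lesion mask: no lesion-overlapping regions",
                      stacklevel=2)
        return {}
    labels = atlas.label_img.data.astype(int)
    out: dict[int, float] = {}
    for rid in atlas.region_ids:
        region = labels == rid
        frac = float((region & lesion).sum() / region.sum())
        if frac > min_overlap_frac:
            out[rid] = frac
    return out


def mean_strength(fc: ConnectivityMatrix, lesion_regions, sign: str = "positive",
                  normalize: bool = False) -> float:
    """Mean (over lesion regions) of the summed positive or negative edges.

    Positive variant sums only positive correlations (result >= 0), the
    negative variant only negative ones (result <= 0). ``normalize``
    divides each region's sum by R-1 for cross-atlas comparability.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    regions = sorted(int(r) for r in lesion_regions)
    if not regions:
        warnings.warn("no lesion regions: mean strength undefined", stacklevel=2)
        return float("nan")
    id_index = {rid: i for i, rid in enumerate(fc.region_ids)}
    unknown = [r for r in regions if r not in id_index]
    if unknown:
        raise ValueError(f"lesion regions not in connectivity matrix: {unknown}")
    m = fc.matrix
    strengths = []
    for rid in regions:
        i = id_index[rid]
        row = np.delete(m[i], i)
        vals = row[row > 0] if sign == "positive" else row[row < 0]
        s = float(vals.sum())
        if normalize:
            s /= (fc.n_regions - 1)
        strengths.append(s)
    return float(np.mean(strengths))


def _edge_partition(fc: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    nets = np.asarray(fc.network_labels)
    iu, ju = np.triu_indices(fc.n_regions, k=1)
    vals = fc.matrix[iu, ju]
    within = nets[iu] == nets[ju]
    return vals[within], vals[~within]


def rank_sum_z(x: np.ndarray, y: np.ndarray,
               continuity: bool = True) -> float:
    """Two-sample rank-sum Z (normal approximation, tie-corrected).

    Signed so that ``x`` stochastically larger than ``y`` gives Z > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    diff = r1 - mu
    if continuity:
        diff -= 0.5 * np.sign(diff)
    return float(diff / np.sqrt(var))


def fcc(fc: ConnectivityMatrix, exclude_regions=None,
        continuity: bool = True) -> float:
    """Functional connectivity contrast: rank-sum Z of within- vs
    between-network edge values (positive = within edges larger).

    ``exclude_regions`` optionally drops all edges touching the given
    region ids (e.g. lesion-overlapping regions) first.
    """
    if exclude_regions:
        keep = [i for i, rid in enumerate(fc.region_ids)
                if rid not in set(exclude_regions)]
        if len(keep) < 4:
            raise ValueError("too few regions left after exclusion")
        sub = ConnectivityMatrix(
            matrix=fc.matrix[np.ix_(keep, keep)],
            region_ids=[fc.region_ids[i] for i in keep],
            network_labels=[fc.network_labels[i] for i in keep],
            estimator=fc.estimator)
        fc = sub
    nets = set(fc.network_labels)
    if len(nets) < 2:
        raise ValueError("FCC needs at least 2 networks")
    wne, bne = _edge_partition(fc)
    if wne.size == 0 or bne.size == 0:
        raise ValueError("within- or between-network edge set empty")
    return rank_sum_z(wne, bne, continuity=continuity)


def modularity_q(fc: ConnectivityMatrix, gamma: float = 1.0, seed: int = 0,
                 n_restarts: int = 10) -> float:
    """Newman modularity of the positive-weight graph, best Louvain
    partition over ``n_restarts`` seeded restarts; negative edges are
    zeroed, an all-nonpositive matrix yields Q = 0 with a warning."""
    if fc.n_regions < 2:
        raise ValueError("need at least 2 regions")
    w = fc.matrix.copy()
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    if not (w > 0).any():
        warnings.warn("no positive edges: Q set to 0", stacklevel=2)
        return 0.0
    g = nx.from_numpy_array(w)
    best = -np.inf
    for i in range(n_restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=seed + i)
        q = nx.community.modularity(g, comms, weight="weight", resolution=gamma)
        best = max(best, q)
    return float(best)


def compute_report(fc: ConnectivityMatrix, atlas: AtlasSpec,
                   lesion_mask: VolumeImage, pipeline: str,
                   subject: str = "", min_overlap_frac: float = 0.0,
                   with_q: bool = True, seed: int = 0) -> MetricsReport:
    """All evaluation metrics for one connectivity matrix."""
    lesion_regions = lesion_overlap_regions(atlas, lesion_mask,
                                            min_overlap_frac=min_overlap_frac)
    present = {r: f for r, f in lesion_regions.items() if r in set(fc.region_ids)}
    pos = mean_strength(fc, present, "positive") if present else float("nan")
    neg = mean_strength(fc, present, "negative") if present else float("nan")
    return MetricsReport(
        pipeline=pipeline,
        subject=subject,
        lesion_regions=present,
        positive_mean_strength=pos,
        negative_mean_strength=neg,
        fcc_z=fcc(fc),
        q_value=modularity_q(fc, seed=seed) if with_q else None,
        n_regions=fc.n_regions,
        n_networks=len(set(fc.network_labels)),
    )


def compare_pipelines(reports: list[MetricsReport]) -> pd.DataFrame:
    """Long-format comparison table: subject, pipeline, metric, value.

    A per-metric ordering summary (pipelines sorted by mean value, or
    "tie") is attached as ``DataFrame.attrs["ordering"]``.
    """
    if not reports:
        raise ValueError("no reports to compare")
    n_regions = {r.n_regions for r in reports}
    if len(n_regions) > 1:
        raise ValueError(f"reports computed on different atlases: {n_regions}")
    metric_names = ("positive_mean_strength", "negative_mean_strength",
                    "fcc_z", "q_value")
    rows = []
    for rep in reports:
        for metric in metric_names:
            val = getattr(rep, metric)
            rows.append({
                "subject": rep.subject,
                "pipeline": rep.pipeline,
                "metric": metric,
                "value": float(val) if val is not None and np.isfinite(val)
                         else np.nan,
            })
    table = pd.DataFrame(rows)
    ordering: dict[str, str] = {}
    for metric in metric_names:
        sub = table[table.metric == metric].dropna(subset=["value"])
        if sub.empty:
            ordering[metric] = "n/a"
            continue
        means = sub.groupby("pipeline")["value"].mean().sort_values(
            ascending=False)
        if means.nunique() == 1:
            ordering[metric] = "tie"
        else:
            ordering[metric] = " > ".join(means.index)
    table.attrs["ordering"] = ordering
    return table
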