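"""Smoothed abundance trajectories over age and their clustering.

Per-protein abundances are z-scored across individuals, LOESS-smoothed
against age on a fixed grid spanning the observed age range, and the
smoothed curves are clustered by complete-linkage hierarchical
clustering on Euclidean distance, with flat clusters cut at a fixed
dendrogram height.  Cluster-level matrisome enrichment uses the full
measured proteome as the hypergeometric background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._stats import set_enrichment
from .cohort import Cohort
from .smoothing import loess_matrix

logger = logging.getLogger(__name__)


@dataclass
class TrajectorySet:
    """LOESS-smoothed z-score curves on a common age grid."""

    age_grid: np.ndarray
    curves: pd.DataFrame  # proteins × grid
    cluster_id: pd.Series | None = None

    @property
    def protein_ids(self) -> pd.Index:
        return self.curves.index


def smooth_trajectories(
    cohort: Cohort,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 101,
) -> TrajectorySet:
    """z-score each protein across samples and LOESS-smooth over age.

    The grid is evenly spaced over the observed age range (no
    extrapolation).  Constant proteins cannot be z-scored and are
    excluded with a warning.
    """
    if cohort.n_samples < 10:
        raise ValueError("need at least 10 samples to smooth trajectories")
    ages = cohort.ages.to_numpy(dtype=float)
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    z = cohort.zscored_abundance(drop_constant=True)
    n_dropped = cohort.n_proteins - z.shape[1]
    if n_dropped:
        logger.warning("%d constant proteins excluded from trajectories", n_dropped)
    grid = np.linspace(ages.min(), ages.max(), n_grid)
    smoothed = loess_matrix(ages, z.to_numpy(), grid, span=span, degree=degree)
    curves = pd.DataFrame(smoothed.T, index=z.columns.copy(), columns=grid)
    curves.index.name = "protein_id"
    return TrajectorySet(age_grid=grid, curves=curves)


def cluster_trajectories(
    traj: TrajectorySet,
    cut_height: float = 5.0,
    linkage: str = "complete",
) -> pd.Series:
    """Complete-linkage clustering of smoothed curves, cut at a fixed height.

    Curves enter in lexicographic protein-id order so the assignment is
    invariant to input ordering; a merge at exactly ``cut_height`` keeps
    the pair together (distance criterion is inclusive).
    """
    if traj.curves.shape[0] < 2:
        raise ValueError("need at least 2 curves to cluster")
    curves = traj.curves.sort_index()
    Z = hierarchy.linkage(pdist(curves.to_numpy(), metric="euclidean"), method=linkage)
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    assignment = pd.Series(flat, index=curves.index.copy(), name="cluster_id")
    traj.cluster_id = assignment
    return assignment


def merge_heights(traj: TrajectorySet, linkage: str = "complete") -> np.ndarray:
    """Dendrogram merge heights (sorted ascending), for diagnostics."""
    curves = traj.curves.sort_index()
    Z = hierarchy.linkage(pdist(curves.to_numpy(), metric="euclidean"), method=linkage)
    return Z[:, 2]


def cluster_matrisome_enrichment(
    assignment: pd.Series, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Upper-tail hypergeometric matrisome enrichment per cluster, BH over clusters.

    The background universe is the full measured proteome, i.e. every
    clustered protein; proteins missing from the annotation count as
    non-matrisome.
    """
    division = annotation["division"].reindex(assignment.index).fillna("non_matrisome")
    is_matrisome = division != "non_matrisome"
    out = set_enrichment(assignment, is_matrisome, side="over")
    out.index.name = "cluster_id"
    return out.rename(columns={"hits": "n_matrisome"})


def sasp_trajectory_contrast(
    traj: TrajectorySet, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Mean curves per (matrisome category × SASP flag) with 95% bands.

    Bands are pointwise normal approximations across proteins
    (mean ± 1.96·SD/√k); single-protein strata report the curve with the
    band omitted, empty strata are omitted entirely.
    """
    ann = annotation.reindex(traj.protein_ids)
    rows = []
    for (category, sasp), ids in ann.groupby(["category", "sasp"], observed=True).groups.items():
        ids = [i for i in ids if i in traj.curves.index]
        if not ids or category == "none":
            continue
        sub = traj.curves.loc[ids].to_numpy()
        mean = sub.mean(axis=0)
        if sub.shape[0] >= 2:
            half = 1.96 * sub.std(axis=0, ddof=1) / np.sqrt(sub.shape[0])
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.full_like(mean, np.nan)
        for age, m, l, h in zip(traj.age_grid, mean, lo, hi):
            rows.append(
                {"category": category, "sasp": bool(sasp), "n_proteins": sub.shape[0],
                 "age": age, "mean": m, "lo": l, "hi": h}
            )
    return pd.DataFrame(rows)
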