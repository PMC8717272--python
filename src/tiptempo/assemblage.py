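"""Assemblage-level spatialization of tip metrics and uncertainty.

Species-level TR/ST/LT estimates are averaged (unweighted) across the
species present at each sampled point, giving aTR/aST/aLT per point and
per (phylogeny, simulation) estimate.  Across-estimate means and
standard deviations summarize phylogenetic + mapping uncertainty; a
within/between-phylogeny randomization separates the two sources; Faith's
phylogenetic diversity and richness characterize each assemblage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tip_metrics import EstimateCube
from .tree_io import PhyloTree, lineage_nodes

__all__ = [
    "AssemblageMetrics",
    "assemblage_means",
    "uncertainty_summary",
    "subsample_estimates",
    "within_between_randomization",
    "faith_pd",
]

METRICS = ("aTR", "aST", "aLT")


@dataclass
class AssemblageMetrics:
    """Per-point aTR/aST/aLT over the (phylogeny x simulation) grid."""

    point_ids: list
    atr: np.ndarray      # (n_points, n_trees, n_sims)
    ast: np.ndarray
    alt: np.ndarray
    richness: np.ndarray  # (n_points,)

    @property
    def arrays(self) -> dict[str, np.ndarray]:
        return {"aTR": self.atr, "aST": self.ast, "aLT": self.alt}

    @property
    def n_estimates(self) -> int:
        return self.atr.shape[1] * self.atr.shape[2]


def assemblage_means(cube: EstimateCube, occurrence: pd.DataFrame
                     ) -> AssemblageMetrics:
    """Unweighted per-point species means of TR/ST/LT for every estimate.

    Every species occurring in ``occurrence`` must be in the cube.
    Points with zero species get NaN in all metrics and are excluded
    downstream (a warning reports how many).
    """
    missing = [sp for sp in occurrence.columns if sp not in cube.species]
    if missing:
        raise ValueError(f"species in occurrences but not in cube: {missing}")
    sp_idx = {s: i for i, s in enumerate(cube.species)}
    cols = np.array([sp_idx[s] for s in occurrence.columns])
    occ = occurrence.to_numpy(dtype=bool)
    n_points = occ.shape[0]
    _, nt, nm = cube.shape
    atr = np.full((n_points, nt, nm), np.nan)
    ast = np.full((n_points, nt, nm), np.nan)
    alt = np.full((n_points, nt, nm), np.nan)
    richness = occ.sum(axis=1)
    for i in range(n_points):
        if richness[i] == 0:
            continue
        idx = cols[occ[i]]
        atr[i] = cube.tr[idx].mean(axis=0)
        ast[i] = cube.st[idx].mean(axis=0)
        alt[i] = cube.lt[idx].mean(axis=0)
    n_empty = int((richness == 0).sum())
    if n_empty:
        warnings.warn(f"{n_empty} of {n_points} points have no species; "
                      "their assemblage metrics are NaN")
    return AssemblageMetrics(point_ids=list(occurrence.index), atr=atr,
                             ast=ast, alt=alt, richness=richness)


def uncertainty_summary(metrics: AssemblageMetrics) -> pd.DataFrame:
    """Across-estimate mean and sample SD (n-1) per point and metric."""
    if metrics.n_estimates < 2:
        raise ValueError("SD undefined with a single estimate")
    rows = []
    for name, arr in metrics.arrays.items():
        flat = arr.reshape(arr.shape[0], -1)
        rows.append(pd.DataFrame({
            "point_id": metrics.point_ids,
            "metric": name,
            "mean": flat.mean(axis=1),
            "sd": flat.std(axis=1, ddof=1),
            "richness": metrics.richness,
        }))
    return pd.concat(rows, ignore_index=True)


def subsample_estimates(n_trees: int, n_sims: int, m: int = 2000,
                        seed: int = 0) -> np.ndarray:
    """Uniform without-replacement sample of (phylogeny, simulation) pairs.

    Returns an (m, 2) int array of (tree_id, sim_id) pairs in canonical
    order; deterministic for a fixed seed.
    """
    total = n_trees * n_sims
    if m > total:
        raise ValueError(f"cannot subsample {m} of {total} estimates")
    rng = np.random.default_rng(seed)
    flat = np.sort(rng.choice(total, size=m, replace=False))
    return np.column_stack(np.divmod(flat, n_sims))


def within_between_randomization(metrics: AssemblageMetrics,
                                 n_rand: int = 1000, group_size: int = 10,
                                 seed: int = 0,
                                 independent_sims: bool = False
                                 ) -> dict[str, float]:
    """Proportion of randomizations with within-phylogeny SD < between.

    Each randomization pools, over all points, ``group_size`` estimates
    from simulations within one phylogeny (within-set) against
    ``group_size`` estimates taken one per phylogeny (between-set); by
    default the between-set shares a single simulation index, or one
    drawn independently per phylogeny with ``independent_sims``.  The
    pooled SDs are compared and the proportion of within < between is
    reported per metric.
    """
    npts, nt, nm = metrics.atr.shape
    if nt < group_size or nm < group_size:
        raise ValueError(
            f"need >= {group_size} phylogenies and simulations, "
            f"have {nt} x {nm}")
    rng = np.random.default_rng(seed)
    valid = ~np.isnan(metrics.atr[:, 0, 0])
    counts = {m: 0 for m in METRICS}
    arrays = {m: a[valid] for m, a in metrics.arrays.items()}
    for _ in range(n_rand):
        tree_w = rng.integers(nt)
        sims_w = rng.choice(nm, size=group_size, replace=False)
        trees_b = rng.choice(nt, size=group_size, replace=False)
        if independent_sims:
            sims_b = rng.integers(nm, size=group_size)
        else:
            sims_b = np.full(group_size, rng.integers(nm))
        for m, arr in arrays.items():
            within = arr[:, tree_w, sims_w]
            between = arr[:, trees_b, sims_b]
            if np.std(within) < np.std(between):
                counts[m] += 1
    return {m: counts[m] / n_rand for m in METRICS}


def faith_pd(tree: PhyloTree, species: list[str]) -> float:
    """Faith's PD: summed branch lengths of the minimal subtree spanning
    the given tips (root-inclusive convention)."""
    if not species:
        raise ValueError("Faith's PD needs at least one species")
    edges: set[int] = set()
    for sp in species:
        path = lineage_nodes(tree, sp)  # raises KeyError for unknown species
        edges.update(path[1:])
    return float(sum(tree.branch_length[v] for v in edges))
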