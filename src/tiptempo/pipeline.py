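"""End-to-end orchestration of a synthetic scenario through the pipeline.

Chains the full analysis on generated inputs: landscape and ranges,
tree set, ground-truth trait history, per-tree Mk refits, stochastic
maps, the TR/ST/LT estimate cube, core/ecotone point sampling, buffer
composition with exclusivity filtering, assemblage means, and the
core-vs-ecotone contrast.  This is what the ``simulate`` CLI subcommand
and the planted-effect recovery tests run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assemblage import AssemblageMetrics, assemblage_means
from .mk_model import build_rate_matrix
from .spatial_sampling import Landscape, buffer_composition, select_core_ecotone
from .stochastic_mapping import simulate_maps
from .synthetic_data import (SyntheticScenario, simulate_trait_history,
                             simulate_tree, simulate_tree_set,
                             synthetic_landscape, synthetic_ranges)
from .tip_metrics import EstimateCube, compute_cube
from .tree_io import PhyloTree, TreeSet

__all__ = ["ScenarioResult", "run_scenario", "core_ecotone_contrast"]


@dataclass
class ScenarioResult:
    scenario: SyntheticScenario
    landscape: Landscape
    truth_tree: PhyloTree
    tree_set: TreeSet
    tip_states: dict[str, int]
    affiliation: dict[str, str]          # species -> 'core' | 'ecotone'
    cube: EstimateCube
    points: pd.DataFrame
    occurrence: pd.DataFrame
    metrics: AssemblageMetrics
    contrast: dict[str, float] = field(default_factory=dict)


def _ecotone_branch_multipliers(tree: PhyloTree, affiliation: dict[str, int],
                                multiplier: float) -> np.ndarray:
    """Rate multiplier per branch: boosted where every descendant tip is
    ecotone-affiliated (with tip-by-tip affiliation this is essentially
    the terminal branches of ecotone species)."""
    mult = np.ones(tree.n_nodes)
    all_eco = np.zeros(tree.n_nodes, dtype=bool)
    for v in range(tree.n_nodes - 1, -1, -1):
        kids = tree.children[v]
        if not kids:
            all_eco[v] = affiliation[tree.tip_label[v]] == "ecotone"
        else:
            all_eco[v] = all(all_eco[c] for c in kids)
        if all_eco[v]:
            mult[v] = multiplier
    return mult


def run_scenario(scenario: SyntheticScenario, model: str = "ER",
                 max_trait_retries: int = 20) -> ScenarioResult:
    """Generate a scenario's inputs and run the full analysis on them."""
    sc = scenario
    master = np.random.SeedSequence(sc.seed)
    s_tree, s_trait, s_set, s_land, s_range, s_map, s_assign = master.spawn(7)

    landscape = synthetic_landscape(sc.landscape_rows, sc.landscape_cols,
                                    sc.ecoregion_size_km, sc.habitat_rule,
                                    seed=s_land.entropy % (2**31))
    truth_tree = simulate_tree(sc.n_tips, sc.birth_rate, sc.death_rate,
                               np.random.default_rng(s_tree))
    species = sorted(truth_tree.tip_labels)
    # Randomized-block affiliation: phylogenetically adjacent tips (label
    # order = preorder, so consecutive labels are usually close relatives)
    # are paired, and a fair coin decides which member of each pair is
    # core- vs ecotone-affiliated.  The coin flip makes the core-ecotone
    # comparison exactly unbiased under the null, while pairing within
    # clades cancels clade-level noise in the contrast.  Both members of
    # a pair share a home ecoregion (blocking extends to space).
    assign_rng = np.random.default_rng(s_assign)
    affiliation: dict[str, str] = {}
    home: dict[str, str] = {}
    eco_ids = landscape.ids
    for p, i in enumerate(range(0, len(species) - 1, 2)):
        first_is_core = bool(assign_rng.integers(2))
        a, b = species[i], species[i + 1]
        affiliation[a] = "core" if first_is_core else "ecotone"
        affiliation[b] = "ecotone" if first_is_core else "core"
        home[a] = home[b] = eco_ids[p % len(eco_ids)]
    if len(species) % 2:  # odd species count: last one unpaired
        sp = species[-1]
        affiliation[sp] = "core" if assign_rng.integers(2) else "ecotone"
        home[sp] = eco_ids[(len(species) // 2) % len(eco_ids)]
    biases = {sp: (0.95 if aff == "ecotone" else 0.05)
              for sp, aff in affiliation.items()}
    ranges = synthetic_ranges(species, landscape, sc.range_log_mean,
                              sc.range_log_sd, placement_bias=biases,
                              seed=s_range.entropy % (2**31), home=home)
    tree_set = simulate_tree_set(truth_tree, sc.n_trees, sc.jitter,
                                 seed=s_set.entropy % (2**31))

    Q_true = build_rate_matrix([sc.base_rate], "ER", sc.k_states)
    mult = _ecotone_branch_multipliers(truth_tree, affiliation,
                                       sc.planted_multiplier)
    trait_rng = np.random.default_rng(s_trait)
    tip_states = None
    for _ in range(max_trait_retries):
        _, candidate = simulate_trait_history(
            truth_tree, Q_true, seed=trait_rng, branch_rate_multiplier=mult)
        if len(set(candidate.values())) >= 2:
            tip_states = candidate
            break
    if tip_states is None:
        raise RuntimeError("trait simulation kept producing a single state; "
                           "increase base_rate or tree depth")

    maps = simulate_maps(tree_set, tip_states, model=model,
                         n_sim_per_tree=sc.n_sims,
                         seed=s_map.entropy % (2**31), k=sc.k_states)
    cube = compute_cube(maps, species=species)

    points = select_core_ecotone(landscape, sc.cell_width_km, sc.k_points)
    occurrence = buffer_composition(points, ranges, sc.buffer_radius_km)
    metrics = assemblage_means(cube, occurrence)

    result = ScenarioResult(scenario=sc, landscape=landscape,
                            truth_tree=truth_tree, tree_set=tree_set,
                            tip_states=tip_states, affiliation=affiliation,
                            cube=cube, points=points, occurrence=occurrence,
                            metrics=metrics)
    result.contrast = core_ecotone_contrast(metrics, points)
    return result


def core_ecotone_contrast(metrics: AssemblageMetrics, points: pd.DataFrame
                          ) -> dict[str, float]:
    """mean(ecotone points) - mean(core points) of across-estimate point
    means, per metric; NaN points (no species) are ignored."""
    pos = points.set_index("point_id").loc[metrics.point_ids, "position"]
    is_eco = (pos == "ecotone").to_numpy()
    out = {}
    for name, arr in metrics.arrays.items():
        per_point = arr.reshape(arr.shape[0], -1).mean(axis=1)
        with np.errstate(invalid="ignore"):
            out[name] = float(np.nanmean(per_point[is_eco])
                              - np.nanmean(per_point[~is_eco]))
    return out
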