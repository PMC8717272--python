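"""Synthetic inputs for the whole pipeline: trees, traits, landscapes, ranges.

Everything the real analysis would read from external sources — a set of
dated phylogenies, a discrete trait evolving under an Mk process, a
tiled landscape of ecoregions with forest/open habitats, and species
range polygons with right-skewed sizes — is generated here from a single
seed, with the ground-truth character history kept alongside so that
mapping and metric code can be checked against what actually happened.

A planted "ecotone effect" (a transition-intensity multiplier on the
branches leading to ecotone-affiliated species) lets end-to-end tests
verify both that the pipeline invents no signal when none is planted
and that it recovers the sign of a real one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from shapely.geometry import Point, Polygon, box

from .mk_model import RateMatrix, build_rate_matrix
from .spatial_sampling import Landscape
from .stochastic_mapping import MappedHistory, _forward_path
from .tree_io import PhyloTree, TreeSet

__all__ = [
    "SyntheticScenario",
    "simulate_tree",
    "simulate_trait_history",
    "simulate_tree_set",
    "synthetic_landscape",
    "synthetic_ranges",
]


@dataclass
class SyntheticScenario:
    """All parameters of one synthetic study, fully determined by the seed.

    Defaults mirror the real study design at generation scale: a 4-state
    trait under a symmetric Mk process on dated ultrametric trees, a
    grid of contiguous ecoregions with forest/open habitats, and
    log-normal (right-skewed) range sizes.
    """

    seed: int = 0
    n_tips: int = 40
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_trees: int = 10
    n_sims: int = 10
    jitter: float = 0.1
    k_states: int = 4
    base_rate: float = 0.1          # per-pair ER rate, events per Ma
    planted_multiplier: float = 1.0  # 1.0 = no planted ecotone effect
    landscape_rows: int = 3
    landscape_cols: int = 3
    ecoregion_size_km: float = 150.0
    habitat_rule: str = "checkerboard"
    cell_width_km: float = 20.0
    k_points: int = 10
    buffer_radius_km: float = 10.0
    range_log_mean: float = np.log(1200.0)  # log km^2; median ~20 km radius
    range_log_sd: float = 0.6

    def manifest(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


# -- trees -------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  death_rate: float = 0.0, seed: int | np.random.Generator = 0,
                  max_retries: int = 100) -> PhyloTree:
    """Constant-rate birth-death tree conditioned on ``n_tips`` extant tips.

    Forward simulation from two root lineages; when the extant count
    first reaches ``n_tips`` the process runs for one more exponential
    waiting time (the standard stop-just-before-the-next-event snapshot,
    so that under pure birth the expected root age is
    sum_{k=2..n} 1/(b k)).  Extinct subtrees are pruned; full extinction
    triggers a retry up to ``max_retries``.
    """
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _simulate_bd_once(n_tips, birth_rate, death_rate, rng)
        if tree is not None:
            return tree
    raise RuntimeError(f"all lineages went extinct in {max_retries} attempts")


def _simulate_bd_once(n_tips, b, d, rng) -> PhyloTree | None:
    # node records: parent index, time its branch started, time it ended
    parent = [-1, 0, 0]
    start = [0.0, 0.0, 0.0]
    end: list[float | None] = [0.0, None, None]
    extinct: set[int] = set()
    active = [1, 2]
    t = 0.0
    total = b + d
    while len(active) != n_tips:
        k = len(active)
        if k == 0:
            return None
        t += rng.exponential(1.0 / (total * k))
        v = active.pop(rng.integers(k))
        end[v] = t
        if rng.random() < b / total:
            for _ in range(2):
                parent.append(v)
                start.append(t)
                end.append(None)
                active.append(len(parent) - 1)
        else:
            extinct.add(v)
    t += rng.exponential(1.0 / (total * n_tips))
    for v in active:
        end[v] = t
    return _assemble_tree(parent, start, end, extinct, rng)


def _assemble_tree(parent, start, end, extinct, rng) -> PhyloTree | None:
    n = len(parent)
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for v in range(1, n):
        children[parent[v]].append(v)
    alive = [False] * n

    def mark(v) -> bool:
        kids = children[v]
        if not kids:
            alive[v] = v not in extinct
        else:
            alive[v] = any([mark(c) for c in kids])
        return alive[v]

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        if not mark(0):
            return None
    finally:
        sys.setrecursionlimit(old)

    # collapse dead subtrees and unary pass-through nodes, assign preorder ids
    new_parent: list[int] = []
    new_children: list[list[int]] = []
    new_blen: list[float] = []
    tip_label: dict[int, str] = {}
    label_counter = [0]

    def build(v: int, new_p: int, extra_len: float) -> None:
        kids = [c for c in children[v] if alive[c]]
        blen = (end[v] - start[v]) + extra_len
        if len(kids) == 1 and v != 0:
            build(kids[0], new_p, blen)
            return
        nid = len(new_parent)
        new_parent.append(new_p)
        new_children.append([])
        new_blen.append(0.0 if new_p < 0 else blen)
        if new_p >= 0:
            new_children[new_p].append(nid)
        if not kids:
            tip_label[nid] = f"s{label_counter[0]:04d}"
            label_counter[0] += 1
        for c in kids:
            build(c, nid, 0.0)

    root_kids = [c for c in children[0] if alive[c]]
    if len(root_kids) < 2:
        return None  # one whole side died: root would be unary
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 100))
    try:
        build(0, -1, 0.0)
    finally:
        sys.setrecursionlimit(old_limit)
    return PhyloTree(parent=np.array(new_parent), children=new_children,
                     branch_length=np.array(new_blen), tip_label=tip_label)


def simulate_tree_set(base_tree: PhyloTree | None = None, n_trees: int = 10,
                      jitter: float = 0.1, seed: int = 0,
                      n_tips: int = 40, birth_rate: float = 1.0,
                      death_rate: float = 0.0) -> TreeSet:
    """A set of trees sharing a tip set with controllable between-tree variance.

    Starting from ``base_tree`` (simulated if not given), each member
    tree gets (a) a global depth factor and per-branch length noise,
    both log-normal with sigma proportional to ``jitter``, and (b)
    ``round(jitter * n_tips)`` random tip-label swaps, which vary the
    topology relative to the shared label set.  Trees are re-dated to
    ultrametric by extending terminal branches to the deepest tip.
    ``jitter=0`` returns identical copies.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_trees + 1)
    if base_tree is None:
        base_tree = simulate_tree(n_tips, birth_rate, death_rate,
                                  np.random.default_rng(streams[0]))
    trees = []
    n = base_tree.n_tips
    for i in range(n_trees):
        rng = np.random.default_rng(streams[i + 1])
        blen = base_tree.branch_length.copy()
        if jitter > 0:
            blen = blen * np.exp(rng.normal(0.0, jitter, size=len(blen))) \
                * np.exp(rng.normal(0.0, jitter))
        labels = dict(base_tree.tip_label)
        n_swaps = int(round(jitter * n))
        tip_ids = sorted(labels)
        for _ in range(n_swaps):
            a, b2 = rng.choice(len(tip_ids), size=2, replace=False)
            ia, ib = tip_ids[a], tip_ids[b2]
            labels[ia], labels[ib] = labels[ib], labels[ia]
        tree = PhyloTree(parent=base_tree.parent.copy(),
                         children=[list(c) for c in base_tree.children],
                         branch_length=blen, tip_label=labels)
        trees.append(_make_ultrametric(tree))
    return TreeSet(trees=trees, provenance=f"synthetic jitter={jitter}")


def _make_ultrametric(tree: PhyloTree) -> PhyloTree:
    """Extend terminal branches so every tip reaches the deepest depth."""
    d = tree.depths()
    target = max(d[v] for v in tree.tips)
    blen = tree.branch_length.copy()
    for v in tree.tips:
        blen[v] += target - d[v]
    return PhyloTree(parent=tree.parent, children=tree.children,
                     branch_length=blen, tip_label=tree.tip_label)


# -- traits ------------------------------------------------------------


def simulate_trait_history(tree: PhyloTree, Q: RateMatrix,
                           root_state: int | None = None,
                           seed: int | np.random.Generator = 0,
                           branch_rate_multiplier: np.ndarray | None = None
                           ) -> tuple[MappedHistory, dict[str, int]]:
    """Forward CTMC simulation of a trait along every branch.

    Returns the full (ground-truth) mapped history and the tip states
    read off it.  ``branch_rate_multiplier`` scales Q on selected
    branches (indexed by child node), which is how a transition-
    intensity contrast is planted for lineage subsets.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = Q.k
    if root_state is None:
        root_state = int(rng.choice(k, p=Q.stationary_distribution()))
    node_state = np.zeros(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = root_state
    segments: dict[int, list[tuple[int, float]]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        mult = 1.0 if branch_rate_multiplier is None \
            else float(branch_rate_multiplier[v])
        segs = _forward_path(int(node_state[tree.parent[v]]),
                             float(tree.branch_length[v]), Q.Q * mult, rng)
        segments[v] = segs
        node_state[v] = segs[-1][0]
    history = MappedHistory(tree=tree, node_state=node_state,
                            segments=segments)
    tip_states = {lab: int(node_state[nid])
                  for nid, lab in tree.tip_label.items()}
    return history, tip_states


# -- landscape and ranges ---------------------------------------------


def synthetic_landscape(n_rows: int = 3, n_cols: int = 3,
                        ecoregion_size_km: float = 150.0,
                        habitat_rule: str = "checkerboard",
                        seed: int = 0) -> Landscape:
    """A plane tiled by rectangular ecoregions with habitat labels.

    Habitats by ``checkerboard`` (every neighbor pair contrasts),
    ``random``, or ``blocks`` (left half forest, right half open).  The
    westernmost column is flagged as the Andes region, the easternmost
    as the Atlantic Rainforest, mimicking the two named-region
    covariates of the sampling design.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("landscape grid must be at least 2x2")
    rng = np.random.default_rng(seed)
    polygons: dict[str, Polygon] = {}
    habitat: dict[str, str] = {}
    andes, atlantic = set(), set()
    s = ecoregion_size_km
    for r in range(n_rows):
        for c in range(n_cols):
            eid = f"E{r:02d}_{c:02d}"
            polygons[eid] = box(c * s, r * s, (c + 1) * s, (r + 1) * s)
            if habitat_rule == "checkerboard":
                habitat[eid] = "forest" if (r + c) % 2 == 0 else "open"
            elif habitat_rule == "random":
                habitat[eid] = "forest" if rng.random() < 0.5 else "open"
            elif habitat_rule == "blocks":
                habitat[eid] = "forest" if c < n_cols / 2 else "open"
            else:
                raise ValueError(f"unknown habitat rule {habitat_rule!r}")
            if c == 0:
                andes.add(eid)
            if c == n_cols - 1:
                atlantic.add(eid)
    return Landscape(polygons=polygons, habitat=habitat, andes=andes,
                     atlantic=atlantic)


def synthetic_ranges(species: list[str], landscape: Landscape,
                     log_mean: float = np.log(1200.0), log_sd: float = 0.6,
                     placement_bias: dict[str, float] | float = 0.5,
                     seed: int = 0,
                     home: dict[str, str] | None = None) -> dict[str, Polygon]:
    """One circular range polygon per species, clipped to the landscape.

    Range areas (km^2) are log-normal, hence right-skewed.  Each
    species is assigned a home ecoregion round-robin (or per the
    ``home`` mapping); its range center sits on the segment from the
    ecoregion centroid to a random boundary point, at fraction
    ``placement_bias`` (0 = dead center / core-affiliated, 1 = on the
    boundary / ecotone-affiliated).  A scalar bias applies to all
    species; a dict gives per-species biases.
    """
    rng = np.random.default_rng(seed)
    ids = landscape.ids
    hull = None
    for p in landscape.polygons.values():
        hull = p if hull is None else hull.union(p)
    ranges: dict[str, Polygon] = {}
    for i, sp in enumerate(species):
        eid = home[sp] if home is not None else ids[i % len(ids)]
        poly = landscape.polygons[eid]
        bias = placement_bias[sp] if isinstance(placement_bias, dict) \
            else float(placement_bias)
        if not 0.0 <= bias <= 1.0:
            raise ValueError(f"placement bias for {sp!r} outside [0, 1]")
        centroid = poly.centroid
        bpt = poly.exterior.interpolate(rng.random(), normalized=True)
        cx = centroid.x + bias * (bpt.x - centroid.x)
        cy = centroid.y + bias * (bpt.y - centroid.y)
        area = float(np.exp(rng.normal(log_mean, log_sd)))
        radius = np.sqrt(area / np.pi)
        ranges[sp] = Point(cx, cy).buffer(radius, quad_segs=32).intersection(hull)
    return ranges
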