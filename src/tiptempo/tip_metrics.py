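"""Tip-based metrics of discrete-trait evolution: TR, ST and LT.

For each species the root-to-tip lineage is read off a stochastic map:

* Transition Rate ``TR = t / N`` — the number of state changes fixed at
  the nodes along the lineage (including the last-node-to-tip
  comparison), divided by the number of internal nodes N on the path
  (root included, tip excluded).  TR is 0 when tip and root state never
  changed at a node and 1 when every node comparison changed.
* Stasis Time ``ST`` — the longest contiguous stretch of time (Ma) the
  lineage spent in the current tip state, anywhere along its history.
  Runs are built from within-branch dwell segments and merged across
  node boundaries, so a brief within-branch excursion away from the
  state truncates a run even though it is invisible to TR.
* Last Transition Time ``LT`` — the duration (Ma) of the terminal run
  in the tip state: the time since the lineage last entered the state
  it has today.  A lineage that never changed has ST = LT = its depth.

Per-species values across (phylogeny x simulation) maps are collected in
an :class:`EstimateCube` for downstream uncertainty propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stochastic_mapping import MappedHistory
from .tree_io import PhyloTree, lineage_nodes

__all__ = [
    "LineagePath",
    "EstimateCube",
    "extract_lineage",
    "transition_rate",
    "stasis_time",
    "last_transition_time",
    "compute_cube",
]


@dataclass
class LineagePath:
    """The root-to-tip history of one species on one map."""

    species: str
    tip_state: int
    node_ids: list[int]          # root ... tip
    node_states: list[int]       # state at each node on the path
    node_ages: list[float]       # Ma before present
    segments: list[tuple[int, float]]  # concatenated root->tip dwell segments
    st_mode: str = "runs"
    count_tip_node: bool = False

    @property
    def n_internal(self) -> int:
        """N: nodes on the path counted for TR's denominator.

        Default: internal nodes only (root included, tip excluded),
        which makes TR = 1 attainable; ``count_tip_node`` adds the tip.
        """
        return len(self.node_ids) - (0 if self.count_tip_node else 1)

    @property
    def n_changes(self) -> int:
        """t: state changes over the N node comparisons (tip included)."""
        return sum(a != b for a, b in zip(self.node_states,
                                          self.node_states[1:]))

    @property
    def depth(self) -> float:
        """Time span of the lineage (root age minus tip age, Ma)."""
        return self.node_ages[0] - self.node_ages[-1]

    def runs(self) -> list[tuple[int, float]]:
        """Maximal contiguous constant-state runs along the lineage."""
        merged: list[tuple[int, float]] = []
        for s, d in self.segments:
            if merged and merged[-1][0] == s:
                merged[-1] = (s, merged[-1][1] + d)
            else:
                merged.append((int(s), float(d)))
        return merged


def extract_lineage(mapped: MappedHistory, species: str,
                    st_mode: str = "runs",
                    count_tip_node: bool = False) -> LineagePath:
    """Read the root-to-tip path of ``species`` off one stochastic map."""
    tree = mapped.tree
    path = lineage_nodes(tree, species)
    ages = tree.ages
    segments: list[tuple[int, float]] = []
    for v in path[1:]:
        segments.extend(mapped.segments[v])
    return LineagePath(
        species=species,
        tip_state=int(mapped.node_state[path[-1]]),
        node_ids=path,
        node_states=[int(mapped.node_state[v]) for v in path],
        node_ages=[float(ages[v]) for v in path],
        segments=segments,
        st_mode=st_mode,
        count_tip_node=count_tip_node,
    )


def transition_rate(path: LineagePath) -> float:
    """TR = t / N: node-fixed state changes per node along the lineage.

    Within-branch excursions that return to the same state before the
    next node are not counted — only changes fixed at the nodes (or at
    the tip) are.
    """
    if path.n_internal < 1:
        raise RuntimeError("lineage with no internal node (tip at root?)")
    return path.n_changes / path.n_internal


def stasis_time(path: LineagePath) -> float:
    """ST: longest contiguous dwell (Ma) in the tip state along the lineage.

    In the default ``runs`` mode dwell segments are merged across node
    boundaries, so a run can span several branches; brief within-branch
    flips truncate it.  In ``branchwise`` mode the maximum single
    segment dwell is returned instead (compatibility mode).
    """
    a = path.tip_state
    if path.st_mode == "branchwise":
        durations = [d for s, d in path.segments if s == a]
        return max(durations, default=0.0)
    return max((d for s, d in path.runs() if s == a), default=0.0)


def last_transition_time(path: LineagePath) -> float:
    """LT: duration (Ma) of the terminal contiguous run in the tip state.

    Measures the time since the lineage last entered the state observed
    at the tip; equals the full lineage depth when the state never
    changed, and is cut short by any excursion, however brief.
    """
    a = path.tip_state
    total = 0.0
    for s, d in reversed(path.segments):
        if s != a:
            break
        total += d
    return total


@dataclass
class EstimateCube:
    """TR/ST/LT (and their ingredients) per species x phylogeny x simulation."""

    species: list[str]
    tr: np.ndarray          # (n_species, n_trees, n_sims)
    st: np.ndarray
    lt: np.ndarray
    n_changes: np.ndarray   # t per record
    n_nodes: np.ndarray     # N per record

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tr.shape

    @property
    def n_estimates(self) -> int:
        return self.shape[1] * self.shape[2]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: species, tree_id, sim_id, TR, ST, LT."""
        ns, nt, nm = self.shape
        sp, tr_i, si = np.meshgrid(np.arange(ns), np.arange(nt),
                                   np.arange(nm), indexing="ij")
        return pd.DataFrame({
            "species": np.asarray(self.species)[sp.ravel()],
            "tree_id": tr_i.ravel(),
            "sim_id": si.ravel(),
            "TR": self.tr.ravel(),
            "ST": self.st.ravel(),
            "LT": self.lt.ravel(),
        })

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EstimateCube":
        species = sorted(df["species"].unique())
        nt = int(df["tree_id"].max()) + 1
        nm = int(df["sim_id"].max()) + 1
        shape = (len(species), nt, nm)
        arrays = {m: np.full(shape, np.nan) for m in ("TR", "ST", "LT")}
        sp_idx = {s: i for i, s in enumerate(species)}
        rows = df["species"].map(sp_idx).to_numpy()
        cols = (df["tree_id"].to_numpy(), df["sim_id"].to_numpy())
        for m in ("TR", "ST", "LT"):
            arrays[m][rows, cols[0], cols[1]] = df[m].to_numpy()
        if any(np.isnan(a).any() for a in arrays.values()):
            raise ValueError("incomplete cube: missing (species, tree, sim) cells")
        return cls(species=species, tr=arrays["TR"], st=arrays["ST"],
                   lt=arrays["LT"], n_changes=np.zeros(shape),
                   n_nodes=np.zeros(shape))


def compute_cube(maps: list[MappedHistory], species: list[str] | None = None,
                 st_mode: str = "runs") -> EstimateCube:
    """Evaluate TR/ST/LT for every species on every map.

    Maps must cover a full (tree x simulation) grid and every species
    must be a tip of every map's tree; the cube has no missing cells.
    """
    if not maps:
        raise ValueError("no maps given")
    if species is None:
        species = sorted(maps[0].tree.tip_labels)
    tree_ids = sorted({m.tree_index for m in maps})
    sim_ids = sorted({m.sim_index for m in maps})
    ti_of = {t: i for i, t in enumerate(tree_ids)}
    si_of = {s: i for i, s in enumerate(sim_ids)}
    shape = (len(species), len(tree_ids), len(sim_ids))
    tr = np.full(shape, np.nan)
    st = np.full(shape, np.nan)
    lt = np.full(shape, np.nan)
    nch = np.full(shape, np.nan)
    nnod = np.full(shape, np.nan)
    for m in maps:
        tips = set(m.tree.tip_labels)
        for j, sp in enumerate(species):
            if sp not in tips:
                raise ValueError(
                    f"species {sp!r} missing from tree {m.tree_index}")
            path = extract_lineage(m, sp, st_mode=st_mode)
            a, b = ti_of[m.tree_index], si_of[m.sim_index]
            tr[j, a, b] = transition_rate(path)
            st[j, a, b] = stasis_time(path)
            lt[j, a, b] = last_transition_time(path)
            nch[j, a, b] = path.n_changes
            nnod[j, a, b] = path.n_internal
    if np.isnan(tr).any():
        raise ValueError("maps do not cover the full (tree x simulation) grid")
    return EstimateCube(species=list(species), tr=tr, st=st, lt=lt,
                        n_changes=nch, n_nodes=nnod)
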