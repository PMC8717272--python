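"""Stochastic character mapping: full trait histories on dated trees.

Given tip states and a fitted Mk model, draws joint samples of internal
node states from their posterior (root draw followed by preorder
conditional draws) and fills in within-branch change times with
endpoint-conditioned CTMC paths.  Path sampling tries cheap rejection
sampling of forward paths first and falls back to exact uniformization
when the endpoint pair is too improbable, so sampling always terminates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mk_model import (MkFit, RateMatrix, _pruning_partials, fit_mk,
                       transition_probabilities)
from .tree_io import PhyloTree, TreeSet

__all__ = [
    "MappedHistory",
    "SamplingError",
    "sample_node_states",
    "sample_branch_history",
    "simulate_maps",
    "maps_to_csv",
    "maps_from_csv",
]


class SamplingError(RuntimeError):
    """Raised when a conditioned sample cannot be drawn."""


@dataclass
class MappedHistory:
    """One stochastic map on one tree.

    ``segments[v]`` is the ordered (state, duration) list along the
    branch from ``parent(v)`` to ``v``; the first segment starts in the
    parent's state, the last ends in the child's state, consecutive
    segments differ in state, and durations sum to the branch length.
    """

    tree: PhyloTree
    node_state: np.ndarray                 # int state per node id
    segments: dict[int, list[tuple[int, float]]]
    tree_index: int = 0
    sim_index: int = 0
    seed: int | None = None

    def validate(self, atol: float = 1e-9) -> None:
        for v in range(self.tree.n_nodes):
            if v == self.tree.root:
                continue
            segs = self.segments[v]
            blen = self.tree.branch_length[v]
            total = sum(d for _, d in segs)
            if abs(total - blen) > atol:
                raise ValueError(f"branch {v}: segment durations sum to "
                                 f"{total}, branch length {blen}")
            if segs[0][0] != self.node_state[self.tree.parent[v]]:
                raise ValueError(f"branch {v}: first segment state differs "
                                 "from parent node state")
            if segs[-1][0] != self.node_state[v]:
                raise ValueError(f"branch {v}: last segment state differs "
                                 "from child node state")
            for (s0, d0), (s1, _) in zip(segs, segs[1:]):
                if s0 == s1:
                    raise ValueError(f"branch {v}: consecutive segments share "
                                     "a state")
                if d0 <= 0:
                    raise ValueError(f"branch {v}: non-terminal zero segment")

    @property
    def n_changes(self) -> int:
        """Total number of state-change events across all branches."""
        return sum(len(s) - 1 for v, s in self.segments.items())

    def total_dwell(self) -> float:
        return sum(d for segs in self.segments.values() for _, d in segs)


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray
                        ) -> np.ndarray:
    """Vectorized categorical draw; probs has shape (m, k), rows sum to 1."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])[:, None]
    return np.argmax(u < cum, axis=1)


def sample_node_states(tree: PhyloTree, tip_states: dict[str, int],
                       Q: RateMatrix, root_prior: np.ndarray,
                       rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Joint posterior draws of the state at every node.

    The root is drawn from prior x partial likelihood; descendants are
    drawn preorder conditional on the sampled parent state.  Returns an
    int array of shape (n_nodes,) for ``size == 1`` else
    (size, n_nodes).  Tip states are fixed at their observed values.
    """
    root_prior = np.asarray(root_prior, dtype=float)
    partials, P, _ = _pruning_partials(tree, tip_states, Q)
    states = np.empty((size, tree.n_nodes), dtype=np.int64)
    w = root_prior * partials[tree.root]
    tot = w.sum()
    if tot <= 0:
        raise SamplingError("zero posterior mass at root")
    states[:, tree.root] = _sample_categorical(
        rng, np.broadcast_to(w / tot, (size, Q.k)))
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        ps = states[:, tree.parent[v]]
        probs = P[v][ps] * partials[v][None, :]
        tots = probs.sum(axis=1, keepdims=True)
        if np.any(tots <= 0):
            raise SamplingError(f"zero posterior mass at node {v}")
        states[:, v] = _sample_categorical(rng, probs / tots)
    return states[0] if size == 1 else states


def _forward_path(state: int, t: float, Q: np.ndarray,
                  rng: np.random.Generator) -> list[tuple[int, float]]:
    """Unconditioned forward CTMC path over duration t from ``state``."""
    segs: list[tuple[int, float]] = []
    k = Q.shape[0]
    remaining = t
    s = state
    while True:
        exit_rate = -Q[s, s]
        wait = np.inf if exit_rate <= 0 else rng.exponential(1.0 / exit_rate)
        if wait >= remaining:
            segs.append((s, remaining))
            return segs
        segs.append((s, wait))
        remaining -= wait
        probs = Q[s].copy()
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(k, p=probs))


def _uniformization_path(a: int, b: int, t: float, Q: np.ndarray,
                         rng: np.random.Generator) -> list[tuple[int, float]]:
    """Exact endpoint-conditioned path via uniformization.

    A dominating Poisson process at rate mu >= max exit rate converts
    the CTMC into a discrete chain R = I + Q/mu; the conditioned number
    of (possibly virtual) jumps is drawn from its exact distribution,
    the jump states from the discrete bridge, the jump times as uniform
    order statistics, and virtual (self) jumps are then collapsed.
    """
    k = Q.shape[0]
    mu = 1.05 * max(-Q.diagonal().min(), 1e-12)
    R = np.eye(k) + Q / mu
    p_ab = transition_probabilities(Q, t)[a, b]
    if p_ab <= 0:
        raise SamplingError(f"endpoint pair ({a}->{b}) impossible over t={t}")
    # p(n) proportional to Poisson(mu t)(n) * R^n[a, b]
    u = rng.random() * p_ab
    Rp = [np.eye(k)]
    pois = np.exp(-mu * t)
    cum = pois * Rp[0][a, b]
    n = 0
    while cum < u:
        n += 1
        Rp.append(Rp[-1] @ R)
        pois *= mu * t / n
        cum += pois * Rp[n][a, b]
        if n > 100000:  # pragma: no cover - unreachable for sane rates
            raise SamplingError("uniformization jump count overflow")
    # bridge over jump states
    states = [a]
    for j in range(1, n):
        prev = states[-1]
        w = R[prev] * Rp[n - j][:, b]
        w_sum = w.sum()
        states.append(int(rng.choice(k, p=w / w_sum)))
    if n > 0:
        states.append(b)
    times = np.sort(rng.random(n)) * t
    bounds = np.concatenate([[0.0], times, [t]])
    segs: list[tuple[int, float]] = []
    for s, d in zip(states, np.diff(bounds)):
        if segs and segs[-1][0] == s:
            segs[-1] = (s, segs[-1][1] + d)
        elif d > 0 or not segs:
            segs.append((int(s), float(d)))
        else:
            segs.append((int(s), float(d)))
    # collapse any zero-length interior artifacts
    merged: list[tuple[int, float]] = []
    for s, d in segs:
        if merged and merged[-1][0] == s:
            merged[-1] = (s, merged[-1][1] + d)
        else:
            merged.append((s, d))
    return merged


def sample_branch_history(state_a: int, state_b: int, t: float,
                          Q: RateMatrix | np.ndarray,
                          rng: np.random.Generator,
                          max_rejections: int = 10000
                          ) -> list[tuple[int, float]]:
    """Endpoint-conditioned path from ``state_a`` to ``state_b`` over t.

    Rejection sampling of forward paths is tried first (cheap when the
    endpoints are probable); after ``max_rejections`` failures the exact
    uniformization sampler takes over, so the call always terminates.
    """
    if t < 0:
        raise ValueError("negative duration")
    Qm = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, float)
    if t == 0:
        if state_a != state_b:
            raise SamplingError("zero-length branch with differing endpoints")
        return [(int(state_a), 0.0)]
    for _ in range(max_rejections):
        segs = _forward_path(int(state_a), t, Qm, rng)
        if segs[-1][0] == state_b:
            return segs
    return _uniformization_path(int(state_a), int(state_b), t, Qm, rng)


def _history_from_node_states(tree: PhyloTree, node_state: np.ndarray,
                              Q: RateMatrix, rng: np.random.Generator,
                              tree_index: int = 0, sim_index: int = 0,
                              seed: int | None = None) -> MappedHistory:
    segments: dict[int, list[tuple[int, float]]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        a = int(node_state[tree.parent[v]])
        b = int(node_state[v])
        segments[v] = sample_branch_history(
            a, b, float(tree.branch_length[v]), Q, rng)
    return MappedHistory(tree=tree, node_state=np.asarray(node_state),
                         segments=segments, tree_index=tree_index,
                         sim_index=sim_index, seed=seed)


def simulate_maps(tree_set: TreeSet, tip_states: dict[str, int],
                  model: str = "SYM", n_sim_per_tree: int = 100,
                  seed: int = 0, root_prior_mode: str = "stationary",
                  k: int | None = None,
                  fits: list[MkFit] | None = None) -> list[MappedHistory]:
    """Simmap ensemble: refit Q on each tree, draw n maps per tree.

    The Mk model is re-fitted per phylogeny (topology and branch lengths
    differ across trees); pass ``fits`` to reuse existing per-tree fits.
    One master seed spawns a deterministic substream per (tree,
    simulation) pair, so any subset is reproducible in isolation.
    Trees whose fit fails are skipped with a warning.
    """
    master = np.random.SeedSequence(seed)
    tree_seqs = master.spawn(len(tree_set))
    maps: list[MappedHistory] = []
    n_failed = 0
    for ti, tree in enumerate(tree_set):
        try:
            fit = fits[ti] if fits is not None else fit_mk(
                tree, tip_states, model, root_prior_mode=root_prior_mode, k=k)
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            warnings.warn(f"Mk fit failed on tree {ti}: {exc}; tree skipped")
            continue
        Q = fit.rate_matrix
        sim_seqs = tree_seqs[ti].spawn(n_sim_per_tree)
        for si in range(n_sim_per_tree):
            rng = np.random.default_rng(sim_seqs[si])
            node_state = sample_node_states(
                tree, tip_states, Q, fit.root_prior, rng)
            maps.append(_history_from_node_states(
                tree, node_state, Q, rng, tree_index=ti, sim_index=si))
    if n_failed:
        warnings.warn(f"{n_failed} of {len(tree_set)} trees skipped due to "
                      "fit failures")
    return maps


def consensus_node_states(maps: list[MappedHistory],
                          tree_index: int | None = None) -> np.ndarray:
    """Modal node states across maps of one tree, with a dwell tie-break.

    For each node the most frequent sampled state is returned; exact
    frequency ties go to the state with the longer total dwell time on
    the branches incident to that node (summed over the tied maps) —
    the "state present longer at that node" rule for summarized maps.
    """
    pool = [m for m in maps
            if tree_index is None or m.tree_index == tree_index]
    if not pool:
        raise ValueError("no maps for the requested tree")
    tree = pool[0].tree
    k = int(max(m.node_state.max() for m in pool)) + 1
    counts = np.zeros((tree.n_nodes, k))
    dwell = np.zeros((tree.n_nodes, k))
    for m in pool:
        counts[np.arange(tree.n_nodes), m.node_state] += 1
        for v, segs in m.segments.items():
            for s, d in segs:
                dwell[v, s] += d
                dwell[tree.parent[v], s] += d
    best = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in range(tree.n_nodes):
        top = counts[v].max()
        tied = np.flatnonzero(counts[v] == top)
        best[v] = tied[np.argmax(dwell[v, tied])] if len(tied) > 1 else tied[0]
    return best


# -- plain-text serialization -----------------------------------------

CSV_HEADER = "tree_id,sim_id,child_node,segment_index,state,duration"


def maps_to_csv(maps: list[MappedHistory], path: str) -> None:
    """Write maps as a per-branch segment table (lossless)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(CSV_HEADER + "\n")
        for m in maps:
            for v in sorted(m.segments):
                for j, (s, d) in enumerate(m.segments[v]):
                    fh.write(f"{m.tree_index},{m.sim_index},{v},{j},{int(s)},"
                             f"{float(d):.17g}\n")


def maps_from_csv(path: str, trees: TreeSet | list[PhyloTree]
                  ) -> list[MappedHistory]:
    """Read a segment table back into MappedHistory objects.

    Node states are recovered from the segment endpoints (the last
    segment on the branch above v ends in v's state; the root state is
    the first segment state of any root-child branch).
    """
    import csv

    rows: dict[tuple[int, int], dict[int, list[tuple[int, float]]]] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            key = (int(row["tree_id"]), int(row["sim_id"]))
            segs = rows.setdefault(key, {})
            segs.setdefault(int(row["child_node"]), []).append(
                (int(row["state"]), float(row["duration"])))
    maps = []
    tree_list = list(trees)
    for (ti, si), segments in sorted(rows.items()):
        tree = tree_list[ti]
        node_state = np.zeros(tree.n_nodes, dtype=np.int64)
        for v, segs in segments.items():
            node_state[v] = segs[-1][0]
        for c in tree.children[tree.root]:
            node_state[tree.root] = segments[c][0][0]
            break
        maps.append(MappedHistory(tree=tree, node_state=node_state,
                                  segments=segments, tree_index=ti,
                                  sim_index=si))
    return maps
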