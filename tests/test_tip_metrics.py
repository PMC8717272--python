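import numpy as np
import pytest

import tiptempo as tt
from tiptempo.tip_metrics import (extract_lineage, last_transition_time,
                                  stasis_time, transition_rate)

from conftest import make_history


def brute_force_metrics(path):
    """Independent run-scan implementation of TR, ST, LT.

    Enumerates node-state changes directly and scans every contiguous
    constant-state interval of the concatenated segment sequence.
    """
    states = path.node_states
    t = sum(1 for i in range(len(states) - 1) if states[i] != states[i + 1])
    n = len(states) - 1
    tr = t / n
    # enumerate runs by explicit scan
    runs = []
    cur_state, cur_len = None, 0.0
    for s, d in path.segments:
        if s == cur_state:
            cur_len += d
        else:
            if cur_state is not None:
                runs.append((cur_state, cur_len))
            cur_state, cur_len = s, d
    if cur_state is not None:
        runs.append((cur_state, cur_len))
    a = path.tip_state
    st = max((d for s, d in runs if s == a), default=0.0)
    lt = runs[-1][1] if runs and runs[-1][0] == a else 0.0
    return tr, st, lt


@pytest.fixture
def two_tip_tree(tmp_path):
    p = tmp_path / "p.nwk"
    p.write_text("(A:2,B:2);\n")
    return tt.read_trees(str(p))[0]


@pytest.fixture
def four_tip_tree(tmp_path):
    p = tmp_path / "q.nwk"
    p.write_text("(((A:1,B:1):1,C:2):1,D:3);\n")
    return tt.read_trees(str(p))[0]


class TestExtractLineage:
    def test_constant_two_tip_history(self, two_tip_tree):
        m = make_history(two_tip_tree)
        path = extract_lineage(m, "A")
        assert path.n_internal == 1
        assert path.n_changes == 0
        assert path.depth == pytest.approx(2.0)

    def test_terminal_branch_event_counts_at_tip(self, four_tip_tree):
        tipA = four_tip_tree.tip_id("A")
        m = make_history(four_tip_tree,
                         {tipA: [(0, 0.4), (1, 0.6)]})
        path = extract_lineage(m, "A")
        # the node-to-tip change is counted; N is unchanged
        assert path.n_changes == 1
        assert path.n_internal == 3
        pathB = extract_lineage(m, "B")
        assert pathB.n_changes == 0

    def test_segments_concatenate_branch_tables(self):
        tree = tt.simulate_tree(15, 1.0, 0.0, seed=6)
        Q = tt.build_rate_matrix([0.4], "ER", 3)
        hist, _ = tt.simulate_trait_history(tree, Q, seed=7)
        for tip in tree.tip_labels[:5]:
            path = extract_lineage(hist, tip)
            manual = []
            for v in tt.lineage_nodes(tree, tip)[1:]:
                manual.extend(hist.segments[v])
            assert path.segments == manual

    def test_unknown_species(self, two_tip_tree):
        m = make_history(two_tip_tree)
        with pytest.raises(KeyError):
            extract_lineage(m, "Z")


class TestMetricFormulas:
    def test_no_transitions_gives_zero_tr_full_depth_st_lt(self, four_tip_tree):
        m = make_history(four_tip_tree, root_state=2)
        path = extract_lineage(m, "A")
        assert transition_rate(path) == 0.0
        assert stasis_time(path) == pytest.approx(path.depth)
        assert last_transition_time(path) == pytest.approx(path.depth)

    def test_change_at_every_node_gives_tr_one(self, four_tip_tree):
        t = four_tip_tree
        A, B = t.tip_id("A"), t.tip_id("B")
        ab = t.parent[A]
        abc = t.parent[ab]
        m = make_history(t, {
            abc: [(0, 0.5), (1, 0.5)],
            ab: [(1, 0.5), (2, 0.5)],
            A: [(2, 0.5), (3, 0.5)],
            B: [(2, 1.0)],
        })
        path = extract_lineage(m, "A")
        assert path.n_changes == 3 and path.n_internal == 3
        assert transition_rate(path) == 1.0

    def test_tr_simple_ratio(self):
        # t=3 changes over N=12 nodes -> 0.25, via a hand-built path
        path = tt.LineagePath(
            species="x", tip_state=1,
            node_ids=list(range(13)),
            node_states=[0, 0, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1, 1],
            node_ages=list(np.linspace(12, 0, 13)),
            segments=[(0, 2.0), (1, 2.0), (0, 4.0), (1, 4.0)])
        assert transition_rate(path) == pytest.approx(0.25)

    def test_max_run_can_predate_last_transition(self, two_tip_tree):
        # a 3 Ma, then b 1 Ma, then a 2 Ma to the tip: ST=3 from the old
        # run, LT=2 from the terminal run (so ST > LT is possible)
        tipA = two_tip_tree.tip_id("A")
        tipB = two_tip_tree.tip_id("B")
        tree = two_tip_tree
        # lengthen branches to 6 Ma for the 3+1+2 layout
        tree = tt.PhyloTree(parent=tree.parent, children=tree.children,
                            branch_length=np.array([0.0, 6.0, 6.0]),
                            tip_label=tree.tip_label)
        m = make_history(tree, {tipA: [(0, 3.0), (1, 1.0), (0, 2.0)],
                                tipB: [(0, 6.0)]})
        path = extract_lineage(m, "A")
        assert stasis_time(path) == pytest.approx(3.0)
        assert last_transition_time(path) == pytest.approx(2.0)

    def test_runs_merge_across_node_boundaries(self, four_tip_tree):
        # state 0 throughout except a brief flip deep on the root branch:
        # the post-flip run spans several branches
        t = four_tip_tree
        abc = t.parent[t.parent[t.tip_id("A")]]
        m = make_history(t, {abc: [(0, 0.2), (1, 0.3), (0, 0.5)]})
        path = extract_lineage(m, "A")
        assert stasis_time(path) == pytest.approx(0.5 + 1.0 + 1.0)
        assert last_transition_time(path) == pytest.approx(2.5)

    def test_branchwise_mode_takes_single_interval(self, four_tip_tree):
        t = four_tip_tree
        abc = t.parent[t.parent[t.tip_id("A")]]
        m = make_history(t, {abc: [(0, 0.2), (1, 0.3), (0, 0.5)]})
        path = extract_lineage(m, "A", st_mode="branchwise")
        assert stasis_time(path) == pytest.approx(1.0)

    def test_excursion_reduces_st_lt_not_tr(self, four_tip_tree):
        t = four_tip_tree
        tipA = t.tip_id("A")
        clean = make_history(t)
        flip = make_history(t, {tipA: [(0, 0.3), (1, 0.2), (0, 0.5)]})
        p0 = extract_lineage(clean, "A")
        p1 = extract_lineage(flip, "A")
        assert transition_rate(p1) == transition_rate(p0) == 0.0
        assert stasis_time(p1) <= stasis_time(p0)
        assert last_transition_time(p1) < last_transition_time(p0)
        assert last_transition_time(p1) == pytest.approx(0.5)


class TestAgainstBruteForce:
    def test_random_histories_match_oracle(self):
        rng = np.random.default_rng(21)
        n_checked = 0
        for rep in range(30):
            tree = tt.simulate_tree(int(rng.integers(8, 20)), 1.0, 0.0,
                                    seed=int(rng.integers(2**31)))
            Q = tt.build_rate_matrix(rng.uniform(0.1, 0.8, 6), "SYM", 4)
            hist, _ = tt.simulate_trait_history(
                tree, Q, seed=int(rng.integers(2**31)))
            for tip in tree.tip_labels:
                path = extract_lineage(hist, tip)
                tr_o, st_o, lt_o = brute_force_metrics(path)
                assert transition_rate(path) == tr_o
                assert stasis_time(path) == pytest.approx(st_o, abs=1e-9)
                assert last_transition_time(path) == pytest.approx(lt_o, abs=1e-9)
                assert 0.0 <= transition_rate(path) <= 1.0
                assert 0.0 <= stasis_time(path) <= path.depth + 1e-9
                assert 0.0 <= last_transition_time(path) <= path.depth + 1e-9
                n_checked += 1
        assert n_checked > 200


class TestComputeCube:
    def test_counting(self):
        ts = tt.simulate_tree_set(n_tips=5, n_trees=2, jitter=0.05, seed=2)
        Q = tt.build_rate_matrix([0.5], "ER", 2)
        _, tips = tt.simulate_trait_history(ts[0], Q, seed=3)
        if len(set(tips.values())) < 2:
            tips[ts.tip_labels[0]] = 1 - tips[ts.tip_labels[0]]
        maps = tt.simulate_maps(ts, tips, model="ER", n_sim_per_tree=3,
                                seed=4, k=2)
        cube = tt.compute_cube(maps)
        assert cube.shape == (5, 2, 3)
        df = cube.to_dataframe()
        assert len(df) == 30

    def test_sister_tips_with_shared_history_are_equal(self, four_tip_tree):
        t = four_tip_tree
        ab = t.parent[t.tip_id("A")]
        abc = t.parent[ab]
        m = make_history(t, {abc: [(0, 1.0), (1, 1.0)]}, root_state=0)
        pa = extract_lineage(m, "A")
        pb = extract_lineage(m, "B")
        for f in (transition_rate, stasis_time, last_transition_time):
            assert f(pa) == f(pb)

    def test_missing_species_rejected(self, four_tip_tree):
        m = make_history(four_tip_tree)
        with pytest.raises(ValueError, match="missing from tree"):
            tt.compute_cube([m], species=["A", "Z"])

    def test_cube_mean_matches_recomputation(self):
        ts = tt.simulate_tree_set(n_tips=8, n_trees=2, jitter=0.05, seed=9)
        Q = tt.build_rate_matrix([0.4], "ER", 3)
        _, tips = tt.simulate_trait_history(ts[0], Q, seed=10)
        if len(set(tips.values())) < 2:
            pytest.skip("degenerate draw")
        maps = tt.simulate_maps(ts, tips, model="ER", n_sim_per_tree=2,
                                seed=11, k=3)
        cube = tt.compute_cube(maps)
        # independent recomputation: loop over maps and species
        acc = []
        for m in maps:
            for sp in cube.species:
                acc.append(brute_force_metrics(extract_lineage(m, sp))[0])
        assert cube.tr.mean() == pytest.approx(np.mean(acc), abs=1e-12)

    def test_csv_roundtrip(self, tmp_path):
        ts = tt.simulate_tree_set(n_tips=5, n_trees=2, jitter=0.05, seed=2)
        Q = tt.build_rate_matrix([0.5], "ER", 2)
        _, tips = tt.simulate_trait_history(ts[0], Q, seed=5)
        if len(set(tips.values())) < 2:
            tips[ts.tip_labels[0]] = 1 - tips[ts.tip_labels[0]]
        maps = tt.simulate_maps(ts, tips, model="ER", n_sim_per_tree=3,
                                seed=4, k=2)
        cube = tt.compute_cube(maps)
        p = tmp_path / "cube.csv"
        cube.to_csv(str(p))
        import pandas as pd
        back = tt.EstimateCube.from_dataframe(pd.read_csv(p))
        assert np.allclose(back.tr, cube.tr)
        assert np.allclose(back.st, cube.st)
        assert np.allclose(back.lt, cube.lt)


def test_count_tip_node_convention(four_tip_tree):
    m = make_history(four_tip_tree)
    default = extract_lineage(m, "A")
    with_tip = extract_lineage(m, "A", count_tip_node=True)
    assert with_tip.n_internal == default.n_internal + 1
    assert with_tip.n_changes == default.n_changes
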