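import numpy as np
import pytest

import tiptempo as tt


@pytest.fixture
def three_tip_newick(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    return str(p)


@pytest.fixture
def three_tip_tree(three_tip_newick):
    return tt.read_trees(three_tip_newick)[0]


@pytest.fixture
def yule_tree():
    return tt.simulate_tree(20, birth_rate=1.0, death_rate=0.0, seed=11)


def make_history(tree, segments_by_tip=None, **kwargs):
    """Hand-build a MappedHistory from explicit per-branch segments.

    ``segments_by_tip`` maps child-node id -> list of (state, duration);
    unspecified branches get a single segment in the parent's state.
    Node states are derived from the segment endpoints.
    """
    from tiptempo.stochastic_mapping import MappedHistory

    segs = dict(segments_by_tip or {})
    node_state = np.zeros(tree.n_nodes, dtype=np.int64)
    root_state = kwargs.pop("root_state", 0)
    node_state[tree.root] = root_state
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        if v not in segs:
            segs[v] = [(int(node_state[tree.parent[v]]),
                        float(tree.branch_length[v]))]
        node_state[v] = segs[v][-1][0]
    return MappedHistory(tree=tree, node_state=node_state, segments=segs,
                         **kwargs)
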