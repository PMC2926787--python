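import numpy as np
import pytest

from tumult.core import TreeEdge, TreeNode, TumorTree
from tumult.profiles import (DiscreteProfile, MarkerMap,
                             delineate_segments, segment_vector)


@pytest.fixture
def small_map():
    """Two chromosomes with 10 and 8 evenly spaced probes."""
    n1, n2 = 10, 8
    ids = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    chroms = ["c1"] * n1 + ["c2"] * n2
    pos = list(range(1000, 1000 + 1000 * n1, 1000)) + \
        list(range(1000, 1000 + 1000 * n2, 1000))
    return MarkerMap(np.array(ids, object), np.array(chroms, object),
                     np.array(pos))


def make_profile(sample_id, *chrom_statuses):
    return DiscreteProfile(sample_id, np.concatenate(
        [np.asarray(c, dtype=np.int64) for c in chrom_statuses]))


def make_tree(marker_map, node_probe_profiles, edges, root="normal"):
    """Assemble a TumorTree from per-probe node profiles and (parent, child)
    pairs; node kinds are inferred (root / leaf / precursor)."""
    children = {}
    for p, c in edges:
        children.setdefault(p, []).append(c)
    profs = [DiscreteProfile(n, v) for n, v in node_probe_profiles.items()]
    partition = delineate_segments(profs, marker_map)
    nodes = {}
    for name, probe_vals in node_probe_profiles.items():
        kind = ("normal" if name == root
                else "precursor" if children.get(name) else "tumor")
        nodes[name] = TreeNode(
            name, kind,
            segment_vector(DiscreteProfile(name, probe_vals), partition),
            children=list(children.get(name, [])))
    edge_objs = {}
    for p, c in edges:
        nodes[c].parent = p
        edge_objs[(p, c)] = TreeEdge(p, c, [])
    return TumorTree(partition=partition, nodes=nodes, edges=edge_objs,
                     root=root, amplicon_mode="breakpoint")
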