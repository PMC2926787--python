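"""Statistics over collections of tumor progression trees.

Once individual progression trees are reconstructed, the relative timing of
aberrations is known within each patient, which supports cohort-level
questions: which aberrations arise early (before the common precursor)
versus late, which pairs of aberrations co-occur on the same edge more often
than chance (suggesting synergy), what the ancestral clones recurrently
carry, and how probable an observed clade (e.g. all liver metastases forming
one subtree) would be among random topologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core import TumorTree


@dataclass(frozen=True)
class ArmAberration:
    """A recurrent arm-level (or focal) aberration to score on tree edges.

    ``kind`` is one of ``gain``, ``loss``, ``amplicon``,
    ``homozygous-deletion``; positions are base pairs on ``chrom``.
    """

    name: str
    chrom: str
    start: int
    end: int
    kind: str


def fisher_two_tailed(table) -> float:
    """Two-tailed Fisher exact p-value of a 2x2 contingency table.

    Minimum-likelihood convention: the sum of hypergeometric probabilities
    (margins fixed) of every table at most as probable as the observed one.
    Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    return float(fisher_exact(t, alternative="two-sided")[1])


def _arm_probe_mask(mm, ab: ArmAberration) -> np.ndarray:
    sl = mm.chrom_slice(ab.chrom)
    mask = np.zeros(mm.n_probes, dtype=bool)
    pos = mm.positions[sl]
    inside = (pos >= ab.start) & (pos <= ab.end)
    mask[sl.start:sl.stop][inside] = True
    return mask


def _direction(kind: str) -> int:
    return 1 if kind in ("gain", "amplicon") else -1


def _edge_presence(tree: TumorTree, parent: str, child: str,
                   ab: ArmAberration, threshold: float) -> bool:
    """An aberration is present on an edge when at least ``threshold`` of the
    probes in its interval change in its direction along that edge."""
    mm = tree.partition.marker_map
    mask = _arm_probe_mask(mm, ab)
    if not mask.any():
        return False
    diff = tree.probe_profile(child) - tree.probe_profile(parent)
    frac = np.mean(np.sign(diff[mask]) == _direction(ab.kind))
    return bool(frac >= threshold)


def _three_edge_shape(tree: TumorTree):
    """Return (cp, leaf_a, leaf_b) for a normal -> CP -> {two tumors} tree."""
    root_children = tree.nodes[tree.root].children
    if len(root_children) != 1:
        raise ValueError("tree root must have a single precursor child")
    cp = root_children[0]
    kids = tree.nodes[cp].children
    if len(kids) != 2 or any(tree.nodes[k].children for k in kids):
        raise ValueError(
            f"tree rooted at {cp!r} does not have the required "
            f"normal->CP->(primary, recurrence) shape")
    return cp, kids[0], kids[1]


def early_late_test(trees, aberrations, primary_ids=None,
                    arm_threshold: float = 0.6) -> pd.DataFrame:
    """Classify aberrations as early or late across primary/recurrence pairs.

    Every tree must have exactly three edges: normal -> CP, CP -> primary and
    CP -> recurrence.  An aberration is *early* when present on the
    normal -> CP edge and *late* when present on the CP -> primary edge; the
    recurrence edge is excluded (its events may reflect treatment rather
    than natural progression).  Association of each aberration with the
    early versus late step is scored by a two-tailed Fisher exact test on
    occurrence counts across the ``n`` trees.

    Parameters
    ----------
    trees : list of TumorTree
    aberrations : list of ArmAberration
    primary_ids : list of str, optional
        The primary-tumor leaf of each tree; defaults to the
        lexicographically first leaf.
    arm_threshold : float
        Fraction of the aberration's probes that must change on an edge for
        the aberration to count as present there (default 0.6).

    Returns
    -------
    DataFrame with columns name, n_early, n_late, freq_early, freq_late, p.
    """
    n = len(trees)
    rows = []
    shapes = []
    for i, tree in enumerate(trees):
        try:
            cp, a, b = _three_edge_shape(tree)
        except ValueError as exc:
            raise ValueError(f"tree #{i}: {exc}") from exc
        if primary_ids is not None:
            primary = primary_ids[i]
            if primary not in (a, b):
                raise ValueError(f"tree #{i}: {primary!r} is not a leaf")
        else:
            primary = min(a, b)
        shapes.append((tree, cp, primary))
    for ab in aberrations:
        early = sum(_edge_presence(t, t.root, cp, ab, arm_threshold)
                    for t, cp, _ in shapes)
        late = sum(_edge_presence(t, cp, primary, ab, arm_threshold)
                   for t, cp, primary in shapes)
        p = fisher_two_tailed([[early, n - early], [late, n - late]])
        rows.append((ab.name, early, late, early / n, late / n, p))
    return pd.DataFrame(rows, columns=["name", "n_early", "n_late",
                                       "freq_early", "freq_late", "p"])


def edge_occurrence_matrix(trees, aberrations,
                           arm_threshold: float = 0.6) -> pd.DataFrame:
    """Boolean aberration x edge presence matrix over every edge of a set of
    trees (columns labelled ``tree<i>:<parent>-><child>``)."""
    cols, data = [], []
    for i, tree in enumerate(trees):
        for (parent, child) in tree.edges:
            cols.append(f"tree{i}:{parent}->{child}")
            data.append([_edge_presence(tree, parent, child, ab, arm_threshold)
                         for ab in aberrations])
    mat = np.array(data, dtype=bool).T if data else np.zeros(
        (len(aberrations), 0), bool)
    return pd.DataFrame(mat, index=[ab.name for ab in aberrations],
                        columns=cols)


def cooccurrence_test(trees=None, aberrations=None, fdr: float = 0.15,
                      min_edges: int = 3, arm_threshold: float = 0.6,
                      occurrence: pd.DataFrame = None) -> pd.DataFrame:
    """Test every pair of aberrations for co-occurrence on the same edges.

    Aberrations observed on fewer than ``min_edges`` edges are dropped; each
    remaining pair is scored by a two-tailed Fisher exact test on the 2x2
    co-presence table over all edges pooled across trees, with
    Benjamini–Hochberg control of the false discovery rate at ``fdr``.
    A precomputed boolean aberration x edge ``occurrence`` matrix may be
    supplied instead of trees.

    Returns a DataFrame with columns a, b, n_both, n_a, n_b, p, q,
    significant (empty when fewer than two aberrations are retained).
    """
    occ = (occurrence if occurrence is not None
           else edge_occurrence_matrix(trees, aberrations, arm_threshold))
    keep = occ.index[occ.sum(axis=1) >= min_edges]
    n_edges = occ.shape[1]
    rows = []
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            va, vb = occ.loc[a].to_numpy(), occ.loc[b].to_numpy()
            both = int(np.sum(va & vb))
            a_only = int(np.sum(va & ~vb))
            b_only = int(np.sum(~va & vb))
            neither = n_edges - both - a_only - b_only
            p = fisher_two_tailed([[both, a_only], [b_only, neither]])
            rows.append((a, b, both, int(va.sum()), int(vb.sum()), p))
    df = pd.DataFrame(rows, columns=["a", "b", "n_both", "n_a", "n_b", "p"])
    if len(df):
        reject, q, _, _ = multipletests(df["p"], alpha=fdr, method="fdr_bh")
        df["q"] = q
        df["significant"] = reject
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def precursor_frequencies(trees) -> pd.DataFrame:
    """Per-probe gain/loss frequency across the root-most precursor clones.

    For each tree, the common ancestor of all leaves (the precursor directly
    below the normal root) is taken; the output is the fraction of trees in
    which each probe is gained (status > 0) or lost (status < 0) in that
    clone.  All trees must share a marker map.
    """
    if not trees:
        raise ValueError("at least one tree is required")
    mm = trees[0].partition.marker_map
    gains = np.zeros(mm.n_probes)
    losses = np.zeros(mm.n_probes)
    for tree in trees:
        if tree.partition.marker_map.n_probes != mm.n_probes:
            raise ValueError("trees are not on a common marker map")
        top = tree.nodes[tree.root].children[0]
        prof = tree.probe_profile(top)
        gains += prof > 0
        losses += prof < 0
    n = len(trees)
    return pd.DataFrame({"probe_id": mm.probe_ids, "chrom": mm.chroms,
                         "pos": mm.positions,
                         "gain_freq": gains / n, "loss_freq": losses / n})


# ---------------------------------------------------------------------------
# clade probability among random topologies

def double_factorial(n: int) -> int:
    if n <= 0:
        return 1
    out = 1
    while n > 0:
        out *= n
        n -= 2
    return out


def count_rooted_topologies(n_leaves: int) -> int:
    """Number of rooted binary leaf-labelled topologies: (2n - 3)!!."""
    return double_factorial(2 * n_leaves - 3)


def enumerate_rooted_topologies(labels):
    """All rooted binary leaf-labelled topologies on ``labels``.

    Trees are nested 2-tuples with labels at the leaves; each topology is
    produced exactly once by inserting one leaf at a time on every edge
    (including above the root), hence (2n - 3)!! trees for n leaves.
    """
    labels = list(labels)

    def insert(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insert(left, leaf):
                yield (t, right)
            for t in insert(right, leaf):
                yield (left, t)

    trees = [labels[0]]
    for lab in labels[1:]:
        trees = [t2 for t in trees for t2 in insert(t, lab)]
    return trees


def _clades(tree) -> set:
    out = set()

    def rec(t):
        if not isinstance(t, tuple):
            return frozenset([t])
        s = rec(t[0]) | rec(t[1])
        out.add(s)
        return s

    rec(tree)
    return out


def clade_fraction(n_leaves: int, subset_size: int,
                   enumerate_up_to: int = 9) -> float:
    """Fraction of rooted binary leaf-labelled topologies on ``n_leaves`` in
    which a fixed subset of ``subset_size`` leaves forms a clade.

    Exact enumeration for small trees; otherwise the closed-form ratio
    (2k - 3)!! (2(n - k + 1) - 3)!! / (2n - 3)!!, i.e. trees built from a
    clade on the subset combined with a tree on the remaining leaves plus
    the collapsed clade.
    """
    n, k = n_leaves, subset_size
    if not (1 <= k <= n):
        raise ValueError("subset size must be between 1 and the leaf count")
    if k in (1, n):
        return 1.0
    if n <= enumerate_up_to:
        labels = list(range(n))
        target = frozenset(range(k))
        trees = enumerate_rooted_topologies(labels)
        hits = sum(target in _clades(t) for t in trees)
        return hits / len(trees)
    num = double_factorial(2 * k - 3) * double_factorial(2 * (n - k + 1) - 3)
    return num / double_factorial(2 * n - 3)


def subtree_probability(n_leaves_per_patient, subset_sizes) -> float:
    """Probability that designated leaf subsets form clades in every patient.

    The per-patient fractions of rooted binary leaf-labelled topologies
    containing the subset as a clade are multiplied across patients (random
    independent topologies under the null).
    """
    if len(n_leaves_per_patient) != len(subset_sizes):
        raise ValueError("leaf counts and subset sizes must align")
    p = 1.0
    for n, k in zip(n_leaves_per_patient, subset_sizes):
        if k == 0:
            raise ValueError("subset size must be >= 1")
        p *= clade_fraction(n, k)
    return p
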