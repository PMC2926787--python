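"""Simulation of tumor progression trees, noisy array signals, and the
reconstruction benchmark.

The generator mimics the clonal expansion that produced a patient's tumors:
starting from a first transformed precursor, a random leaf of the growing
tree is repeatedly split into two daughter clones, each acquiring its own
random set of interval aberrations, until the requested number of tumors is
reached.  Probe-level log-ratio signals can then be synthesized from the
leaf profiles under a normal-cell contamination/noise model, re-discretized
with a change-point segmenter, and fed back to the reconstruction algorithm;
recovery is scored by topology identity (Robinson–Foulds distance 0) and by
the per-probe error rate of the inferred ancestral profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import core
from .profiles import DiscreteProfile, MarkerMap, delineate_segments, segment_vector
from .core import Aberration, TreeEdge, TreeNode, TumorTree, build_tree

# hg19 autosome lengths (Mb), used only to shape a realistic genome-wide grid
_CHROM_MB = (249, 243, 198, 191, 181, 171, 159, 146, 141, 134, 135, 134,
             115, 107, 103, 90, 81, 78, 59, 63, 48, 51)

DEFAULT_N_PROBES = 2360
# minimum copy ratio kept when synthesizing log-ratios: a homozygous deletion
# in a pure sample has ratio 0 and would otherwise produce -inf
_MIN_RATIO = 0.05


def default_marker_map(n_probes: int = DEFAULT_N_PROBES) -> MarkerMap:
    """Synthetic genome-wide probe grid: 22 autosomes, probe counts
    proportional to human chromosome lengths, evenly spaced positions."""
    total_mb = sum(_CHROM_MB)
    counts = [max(2, int(round(n_probes * mb / total_mb))) for mb in _CHROM_MB]
    # absorb rounding drift on the largest chromosome (tiny grids may end up
    # slightly above n_probes once every chromosome keeps its 2-probe minimum)
    counts[0] = max(2, counts[0] + n_probes - sum(counts))
    probe_ids, chroms, positions = [], [], []
    for i, n_c in enumerate(counts):
        label = f"chr{i + 1}"
        spacing = _CHROM_MB[i] * 1_000_000 // (n_c + 1)
        for j in range(n_c):
            probe_ids.append(f"{label}_p{j}")
            chroms.append(label)
            positions.append((j + 1) * spacing)
    return MarkerMap(np.array(probe_ids, object), np.array(chroms, object),
                     np.array(positions))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulation.

    Defaults follow the validation setup: 2,360 genome-wide probes and 3 to
    15 aberrations per edge, in line with counts observed in experimental
    trees.  ``breakpoint_weights`` optionally maps chromosome to a weight
    array over its probe boundaries (length n_probes + 1), emulating
    sampling of breakpoints according to their frequency in a reference
    cohort; ``None`` means uniform.
    """

    n_tumors: int
    n_probes: int = DEFAULT_N_PROBES
    aberrations_per_edge: tuple = (3, 15)
    breakpoint_weights: dict = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tumors < 2:
            raise ValueError("n_tumors must be >= 2")
        if self.n_probes < 2:
            raise ValueError("n_probes must be >= 2")
        lo, hi = self.aberrations_per_edge
        if not (1 <= lo <= hi):
            raise ValueError("invalid aberrations_per_edge range")


@dataclass(frozen=True)
class NoiseModel:
    """Normal-cell contamination fraction C and log-ratio noise sd S.

    Either may be a single value or an inclusive (low, high) range sampled
    per sample.  C is capped at 0.8 and S at 0.2, the ranges explored in the
    validation study.
    """

    contamination: tuple = 0.0
    noise_sd: tuple = 0.0

    def __post_init__(self):
        for v, hi, name in ((self.contamination, 0.8, "contamination"),
                            (self.noise_sd, 0.2, "noise_sd")):
            lo_v, hi_v = (v, v) if np.isscalar(v) else v
            if not (0 <= lo_v <= hi_v <= hi):
                raise ValueError(f"{name} outside [0, {hi}]")

    def draw(self, rng) -> tuple:
        c = self.contamination
        s = self.noise_sd
        c = float(c) if np.isscalar(c) else float(rng.uniform(*c))
        s = float(s) if np.isscalar(s) else float(rng.uniform(*s))
        return c, s


@dataclass(frozen=True)
class BenchmarkResult:
    """Recovery summary over simulated replicates.

    ``internal_node_error_rate`` is the mean per-probe mismatch fraction of
    ancestral profiles, computed over topology-correct replicates only
    (``None`` if there were none).
    """

    n_replicates: int
    topology_correct_fraction: float
    internal_node_error_rate: float
    per_replicate: tuple = field(default=(), repr=False)


# ---------------------------------------------------------------------------
# tree simulation

def _draw_aberration(rng, mm: MarkerMap, profile: np.ndarray, weights,
                     max_tries: int = 1000):
    """One feasible interval aberration: chromosome by probe weight, two
    distinct boundary slots within it, gain or loss with equal probability.
    Draws leading out of {-2..2} are discarded and replaced."""
    sizes = mm.chrom_sizes()
    labels = list(sizes)
    p = np.array([sizes[c] for c in labels], float)
    p /= p.sum()
    for _ in range(max_tries):
        chrom = labels[rng.choice(len(labels), p=p)]
        sl = mm.chrom_slice(chrom)
        n_c = sl.stop - sl.start
        if weights is not None and chrom in weights:
            w = np.asarray(weights[chrom], float)
            w = w / w.sum()
            lo, hi = np.sort(rng.choice(n_c + 1, size=2, replace=False, p=w))
        else:
            lo, hi = np.sort(rng.choice(n_c + 1, size=2, replace=False))
        delta = 1 if rng.random() < 0.5 else -1
        seg = profile[sl.start + lo: sl.start + hi]
        if np.all(np.abs(seg + delta) <= 2):
            return chrom, int(lo), int(hi), delta
    return None


def simulate_tree(config: SimulationConfig, rng=None) -> TumorTree:
    """Generate a random ground-truth tumor progression tree.

    A first precursor is created from the normal cell; thereafter a random
    leaf of the growing tree is split into two children until ``n_tumors``
    leaves exist.  Every edge carries ``n_ab ~ Uniform{3..15}`` interval
    aberrations (each one 'up' plus one 'down' breakpoint).  All node
    profiles are retained, so the tree can serve as reconstruction truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mm = default_marker_map(config.n_probes)
    lo_ab, hi_ab = config.aberrations_per_edge

    profiles = {}   # internal name -> per-probe status
    events = {}     # internal name -> list of (chrom, lo, hi, delta)
    children = {}
    counter = itertools.count()

    def new_node(parent_profile):
        name = next(counter)
        n_ab = int(rng.integers(lo_ab, hi_ab + 1))
        prof = parent_profile.copy()
        evs = []
        for _ in range(n_ab):
            drawn = _draw_aberration(rng, mm, prof, config.breakpoint_weights)
            if drawn is None:
                break
            chrom, lo, hi, delta = drawn
            sl = mm.chrom_slice(chrom)
            prof[sl.start + lo: sl.start + hi] += delta
            evs.append((chrom, lo, hi, delta))
        profiles[name] = prof
        events[name] = evs
        children[name] = []
        return name

    first = new_node(np.zeros(mm.n_probes, dtype=np.int64))
    leaves = [first]
    while len(leaves) < config.n_tumors:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = new_node(profiles[parent])
            children[parent].append(child)
            leaves.append(child)

    # name leaves T1.. in creation order, internals P1..
    leaf_names, internal_names = {}, {}
    for name in sorted(profiles):
        if children[name]:
            internal_names[name] = f"P{len(internal_names) + 1}"
        else:
            leaf_names[name] = f"T{len(leaf_names) + 1}"
    rename = {**leaf_names, **internal_names}

    all_profiles = [DiscreteProfile(rename[n], profiles[n]) for n in sorted(profiles)]
    partition = delineate_segments(all_profiles, mm)

    nodes, edges = {}, {}
    for n in sorted(profiles):
        nid = rename[n]
        kind = "precursor" if children[n] else "tumor"
        nodes[nid] = TreeNode(nid, kind,
                              segment_vector(DiscreteProfile(nid, profiles[n]),
                                             partition))
    for n in sorted(profiles):
        for c in children[n]:
            nodes[rename[c]].parent = rename[n]
            nodes[rename[n]].children.append(rename[c])
            edges[(rename[n], rename[c])] = TreeEdge(
                rename[n], rename[c],
                [Aberration("gain" if d > 0 else "loss", chrom, -1, -1, d,
                            probe_span=(lo, hi))
                 for chrom, lo, hi, d in events[c]])
    root_seg = {c: np.zeros(partition.n_segments(c), dtype=np.int64)
                for c in mm.chrom_order}
    nodes["normal"] = TreeNode("normal", "normal", root_seg,
                               children=[rename[first]])
    nodes[rename[first]].parent = "normal"
    edges[("normal", rename[first])] = TreeEdge(
        "normal", rename[first],
        [Aberration("gain" if d > 0 else "loss", chrom, -1, -1, d,
                    probe_span=(lo, hi))
         for chrom, lo, hi, d in events[first]])
    return TumorTree(partition=partition, nodes=nodes, edges=edges,
                     root="normal", amplicon_mode="breakpoint")


# ---------------------------------------------------------------------------
# noise model and re-discretization

def _theoretical_logratios(C: float) -> np.ndarray:
    """Expected log2 ratio of each status in {-2..2} at contamination C."""
    copies = np.arange(5)  # status + 2
    mix = copies * (1.0 - C) + 2.0 * C
    return np.log2(np.maximum(mix, _MIN_RATIO) / 2.0)


def simulate_logratios(status: np.ndarray, noise: NoiseModel = None,
                       rng=None, contamination: float = None,
                       noise_sd: float = None) -> np.ndarray:
    """Synthesize per-probe log ratios from a discrete profile.

    For copy count ``N = status + 2`` and contamination ``C``, the expected
    ratio is ``(N (1 - C) + 2 C) / 2`` (the tumor signal diluted by diploid
    normal cells); Gaussian noise of sd ``S`` is added on the log2 scale.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if contamination is None or noise_sd is None:
        contamination, noise_sd = (noise or NoiseModel()).draw(rng)
    status = np.asarray(status)
    levels = _theoretical_logratios(contamination)
    values = levels[status + 2].astype(float)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return values


def _segment_chromosome(x: np.ndarray, min_seg: int,
                        penalty: float = None) -> list:
    """Recursive mean-shift segmentation of one chromosome's log ratios.

    At each recursion the best interior window [i, j) (or edge split) is the
    one whose own mean maximally reduces the residual sum of squares; it is
    carved out when the reduction, normalized by a robust noise-variance
    estimate (median absolute first difference), exceeds a BIC-style penalty
    of ``3 log(#candidate windows)``.  Flanks of an interior window share one
    mean until their own recursion, as in circular binary segmentation, so
    short interior segments that a single mid-point split cannot expose are
    still found.  Every emitted segment has at least ``min_seg`` probes:
    single-probe spikes never become segments.

    Returns the sorted interior cut indices.
    """
    n = len(x)
    if n < 2 * min_seg:
        return []
    diffs = np.abs(np.diff(x))
    sigma2 = max(float(np.median(diffs) / (np.sqrt(2) * 0.6745)) ** 2, 1e-10)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(lo, hi):
        m = hi - lo
        s = c1[hi] - c1[lo]
        return (c2[hi] - c2[lo]) - s * s / m

    cuts = []

    def segment(lo, hi):
        m = hi - lo
        if m < 2 * min_seg:
            return
        pen = (penalty if penalty is not None
               else 3.0 * np.log(max(m * (m + 1) / 2.0, 8.0)))
        sse0 = sse(lo, hi)
        best = None  # (reduction, i, j)
        for i in range(lo, hi - min_seg + 1):
            if i != lo and i - lo < min_seg:
                continue
            js = np.arange(i + min_seg, hi + 1)
            js = js[(js == hi) | (hi - js >= min_seg)]
            if i == lo:
                js = js[js != hi]
            if len(js) == 0:
                continue
            nw = js - i
            sw = c1[js] - c1[i]
            sse_w = (c2[js] - c2[i]) - sw * sw / nw
            nc = m - nw
            sc = (c1[hi] - c1[lo]) - sw
            sse_c = ((c2[hi] - c2[lo]) - (c2[js] - c2[i])
                     - np.where(nc > 0, sc * sc / np.maximum(nc, 1), 0.0))
            red = sse0 - (sse_w + sse_c)
            k = int(np.argmax(red))
            if best is None or red[k] > best[0]:
                best = (float(red[k]), i, int(js[k]))
        if best is None or best[0] / sigma2 <= pen:
            return
        _, i, j = best
        for t in (i, j):
            if lo < t < hi:
                cuts.append(t)
        if i > lo:
            segment(lo, i)
        segment(i, j)
        if j < hi:
            segment(j, hi)

    segment(0, n)
    return sorted(cuts)


def discretize_noisy(values: np.ndarray, marker_map: MarkerMap,
                     contamination: float = 0.0, sample_id: str = "sample",
                     min_seg: int = 3, penalty: float = None) -> DiscreteProfile:
    """Segment noisy log ratios and call discrete statuses.

    Each chromosome is segmented by recursive binary splitting on mean shift
    (minimum ``min_seg`` probes per segment, BIC-style stopping), then each
    segment mean is assigned the nearest contamination-adjusted theoretical
    level of the five statuses.
    """
    values = np.asarray(values, float)
    levels = _theoretical_logratios(contamination)
    status = np.empty(len(values), dtype=np.int64)
    for chrom in marker_map.chrom_order:
        sl = marker_map.chrom_slice(chrom)
        x = values[sl]
        sigma = float(np.median(np.abs(np.diff(x)))) / (np.sqrt(2) * 0.6745)
        if sigma < 1e-6:
            # noise-free signal: every change point is real, no length limit
            cuts = (np.flatnonzero(np.diff(x) != 0) + 1).tolist()
        else:
            cuts = _segment_chromosome(x, min_seg, penalty)
        cuts = [0] + cuts + [len(x)]
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            # median level: robust to a lone artefact probe inside a segment
            level = float(np.median(x[lo:hi]))
            status[sl.start + lo: sl.start + hi] = int(
                np.argmin(np.abs(levels - level))) - 2
    return DiscreteProfile(sample_id, status)


# ---------------------------------------------------------------------------
# evaluation metrics

def _bipartitions(tree: TumorTree, labels: frozenset) -> set:
    parts = set()
    for nid, node in tree.nodes.items():
        if nid == tree.root or not node.children:
            continue
        clade = frozenset(tree.leaf_set(nid))
        rest = labels - clade
        if len(clade) >= 2 and len(rest) >= 2:
            parts.add(frozenset((clade, rest)))
    return parts


def rf_distance(tree_a: TumorTree, tree_b: TumorTree,
                include_root: bool = False) -> int:
    """Robinson–Foulds distance: symmetric difference of the non-trivial
    leaf bipartitions induced by internal edges.

    With ``include_root`` the normal-cell root counts as an additional
    labelled leaf, which makes the comparison sensitive to the rooted shape
    (used by the benchmark so that ancestral nodes can be matched by their
    descendant sets).  Zero means identical topology.
    """
    la = frozenset(tree_a.leaf_ids())
    lb = frozenset(tree_b.leaf_ids())
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la)} vs {sorted(lb)}")
    labels = la | ({tree_a.root} if include_root else frozenset())
    if include_root and tree_a.root != tree_b.root:
        raise ValueError("root labels differ")
    return len(_bipartitions(tree_a, labels) ^ _bipartitions(tree_b, labels))


def internal_node_error(truth: TumorTree, reconstructed: TumorTree) -> float:
    """Mean per-probe mismatch fraction of ancestral (precursor) profiles.

    Nodes are matched by their descendant tumor sets, which requires the two
    trees to have the same rooted topology; a topology mismatch raises, as
    the metric is defined only for correctly reconstructed trees.
    """
    by_leafset = {truth.leaf_set(nid): nid for nid in truth.precursor_ids()}
    recon_ids = reconstructed.precursor_ids()
    errs = []
    for rid in recon_ids:
        ls = reconstructed.leaf_set(rid)
        if ls not in by_leafset:
            raise ValueError(
                f"topology mismatch: no ancestral node with descendants {sorted(ls)}")
        tprof = truth.probe_profile(by_leafset[ls])
        rprof = reconstructed.probe_profile(rid)
        errs.append(float(np.mean(tprof != rprof)))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# benchmark driver

def run_benchmark(n_tumors: int, n_replicates: int, noise: NoiseModel = None,
                  seed: int = 0, n_probes: int = DEFAULT_N_PROBES,
                  tolerance: int = None,
                  aberrations_per_edge: tuple = (3, 15)) -> BenchmarkResult:
    """Simulate, (optionally) add noise and re-discretize, reconstruct, score.

    Per replicate: a random progression tree is generated; the leaf profiles
    (passed through the log-ratio noise model and the change-point
    discretizer when ``noise`` is given) are handed to the reconstruction;
    topology is scored by rooted Robinson–Foulds identity and ancestral
    profiles by per-probe mismatch over the topology-correct replicates.

    ``tolerance`` defaults to 0 for noiseless input (breakpoint locations are
    exact) and to 2 probes otherwise: the matching window must absorb the
    *relative* displacement of the same breakpoint called in two samples,
    i.e. twice the change-point segmenter's 95th-percentile relocation error
    of 1 probe under the noise ranges studied (estimated as the distance
    between true and re-called breakpoint locations on noisy replicates).
    """
    noiseless = noise is None or (
        np.isscalar(noise.contamination) and noise.contamination == 0
        and np.isscalar(noise.noise_sd) and noise.noise_sd == 0)
    if tolerance is None:
        tolerance = 0 if noiseless else 2
    details = []
    n_correct = 0
    err_sum = 0.0
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        config = SimulationConfig(n_tumors=n_tumors, n_probes=n_probes,
                                  aberrations_per_edge=aberrations_per_edge,
                                  seed=seed)
        truth = simulate_tree(config, rng=rng)
        mm = truth.partition.marker_map
        leaf_profiles = []
        for lid in sorted(truth.leaf_ids()):
            status = truth.probe_profile(lid)
            if noiseless:
                leaf_profiles.append(DiscreteProfile(lid, status))
            else:
                c, s = noise.draw(rng)
                lr = simulate_logratios(status, rng=rng, contamination=c,
                                        noise_sd=s)
                leaf_profiles.append(
                    discretize_noisy(lr, mm, contamination=c, sample_id=lid))
        recon = build_tree(leaf_profiles, mm, F=None, tolerance=tolerance,
                           amplicon_mode="breakpoint")
        correct = rf_distance(truth, recon, include_root=True) == 0
        err = internal_node_error(truth, recon) if correct else None
        details.append((correct, err))
        if correct:
            n_correct += 1
            err_sum += err
    frac = n_correct / n_replicates
    err_rate = (err_sum / n_correct) if n_correct else None
    return BenchmarkResult(n_replicates=n_replicates,
                           topology_correct_fraction=frac,
                           internal_node_error_rate=err_rate,
                           per_replicate=tuple(details))
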