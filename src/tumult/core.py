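"""Agglomerative reconstruction of tumor lineage trees from shared breakpoints.

Multiple tumors from one patient descend from a single transformed cell;
chromosome aberrations accumulate along that lineage and are inherited by
daughter clones.  Two samples that separated recently therefore share many
chromosome breakpoints.  The algorithm exploits this: starting from the
observed tumors (the *front*), it repeatedly joins the two nodes with the
highest identical-breakpoint score

    IBS(a_i, a_j) = sum_k  min(a_i[k], a_j[k]) * (1 - F_k)

(shared breakpoint amplitudes, down-weighted by the breakpoint's frequency
``F_k`` in a reference cohort), reconstructs the copy-number profile of
their common precursor from the shared breakpoints, and replaces the pair by
the precursor, until a single ancestor remains.  A normal-cell root is
attached above it.

The precursor's shared-breakpoint vector may be unbalanced (``sum b != 0``)
when a breakpoint is shared by coincidence, or when a shared breakpoint was
erased in one descendant by a later opposite-sign breakpoint at the same
location.  Balance is then restored by removing a shared breakpoint of
``sign(delta)`` or adding a sample-specific breakpoint of ``sign(-delta)``,
choosing the correction that yields a viable profile and minimizes total
breakpoint usage of the implied scenario (precursor events plus both edge
event sets).  Cost ties are broken by the breakpoint's support among the
patient's other samples (a genuinely erased shared breakpoint is vouched for
by relatives; a coincidental match is not), then by preferring removal of
the unsupported common breakpoint, then by the lowest genomic slot.

High-level amplifications can be handled in two ways (``amplicon_mode``):

``"interval"``
    statuses of +2 are clamped to +1 for the breakpoint arithmetic and the
    amplified intervals are tracked separately, ascending to a precursor only
    when present in both children with boundaries within the tolerance.
    Appropriate for real array data, where an amplicon arises by a dedicated
    mechanism rather than by two stacked gains.
``"breakpoint"``
    +2 participates in the vector arithmetic like any other level, so that
    two stacked unit gains are reconstructed as such.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .profiles import (
    DiscreteProfile,
    MarkerMap,
    SegmentPartition,
    delineate_segments,
    expand_to_probes,
    segment_vector,
    to_amplitudes,
    to_breakpoints,
    to_segments,
)
from .reference import BreakpointFrequencyTable

DEFAULT_TOLERANCE = 10  # probes


class CoreError(ValueError):
    """Raised when reconstruction is impossible for structurally invalid input."""


@dataclass(frozen=True)
class Aberration:
    """One chromosomal event on a tree edge.

    ``seg_start``/``seg_end`` index homogeneous segments (half-open); probe
    coordinates can be recovered through the tree's partition.  ``delta`` is
    +1 (gain) or -1 (loss/homozygous-deletion step); amplicon events carry
    ``delta = 0`` and probe-interval coordinates in ``probe_span``.
    """

    kind: str  # "gain" | "loss" | "homozygous-deletion" | "amplicon"
    chrom: str
    seg_start: int
    seg_end: int
    delta: int
    probe_span: tuple = None

    def label(self) -> str:
        symbol = {"gain": "+", "loss": "-", "homozygous-deletion": "--",
                  "amplicon": "++"}[self.kind]
        return f"{symbol}{self.chrom}:{self.seg_start}-{self.seg_end - 1}"


@dataclass(frozen=True)
class CorrectionRecord:
    """Audit trail of one unbalanced-chromosome correction."""

    chrom: str
    delta: int
    action: str  # "remove-common" | "add-from-specific" | "mixed"
    steps: tuple  # ((action, slot, sign), ...) unit corrections applied
    cost: int
    alternatives: tuple  # ((description, cost, feasible), ...)


@dataclass(frozen=True)
class MatchedPair:
    """One common breakpoint: same-sign slots of the two samples paired
    within the tolerance window."""

    sign: int
    slot_i: int
    slot_j: int
    common: int  # min of the two amplitudes
    placement: int  # slot carrying the common amplitude in the precursor


@dataclass
class TreeNode:
    node_id: str
    kind: str  # "normal" | "precursor" | "tumor"
    segments: dict  # chrom -> segment-status array (full profile, may hold +-2)
    amplicons: list = field(default_factory=list)  # (chrom, probe_lo, probe_hi)
    children: list = field(default_factory=list)
    parent: str = None


@dataclass
class TreeEdge:
    parent: str
    child: str
    aberrations: list


@dataclass
class StepRecord:
    """One agglomeration step: the pair joined and every candidate score."""

    step: int
    joined: tuple
    ibs: float
    distance: float
    candidates: tuple  # ((id_a, id_b, ibs, distance), ...)


@dataclass
class TumorTree:
    """Rooted lineage tree: normal root, precursor internal nodes, tumor leaves."""

    partition: SegmentPartition
    nodes: dict
    edges: dict  # (parent, child) -> TreeEdge
    root: str
    amplicon_mode: str = "interval"
    steps: list = field(default_factory=list)
    corrections: list = field(default_factory=list)

    def leaf_ids(self) -> list:
        return [n.node_id for n in self.nodes.values() if n.kind == "tumor"]

    def precursor_ids(self) -> list:
        return [n.node_id for n in self.nodes.values() if n.kind == "precursor"]

    def leaf_set(self, node_id: str) -> frozenset:
        node = self.nodes[node_id]
        if not node.children:
            return frozenset([node_id])
        out = set()
        for c in node.children:
            out |= self.leaf_set(c)
        return frozenset(out)

    def probe_profile(self, node_id: str) -> np.ndarray:
        """Per-probe statuses of a node (amplicon intervals overlaid at +2)."""
        node = self.nodes[node_id]
        out = expand_to_probes(node.segments, self.partition)
        mm = self.partition.marker_map
        for chrom, lo, hi in node.amplicons:
            sl = mm.chrom_slice(chrom)
            out[sl.start + lo: sl.start + hi] = 2
        return out

    def newick(self, include_root: bool = True) -> str:
        def rec(nid):
            node = self.nodes[nid]
            if not node.children:
                return nid
            return "(" + ",".join(rec(c) for c in node.children) + ")" + nid

        top = self.nodes[self.root].children[0]
        if include_root:
            return "(" + rec(top) + ")" + self.root + ";"
        return rec(top) + ";"


# ---------------------------------------------------------------------------
# amplitude-vector helpers

def amplitude_vectors(seg_vec: dict) -> dict:
    """Per-chromosome amplitude vectors of a genome-wide segment vector."""
    return {c: to_amplitudes(to_breakpoints(s)) for c, s in seg_vec.items()}


def amplicon_intervals(seg_vec: dict, partition: SegmentPartition) -> list:
    """Maximal probe intervals at status +2, as (chrom, probe_lo, probe_hi)."""
    out = []
    for chrom in partition.marker_map.chrom_order:
        s = seg_vec[chrom]
        bounds = partition.boundaries[chrom]
        j = 0
        while j < len(s):
            if s[j] == 2:
                k = j
                while k + 1 < len(s) and s[k + 1] == 2:
                    k += 1
                out.append((chrom, int(bounds[j]), int(bounds[k + 1])))
                j = k + 1
            else:
                j += 1
    return out


def match_common_chrom(a_i: np.ndarray, a_j: np.ndarray,
                       slot_pos: np.ndarray, tolerance: int):
    """Pair same-sign breakpoints of one chromosome within the tolerance.

    Greedy nearest-first one-to-one matching, processed by increasing probe
    distance (ties by slot index); the common amplitude of a pair is the
    minimum of the two amplitudes and is placed at the slot of the
    larger-amplitude sample (ties -> lower slot).  Residual amplitude stays
    specific to its sample: a breakpoint can be both common and specific when
    its amplitude differs between the samples.

    Returns (common amplitude vector, matched pairs, residual_i, residual_j).
    """
    half = len(slot_pos)
    common = np.zeros(2 * half, dtype=np.int64)
    res_i = a_i.astype(np.int64).copy()
    res_j = a_j.astype(np.int64).copy()
    pairs = []
    for sign, base in ((1, 0), (-1, half)):
        si = np.flatnonzero(a_i[base:base + half] > 0)
        sj = np.flatnonzero(a_j[base:base + half] > 0)
        cands = []
        for p in si:
            for q in sj:
                d = abs(int(slot_pos[p]) - int(slot_pos[q]))
                if d <= tolerance:
                    cands.append((d, min(p, q), max(p, q), int(p), int(q)))
        cands.sort()
        used_i, used_j = set(), set()
        for d, _, _, p, q in cands:
            if p in used_i or q in used_j:
                continue
            used_i.add(p)
            used_j.add(q)
            amp_i, amp_j = int(a_i[base + p]), int(a_j[base + q])
            c = min(amp_i, amp_j)
            if amp_i > amp_j:
                place = p
            elif amp_j > amp_i:
                place = q
            else:
                place = min(p, q)
            common[base + place] += c
            res_i[base + p] -= c
            res_j[base + q] -= c
            pairs.append(MatchedPair(sign, p, q, c, place))
    return common, pairs, res_i, res_j


def match_common(a_i: dict, a_j: dict, partition: SegmentPartition,
                 tolerance: int = DEFAULT_TOLERANCE):
    """Genome-wide common amplitude vector and pairing (see
    :func:`match_common_chrom`)."""
    common, pairs = {}, {}
    for chrom in partition.marker_map.chrom_order:
        c, p, _, _ = match_common_chrom(a_i[chrom], a_j[chrom],
                                        partition.slot_positions(chrom),
                                        tolerance)
        common[chrom] = c
        pairs[chrom] = p
    return common, pairs


def _weight(F, chrom, slot, sign):
    if F is None:
        return 1.0
    return F.weight(chrom, slot, sign)


def ibs(a_i: dict, a_j: dict, partition: SegmentPartition,
        F: BreakpointFrequencyTable = None,
        tolerance: int = DEFAULT_TOLERANCE) -> float:
    """Identical breakpoint score: frequency-weighted shared amplitudes."""
    score = 0.0
    for chrom in partition.marker_map.chrom_order:
        _, pairs, _, _ = match_common_chrom(a_i[chrom], a_j[chrom],
                                            partition.slot_positions(chrom),
                                            tolerance)
        for m in pairs:
            score += m.common * _weight(F, chrom, m.placement, m.sign)
    return score


def distance(a_i: dict, a_j: dict, partition: SegmentPartition,
             F: BreakpointFrequencyTable = None,
             tolerance: int = DEFAULT_TOLERANCE) -> float:
    """Frequency-weighted count of breakpoints differing between two profiles.

    Matched breakpoints contribute their amplitude difference (so a shared
    breakpoint with unequal amplitudes still counts its residual); unmatched
    breakpoints contribute their full amplitude.
    """
    score = 0.0
    for chrom in partition.marker_map.chrom_order:
        slot_pos = partition.slot_positions(chrom)
        half = len(slot_pos)
        ai, aj = a_i[chrom], a_j[chrom]
        _, pairs, res_i, res_j = match_common_chrom(ai, aj, slot_pos, tolerance)
        matched_i = {(m.sign, m.slot_i) for m in pairs}
        matched_j = {(m.sign, m.slot_j) for m in pairs}
        for m in pairs:
            base = 0 if m.sign > 0 else half
            diff = abs(int(ai[base + m.slot_i]) - int(aj[base + m.slot_j]))
            score += diff * _weight(F, chrom, m.placement, m.sign)
        for sign, base in ((1, 0), (-1, half)):
            for k in np.flatnonzero(ai[base:base + half] > 0):
                if (sign, int(k)) not in matched_i:
                    score += int(ai[base + k]) * _weight(F, chrom, int(k), sign)
            for k in np.flatnonzero(aj[base:base + half] > 0):
                if (sign, int(k)) not in matched_j:
                    score += int(aj[base + k]) * _weight(F, chrom, int(k), sign)
    return score


# ---------------------------------------------------------------------------
# precursor reconstruction

def _aligned_breakpoints(a: np.ndarray, pairs, role: str, half: int) -> np.ndarray:
    """Child breakpoint vector with matched amplitudes moved to placement slots."""
    b = a[:half].astype(np.int64) - a[half:].astype(np.int64)
    for m in pairs:
        slot = m.slot_i if role == "i" else m.slot_j
        if slot != m.placement:
            b[slot] -= m.sign * m.common
            b[m.placement] += m.sign * m.common
    return b


def _scenario_cost(b_cp, b_i_al, b_j_al) -> int:
    """Total breakpoint usage of the scenario implied by a candidate precursor:
    precursor events plus both edge event sets."""
    return int(np.abs(b_cp).sum()
               + np.abs(b_i_al - b_cp).sum()
               + np.abs(b_j_al - b_cp).sum())


def _feasible(b_cp: np.ndarray, smax: int) -> bool:
    if b_cp.sum() != 0:
        return False
    s = np.cumsum(b_cp[:-1])
    return bool(np.all(s >= -2) and np.all(s <= smax))


def _correct_chromosome(b_ij, res_i, res_j, b_i_al, b_j_al, chrom, smax,
                        support=None, allow_infeasible=False):
    """Restore breakpoint balance on one chromosome.

    Enumerates every way of applying ``|delta|`` unit corrections — removing
    a unit of common amplitude of ``sign(delta)`` or adding a unit of
    sample-specific amplitude of ``sign(-delta)`` — keeps the feasible ones,
    and picks the minimum-usage scenario.  Cost ties are broken by the
    breakpoint's support among the *other* samples of the patient
    (``support(slot, sign)``: profiles outside the joined pair carrying a
    same-sign breakpoint there): a candidate that adds well-supported
    breakpoints, or removes unsupported ones, describes the likelier
    history.  Residual ties prefer remove-common, then the lowest slot.
    """
    half = len(b_ij)
    delta = int(b_ij.sum())
    sgn = 1 if delta > 0 else -1
    n_units = abs(delta)
    units = []  # (action, slot, sign, multiplicity)
    for k in range(half):
        amp = b_ij[k] if sgn > 0 else -b_ij[k]
        if amp > 0:
            units.append(("remove-common", k, sgn, int(amp)))
    base = 0 if -sgn > 0 else half
    for k in range(half):
        avail = int(res_i[base + k]) + int(res_j[base + k])
        if avail > 0:
            units.append(("add-from-specific", k, -sgn, int(avail)))
    if not units:
        raise CoreError(
            f"chromosome {chrom!r}: unbalanced common breakpoints (delta={delta}) "
            f"with no candidate correction; input profiles are inconsistent")

    best = None
    best_any = None
    alternatives = []
    for combo in itertools.combinations_with_replacement(range(len(units)), n_units):
        counts = {}
        ok = True
        for u in combo:
            counts[u] = counts.get(u, 0) + 1
            if counts[u] > units[u][3]:
                ok = False
                break
        if not ok:
            continue
        b_corr = b_ij.copy()
        steps = []
        n_adds = 0
        net_support = 0
        for u, c in sorted(counts.items()):
            action, slot, sign, _ = units[u]
            sup = support(slot, sign) if support is not None else 0
            if action == "remove-common":
                b_corr[slot] -= sign * c
                net_support -= sup * c
            else:
                b_corr[slot] += sign * c
                n_adds += c
                net_support += sup * c
            steps.extend([(action, slot, sign)] * c)
        feasible = _feasible(b_corr, smax)
        cost = _scenario_cost(b_corr, b_i_al, b_j_al)
        desc = "+".join(f"{a[0]}@{a[1]}" for a in steps)
        alternatives.append((desc, cost, feasible))
        # ties: best-supported history first; residual ties prefer removal —
        # a genuinely erased shared breakpoint is vouched for by the other
        # samples, so an unsupported tie is most likely a coincidental match
        # whose false common breakpoint should go
        key = (cost, -net_support, n_adds,
               tuple(sorted((s[1], s[0] != "remove-common")
                            for s in steps)))
        if best_any is None or key < best_any[0]:
            best_any = (key, b_corr, steps, cost, n_adds)
        if not feasible:
            continue
        if best is None or key < best[0]:
            best = (key, b_corr, steps, cost, n_adds)
    if best is None and allow_infeasible and best_any is not None:
        best = best_any
    if best is None:
        raise CoreError(
            f"chromosome {chrom!r}: no feasible correction for delta={delta}")
    _, b_corr, steps, cost, n_adds = best
    if n_adds == 0:
        action = "remove-common"
    elif n_adds == len(steps):
        action = "add-from-specific"
    else:
        action = "mixed"
    record = CorrectionRecord(chrom=chrom, delta=delta, action=action,
                              steps=tuple(steps), cost=cost,
                              alternatives=tuple(alternatives))
    return b_corr, record


def _balance_and_repair(b_ij, res_i, res_j, b_i_al, b_j_al, chrom, smax,
                        support=None):
    """Drive the common breakpoint vector to a balanced, in-range profile.

    Imbalance (``sum b != 0``) invokes the minimum-usage correction search.
    A balanced vector whose implied statuses still leave the authorized range
    — possible when stacked common amplitudes coincide — sheds one unit of
    the common breakpoint bounding the first violation, after which balance
    is restored again.  Each round removes or adds single units, so the loop
    terminates; it is a guard for pathological inputs and is not normally
    entered more than once.
    """
    b = b_ij.copy()
    corrections = []
    for _ in range(4 * (int(np.abs(b_ij).sum()) + 2)):
        if b.sum() != 0:
            b, record = _correct_chromosome(
                b, res_i, res_j, b_i_al, b_j_al, chrom, smax,
                support=support, allow_infeasible=True)
            corrections.append(record)
            continue
        s = np.cumsum(b[:-1])
        if np.all(s >= -2) and np.all(s <= smax):
            return b, corrections
        v = int(np.flatnonzero((s < -2) | (s > smax))[0])
        sign = -1 if s[v] < -2 else 1
        slots = np.flatnonzero(np.sign(b[:v + 1]) == sign)
        if len(slots) == 0:
            break
        k = int(slots[-1])
        b[k] -= sign  # shed one unit of the bounding common breakpoint
        corrections.append(CorrectionRecord(
            chrom=chrom, delta=0, action="remove-common",
            steps=(("remove-common", k, sign),),
            cost=_scenario_cost(b, b_i_al, b_j_al), alternatives=()))
    raise CoreError(
        f"chromosome {chrom!r}: could not restore a viable precursor profile")


def decompose_difference(s_parent: np.ndarray, s_child: np.ndarray, chrom: str):
    """Split ``s_child - s_parent`` into unit-level interval aberrations.

    Sweeps the chromosome peeling one unit-deep interval of uniform sign at a
    time, so intermediate profiles stay between parent and child and hence
    within the authorized status range.  A unit loss whose resulting level
    reaches -2 is labelled a homozygous-deletion step.
    """
    d = (np.asarray(s_child) - np.asarray(s_parent)).astype(np.int64)
    level = np.asarray(s_parent).astype(np.int64).copy()
    events = []
    while np.any(d != 0):
        j = int(np.flatnonzero(d != 0)[0])
        g = 1 if d[j] > 0 else -1
        k = j
        while k + 1 < len(d) and np.sign(d[k + 1]) == g:
            k += 1
        level[j:k + 1] += g
        d[j:k + 1] -= g
        if g > 0:
            kind = "gain"
        else:
            kind = ("homozygous-deletion"
                    if np.any(level[j:k + 1] == -2) else "loss")
        events.append(Aberration(kind=kind, chrom=chrom, seg_start=j,
                                 seg_end=k + 1, delta=g))
    return events


def _support_function(context, chrom, slot_pos, tolerance):
    """Breakpoint support among other samples: number of context profiles
    with a same-sign breakpoint within the tolerance window of a slot."""
    half = len(slot_pos)
    ups, downs = [], []
    for a in context:
        ac = a[chrom]
        ups.append(slot_pos[np.flatnonzero(ac[:half] > 0)])
        downs.append(slot_pos[np.flatnonzero(ac[half:] > 0)])

    def support(slot, sign):
        pos = slot_pos[slot]
        pools = ups if sign > 0 else downs
        return sum(bool(len(p) and np.min(np.abs(p - pos)) <= tolerance)
                   for p in pools)

    return support


def _rescue_pairs(pairs, res_i, res_j, slot_pos, tolerance, support):
    """Second matching pass for displaced shared breakpoints.

    Breakpoint calls on noisy data are occasionally relocated beyond the
    matching tolerance, leaving both copies of a genuinely shared breakpoint
    specific and the chromosome unbalanced.  Residual same-sign breakpoints
    within an extended window (``2 * tolerance + 1``) are therefore paired —
    but only when another sample of the patient independently carries a
    same-sign breakpoint within tolerance of one of the copies, which a
    coincidental proximity of two private breakpoints almost never enjoys.
    The pair is placed at the externally supported copy's slot.
    """
    half = len(slot_pos)
    extended = 2 * tolerance + 1
    for sign, base in ((1, 0), (-1, half)):
        si = np.flatnonzero(res_i[base:base + half] > 0)
        sj = np.flatnonzero(res_j[base:base + half] > 0)
        cands = []
        for p in si:
            for q in sj:
                d = abs(int(slot_pos[p]) - int(slot_pos[q]))
                if tolerance < d <= extended:
                    cands.append((d, min(p, q), max(p, q), int(p), int(q)))
        cands.sort()
        used_i, used_j = set(), set()
        for d, _, _, p, q in cands:
            if p in used_i or q in used_j:
                continue
            sup_p, sup_q = support(p, sign), support(q, sign)
            if max(sup_p, sup_q) == 0:
                continue
            used_i.add(p)
            used_j.add(q)
            c = min(int(res_i[base + p]), int(res_j[base + q]))
            place = (p if sup_p > sup_q else q if sup_q > sup_p
                     else min(p, q))
            res_i[base + p] -= c
            res_j[base + q] -= c
            pairs.append(MatchedPair(sign, p, q, c, place))


def reconstruct_precursor(a_i: dict, a_j: dict, partition: SegmentPartition,
                          tolerance: int = DEFAULT_TOLERANCE,
                          amplicon_mode: str = "interval",
                          context=()):
    """Infer the common precursor of two nodes from their shared breakpoints.

    ``context`` may hold the amplitude vectors of the patient's other
    samples; they are used to verify rescues of shared breakpoints displaced
    beyond the matching tolerance, and unbalanced-chromosome corrections
    break cost ties in favor of the history supported by those samples.

    Returns ``(cp_segments, corrections, edge_i, edge_j)`` where
    ``cp_segments`` maps chromosome to the precursor's (working) segment
    vector, ``corrections`` lists :class:`CorrectionRecord` for every
    chromosome whose shared breakpoints were unbalanced, and ``edge_*`` hold
    the :class:`Aberration` lists of the two descending edges.
    """
    smax = 1 if amplicon_mode == "interval" else 2
    cp, corrections, edge_i, edge_j = {}, [], [], []
    for chrom in partition.marker_map.chrom_order:
        slot_pos = partition.slot_positions(chrom)
        half = len(slot_pos)
        common, pairs, res_i, res_j = match_common_chrom(
            a_i[chrom], a_j[chrom], slot_pos, tolerance)
        support = (_support_function(context, chrom, slot_pos, tolerance)
                   if context else None)
        if support is not None and tolerance > 0:
            _rescue_pairs(pairs, res_i, res_j, slot_pos, tolerance, support)
            common = np.zeros(2 * half, dtype=np.int64)
            for m in pairs:
                common[(0 if m.sign > 0 else half) + m.placement] += m.common
        b_ij = common[:half] - common[half:]
        b_i_al = _aligned_breakpoints(a_i[chrom], pairs, "i", half)
        b_j_al = _aligned_breakpoints(a_j[chrom], pairs, "j", half)
        b_cp, chrom_corrections = _balance_and_repair(
            b_ij, res_i, res_j, b_i_al, b_j_al, chrom, smax, support)
        corrections.extend(chrom_corrections)
        s_cp = to_segments(b_cp)
        cp[chrom] = s_cp
        s_i = to_segments(b_i_al)
        s_j = to_segments(b_j_al)
        edge_i.extend(decompose_difference(s_cp, s_i, chrom))
        edge_j.extend(decompose_difference(s_cp, s_j, chrom))
    return cp, corrections, edge_i, edge_j


def place_amplicons(amp_i, amp_j, tolerance: int = DEFAULT_TOLERANCE):
    """Assign amplicon intervals to the precursor or to the child edges.

    Intervals present in both children — same chromosome, both boundaries
    within the tolerance (in probes) — ascend to the precursor as the
    intersection of the two intervals; the rest stay specific to their edge.

    Returns ``(common, specific_i, specific_j)`` interval lists.
    """
    common, spec_i = [], []
    remaining_j = list(amp_j)
    for chrom, lo, hi in amp_i:
        match = None
        best = None
        for idx, (c2, lo2, hi2) in enumerate(remaining_j):
            if c2 != chrom:
                continue
            d = max(abs(lo - lo2), abs(hi - hi2))
            if d <= tolerance and (best is None or d < best):
                best, match = d, idx
        if match is None:
            spec_i.append((chrom, lo, hi))
        else:
            c2, lo2, hi2 = remaining_j.pop(match)
            common.append((chrom, max(lo, lo2), min(hi, hi2)))
    return common, spec_i, remaining_j


# ---------------------------------------------------------------------------
# tree construction

def build_tree(profiles, marker_map: MarkerMap,
               F: BreakpointFrequencyTable = None,
               tolerance: int = DEFAULT_TOLERANCE,
               amplicon_mode: str = "interval") -> TumorTree:
    """Reconstruct the full tumor lineage tree of one patient.

    Parameters
    ----------
    profiles : list of DiscreteProfile
        At least two tumors on the shared marker map.
    F : BreakpointFrequencyTable, optional
        Reference-cohort breakpoint frequencies; ``None`` means unweighted.
    tolerance : int
        Maximum probe offset for two breakpoints to be deemed identical.
    amplicon_mode : {"interval", "breakpoint"}
        See the module docstring.

    The homogeneous-segment partition is fixed once from all input tumors;
    every reconstructed profile lives on it.
    """
    if len(profiles) < 2:
        raise CoreError("at least 2 tumor profiles are required")
    if amplicon_mode not in ("interval", "breakpoint"):
        raise CoreError(f"unknown amplicon_mode {amplicon_mode!r}")
    partition = delineate_segments(profiles, marker_map)

    nodes, edges = {}, {}
    working, amps = {}, {}
    for p in profiles:
        if p.sample_id in nodes:
            raise CoreError(f"duplicate sample id {p.sample_id!r}")
        full = segment_vector(p, partition)
        if amplicon_mode == "interval":
            w = {c: np.minimum(s, 1) for c, s in full.items()}
            intervals = amplicon_intervals(full, partition)
        else:
            w, intervals = full, []
        nodes[p.sample_id] = TreeNode(p.sample_id, "tumor", full,
                                      amplicons=intervals)
        working[p.sample_id] = w
        amps[p.sample_id] = amplitude_vectors(w)

    tree = TumorTree(partition=partition, nodes=nodes, edges=edges, root="normal",
                     amplicon_mode=amplicon_mode)
    front = sorted(nodes)
    step = 0
    while len(front) > 1:
        step += 1
        candidates = []
        for x, y in itertools.combinations(front, 2):
            sc = ibs(amps[x], amps[y], partition, F, tolerance)
            dist = distance(amps[x], amps[y], partition, F, tolerance)
            candidates.append((x, y, sc, dist))
        candidates.sort(key=lambda c: (-c[2], c[3], tuple(sorted((c[0], c[1])))))
        x, y, sc, dist = candidates[0]
        cp_id = f"CP{step}"
        context = [amps[n] for n in front if n not in (x, y)]
        cp_seg, corrections, ev_x, ev_y = reconstruct_precursor(
            amps[x], amps[y], partition, tolerance, amplicon_mode,
            context=context)
        tree.corrections.extend(corrections)

        cp_amp_intervals = []
        amp_ev_x, amp_ev_y = [], []
        if amplicon_mode == "interval":
            common_amp, spec_x, spec_y = place_amplicons(
                nodes[x].amplicons, nodes[y].amplicons, tolerance)
            cp_amp_intervals = common_amp
            amp_ev_x = [Aberration("amplicon", c, -1, -1, 0, probe_span=(lo, hi))
                        for c, lo, hi in spec_x]
            amp_ev_y = [Aberration("amplicon", c, -1, -1, 0, probe_span=(lo, hi))
                        for c, lo, hi in spec_y]

        nodes[cp_id] = TreeNode(cp_id, "precursor", cp_seg,
                                amplicons=cp_amp_intervals,
                                children=[x, y])
        nodes[x].parent = cp_id
        nodes[y].parent = cp_id
        edges[(cp_id, x)] = TreeEdge(cp_id, x, ev_x + amp_ev_x)
        edges[(cp_id, y)] = TreeEdge(cp_id, y, ev_y + amp_ev_y)
        tree.steps.append(StepRecord(step, (x, y), sc, dist,
                                     tuple((a, b, s, d)
                                           for a, b, s, d in candidates)))
        working[cp_id] = cp_seg
        amps[cp_id] = amplitude_vectors(cp_seg)
        front = [n for n in front if n not in (x, y)] + [cp_id]

    top = front[0]
    root_seg = {c: np.zeros(partition.n_segments(c), dtype=np.int64)
                for c in marker_map.chrom_order}
    nodes["normal"] = TreeNode("normal", "normal", root_seg, children=[top])
    nodes[top].parent = "normal"
    root_events = []
    for chrom in marker_map.chrom_order:
        root_events.extend(decompose_difference(root_seg[chrom],
                                                working[top][chrom], chrom))
    root_events.extend(
        Aberration("amplicon", c, -1, -1, 0, probe_span=(lo, hi))
        for c, lo, hi in nodes[top].amplicons)
    edges[("normal", top)] = TreeEdge("normal", top, root_events)
    return tree


# ---------------------------------------------------------------------------
# export

def save_tree(tree: TumorTree, path) -> None:
    """Serialize a tree (marker map, partition, profiles, edges) to JSON."""
    import json

    mm = tree.partition.marker_map
    doc = {
        "marker_map": {
            "probe_ids": mm.probe_ids.tolist(),
            "chroms": mm.chroms.tolist(),
            "positions": mm.positions.tolist(),
        },
        "boundaries": {c: b.tolist() for c, b in tree.partition.boundaries.items()},
        "amplicon_mode": tree.amplicon_mode,
        "root": tree.root,
        "nodes": [
            {"id": n.node_id, "kind": n.kind,
             "segments": {c: s.tolist() for c, s in n.segments.items()},
             "amplicons": [list(a) for a in n.amplicons],
             "children": n.children, "parent": n.parent}
            for n in tree.nodes.values()
        ],
        "edges": [
            {"parent": e.parent, "child": e.child,
             "aberrations": [
                 {"kind": ab.kind, "chrom": ab.chrom,
                  "seg_start": ab.seg_start, "seg_end": ab.seg_end,
                  "delta": ab.delta,
                  "probe_span": list(ab.probe_span) if ab.probe_span else None}
                 for ab in e.aberrations]}
            for e in tree.edges.values()
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_tree(path) -> TumorTree:
    """Inverse of :func:`save_tree`."""
    import json

    with open(path) as fh:
        doc = json.load(fh)
    mmd = doc["marker_map"]
    mm = MarkerMap(np.array(mmd["probe_ids"], object),
                   np.array(mmd["chroms"], object),
                   np.array(mmd["positions"]))
    partition = SegmentPartition(
        mm, {c: np.array(b, dtype=np.int64)
             for c, b in doc["boundaries"].items()})
    nodes = {}
    for nd in doc["nodes"]:
        nodes[nd["id"]] = TreeNode(
            nd["id"], nd["kind"],
            {c: np.array(s, dtype=np.int64) for c, s in nd["segments"].items()},
            amplicons=[tuple(a) for a in nd["amplicons"]],
            children=list(nd["children"]), parent=nd["parent"])
    edges = {}
    for ed in doc["edges"]:
        abs_ = [Aberration(a["kind"], a["chrom"], a["seg_start"], a["seg_end"],
                           a["delta"],
                           probe_span=tuple(a["probe_span"]) if a["probe_span"]
                           else None)
                for a in ed["aberrations"]]
        edges[(ed["parent"], ed["child"])] = TreeEdge(ed["parent"], ed["child"],
                                                      abs_)
    return TumorTree(partition=partition, nodes=nodes, edges=edges,
                     root=doc["root"], amplicon_mode=doc["amplicon_mode"])


def _edge_label(edge: TreeEdge) -> str:
    return ", ".join(ab.label() for ab in edge.aberrations) or "(none)"

def export_tree(tree: TumorTree, fmt: str) -> str:
    """Serialize a tree as DOT, Newick or a TSV aberration/profile dump.

    DOT carries node kinds and per-edge aberration summaries; Newick carries
    the leaf-labelled topology only; TSV holds per-node segment profiles
    followed by the per-edge aberration table.
    """
    if fmt == "dot":
        lines = ["digraph lineage {", '  node [shape=box];']
        for nid, node in tree.nodes.items():
            lines.append(f'  "{nid}" [label="{nid}\\n({node.kind})"];')
        for (parent, child), edge in tree.edges.items():
            lines.append(
                f'  "{parent}" -> "{child}" [label="{_edge_label(edge)}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "newick":
        return tree.newick() + "\n"
    if fmt == "tsv":
        mm = tree.partition.marker_map
        lines = ["#nodes", "node\tkind\tchrom\tsegment\tstatus"]
        for nid, node in tree.nodes.items():
            for chrom in mm.chrom_order:
                for j, v in enumerate(node.segments[chrom]):
                    lines.append(f"{nid}\t{node.kind}\t{chrom}\t{j}\t{int(v)}")
        lines += ["#edges", "parent\tchild\tkind\tchrom\tseg_start\tseg_end\tdelta"]
        for (parent, child), edge in tree.edges.items():
            for ab in edge.aberrations:
                lines.append(f"{parent}\t{child}\t{ab.kind}\t{ab.chrom}\t"
                             f"{ab.seg_start}\t{ab.seg_end}\t{ab.delta}")
        return "\n".join(lines) + "\n"
    raise CoreError(f"unknown export format {fmt!r}")
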