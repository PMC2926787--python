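"""Model/results facade for tumor lineage reconstruction.

`LineageModel` bundles one patient's data (probe-level profiles, an optional
reference cohort for breakpoint-frequency weighting, the matching tolerance)
and `fit()` runs the agglomerative reconstruction, returning a
`LineageResult` that carries the tree, the per-step score log, the
unbalanced-chromosome corrections, and export/plot helpers.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import core
from .core import build_tree, export_tree
from .profiles import delineate_segments, read_profiles
from .reference import estimate_frequencies


class LineageModel:
    """Tumor lineage reconstruction for the samples of one patient.

    Parameters
    ----------
    profiles : list of DiscreteProfile
        At least two tumors of one patient on a shared marker map.
    marker_map : MarkerMap
    reference : list of DiscreteProfile, optional
        Independent tumors used to estimate breakpoint frequencies ``F_k``;
        without it, shared breakpoints are counted unweighted.
    tolerance : int
        Maximum probe offset for two breakpoints to count as identical
        (default 10, suitable for discretized array data).
    amplicon_mode : {"interval", "breakpoint"}
        How +2 statuses enter the breakpoint arithmetic; see
        :mod:`tumult.core`.

    Examples
    --------
    >>> model = LineageModel.from_table("profiles.tsv")   # doctest: +SKIP
    >>> result = model.fit()                              # doctest: +SKIP
    >>> print(result.summary())                           # doctest: +SKIP
    """

    def __init__(self, profiles, marker_map, reference=None,
                 tolerance: int = core.DEFAULT_TOLERANCE,
                 amplicon_mode: str = "interval"):
        self.profiles = list(profiles)
        self.marker_map = marker_map
        self.reference = list(reference) if reference else None
        self.tolerance = int(tolerance)
        self.amplicon_mode = amplicon_mode

    @classmethod
    def from_table(cls, path, reference_path=None, **kwargs) -> "LineageModel":
        """Build a model from tab-delimited probe tables
        (``probe_id  chrom  pos  <sample> ...``)."""
        mm, profiles = read_profiles(path)
        reference = None
        if reference_path is not None:
            mm_ref, reference = read_profiles(reference_path)
            if mm_ref.n_probes != mm.n_probes or np.any(
                    mm_ref.positions != mm.positions):
                raise ValueError(
                    "reference cohort is not on the patient's marker map")
        return cls(profiles, mm, reference=reference, **kwargs)

    def fit(self) -> "LineageResult":
        """Run the agglomerative reconstruction and return the results."""
        F = None
        if self.reference:
            partition = delineate_segments(self.profiles, self.marker_map)
            F = estimate_frequencies(self.reference, partition, self.tolerance)
        tree = build_tree(self.profiles, self.marker_map, F=F,
                          tolerance=self.tolerance,
                          amplicon_mode=self.amplicon_mode)
        return LineageResult(self, tree, F)


class LineageResult:
    """Fitted lineage: the reconstructed tree plus diagnostics."""

    def __init__(self, model: LineageModel, tree, frequency_table=None):
        self.model = model
        self.tree = tree
        self.frequency_table = frequency_table

    @property
    def steps(self):
        return self.tree.steps

    @property
    def corrections(self):
        return self.tree.corrections

    def nodes_frame(self) -> pd.DataFrame:
        """Long-format per-node segment profiles with genomic coordinates."""
        part = self.tree.partition
        mm = part.marker_map
        rows = []
        for nid, node in self.tree.nodes.items():
            for chrom in mm.chrom_order:
                sl = mm.chrom_slice(chrom)
                pos = mm.positions[sl]
                for j, (lo, hi) in enumerate(part.segment_spans(chrom)):
                    rows.append((nid, node.kind, chrom, j, int(pos[lo]),
                                 int(pos[hi - 1]),
                                 int(node.segments[chrom][j])))
        return pd.DataFrame(rows, columns=["node", "kind", "chrom", "segment",
                                           "start_pos", "end_pos", "status"])

    def edges_frame(self) -> pd.DataFrame:
        """Per-edge aberration table (one row per event)."""
        rows = []
        for (parent, child), edge in self.tree.edges.items():
            for ab in edge.aberrations:
                rows.append((parent, child, ab.kind, ab.chrom, ab.seg_start,
                             ab.seg_end, ab.delta, ab.label()))
        return pd.DataFrame(rows, columns=["parent", "child", "kind", "chrom",
                                           "seg_start", "seg_end", "delta",
                                           "label"])

    def to_dot(self) -> str:
        return export_tree(self.tree, "dot")

    def to_newick(self) -> str:
        return export_tree(self.tree, "newick")

    def summary(self) -> str:
        """Human-readable fit report (samples, joins, corrections, events)."""
        mm = self.model.marker_map
        part = self.tree.partition
        n_ref = (self.frequency_table.n_reference
                 if self.frequency_table else 0)
        lines = [
            "Tumor lineage reconstruction",
            "=" * 60,
            f"samples:             {len(self.model.profiles)}",
            f"probes:              {mm.n_probes} on {len(mm.chrom_order)} chromosomes",
            f"homogeneous segments:{part.total_segments():>6}",
            f"tolerance:           {self.model.tolerance} probes",
            f"reference cohort:    {n_ref} samples"
            + ("" if n_ref else " (unweighted IBS)"),
            "",
            "joins (identical breakpoint score):",
            f"{'step':>4} {'joined':<24} {'IBS':>10} {'distance':>10}",
        ]
        for s in self.steps:
            pair = " + ".join(s.joined)
            lines.append(f"{s.step:>4} {pair:<24} {s.ibs:>10.3f} "
                         f"{s.distance:>10.3f}")
        lines.append("")
        lines.append(f"unbalanced-chromosome corrections: {len(self.corrections)}")
        for c in self.corrections:
            lines.append(f"  {c.chrom}: delta={c.delta:+d} -> {c.action} "
                         f"(usage {c.cost})")
        lines.append("")
        lines.append("edge aberration counts:")
        for (parent, child), edge in self.tree.edges.items():
            lines.append(f"  {parent} -> {child}: {len(edge.aberrations)}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write tree.dot, tree.nwk, tree.json, nodes.tsv, edges.tsv and
        corrections.log under ``outdir``."""
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "tree.dot"), "w") as fh:
            fh.write(self.to_dot())
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.to_newick())
        core.save_tree(self.tree, os.path.join(outdir, "tree.json"))
        self.nodes_frame().to_csv(os.path.join(outdir, "nodes.tsv"),
                                  sep="\t", index=False)
        self.edges_frame().to_csv(os.path.join(outdir, "edges.tsv"),
                                  sep="\t", index=False)
        with open(os.path.join(outdir, "corrections.log"), "w") as fh:
            for c in self.corrections:
                fh.write(f"{c.chrom}\tdelta={c.delta:+d}\t{c.action}\t"
                         f"steps={c.steps}\tusage={c.cost}\t"
                         f"alternatives={len(c.alternatives)}\n")

    def plot_tree(self, ax=None):
        """Draw the lineage tree (leaves at the bottom, normal cell on top);
        edges are annotated with their aberration counts."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        xs = {}
        leaves = sorted(self.tree.leaf_ids())
        for i, leaf in enumerate(leaves):
            xs[leaf] = float(i)

        def depth(nid):
            node = self.tree.nodes[nid]
            if not node.children:
                return 0
            return 1 + max(depth(c) for c in node.children)

        def x_of(nid):
            if nid in xs:
                return xs[nid]
            node = self.tree.nodes[nid]
            xs[nid] = float(np.mean([x_of(c) for c in node.children]))
            return xs[nid]

        for nid, node in self.tree.nodes.items():
            y = depth(nid)
            ax.text(x_of(nid), y, nid, ha="center", va="center",
                    bbox=dict(boxstyle="round", fc="w"))
        for (parent, child), edge in self.tree.edges.items():
            x0, y0 = x_of(parent), depth(parent)
            x1, y1 = x_of(child), depth(child)
            ax.plot([x0, x1], [y0, y1], "k-", lw=1, zorder=0)
            ax.annotate(str(len(edge.aberrations)),
                        ((x0 + x1) / 2, (y0 + y1) / 2), fontsize=8,
                        color="tab:blue")
        ax.set_axis_off()
        return ax
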