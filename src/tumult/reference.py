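"""Breakpoint frequencies in a reference cohort of independent tumors.

Breakpoints recurring at the same genomic location across unrelated tumors
are likely fragile-site or technical artefacts and carry little lineage
information: two related samples sharing such a breakpoint may simply have
acquired it independently.  The identical-breakpoint score therefore weights
each shared breakpoint by ``1 - F_k``, where ``F_k`` is the fraction of
reference samples carrying a same-sign breakpoint within the tolerance
window of slot *k*.  With no reference cohort, ``F`` is identically zero and
the score degenerates to the plain count of shared breakpoint amplitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .profiles import DiscreteProfile, SegmentPartition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BreakpointFrequencyTable:
    """Per-slot breakpoint frequencies on a patient's segment partition.

    ``up[chrom]`` / ``down[chrom]`` are arrays of length N + 1 with values in
    [0, 1]: the fraction of reference samples carrying a same-sign breakpoint
    within the tolerance window of each slot.
    """

    up: dict
    down: dict
    n_reference: int = 0

    def weight(self, chrom, slot: int, sign: int) -> float:
        """Return ``1 - F_k`` for one (slot, sign); 1.0 when no table entry."""
        table = self.up if sign > 0 else self.down
        if chrom not in table:
            return 1.0
        return 1.0 - float(table[chrom][slot])

    @classmethod
    def zeros(cls, partition: SegmentPartition) -> "BreakpointFrequencyTable":
        up = {c: np.zeros(partition.n_segments(c) + 1)
              for c in partition.marker_map.chrom_order}
        down = {c: np.zeros(partition.n_segments(c) + 1)
                for c in partition.marker_map.chrom_order}
        return cls(up=up, down=down, n_reference=0)


def _probe_breakpoints(status: np.ndarray):
    """Signed breakpoints of a per-probe chromosome profile.

    Returns (boundary_index, sign) pairs where ``boundary_index`` counts probe
    boundaries 0..n (ends included): the same coordinate system as partition
    slots.
    """
    n = len(status)
    b = np.empty(n + 1, dtype=np.int64)
    b[0] = status[0]
    b[1:-1] = np.diff(status)
    b[-1] = -status[-1]
    idx = np.flatnonzero(b)
    return idx, np.sign(b[idx])


def estimate_frequencies(reference, partition: SegmentPartition,
                         tolerance: int = 0) -> BreakpointFrequencyTable:
    """Estimate ``F_k`` at every breakpoint slot of the patient's partition.

    Parameters
    ----------
    reference : list of DiscreteProfile
        Independent tumors on the same marker map as the patient.
    partition : SegmentPartition
        The patient's homogeneous-segment partition, whose slots define the
        query coordinate system.
    tolerance : int
        Maximum probe offset for a reference breakpoint to count toward a
        slot.  A reference sample contributes at most 1 to a slot's count
        however many same-sign breakpoints fall in its window.

    Returns
    -------
    BreakpointFrequencyTable
        All-zero when the reference cohort is empty (a warning is logged).
    """
    mm = partition.marker_map
    up = {c: np.zeros(partition.n_segments(c) + 1) for c in mm.chrom_order}
    down = {c: np.zeros(partition.n_segments(c) + 1) for c in mm.chrom_order}
    if not reference:
        logger.warning("empty reference cohort: all breakpoint frequencies set to 0")
        return BreakpointFrequencyTable(up=up, down=down, n_reference=0)
    for prof in reference:
        if len(prof.status) != mm.n_probes:
            raise ValueError(
                f"reference sample {prof.sample_id!r} is not on the patient's "
                f"marker map")
        for chrom in mm.chrom_order:
            sl = mm.chrom_slice(chrom)
            idx, signs = _probe_breakpoints(prof.status[sl])
            slots = partition.slot_positions(chrom)
            for sign, table in ((1, up), (-1, down)):
                pts = idx[signs == sign]
                if len(pts) == 0:
                    continue
                # sample counts once per slot, however many hits in window
                hit = np.min(np.abs(slots[:, None] - pts[None, :]), axis=1) <= tolerance
                table[chrom][hit] += 1.0
    n = len(reference)
    for c in mm.chrom_order:
        up[c] /= n
        down[c] /= n
    return BreakpointFrequencyTable(up=up, down=down, n_reference=n)
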