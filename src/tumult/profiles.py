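"""Probe-level copy-number profiles and their segment/breakpoint/amplitude encodings.

A tumor's discretized copy-number profile on one chromosome admits three
equivalent encodings:

``s``
    segment vector: the copy-number status of each of the *N* homogeneous
    segments, with values in ``{-2, -1, 0, 1, 2}`` (homozygous deletion,
    loss, normal, gain, amplification);
``b``
    breakpoint vector of length *N* + 1: ``b[0] = s[0]``,
    ``b[i] = s[i] - s[i-1]`` and ``b[N] = -s[N-1]``, so a breakpoint sits
    between segments *i* - 1 and *i* iff ``b[i] != 0``, with chromosome ends
    counted as breakpoints whenever the terminal status is non-normal;
``a``
    amplitude vector of length 2(*N* + 1): 'up' breakpoints (``b > 0``) in
    the first half, 'down' breakpoints (``-b`` for ``b < 0``) in the second.

All three maps are bijections, which the round-trip helpers below exploit.
Because every aberration creates one 'up' and one 'down' breakpoint, a
breakpoint vector derived from a real profile always sums to zero
("balanced"); balance must be re-checked for vectors assembled from
breakpoints *shared* between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STATUSES = (-2, -1, 0, 1, 2)

STATUS_NAMES = {
    -2: "homozygous deletion",
    -1: "loss",
    0: "normal",
    1: "gain",
    2: "amplification",
}


class ProfileError(ValueError):
    """Raised for malformed probe tables or invalid copy-number statuses."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered probe grid shared by all samples of a patient.

    Parameters
    ----------
    probe_ids : array of str
    chroms : array of str
        Chromosome label per probe; probes of one chromosome are contiguous.
    positions : array of int
        Base-pair position per probe, strictly increasing within a chromosome.
    """

    probe_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    chrom_order: tuple = field(init=False)

    def __post_init__(self):
        pid = np.asarray(self.probe_ids, dtype=object)
        chrom = np.asarray(self.chroms, dtype=object)
        pos = np.asarray(self.positions, dtype=np.int64)
        if not (len(pid) == len(chrom) == len(pos)):
            raise ProfileError("probe_ids, chroms and positions must have equal length")
        object.__setattr__(self, "probe_ids", pid)
        object.__setattr__(self, "chroms", chrom)
        object.__setattr__(self, "positions", pos)
        order, seen = [], set()
        for c in chrom:
            if c in seen:
                if c != order[-1]:
                    raise ProfileError(f"probes of chromosome {c!r} are not contiguous")
            else:
                seen.add(c)
                order.append(c)
        object.__setattr__(self, "chrom_order", tuple(order))
        for c in order:
            p = pos[chrom == c]
            if len(p) < 2:
                raise ProfileError(f"chromosome {c!r} has fewer than 2 probes")
            d = np.diff(p)
            if np.any(d <= 0):
                bad = int(np.flatnonzero(d <= 0)[0]) + 1
                which = pid[chrom == c][bad]
                raise ProfileError(
                    f"positions not strictly increasing on chromosome {c!r} "
                    f"at probe {which!r}"
                )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def chrom_slice(self, chrom) -> slice:
        """Global probe-index slice of one chromosome."""
        idx = np.flatnonzero(self.chroms == chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_sizes(self) -> dict:
        return {c: int(np.sum(self.chroms == c)) for c in self.chrom_order}


@dataclass(frozen=True)
class DiscreteProfile:
    """Per-probe discrete copy-number status of one sample on a :class:`MarkerMap`."""

    sample_id: str
    status: np.ndarray

    def __post_init__(self):
        st = np.asarray(self.status, dtype=np.int64)
        object.__setattr__(self, "status", st)
        bad = ~np.isin(st, VALID_STATUSES)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ProfileError(
                f"sample {self.sample_id!r}: status {st[i]} at probe index {i} "
                f"is outside {{-2, -1, 0, 1, 2}}"
            )


@dataclass(frozen=True)
class SegmentPartition:
    """Homogeneous-segment partition of every chromosome.

    ``boundaries[chrom]`` holds local probe indices ``0 = t0 < t1 < ... < tN``
    (with ``tN`` = number of probes on the chromosome): segment *j* covers
    probes ``[t_j, t_{j+1})``.  Breakpoint slot *i* (``i = 0..N``) sits at
    probe boundary ``t_i``, i.e. between the last probe of segment *i* - 1 and
    the first probe of segment *i*; slots 0 and *N* are the chromosome ends.
    Slot-to-slot distances are measured in probes as ``|t_i - t_j|``.
    """

    marker_map: MarkerMap
    boundaries: dict

    def n_segments(self, chrom) -> int:
        return len(self.boundaries[chrom]) - 1

    def slot_positions(self, chrom) -> np.ndarray:
        """Probe-boundary index of every breakpoint slot (length N + 1)."""
        return np.asarray(self.boundaries[chrom])

    def segment_spans(self, chrom):
        """Yield (start, end) half-open local probe ranges of each segment."""
        b = self.boundaries[chrom]
        for j in range(len(b) - 1):
            yield int(b[j]), int(b[j + 1])

    def total_segments(self) -> int:
        return sum(self.n_segments(c) for c in self.marker_map.chrom_order)


def read_profiles(path) -> tuple:
    """Read a tab-delimited probe table.

    The file must have columns ``probe_id  chrom  pos`` followed by one
    integer status column per sample.  Statuses outside ``{-2..2}`` or
    non-sorted positions are rejected with an error naming the offending
    probe/sample.

    Returns
    -------
    (MarkerMap, list of DiscreteProfile)
        Sample order follows the file's column order.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    if cols[:3] != ["probe_id", "chrom", "pos"]:
        raise ProfileError(
            f"{path}: header must start with 'probe_id\\tchrom\\tpos', got {cols[:3]}"
        )
    if len(cols) < 4:
        raise ProfileError(f"{path}: no sample columns found")
    mm = MarkerMap(df["probe_id"].to_numpy(object),
                   df["chrom"].to_numpy(object),
                   df["pos"].to_numpy())
    profiles = []
    for name in cols[3:]:
        col = df[name]
        vals = col.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = pd.to_numeric(col, errors="coerce").to_numpy(float)
            frac = np.isnan(as_float) | (as_float != np.round(as_float))
            if np.any(frac):
                i = int(np.flatnonzero(frac)[0])
                raise ProfileError(
                    f"{path}: non-integer status {col.iloc[i]!r} for sample "
                    f"{name!r} at probe {df['probe_id'].iloc[i]!r}"
                )
            vals = as_float.astype(np.int64)
        bad = ~np.isin(vals, VALID_STATUSES)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ProfileError(
                f"{path}: status {vals[i]} out of range for sample {name!r} "
                f"at probe {df['probe_id'].iloc[i]!r}"
            )
        profiles.append(DiscreteProfile(name, vals))
    return mm, profiles


def write_profiles(path, marker_map: MarkerMap, profiles) -> None:
    """Write profiles back to the tab-delimited dialect read by :func:`read_profiles`."""
    data = {
        "probe_id": marker_map.probe_ids,
        "chrom": marker_map.chroms,
        "pos": marker_map.positions,
    }
    for p in profiles:
        data[p.sample_id] = p.status
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def delineate_segments(profiles, marker_map: MarkerMap) -> SegmentPartition:
    """Divide every chromosome into homogeneous segments.

    The partition is the coarsest one in which every sample has constant
    status within every segment: its boundaries are the union, over samples,
    of all status change-points, plus the chromosome ends.
    """
    if not profiles:
        raise ProfileError("at least one profile is required")
    for p in profiles:
        if len(p.status) != marker_map.n_probes:
            raise ProfileError(
                f"sample {p.sample_id!r} has {len(p.status)} statuses for "
                f"{marker_map.n_probes} probes"
            )
    boundaries = {}
    for chrom in marker_map.chrom_order:
        sl = marker_map.chrom_slice(chrom)
        n_c = sl.stop - sl.start
        cuts = set()
        for p in profiles:
            st = p.status[sl]
            cuts.update((np.flatnonzero(np.diff(st) != 0) + 1).tolist())
        boundaries[chrom] = np.array(sorted({0, n_c} | cuts), dtype=np.int64)
    return SegmentPartition(marker_map, boundaries)


def segment_vector(profile: DiscreteProfile, partition: SegmentPartition) -> dict:
    """Collapse a per-probe profile to per-segment statuses, per chromosome.

    Raises if the profile is not constant within a segment (i.e. the
    partition was not built from a sample set including this profile).
    """
    mm = partition.marker_map
    out = {}
    for chrom in mm.chrom_order:
        sl = mm.chrom_slice(chrom)
        st = profile.status[sl]
        vals = []
        for lo, hi in partition.segment_spans(chrom):
            seg = st[lo:hi]
            if np.any(seg != seg[0]):
                raise ProfileError(
                    f"sample {profile.sample_id!r} not constant on segment "
                    f"[{lo},{hi}) of chromosome {chrom!r}"
                )
            vals.append(int(seg[0]))
        out[chrom] = np.array(vals, dtype=np.int64)
    return out


def expand_to_probes(seg_vec: dict, partition: SegmentPartition) -> np.ndarray:
    """Inverse of :func:`segment_vector`: per-segment statuses back to probes."""
    mm = partition.marker_map
    out = np.empty(mm.n_probes, dtype=np.int64)
    for chrom in mm.chrom_order:
        sl = mm.chrom_slice(chrom)
        out[sl] = np.repeat(seg_vec[chrom],
                            np.diff(partition.boundaries[chrom]))
    return out


# ---------------------------------------------------------------------------
# per-chromosome vector algebra

def to_breakpoints(s: np.ndarray) -> np.ndarray:
    """Segment vector -> breakpoint vector (length N + 1)."""
    s = np.asarray(s, dtype=np.int64)
    b = np.empty(len(s) + 1, dtype=np.int64)
    b[0] = s[0]
    b[1:-1] = np.diff(s)
    b[-1] = -s[-1]
    return b


def to_segments(b: np.ndarray) -> np.ndarray:
    """Breakpoint vector -> segment vector; requires a balanced ``b``."""
    b = np.asarray(b, dtype=np.int64)
    if b.sum() != 0:
        raise ProfileError("breakpoint vector is not balanced; no segment vector exists")
    return np.cumsum(b[:-1])


def to_amplitudes(b: np.ndarray) -> np.ndarray:
    """Breakpoint vector -> amplitude vector of length 2(N + 1).

    Slot *k* holds the 'up' amplitude, slot N + 1 + *k* the 'down' amplitude;
    at most one of the pair is non-zero.
    """
    b = np.asarray(b, dtype=np.int64)
    return np.concatenate([np.maximum(b, 0), np.maximum(-b, 0)])


def to_breakpoints_inverse(a: np.ndarray) -> np.ndarray:
    """Amplitude vector -> breakpoint vector (inverse of :func:`to_amplitudes`)."""
    a = np.asarray(a, dtype=np.int64)
    half = len(a) // 2
    return a[:half] - a[half:]


def is_balanced(b: np.ndarray) -> bool:
    """True iff the breakpoint vector encodes a biologically viable chromosome."""
    return int(np.sum(b)) == 0


def write_segment_table(path, profile: DiscreteProfile,
                        partition: SegmentPartition) -> None:
    """Write one sample's segments as a BED-like TSV.

    Columns ``chrom  start_pos  end_pos  n_probes  status`` with 1-based
    inclusive base-pair positions (human-readable convention; probe indices
    used internally are 0-based half-open).
    """
    mm = partition.marker_map
    sv = segment_vector(profile, partition)
    rows = []
    for chrom in mm.chrom_order:
        sl = mm.chrom_slice(chrom)
        pos = mm.positions[sl]
        for j, (lo, hi) in enumerate(partition.segment_spans(chrom)):
            rows.append((chrom, int(pos[lo]), int(pos[hi - 1]), hi - lo,
                         int(sv[chrom][j])))
    pd.DataFrame(rows, columns=["chrom", "start_pos", "end_pos",
                                "n_probes", "status"]).to_csv(
        path, sep="\t", index=False)
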