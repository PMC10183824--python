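"""Nonclonal CNA calling from single-cell binned copy-number profiles.

Single cells from a heterogeneous line (e.g. near-triploid HEK293T)
carry a shared non-diploid clonal karyotype plus subclonal variation;
newly induced events must be scored against that background. The
procedure:

1. a median reference karyotype is built from control cells (per 500-kb
   bin, the median integer copy number across cells; lower median for
   even counts so states stay integer);
2. each test cell's profile is re-expressed relative to that reference
   and maximal runs of equal nonzero delta become CNA segments;
3. clonal/subclonal events are identified from control cells (segments
   grouped when they share chromosome and sign with >= 50% reciprocal
   overlap; an event needs support from at least 4 distinct cells) and
   matching test segments are masked;
4. surviving segments with breakpoints <= 1 Mb apart are dropped, and
   the remainder are stratified into large (> 20 Mb) and small (< 20 Mb)
   classes and quantified per chromosome and around the guide locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BinGrid:
    """A fixed-width genomic bin tiling shared by all profiles in a run."""

    chroms: tuple[str, ...]
    starts: tuple[int, ...]
    ends: tuple[int, ...]
    bin_bp: int = 500_000

    @classmethod
    def from_chrom_lengths(cls, lengths: dict[str, int], bin_bp: int = 500_000):
        chroms, starts, ends = [], [], []
        for chrom, length in lengths.items():
            for s in range(0, length, bin_bp):
                chroms.append(chrom)
                starts.append(s)
                ends.append(min(s + bin_bp, length))
        return cls(tuple(chroms), tuple(starts), tuple(ends), bin_bp)

    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous bin index range per chromosome."""
        out: dict[str, slice] = {}
        i = 0
        while i < self.n_bins:
            j = i
            while j < self.n_bins and self.chroms[j] == self.chroms[i]:
                j += 1
            out[self.chroms[i]] = slice(i, j)
            i = j
        return out

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chroms))


@dataclass
class CopyNumberProfile:
    """Integer copy-number states for one cell over a shared bin grid."""

    cell_id: str
    condition: str
    grid: BinGrid
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.shape != (self.grid.n_bins,):
            raise ValueError(
                f"cell {self.cell_id}: expected {self.grid.n_bins} states, "
                f"got {self.states.shape}"
            )
        if not np.issubdtype(self.states.dtype, np.integer):
            raise ValueError(f"cell {self.cell_id}: states must be integers")
        if (self.states < 0).any():
            raise ValueError(f"cell {self.cell_id}: negative copy number")


@dataclass
class MedianReference:
    grid: BinGrid
    median_state: np.ndarray


@dataclass(frozen=True)
class CNASegment:
    """A maximal run of bins with equal nonzero relative copy number."""

    cell_id: str
    chrom: str
    start: int
    end: int
    delta: int

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("CNASegment delta must be nonzero")
        if not self.start < self.end:
            raise ValueError("CNASegment requires start < end")

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def sign(self) -> int:
        return 1 if self.delta > 0 else -1


@dataclass(frozen=True)
class ClonalEvent:
    chrom: str
    start: int
    end: int
    sign: int
    n_cells: int
    segments: tuple[CNASegment, ...] = field(default=(), compare=False)


@dataclass
class ClonalEventSet:
    events: list[ClonalEvent]

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def _check_grid(a: BinGrid, b: BinGrid) -> None:
    if a != b:
        raise ValueError("profiles/reference do not share a common bin grid")


def build_median_reference(control_profiles) -> MedianReference:
    """Per-bin median copy number across control cells (lower median)."""
    profiles = list(control_profiles)
    if not profiles:
        raise ValueError("need at least one control profile")
    grid = profiles[0].grid
    for p in profiles[1:]:
        _check_grid(grid, p.grid)
    mat = np.vstack([p.states for p in profiles])
    # lower median keeps integer states for even cell counts
    med = np.sort(mat, axis=0)[(mat.shape[0] - 1) // 2]
    return MedianReference(grid, med.astype(np.int64))


def call_relative_segments(
    profile: CopyNumberProfile, reference: MedianReference
) -> list[CNASegment]:
    """Maximal runs of equal nonzero (state - median) per chromosome."""
    _check_grid(profile.grid, reference.grid)
    delta = profile.states.astype(np.int64) - reference.median_state
    grid = profile.grid
    segments: list[CNASegment] = []
    for chrom, sl in grid.chrom_slices().items():
        d = delta[sl]
        starts = grid.starts[sl.start : sl.stop]
        ends = grid.ends[sl.start : sl.stop]
        i = 0
        while i < d.size:
            if d[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < d.size and d[j + 1] == d[i]:
                j += 1
            segments.append(
                CNASegment(profile.cell_id, chrom, starts[i], ends[j], int(d[i]))
            )
            i = j + 1
    return segments


def flag_widespread_aneuploidy(
    profile: CopyNumberProfile,
    reference: MedianReference,
    max_altered_fraction: float = 0.5,
) -> bool:
    """True (exclude the cell) iff the altered-bin fraction strictly exceeds the cap."""
    _check_grid(profile.grid, reference.grid)
    delta = profile.states.astype(np.int64) - reference.median_state
    frac = float(np.count_nonzero(delta)) / profile.grid.n_bins
    return frac > max_altered_fraction


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def _overlap_ok(seg, other, min_overlap: float, mode: str) -> bool:
    inter = min(seg.end, other.end) - max(seg.start, other.start)
    if inter <= 0:
        return False
    f_seg = inter / seg.size_bp
    f_other = inter / (other.end - other.start)
    if mode == "reciprocal":
        return f_seg >= min_overlap and f_other >= min_overlap
    if mode == "query":
        return f_seg >= min_overlap
    if mode == "subject":
        return f_other >= min_overlap
    raise ValueError(f"unknown overlap mode {mode!r}")


def identify_clonal_events(
    control_segments,
    min_cells: int = 4,
    min_overlap: float = 0.5,
) -> ClonalEventSet:
    """Group recurring control segments into clonal/subclonal events.

    Two segments are the same event iff they lie on the same chromosome
    with the same delta sign and overlap reciprocally by at least
    ``min_overlap`` of both lengths. Events are the connected components
    of that relation; a component is retained iff it is supported by at
    least ``min_cells`` distinct cells. The event interval is the union
    hull of its supporting segments.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    segs = list(control_segments)
    n = len(segs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = segs[i], segs[j]
            if a.chrom != b.chrom or a.sign != b.sign:
                continue
            if _reciprocal_overlap(a.start, a.end, b.start, b.end) >= min_overlap:
                parent[find(i)] = find(j)
    comps: dict[int, list[CNASegment]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(segs[i])
    events = []
    for members in comps.values():
        cells = {m.cell_id for m in members}
        if len(cells) < min_cells:
            continue
        events.append(
            ClonalEvent(
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                sign=members[0].sign,
                n_cells=len(cells),
                segments=tuple(members),
            )
        )
    events.sort(key=lambda e: (e.chrom, e.start, e.sign))
    return ClonalEventSet(events)


def mask_clonal(
    test_segments,
    clonal: ClonalEventSet,
    min_overlap: float = 0.5,
    min_span_bp: int = 1_000_000,
    overlap_mode: str = "reciprocal",
    against: str = "events",
) -> list[CNASegment]:
    """Remove clonal-matching test segments, then short segments.

    A test segment is removed whole iff some clonal event with the same
    sign on the same chromosome overlaps it by at least ``min_overlap``
    (reciprocal by default; ``against="segments"`` compares to each
    supporting control segment instead of the collapsed event hull).
    Surviving segments whose breakpoints are not more than
    ``min_span_bp`` apart are then dropped.
    """
    out: list[CNASegment] = []
    for seg in test_segments:
        removed = False
        for ev in clonal:
            if ev.chrom != seg.chrom or ev.sign != seg.sign:
                continue
            if against == "events":
                if _overlap_ok(seg, ev, min_overlap, overlap_mode):
                    removed = True
                    break
            elif against == "segments":
                if any(
                    _overlap_ok(seg, m, min_overlap, overlap_mode)
                    for m in ev.segments
                ):
                    removed = True
                    break
            else:
                raise ValueError(f"unknown masking target {against!r}")
        if not removed and seg.size_bp > min_span_bp:
            out.append(seg)
    return out


def stratify_and_quantify(
    nonclonal_segments,
    n_cells: int,
    size_cut_bp: int = 20_000_000,
    locus: tuple[str, int, int] | None = None,
    locus_window_bp: int = 500_000,
    chromosomes=None,
) -> dict[str, pd.DataFrame]:
    """Size-stratified CNA rates per chromosome and around the guide locus.

    Large CNAs (size > ``size_cut_bp``) are tallied per chromosome as
    CNAs per cell; small CNAs (size < ``size_cut_bp``) are split into
    those overlapping the guide locus +/- ``locus_window_bp`` by any
    amount vs the remainder of the genome. Segments of exactly
    ``size_cut_bp`` fall in neither class (strict inequalities).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    segs = list(nonclonal_segments)
    if locus is not None and chromosomes is not None:
        if locus[0] not in set(chromosomes):
            raise KeyError(f"locus chromosome {locus[0]!r} not in the profile set")
    large = [s for s in segs if s.size_bp > size_cut_bp]
    small = [s for s in segs if s.size_bp < size_cut_bp]

    counts: dict[str, int] = {}
    for s in large:
        counts[s.chrom] = counts.get(s.chrom, 0) + 1
    chrom_names = list(chromosomes) if chromosomes is not None else sorted(counts)
    large_table = pd.DataFrame(
        {
            "chrom": chrom_names,
            "count": [counts.get(c, 0) for c in chrom_names],
        }
    )
    large_table["rate_per_cell"] = large_table["count"] / n_cells

    tables = {"large_per_chromosome": large_table}
    if locus is not None:
        lchrom, lstart, lend = locus
        wstart, wend = max(0, lstart - locus_window_bp), lend + locus_window_bp
        in_win = sum(
            1
            for s in small
            if s.chrom == lchrom and s.start < wend and wstart < s.end
        )
        rest = len(small) - in_win
        tables["small_by_locus"] = pd.DataFrame(
            {
                "region": ["locus_window", "rest_of_genome"],
                "count": [in_win, rest],
                "rate_per_cell": [in_win / n_cells, rest / n_cells],
            }
        )
    return tables


def pileup(
    nonclonal_segments, grid: BinGrid, size_cut_bp: int = 20_000_000
) -> pd.DataFrame:
    """Per-bin counts of cells with a gain/loss covering the bin, by size class."""
    cols = {
        name: np.zeros(grid.n_bins, dtype=np.int64)
        for name in ("gain_large", "loss_large", "gain_small", "loss_small")
    }
    slices = grid.chrom_slices()
    starts = np.asarray(grid.starts)
    ends = np.asarray(grid.ends)
    for seg in nonclonal_segments:
        if seg.chrom not in slices:
            raise KeyError(f"segment chromosome {seg.chrom!r} not on the grid")
        sl = slices[seg.chrom]
        cover = (starts[sl] < seg.end) & (seg.start < ends[sl])
        size = "large" if seg.size_bp > size_cut_bp else "small"
        sign = "gain" if seg.delta > 0 else "loss"
        cols[f"{sign}_{size}"][sl][cover] += 1
    df = pd.DataFrame(
        {"chrom": grid.chroms, "start": grid.starts, "end": grid.ends, **cols}
    )
    return df


def chisq_rate_comparison(
    events_a: int, cells_a: int, events_b: int, cells_b: int
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on CNA vs cell counts.

    The 2x2 table is [[events_a, cells_a], [events_b, cells_b]],
    comparing the frequency of CNAs to the number of cells between two
    conditions. Raises when any expected count is zero (degenerate
    margins carry no information about a rate difference).
    """
    if cells_a < 1 or cells_b < 1:
        raise ValueError("cell counts must be >= 1")
    if events_a < 0 or events_b < 0:
        raise ValueError("event counts must be >= 0")
    table = np.array([[events_a, cells_a], [events_b, cells_b]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError(
            "a zero expected count makes the chi-squared test undefined; "
            "both conditions need a nonzero margin (pool conditions or "
            "use an exact test instead)"
        )
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
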