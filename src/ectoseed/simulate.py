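"""Synthetic inputs with machine-readable ground truth.

Two generators:

* genomes with planted tandem arrays of a protospacer+PAM unit
  (variable copy number, per-base divergence, optional spacers, decoy
  arrays on other chromosomes) embedded in random background sequence —
  emulating the endogenous repeat arrays a chromosome-specific guide
  would target;
* single-cell copy-number populations on a fixed bin grid with a shared
  non-diploid clonal karyotype, recurring subclonal CNAs, induced
  segmental aneuploidies on a designated target chromosome whose
  proximal breakpoint falls between the guide locus and the centromere,
  and per-bin miscall noise — emulating the structure of shallow
  single-cell WGS copy-number calls from a heterogeneous line.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna import BinGrid, CopyNumberProfile
from .genome import ReferenceGenome, reverse_complement
from .search import IUPAC


@dataclass(frozen=True)
class RepeatPlantSpec:
    """One tandem array to plant: ``copies`` x (``unit`` + ``spacer``)."""

    chrom: str
    insert_position: int
    unit: str
    copies: int
    per_base_divergence: float = 0.0
    spacer: str = ""

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not 0.0 <= self.per_base_divergence <= 1.0:
            raise ValueError("per_base_divergence must be in [0, 1]")
        if set(self.unit + self.spacer) - set("ACGT"):
            raise ValueError("unit/spacer must be over ACGT")

    @property
    def array_length(self) -> int:
        n = self.copies * len(self.unit) + (self.copies - 1) * len(self.spacer)
        return n


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    alts = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    hits = rng.random(len(chars)) < rate
    for i in np.nonzero(hits)[0]:
        chars[i] = alts[chars[i]][rng.integers(3)]
    return "".join(chars)


def _pam_matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(seq, pattern)
    )


def _count_exact_sites(region: str, protospacer: str, pam: str) -> int:
    """Exact protospacer+PAM occurrences in *region*, both strands (string scan)."""
    total = 0
    for s in (region, reverse_complement(region)):
        start = 0
        while True:
            i = s.find(protospacer, start)
            if i < 0:
                break
            tail = s[i + len(protospacer) : i + len(protospacer) + len(pam)]
            if _pam_matches(tail, pam):
                total += 1
            start = i + 1
    return total


def simulate_repeat_genome(
    specs,
    background_lengths: dict[str, int],
    gc_fraction: float = 0.41,
    seed: int = 0,
    pam: str = "NGG",
    protospacer_length: int = 20,
) -> tuple[ReferenceGenome, pd.DataFrame]:
    """Random-background genome with planted tandem arrays plus truth table.

    Each spec's array is written verbatim over the background at its
    insert position (divergence applied per base first). The truth table
    reports, per plant, the planted interval and the exact 0-mismatch
    site count of the unit's protospacer (its first
    ``protospacer_length`` bases, PAM-adjacent) within the planted
    interval, counted on both strands by direct string scan so
    overlapping occurrences of periodic units are included.
    """
    specs = list(specs)
    rng = np.random.default_rng(seed)
    chrom_seqs = {
        chrom: list(_random_background(rng, length, gc_fraction))
        for chrom, length in background_lengths.items()
    }
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_seqs}
    rows = []
    for spec in specs:
        if spec.chrom not in chrom_seqs:
            raise KeyError(f"plant chromosome {spec.chrom!r} has no background length")
        start = spec.insert_position
        end = start + spec.array_length
        if not (0 <= start and end <= background_lengths[spec.chrom]):
            raise ValueError(
                f"planted array [{start}, {end}) does not fit on {spec.chrom}"
            )
        for s, e in placed[spec.chrom]:
            if start < e and s < end:
                raise ValueError(f"plant specs overlap on {spec.chrom}")
        placed[spec.chrom].append((start, end))
        pieces = []
        for i in range(spec.copies):
            pieces.append(_mutate(rng, spec.unit, spec.per_base_divergence))
            if i + 1 < spec.copies:
                pieces.append(spec.spacer)
        array = "".join(pieces)
        chrom_seqs[spec.chrom][start:end] = list(array)
        protospacer = spec.unit[:protospacer_length]
        rows.append(
            {
                "chrom": spec.chrom,
                "start": start,
                "end": end,
                "unit": spec.unit,
                "copies": spec.copies,
                "per_base_divergence": spec.per_base_divergence,
                "protospacer": protospacer,
                "pam": pam,
                "exact_site_count": _count_exact_sites(array, protospacer, pam),
            }
        )
    genome = ReferenceGenome({c: "".join(s) for c, s in chrom_seqs.items()})
    return genome, pd.DataFrame(rows)


@dataclass(frozen=True)
class InducedAneuploidySpec:
    """Segmental aneuploidies induced on a target chromosome.

    With probability ``event_rate`` a cell receives one event whose
    proximal breakpoint is drawn uniformly (on bin boundaries) between
    the guide locus and the centromere; the segment runs from the
    breakpoint to the chromosome end on the locus side, mimicking
    breakage between the two opposing attachment sites of a
    pseudodicentric chromosome.
    """

    target_chrom: str
    locus: tuple[int, int]
    centromere: tuple[int, int]
    event_rate: float
    deltas: tuple[int, ...] = (1, -1)


@dataclass
class CellPopulationSpec:
    n_cells: int
    chrom_lengths: dict[str, int]
    base_karyotype: dict[str, int]
    clonal_cnas: list[tuple[tuple[str, int, int], int]] = field(default_factory=list)
    subclonal_cnas: list[tuple[tuple[str, int, int], int, float]] = field(
        default_factory=list
    )
    induced: InducedAneuploidySpec | None = None
    noise_flip_prob: float = 0.0
    bin_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.noise_flip_prob <= 1.0:
            raise ValueError("noise_flip_prob must be in [0, 1]")
        for (chrom, s, e), _delta in self.clonal_cnas:
            self._check_interval(chrom, s, e)
        for (chrom, s, e), _delta, frac in self.subclonal_cnas:
            self._check_interval(chrom, s, e)
            if not 0.0 <= frac <= 1.0:
                raise ValueError("subclonal cell_fraction must be in [0, 1]")

    def _check_interval(self, chrom: str, s: int, e: int) -> None:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"interval chromosome {chrom!r} unknown")
        if s % self.bin_bp or (e % self.bin_bp and e != self.chrom_lengths[chrom]):
            raise ValueError(f"interval {chrom}:{s}-{e} is not bin-aligned")


def simulate_cell_population(
    spec: CellPopulationSpec, condition: str = "test"
) -> tuple[list[CopyNumberProfile], pd.DataFrame]:
    """Simulate a cell population and return (profiles, truth table).

    Each cell starts from the base karyotype, receives every clonal CNA,
    each subclonal CNA independently with its cell fraction, at most one
    induced event with probability ``event_rate``, and finally per-bin
    +/-1 miscall noise. Noise flips are only applied to bins not already
    altered by a planted event, so every nonzero bin in the truth table
    has exactly one labelled cause. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = BinGrid.from_chrom_lengths(spec.chrom_lengths, spec.bin_bp)
    slices = grid.chrom_slices()
    starts = np.asarray(grid.starts)
    ends = np.asarray(grid.ends)

    base = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom, cn in spec.base_karyotype.items():
        base[slices[chrom]] = cn

    def bin_mask(chrom: str, s: int, e: int) -> np.ndarray:
        mask = np.zeros(grid.n_bins, dtype=bool)
        sl = slices[chrom]
        mask[sl] = (starts[sl] >= s) & (ends[sl] <= e)
        return mask

    ind = spec.induced
    if ind is not None:
        ls, le = ind.locus
        cs, ce = ind.centromere
        if le <= cs:  # locus on the p-side of the centromere
            lo, hi, left_side = le, cs, True
        elif ind.locus[0] >= ce:  # q-side
            lo, hi, left_side = ce, ind.locus[0], False
        else:
            raise ValueError("induced locus must not overlap the centromere")
        boundaries = [
            b for b in range(0, spec.chrom_lengths[ind.target_chrom] + 1, spec.bin_bp)
            if lo <= b <= hi
        ]
        if not boundaries:
            raise ValueError("no bin boundary between locus and centromere")

    profiles: list[CopyNumberProfile] = []
    truth_rows = []
    width = len(str(spec.n_cells - 1))
    for i in range(spec.n_cells):
        cell_id = f"{condition}_c{i:0{width}d}"
        states = base.copy()
        altered = np.zeros(grid.n_bins, dtype=bool)

        def plant(chrom, s, e, delta, kind):
            mask = bin_mask(chrom, s, e)
            states[mask] += delta
            altered[mask] = True
            truth_rows.append(
                {"cell_id": cell_id, "kind": kind, "chrom": chrom,
                 "start": s, "end": e, "delta": delta}
            )

        for (chrom, s, e), delta in spec.clonal_cnas:
            plant(chrom, s, e, delta, "clonal")
        for (chrom, s, e), delta, frac in spec.subclonal_cnas:
            if rng.random() < frac:
                plant(chrom, s, e, delta, "subclonal")
        if ind is not None and rng.random() < ind.event_rate:
            bp = boundaries[rng.integers(len(boundaries))]
            delta = ind.deltas[rng.integers(len(ind.deltas))]
            if left_side:
                s, e = 0, bp
            else:
                s, e = bp, spec.chrom_lengths[ind.target_chrom]
            plant(ind.target_chrom, s, e, delta, "induced")
        if spec.noise_flip_prob > 0:
            flips = (rng.random(grid.n_bins) < spec.noise_flip_prob) & ~altered
            signs = rng.choice([-1, 1], size=grid.n_bins)
            for b in np.nonzero(flips)[0]:
                d = int(signs[b])
                if states[b] + d < 0:
                    d = 1
                states[b] += d
                truth_rows.append(
                    {"cell_id": cell_id, "kind": "noise", "chrom": grid.chroms[b],
                     "start": grid.starts[b], "end": grid.ends[b], "delta": d}
                )
        np.clip(states, 0, None, out=states)
        profiles.append(CopyNumberProfile(cell_id, condition, grid, states))

    truth = pd.DataFrame(
        truth_rows,
        columns=["cell_id", "kind", "chrom", "start", "end", "delta"],
    )
    return profiles, truth
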