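"""Readers and writers for the package's standard text formats.

All genomic output follows the BED convention (0-based, half-open); the
single exception is the human-readable guide report, whose coordinates
are 1-based inclusive and flagged as such in its header. Every emitted
format round-trips through its reader.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cna import BinGrid, CopyNumberProfile
from .genome import ReferenceGenome
from .search import GuideRNA

_VALID = frozenset("ACGTN")


def parse_fasta(path) -> ReferenceGenome:
    """Load a multi-record FASTA (record id up to first whitespace)."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in chroms:
            raise ValueError(f"duplicate FASTA record id: {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {name!r} is empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"FASTA record {name!r} has illegal characters: {sorted(bad)}"
            )
        chroms[name] = seq
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(chroms)


def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome[name]), id=name, description="") for name in genome.names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def parse_bed(path) -> dict[str, list[tuple[int, int]]]:
    """BED3+ intervals, 0-based half-open, sorted per chromosome."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.setdefault(chrom, []).append((start, end))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


def write_bed(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def write_sites_bed6(sites, path) -> None:
    """Binding sites as BED6: name=guide id, score=mismatch count."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.guide_id}\t{s.mismatches}\t{s.strand}\n"
            )


def parse_chrom_lengths(path) -> dict[str, int]:
    """Two-column (name, length) TSV, faidx style (extra columns ignored)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>length")
            lengths[fields[0]] = int(fields[1])
    return lengths


def parse_guides_tsv(path) -> list[GuideRNA]:
    """Guide queries from a TSV with columns id, sequence, pam (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sequence", "pam"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: guide TSV needs columns {sorted(required)}")
    return [
        GuideRNA(row.id, row.sequence.upper(), row.pam.upper())
        for row in df.itertuples(index=False)
    ]


_CN_COLUMNS = ["cell_id", "condition", "chrom", "start", "end", "copy_number"]


def parse_cn_table(path, expected_bin_bp: int = 500_000) -> list[CopyNumberProfile]:
    """Long-format per-cell copy-number TSV on a validated common grid.

    Every cell must cover the identical bin set; bins must be
    ``expected_bin_bp`` wide except chromosome-terminal bins, which may
    be shorter. Non-integer copy numbers are an error (no imputation).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_CN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    cn = pd.to_numeric(df["copy_number"], errors="coerce").astype(float)
    if cn.isna().any() or (cn % 1 != 0).any() or (cn < 0).any():
        raise ValueError(f"{path}: copy_number must be a non-negative integer")
    df["copy_number"] = cn.astype("int64")
    df = df.astype({"start": "int64", "end": "int64"})

    first_cell = df["cell_id"].iloc[0]
    ref = df[df["cell_id"] == first_cell]
    terminal_end = ref.groupby("chrom")["end"].max().to_dict()
    for row in ref.itertuples(index=False):
        width = row.end - row.start
        if width != expected_bin_bp and row.end != terminal_end[row.chrom]:
            raise ValueError(
                f"{path}: bin {row.chrom}:{row.start}-{row.end} has width "
                f"{width} != {expected_bin_bp} and is not chromosome-terminal"
            )
        if width <= 0 or width > expected_bin_bp:
            raise ValueError(
                f"{path}: bin {row.chrom}:{row.start}-{row.end} has bad width"
            )
    grid = BinGrid(
        tuple(ref["chrom"]), tuple(ref["start"]), tuple(ref["end"]), expected_bin_bp
    )
    ref_key = list(zip(ref["chrom"], ref["start"], ref["end"]))

    profiles = []
    for (cell_id, condition), sub in df.groupby(
        ["cell_id", "condition"], sort=False
    ):
        key = list(zip(sub["chrom"], sub["start"], sub["end"]))
        if key != ref_key:
            raise ValueError(
                f"{path}: cell {cell_id!r} is not on the common bin grid "
                f"(missing/extra/reordered bins)"
            )
        profiles.append(
            CopyNumberProfile(
                str(cell_id),
                str(condition),
                grid,
                sub["copy_number"].to_numpy(dtype=np.int64),
            )
        )
    return profiles


def write_cn_table(profiles, path) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": p.cell_id,
                    "condition": p.condition,
                    "chrom": p.grid.chroms,
                    "start": p.grid.starts,
                    "end": p.grid.ends,
                    "copy_number": p.states,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def write_segments_tsv(segments, path, size_cut_bp: int = 20_000_000) -> None:
    rows = [
        {
            "cell_id": s.cell_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "delta": s.delta,
            "size_class": "large" if s.size_bp > size_cut_bp else "small",
        }
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["cell_id", "chrom", "start", "end", "delta", "size_class"]
    ).to_csv(path, sep="\t", index=False)


def write_bedgraph(pileup_df: pd.DataFrame, column: str, path) -> None:
    """One pileup column as BEDGRAPH (track named after the column)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{column}"\n')
        for row in pileup_df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{getattr(row, column)}\n"
            )


def write_guide_report(guide_table: pd.DataFrame, path) -> None:
    """Human-readable guide report; coordinates 1-based inclusive (flagged)."""
    out = guide_table.copy()
    if not out.empty:
        out["target_start"] = out["target_start"] + 1  # 1-based inclusive
    with open(path, "w") as fh:
        fh.write("# guide report; target coordinates are 1-based inclusive\n")
        out.to_csv(fh, sep="\t", index=False)


def echo_params(params: dict, stream=None) -> None:
    """Write every run parameter (and seed) to a log stream."""
    stream = stream if stream is not None else sys.stderr
    for key in sorted(params):
        print(f"[ectoseed] {key} = {params[key]!r}", file=stream)
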