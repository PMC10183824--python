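"""Mismatch-tolerant, PAM-constrained guide binding-site search.

Implements the SpCas9 convention: a guide RNA of length L base-pairs a
genomic protospacer whose 3' end abuts a protospacer-adjacent motif
(PAM, default NGG). Sites are searched on both strands with up to a
fixed number of protospacer substitutions and an exactly matching PAM;
insertions and deletions (bulges) are not modelled.

Semantics pinned here and relied on downstream:

* The PAM pattern is matched under IUPAC rules where pattern ``N``
  accepts A/C/G/T but never an ``N`` in the genome.
* A genome ``N`` never matches any protospacer base and counts as a
  mismatch.
* Every genomic offset is reported independently, so overlapping
  occurrences of a short-period repeat each count.
* Output ordering is deterministic: genome chromosome order, then start
  coordinate, then strand with ``+`` before ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ReferenceGenome, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# base codes: A=0 C=1 G=2 T=3 N=4
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # complement in code space
_BASE_TO_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class GuideRNA:
    """A protospacer query (5'->3') with its PAM pattern.

    The protospacer is the DNA sequence matched in the genome; the PAM
    lies immediately 3' of it in the strand's reading direction.
    """

    id: str
    protospacer: str
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if not self.protospacer or set(self.protospacer) - set("ACGT"):
            raise ValueError(
                f"guide {self.id!r}: protospacer must be non-empty over ACGT"
            )
        if set(self.pam) - set(IUPAC):
            raise ValueError(f"guide {self.id!r}: PAM {self.pam!r} is not valid IUPAC")

    @property
    def length(self) -> int:
        return len(self.protospacer)


@dataclass(frozen=True, order=True)
class BindingSite:
    """One genomic occurrence of a guide.

    ``start``/``end`` are 0-based half-open over the protospacer-matching
    bases only (the PAM is outside the interval). ``mismatches`` counts
    protospacer substitutions; the PAM matched its pattern exactly.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    guide_id: str = field(default="", compare=False)


def trim_protospacer(protospacer20: str, target_length: int) -> str:
    """PAM-proximal (3') suffix of a 20-nt protospacer.

    Trimming must keep the 3' end so the PAM stays adjacent: an
    N20-NGG site is an N15-NGG or N11-NGG site for the suffix guide.
    """
    if len(protospacer20) != 20:
        raise ValueError(f"expected a 20-nt protospacer, got {len(protospacer20)} nt")
    if not 1 <= target_length < 20:
        raise ValueError(f"target_length must be in [1, 20), got {target_length}")
    return protospacer20[-target_length:]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pam_allowed_luts(pam: str) -> list[np.ndarray]:
    """Per-PAM-position boolean lookup over base codes (N code never allowed)."""
    luts = []
    for ch in pam:
        lut = np.zeros(5, dtype=bool)
        for b in IUPAC[ch]:
            lut[_BASE_TO_CODE[b]] = True
        luts.append(lut)
    return luts


def _scan_strand(arr: np.ndarray, proto: str, pam: str, max_mm: int):
    """Positions p (0-based) and mismatch counts where proto+PAM matches arr."""
    L, P = len(proto), len(pam)
    span = L + P
    n = arr.size
    if n < span:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - span + 1
    ok = np.ones(m, dtype=bool)
    for j, lut in enumerate(_pam_allowed_luts(pam)):
        ok &= lut[arr[L + j : L + j + m]]
    mism = np.zeros(m, dtype=np.int32)
    for j, base in enumerate(proto):
        mism += arr[j : j + m] != _BASE_TO_CODE[base]
    ok &= mism <= max_mm
    pos = np.nonzero(ok)[0]
    return pos, mism[pos].astype(np.int64)


def find_binding_sites(
    guide: GuideRNA, genome: ReferenceGenome, max_mismatches: int = 0
) -> list[BindingSite]:
    """All binding sites of *guide* in *genome* with <= *max_mismatches*.

    Both strands are searched; on the minus strand the protospacer+PAM
    is read on the reverse complement and reported in plus-strand
    coordinates over the protospacer bases. Counts at budget k are
    cumulative over exact-mismatch classes 0..k.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    L = guide.length
    sites: list[BindingSite] = []
    for chrom in genome.names:
        arr = _encode(genome[chrom])
        n = arr.size
        pos, mm = _scan_strand(arr, guide.protospacer, guide.pam, max_mismatches)
        for p, k in zip(pos.tolist(), mm.tolist()):
            sites.append(BindingSite(chrom, p, p + L, "+", k, guide.id))
        rc = _RC_CODE[arr][::-1]
        pos, mm = _scan_strand(rc, guide.protospacer, guide.pam, max_mismatches)
        for p, k in zip(pos.tolist(), mm.tolist()):
            sites.append(BindingSite(chrom, n - p - L, n - p, "-", k, guide.id))
    order = {name: i for i, name in enumerate(genome.names)}
    sites.sort(key=lambda s: (order[s.chrom], s.start, s.strand))  # '+' < '-'
    return sites


def enumerate_protospacers(
    genome: ReferenceGenome, guide_length: int, pam: str = "NGG"
) -> list[tuple[GuideRNA, BindingSite]]:
    """Every PAM-adjacent protospacer window on both strands.

    Windows containing N are excluded; overlapping windows are all
    reported. Each occurrence is returned as a (guide, site) pair where
    the guide carries the genomic protospacer sequence read 5'->3' on
    its strand, with a positional id ``chrom:start:strand``.
    """
    if guide_length < 1:
        raise ValueError("guide_length must be >= 1")
    if set(pam) - set(IUPAC):
        raise ValueError(f"PAM {pam!r} is not valid IUPAC")
    out: list[tuple[GuideRNA, BindingSite]] = []
    for chrom in genome.names:
        seq = genome[chrom]
        arr = _encode(seq)
        rc_seq = reverse_complement(seq)
        n = arr.size
        for strand, a, s in (("+", arr, seq), ("-", _RC_CODE[arr][::-1], rc_seq)):
            span = guide_length + len(pam)
            if n < span:
                continue
            m = n - span + 1
            ok = np.ones(m, dtype=bool)
            for j, lut in enumerate(_pam_allowed_luts(pam)):
                ok &= lut[a[guide_length + j : guide_length + j + m]]
            # exclude protospacer windows containing N
            is_n = (a == 4).astype(np.int32)
            cum = np.concatenate(([0], np.cumsum(is_n)))
            ok &= (cum[guide_length:m + guide_length] - cum[:m]) == 0
            for p in np.nonzero(ok)[0].tolist():
                proto = s[p : p + guide_length]
                if strand == "+":
                    start, end = p, p + guide_length
                else:
                    start, end = n - p - guide_length, n - p
                guide = GuideRNA(f"{chrom}:{start}:{strand}", proto, pam)
                out.append((guide, BindingSite(chrom, start, end, strand, 0, guide.id)))
    order = {name: i for i, name in enumerate(genome.names)}
    out.sort(key=lambda gs: (order[gs[1].chrom], gs[1].start, gs[1].strand))
    return out


def count_sites_per_chromosome(sites) -> dict[str, int]:
    """Tally of sites per chromosome; chromosomes with no sites are absent."""
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.chrom] = counts.get(s.chrom, 0) + 1
    return counts
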