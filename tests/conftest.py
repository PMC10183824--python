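"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ectoseed.genome import ReferenceGenome, reverse_complement
from ectoseed.search import IUPAC, BindingSite, GuideRNA


def oracle_sites(guide: GuideRNA, genome: ReferenceGenome, max_mm: int):
    """Exhaustive sliding-window binding-site search (independent oracle).

    Slides the protospacer over every offset of both strands counting
    character mismatches and checking the PAM under IUPAC rules (genome
    N never matches). Kept deliberately naive — plain string operations,
    no vectorisation — so it shares nothing with the implementation.
    """
    proto, pam = guide.protospacer, guide.pam
    L, P = len(proto), len(pam)
    pam_sets = [set(IUPAC[c]) for c in pam]
    sites = []
    for ci, chrom in enumerate(genome.names):
        seq = genome[chrom]
        n = len(seq)
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for p in range(n - L - P + 1):
                if any(s[p + L + j] not in pam_sets[j] for j in range(P)):
                    continue
                mm = sum(1 for a, b in zip(s[p : p + L], proto) if a != b)
                if mm <= max_mm:
                    start = p if strand == "+" else n - p - L
                    sites.append(
                        BindingSite(chrom, start, start + L, strand, mm, guide.id)
                    )
    order = {name: i for i, name in enumerate(genome.names)}
    sites.sort(key=lambda x: (order[x.chrom], x.start, x.strand))
    return sites


def random_genome(rng: np.random.Generator, lengths: dict[str, int],
                  gc: float = 0.45) -> ReferenceGenome:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return ReferenceGenome(
        {c: "".join(bases[rng.choice(4, size=n, p=p)]) for c, n in lengths.items()}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230417)


@pytest.fixture
def small_genome(rng):
    return random_genome(rng, {"cA": 30_000, "cB": 20_000})
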