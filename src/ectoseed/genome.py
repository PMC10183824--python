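"""Reference genome container.

A genome is an ordered mapping of chromosome name to an uppercase DNA
sequence over the alphabet {A, C, G, T, N}. Chromosome order is
significant: it fixes the deterministic ordering of search output and
the tie-break used when picking a guide's target cluster.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping

_VALID = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome(Mapping[str, str]):
    """Ordered chromosome name -> sequence mapping with alphabet validation.

    Parameters
    ----------
    chromosomes
        Mapping (or iterable of pairs) of chromosome name to sequence.
        Sequences are uppercased; names must be unique and non-empty,
        sequences non-empty and over {A, C, G, T, N}.
    """

    def __init__(self, chromosomes) -> None:
        items = chromosomes.items() if hasattr(chromosomes, "items") else chromosomes
        self._chroms: dict[str, str] = {}
        for name, seq in items:
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if name in self._chroms:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seq = str(seq).upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains illegal characters: {sorted(bad)}"
                )
            self._chroms[name] = seq
        if not self._chroms:
            raise ValueError("genome must contain at least one chromosome")

    def __getitem__(self, name: str) -> str:
        return self._chroms[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chroms.items()}

    def chrom_index(self, name: str) -> int:
        """Position of a chromosome in genome order (for sorting)."""
        return self.names.index(name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReferenceGenome({len(self)} chromosomes, {sum(self.lengths.values())} bp)"
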