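"""Core containers and coordinate conventions.

All internal coordinates are 0-based, half-open, genomic. Strand symbols are
``"+"`` and ``"-"``. A gene's transcription-direction offset ``o`` maps to the
genomic position ``tss + o`` on the plus strand and ``tss - o`` on the minus
strand, so offset 0 is always the TSS base itself.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-")
VALID_BASES = frozenset("ACGTN")
DIPYRIMIDINES = ("TT", "TC", "CT", "CC")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConfigError(Exception):
    """Bad configuration: missing columns, absent files, invalid parameters."""


class DataError(Exception):
    """Malformed or inconsistent data content."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class Genome(Mapping):
    """Uppercase DNA sequences keyed by chromosome name.

    Behaves as a read-only mapping ``name -> sequence`` and keeps an index of
    chromosome lengths.
    """

    def __init__(self, seqs: Mapping[str, str]):
        if not seqs:
            raise DataError("genome has no records")
        clean: dict[str, str] = {}
        for name, seq in seqs.items():
            s = seq.upper()
            if len(s) == 0:
                raise DataError(f"chromosome {name!r} has zero length")
            bad = set(s) - VALID_BASES
            if bad:
                raise DataError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )
            clean[name] = s
        self._seqs = clean
        self.lengths: dict[str, int] = {n: len(s) for n, s in clean.items()}

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Genome({len(self)} chromosomes, {sum(self.lengths.values())} bp)"


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored by its TSS and (optionally) its PAS-derived TES.

    ``tss`` and ``tes`` are 0-based genomic coordinates of the first and the
    one-past-last transcribed base in transcription direction: a plus-strand
    gene transcribes ``[tss, tes)``, a minus-strand gene ``(tes, tss]``. Genes
    lacking a TES (``tes is None``) can anchor TSS metaplots but not gene-body
    bin analyses. ``txn_freq`` is a relative transcription frequency used only
    for ordering heatmap rows and, in simulations, for scaling TC-NER.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int | None = None
    txn_freq: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise DataError(f"gene {self.id}: invalid strand {self.strand!r}")
        if self.tes is not None:
            if self.tss == self.tes:
                raise DataError(f"gene {self.id}: tss == tes")
            if (self.tss < self.tes) != (self.strand == "+"):
                raise DataError(
                    f"gene {self.id}: transcription direction inconsistent with strand"
                )
        if self.txn_freq is not None and self.txn_freq < 0:
            raise DataError(f"gene {self.id}: negative txn_freq")

    @property
    def length(self) -> int | None:
        if self.tes is None:
            return None
        return abs(self.tes - self.tss)

    @property
    def template_strand(self) -> str:
        """The transcribed strand (TS): the strand opposite the coding strand."""
        return "-" if self.strand == "+" else "+"


@dataclass
class GeneSet:
    """An ordered collection of :class:`GeneRecord`."""

    genes: list[GeneRecord] = field(default_factory=list)
    n_dropped: int = 0  # records discarded at load time (invariant violations)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def with_tes(self) -> "GeneSet":
        """Genes usable for gene-body bin analyses (TES present)."""
        return GeneSet([g for g in self.genes if g.tes is not None])

    def on_chroms(self, lengths: Mapping[str, int]) -> tuple["GeneSet", int]:
        """Keep genes on known chromosomes; return (kept, n_dropped)."""
        kept = [g for g in self.genes if g.chrom in lengths]
        return GeneSet(kept), len(self.genes) - len(kept)


class SignalTrack(dict):
    """Dense per-base non-negative signal: ``chrom -> float ndarray``."""

    @classmethod
    def zeros(cls, lengths: Mapping[str, int]) -> "SignalTrack":
        return cls({c: np.zeros(n, dtype=float) for c, n in lengths.items()})


class LesionMap:
    """Strand-specific single-nucleotide lesion counts.

    ``counts[chrom][strand]`` is a dense integer vector over the chromosome.
    The count at coordinate ``a`` on damaged strand ``s`` is the number of
    lesions whose dimer occupies genomic ``{a, a+1}`` when ``s == "+"`` and
    ``{a-1, a}`` when ``s == "-"``: the anchor is always the 5' base of the
    dimer in damaged-strand orientation.
    """

    def __init__(self, lengths: Mapping[str, int], *, filtered: bool = False):
        self.lengths = dict(lengths)
        self.counts: dict[str, dict[str, np.ndarray]] = {
            c: {s: np.zeros(n, dtype=np.int64) for s in STRANDS}
            for c, n in self.lengths.items()
        }
        self.filtered = filtered
        self.filter_losses = 0  # counts removed by the dipyrimidine filter
        self.oob_drops = 0  # reads whose inferred anchor fell off-chromosome

    def total(self) -> int:
        return int(
            sum(arr.sum() for per in self.counts.values() for arr in per.values())
        )

    def copy(self) -> "LesionMap":
        new = LesionMap(self.lengths, filtered=self.filtered)
        for c in self.counts:
            for s in STRANDS:
                new.counts[c][s] = self.counts[c][s].copy()
        new.filter_losses = self.filter_losses
        new.oob_drops = self.oob_drops
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LesionMap):
            return NotImplemented
        if self.lengths != other.lengths:
            return False
        return all(
            np.array_equal(self.counts[c][s], other.counts[c][s])
            for c in self.counts
            for s in STRANDS
        )

    def nonzero(self) -> Iterator[tuple[str, str, int, int]]:
        """Yield ``(chrom, strand, anchor, count)`` for every nonzero anchor."""
        for c in sorted(self.counts):
            for s in STRANDS:
                arr = self.counts[c][s]
                for pos in np.flatnonzero(arr):
                    yield c, s, int(pos), int(arr[pos])
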