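"""Core domain types shared by every pipeline stage.

All genomic coordinates are 0-based, half-open ``[start, end)`` on the
forward reference strand, regardless of transcript orientation.  GFF3 I/O
converts at the boundary; BED is native.  Minus-strand transcripts keep
their exons stored in genomic order — orientation is handled wherever a
transcript-sense view is needed (sequence extraction, coordinate
projection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class IsoscapeError(Exception):
    """Base class for all package errors."""


class ParseError(IsoscapeError):
    """Malformed input file."""


class ConfigError(IsoscapeError):
    """Invalid or infeasible configuration."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """A mapped full-length isoform: a stranded exon chain plus alignment stats.

    ``identity`` and ``coverage`` are the GMAP-style alignment fraction
    statistics the quality filter operates on; curated inputs without these
    attributes default to 1.0.  ``sequence``, when present, is the spliced
    sense-strand (5'→3') nucleotide sequence.
    """

    transcript_id: str
    exons: list[GenomicInterval]
    gene_id: Optional[str] = None
    identity: float = 1.0
    coverage: float = 1.0
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or abut "
                    f"([{a.start},{a.end}) then [{b.start},{b.end}))"
                )
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError(f"{self.transcript_id}: identity/coverage not in [0,1]")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"summed exon length {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Spliced (mature) transcript length in bp."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Hashable intron-coordinate key used by the redundancy collapse."""
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))

    def five_prime(self) -> int:
        """Genomic coordinate of the transcript 5' terminus (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        """Genomic coordinate of the transcript 3' terminus (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class RepeatFeature:
    """One repeat/TE annotation record (RepeatMasker hit or BED row)."""

    interval: GenomicInterval
    family: str
    te_class: str = "Unknown"
    is_transposase_family: bool = False

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")


@dataclass
class TermAnnotationMap:
    """Gene → functional-term annotation used for set enrichment."""

    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                self.term_names.setdefault(t, t)

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out
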