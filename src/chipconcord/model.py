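"""Core domain types and coordinate conventions.

All genomic coordinates are 0-based, half-open ``[start, end)`` — the BED
convention. GTF-style 1-based inclusive inputs are converted on read. A
"±N bp" window around a point ``p`` is the closed genomic range
``[p − N, p + N]``, stored half-open as ``[p − N, p + N + 1)``, so that the
anchor base itself and N bases on each side are all included.

The strand-dependent transcription start site (TSS) of a gene body interval
is ``start`` on the + strand and ``end − 1`` (the last contained base) on
the − strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "ChipConcordError",
    "ValidationError",
    "ParseError",
    "ConfigurationError",
    "Interval",
    "Tag",
    "Peak",
    "MergedRegion",
    "GeneModel",
    "OrthologPair",
    "GeneSet",
    "CoverageProfile",
    "EnrichmentResult",
    "window_around",
]

STRANDS = ("+", "-")


class ChipConcordError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChipConcordError, ValueError):
    """An object or argument violates a documented invariant."""


class ParseError(ChipConcordError, ValueError):
    """A record in an input file could not be parsed.

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class ConfigurationError(ChipConcordError, ValueError):
    """A parameter combination or column mapping is unusable."""


def _check_strand(strand: str) -> None:
    if strand not in STRANDS:
        raise ValidationError(f"strand must be one of {STRANDS!r}, got {strand!r}")


@dataclass(frozen=True, slots=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True, slots=True)
class Tag:
    """One aligned sequencing read, reduced to its 5′ position and strand.

    ``five_prime`` is the 0-based genomic coordinate of the read's 5′ end:
    the BED ``start`` for + reads and ``end − 1`` for − reads.
    """

    chrom: str
    five_prime: int
    strand: str

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValidationError(f"five_prime must be >= 0, got {self.five_prime}")
        _check_strand(self.strand)


@dataclass(frozen=True, slots=True)
class Peak:
    """A called enrichment interval.

    ``score`` is caller-dependent (here −10·log10 of the window p-value);
    ``fdr`` is an empirical false discovery rate as a fraction in [0, 1];
    ``tag_count`` may be ``None`` on ingest and is filled from tag data.
    """

    interval: Interval
    score: float
    fdr: Optional[float]
    tag_count: Optional[int] = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"fdr must lie in [0, 1], got {self.fdr}")
        if self.tag_count is not None and self.tag_count < 0:
            raise ValidationError(f"tag_count must be >= 0, got {self.tag_count}")

    def with_tag_count(self, n: int) -> "Peak":
        return replace(self, tag_count=n)


@dataclass(slots=True)
class MergedRegion:
    """A union interval across datasets' peak sets.

    ``contributing_datasets`` names the datasets whose selected peaks were
    merged into the region. ``counts`` maps dataset label to its
    depth-normalized tag count in the region; ``membership`` maps a fold
    tolerance k to the set of datasets called present under that tolerance.
    """

    interval: Interval
    contributing_datasets: frozenset[str]
    counts: dict[str, float] = field(default_factory=dict)
    membership: dict[float, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contributing_datasets:
            raise ValidationError("MergedRegion needs at least one contributing dataset")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene body with a strand-aware transcription start site."""

    gene_id: str
    interval: Interval
    strand: str

    def __post_init__(self) -> None:
        _check_strand(self.strand)

    @property
    def tss(self) -> int:
        """First transcribed base: start for +, end − 1 for − genes."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True, slots=True)
class OrthologPair:
    """A one-to-one, bidirectional ortholog relationship between two species."""

    gene_a: str
    gene_b: str


@dataclass(frozen=True, slots=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass(slots=True)
class CoverageProfile:
    """Strand-oriented average coverage around a set of anchor positions.

    ``bin_offsets`` are bin start offsets relative to the anchor (negative =
    upstream of the TSS in transcription orientation). ``values`` are mean
    per-base coverages per bin, scaled to the reference library size.
    """

    bin_offsets: "list[int]"
    values: "list[float]"
    n_tss: int
    library_size: int

    def __post_init__(self) -> None:
        if len(self.bin_offsets) != len(self.values):
            raise ValidationError("bin_offsets and values must have equal length")
        if any(v < 0 for v in self.values):
            raise ValidationError("coverage values must be non-negative")


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One gene set's 2×2 contingency margins with raw and adjusted p-values.

    k_overlap = |bound ∩ set|, n_bound = |bound|, K_set = |set ∩ universe|,
    N_universe = |universe|.
    """

    set_name: str
    k_overlap: int
    n_bound: int
    K_set: int
    N_universe: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.k_overlap > min(self.n_bound, self.K_set):
            raise ValidationError("overlap exceeds a margin of the 2x2 table")
        if self.K_set > self.N_universe or self.n_bound > self.N_universe:
            raise ValidationError("margins exceed universe size")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")
        if self.q_value < self.p_value - 1e-15:
            raise ValidationError("adjusted q-value below raw p-value")


def window_around(chrom: str, position: int, half_width: int) -> Interval:
    """The ±half_width window around a point, clipped at the chromosome start.

    Returns the half-open interval [position − half_width,
    position + half_width + 1) ∩ [0, ∞): the closed genomic range covering
    the anchor base and ``half_width`` bases on each side.
    """
    if half_width < 0:
        raise ValidationError(f"half_width must be >= 0, got {half_width}")
    return Interval(chrom, max(0, position - half_width), position + half_width + 1)
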