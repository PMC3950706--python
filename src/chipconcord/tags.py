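"""Read filtering, tag counting, strand-aware elongation and coverage.

The duplicate filter keeps at most ``max_per_start`` reads per
(chromosome, strand, 5′ position) and censors — removes entirely — any
position carrying more than ``censor_above`` reads, the signature of a PCR
amplification artifact. Coverage and summit operations elongate each tag to
a fixed fragment length (default 200 bp) in the 3′ direction of its strand.
Depth normalization rescales counts to a reference library of 20 million
usable reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import ConfigurationError, Interval, Tag, ValidationError

__all__ = [
    "FilterReport",
    "TagIndex",
    "filter_tags",
    "elongate",
    "count_tags",
    "coverage",
    "normalization_factor",
]

DEFAULT_EXTENSION = 200
REFERENCE_LIBRARY = 20_000_000


@dataclass(slots=True)
class FilterReport:
    """Bookkeeping for the duplicate filter; conserves the input count."""

    n_input: int
    n_retained: int
    n_duplicates_removed: int
    n_censored: int
    censored_positions: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + self.n_duplicates_removed + self.n_censored:
            raise ValidationError(
                "filter report does not conserve counts: "
                f"{self.n_input} != {self.n_retained} + "
                f"{self.n_duplicates_removed} + {self.n_censored}"
            )


def filter_tags(
    tags: Iterable[Tag], max_per_start: int = 2, censor_above: int = 7
) -> tuple[list[Tag], FilterReport]:
    """Cap duplicates per start position and censor amplification artifacts.

    Tags are grouped by (chrom, strand, five_prime). A group larger than
    ``censor_above`` contributes nothing — the whole position is censored.
    Any other group contributes ``min(size, max_per_start)`` tags, the
    excess counting as removed duplicates. Output is sorted by
    (chrom, five_prime, strand) so the result is deterministic regardless
    of input order.
    """
    if max_per_start < 1:
        raise ValidationError(f"max_per_start must be >= 1, got {max_per_start}")
    if censor_above < max_per_start:
        raise ValidationError(
            f"censor_above ({censor_above}) must be >= max_per_start ({max_per_start})"
        )

    groups: dict[tuple[str, str, int], int] = {}
    n_input = 0
    for t in tags:
        n_input += 1
        key = (t.chrom, t.strand, t.five_prime)
        groups[key] = groups.get(key, 0) + 1

    retained: list[Tag] = []
    censored_positions: list[tuple[str, str, int]] = []
    n_dup = 0
    n_cens = 0
    for (chrom, strand, pos), size in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1])
    ):
        if size > censor_above:
            n_cens += size
            censored_positions.append((chrom, strand, pos))
            continue
        keep = min(size, max_per_start)
        n_dup += size - keep
        retained.extend(Tag(chrom, pos, strand) for _ in range(keep))

    report = FilterReport(n_input, len(retained), n_dup, n_cens, censored_positions)
    return retained, report


def elongate(tag: Tag, extension: int = DEFAULT_EXTENSION) -> Interval:
    """Extend a tag to its presumed fragment footprint.

    + strand: [five_prime, five_prime + extension);
    − strand: [five_prime − extension + 1, five_prime + 1), clipped at 0.
    """
    if extension < 1:
        raise ValidationError(f"extension must be >= 1, got {extension}")
    if tag.strand == "+":
        return Interval(tag.chrom, tag.five_prime, tag.five_prime + extension)
    return Interval(tag.chrom, max(0, tag.five_prime - extension + 1), tag.five_prime + 1)


class TagIndex:
    """Per-chromosome sorted position index for fast interval counting.

    Positions from both strands are pooled; the unclipped elongated start
    (``five_prime`` for +, ``five_prime − extension + 1`` for −) reduces
    footprint-overlap queries to a half-open range count, which is exact
    even for footprints clipped at the chromosome start.
    """

    def __init__(self, tags: Iterable[Tag]):
        by_chrom: dict[str, list[tuple[int, bool]]] = {}
        n = 0
        for t in tags:
            by_chrom.setdefault(t.chrom, []).append((t.five_prime, t.strand == "+"))
            n += 1
        self.n_tags = n
        self._five: dict[str, np.ndarray] = {}
        self._fwd: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.array([p for p, _ in pairs], dtype=np.int64)
            fwd = np.array([f for _, f in pairs], dtype=bool)
            order = np.argsort(arr, kind="stable")
            self._five[chrom] = arr[order]
            self._fwd[chrom] = fwd[order]

    def chroms(self) -> list[str]:
        return sorted(self._five)

    def max_position(self, chrom: str) -> int:
        arr = self._five.get(chrom)
        return int(arr[-1]) if arr is not None and arr.size else 0

    def count_five_prime_in(self, interval: Interval) -> int:
        arr = self._five.get(interval.chrom)
        if arr is None:
            return 0
        lo = np.searchsorted(arr, interval.start, side="left")
        hi = np.searchsorted(arr, interval.end, side="left")
        return int(hi - lo)

    def count_five_prime_in_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        arr = self._five.get(chrom)
        if arr is None:
            return np.zeros(len(starts), dtype=np.int64)
        return np.searchsorted(arr, ends, side="left") - np.searchsorted(
            arr, starts, side="left"
        )

    def count_overlap_extended(self, interval: Interval, extension: int) -> int:
        arr = self._five.get(interval.chrom)
        if arr is None:
            return 0
        fwd = self._fwd[interval.chrom]
        starts = np.where(fwd, arr, arr - extension + 1)
        starts.sort(kind="stable")
        lo = np.searchsorted(starts, interval.start - extension + 1, side="left")
        hi = np.searchsorted(starts, interval.end, side="left")
        return int(hi - lo)


def count_tags(
    tags: "Iterable[Tag] | TagIndex",
    interval: Interval,
    mode: str = "five_prime_in",
    extension: int = DEFAULT_EXTENSION,
) -> int:
    """Count tags in an interval.

    ``five_prime_in`` counts tags whose 5′ end lies in [start, end);
    ``overlap_extended`` counts tags whose elongated footprint intersects
    the interval. A prebuilt :class:`TagIndex` is accepted in place of a tag
    collection to amortize indexing over many queries.
    """
    if mode not in ("five_prime_in", "overlap_extended"):
        raise ConfigurationError(f"unknown counting mode {mode!r}")
    idx = tags if isinstance(tags, TagIndex) else TagIndex(tags)
    if mode == "five_prime_in":
        return idx.count_five_prime_in(interval)
    if extension < 1:
        raise ValidationError(f"extension must be >= 1, got {extension}")
    return idx.count_overlap_extended(interval, extension)


def coverage(
    tags: Iterable[Tag], interval: Interval, extension: int = DEFAULT_EXTENSION
) -> np.ndarray:
    """Per-base elongated-tag pileup over an interval.

    Returns an integer vector of length ``end − start`` where entry i is
    the number of elongated tags covering base ``start + i``. Coverage is
    additive over any partition of the tag collection.
    """
    if extension < 1:
        raise ValidationError(f"extension must be >= 1, got {extension}")
    length = len(interval)
    delta = np.zeros(length + 1, dtype=np.int64)
    for t in tags:
        if t.chrom != interval.chrom:
            continue
        fp = elongate(t, extension)
        s = max(fp.start, interval.start) - interval.start
        e = min(fp.end, interval.end) - interval.start
        if e > s:
            delta[s] += 1
            delta[e] -= 1
    return np.cumsum(delta[:-1])


def normalization_factor(library_size: int, reference: int = REFERENCE_LIBRARY) -> float:
    """Depth-normalization factor rescaling a library to ``reference`` reads."""
    if library_size < 1:
        raise ValidationError(f"library_size must be >= 1, got {library_size}")
    return reference / library_size
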