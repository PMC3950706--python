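"""Multi-dataset occupancy concordance and summit calling.

Selected peak sets from several ChIP experiments are merged into union
regions; each region carries a depth-normalized tag count per dataset, and
a fold tolerance k calls a dataset "present" in a region when its count is
within a factor k of the best dataset there (count ≥ max/k). Tallying the
exact presence subsets yields a Venn partition whose all-datasets cell
grows as the tolerated fold difference grows. Summits are the positions of
maximal pooled elongated-tag overlap within a region, and fixed half-width
windows around them feed motif-discovery input export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import ConfigurationError, Interval, MergedRegion, Peak, Tag, ValidationError
from .tags import DEFAULT_EXTENSION, REFERENCE_LIBRARY, TagIndex, coverage, normalization_factor

__all__ = [
    "VennPartition",
    "Summit",
    "merge_peak_sets",
    "region_counts",
    "fold_membership",
    "venn_partition",
    "compute_summit",
    "summit_windows",
]


@dataclass(slots=True)
class VennPartition:
    """Counts of merged regions by exact dataset-presence subset at one k."""

    k: float
    cells: dict[frozenset[str], int]

    def total(self) -> int:
        return sum(self.cells.values())

    def cell(self, labels: Iterable[str]) -> int:
        return self.cells.get(frozenset(labels), 0)


@dataclass(slots=True)
class Summit:
    """Position of maximal elongated-tag overlap within a region.

    ``plateau`` is the leftmost maximal run of the peak coverage value;
    ``position`` is its midpoint. ``flagged`` marks zero-coverage regions,
    whose position falls back to the region midpoint.
    """

    region: Interval
    position: int
    height: int
    plateau: Interval
    flagged: bool = False


def merge_peak_sets(peak_sets: Mapping[str, Sequence[Peak]]) -> list[MergedRegion]:
    """Union overlapping peak intervals across datasets into merged regions.

    Maximal runs of mutually overlapping intervals (any dataset) become one
    region spanning their union; ``contributing_datasets`` records which
    datasets placed a peak in the run. Counts and memberships are left for
    :func:`region_counts` / :func:`fold_membership`. The result is
    invariant under dataset ordering and idempotent on its own output.
    """
    events: list[tuple[str, int, int, str]] = []
    for label, peaks in peak_sets.items():
        for p in peaks:
            events.append((p.interval.chrom, p.interval.start, p.interval.end, label))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    regions: list[MergedRegion] = []
    cur_chrom = None
    cur_start = cur_end = 0
    cur_labels: set[str] = set()
    for chrom, start, end, label in events:
        if cur_chrom == chrom and start <= cur_end:  # book-ended intervals merge too
            cur_end = max(cur_end, end)
            cur_labels.add(label)
        else:
            if cur_chrom is not None:
                regions.append(
                    MergedRegion(Interval(cur_chrom, cur_start, cur_end), frozenset(cur_labels))
                )
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur_labels = {label}
    if cur_chrom is not None:
        regions.append(
            MergedRegion(Interval(cur_chrom, cur_start, cur_end), frozenset(cur_labels))
        )
    return regions


def region_counts(
    regions: Sequence[MergedRegion],
    tag_sets: Mapping[str, Sequence[Tag]],
    library_sizes: Mapping[str, int],
    reference: int = REFERENCE_LIBRARY,
) -> list[MergedRegion]:
    """Fill per-dataset depth-normalized tag counts into merged regions.

    ``counts[d] = (# tags of d with 5′ end in region) × reference/library_d``.
    Normalization removes sequencing-depth differences so the fold rule
    compares occupancies, not library sizes.
    """
    labels = set().union(*(r.contributing_datasets for r in regions)) if regions else set()
    missing = labels - set(tag_sets)
    if missing:
        raise ConfigurationError(f"tag sets missing for datasets {sorted(missing)}")
    indexes = {d: TagIndex(ts) for d, ts in tag_sets.items()}
    factors = {d: normalization_factor(library_sizes[d], reference) for d in tag_sets}
    for r in regions:
        r.counts = {
            d: indexes[d].count_five_prime_in(r.interval) * factors[d] for d in sorted(tag_sets)
        }
    return list(regions)


def fold_membership(region: MergedRegion, k: float) -> frozenset[str]:
    """Datasets whose count is within a factor k of the region's maximum.

    With m = max over datasets of the normalized count: if m > 0, the
    membership is {d : counts[d] ≥ m / k}; if every count is zero the
    contributing datasets stand. Membership is monotone in k, so a larger
    tolerated fold difference can only grow each region's presence set.
    The result is also cached on ``region.membership[k]``.
    """
    if k < 1:
        raise ValidationError(f"fold tolerance k must be >= 1, got {k}")
    if not region.counts:
        raise ValidationError("region counts not filled; run region_counts first")
    m = max(region.counts.values())
    if m > 0:
        members = frozenset(d for d, c in region.counts.items() if c >= m / k)
    else:
        members = region.contributing_datasets
    region.membership[k] = members
    return members


def venn_partition(regions: Sequence[MergedRegion], k: float) -> VennPartition:
    """Tally regions by exact fold-tolerance membership subset.

    Cell counts sum to the number of regions for every k.
    """
    cells: dict[frozenset[str], int] = {}
    for r in regions:
        members = r.membership.get(k) or fold_membership(r, k)
        cells[members] = cells.get(members, 0) + 1
    return VennPartition(k, cells)


def compute_summit(
    region: Interval, pooled_tags: Sequence[Tag], extension: int = DEFAULT_EXTENSION
) -> Summit:
    """Locate the position of highest pooled elongated-tag overlap.

    Reads from all datasets are pooled (unnormalized), elongated to
    ``extension`` bp, and piled up over the region; the summit is the
    midpoint ``floor((plateau.start + plateau.end − 1) / 2)`` of the
    leftmost maximal run of the peak coverage value, a deterministic
    tie-break for the plateaus that fixed-length elongation guarantees.
    """
    cov = coverage(pooled_tags, region, extension)
    height = int(cov.max()) if cov.size else 0
    if height == 0:
        mid = (region.start + region.end - 1) // 2
        return Summit(region, mid, 0, Interval(region.chrom, region.start, region.end), True)
    at_max = cov == height
    plat_start = int(np.argmax(at_max))
    plat_end = plat_start
    while plat_end < len(cov) and at_max[plat_end]:
        plat_end += 1
    plateau = Interval(region.chrom, region.start + plat_start, region.start + plat_end)
    position = (plateau.start + plateau.end - 1) // 2
    return Summit(region, position, height, plateau)


def summit_windows(
    summits: Iterable[Summit],
    half_width: int = 150,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Interval]:
    """±half_width windows around summit positions, clipped at chromosome bounds.

    Away from boundaries each window has length ``2·half_width + 1`` (the
    summit base plus half_width on each side).
    """
    if half_width < 0:
        raise ValidationError(f"half_width must be >= 0, got {half_width}")
    out: list[Interval] = []
    for s in summits:
        chrom = s.region.chrom
        start = max(0, s.position - half_width)
        end = s.position + half_width + 1
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        out.append(Interval(chrom, start, end))
    return out
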