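"""Gene-centric annotation of binding sites.

Peaks associate with a gene when they overlap the ±half_window range
around its transcription start site (default ±1250 bp; ±10 kb for
cross-species comparisons where only coarse site lists are available).
Location classification is exclusive with priority TSS-proximal >
intragenic > intergenic. Bound-gene sets from two species are compared
through a one-to-one ortholog map, with species-specific bound genes
tallied separately. TSS metaprofiles average strand-oriented elongated-tag
coverage around all TSSs, normalized to a reference library depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CoverageProfile,
    GeneModel,
    Interval,
    OrthologPair,
    Peak,
    Tag,
    ValidationError,
    window_around,
)
from .tags import DEFAULT_EXTENSION, REFERENCE_LIBRARY, TagIndex, elongate, normalization_factor

__all__ = [
    "LocationBreakdown",
    "HomologyVenn",
    "associate_peaks_tss",
    "classify_locations",
    "bound_genes",
    "homology_venn",
    "tss_metaprofile",
    "tss_count_distribution",
]

TSS_HALF_WINDOW = 1250
CROSS_SPECIES_HALF_WINDOW = 10_000


@dataclass(slots=True)
class LocationBreakdown:
    """Exclusive peak-location categories relative to gene models."""

    n_tss_proximal: int
    n_intragenic: int
    n_intergenic: int

    @property
    def total(self) -> int:
        return self.n_tss_proximal + self.n_intragenic + self.n_intergenic

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (self.n_tss_proximal / t, self.n_intragenic / t, self.n_intergenic / t)


@dataclass(slots=True)
class HomologyVenn:
    """Cross-species bound-gene comparison through one-to-one orthologs.

    Ortholog pairs are tallied by boundness in species A, B or both;
    bound genes with no one-to-one partner count as species-specific.
    """

    n_both: int
    n_a_only: int
    n_b_only: int
    n_a_specific: int
    n_b_specific: int


def _tss_windows(genes: Sequence[GeneModel], half_window: int) -> list[Interval]:
    return [window_around(g.interval.chrom, g.tss, half_window) for g in genes]


def associate_peaks_tss(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    half_window: int = TSS_HALF_WINDOW,
) -> tuple[dict[str, list[Peak]], list[list[str]]]:
    """Associate peaks with genes by TSS-window overlap (many-to-many).

    Returns ``(gene_to_peaks, peak_to_genes)``: the first maps gene_id to
    its associated peaks in input order; the second is aligned with the
    input peak order and lists associated gene_ids sorted lexicographically.
    """
    windows = _tss_windows(genes, half_window)
    gene_to_peaks: dict[str, list[Peak]] = {}
    peak_to_genes: list[list[str]] = []
    for p in peaks:
        hits = [g.gene_id for g, w in zip(genes, windows) if p.interval.overlaps(w)]
        hits.sort()
        peak_to_genes.append(hits)
        for gid in hits:
            gene_to_peaks.setdefault(gid, []).append(p)
    return gene_to_peaks, peak_to_genes


def classify_locations(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    half_window: int = TSS_HALF_WINDOW,
) -> tuple[list[str], LocationBreakdown]:
    """Assign each peak exactly one location category.

    Priority: a peak overlapping any TSS window is ``tss_proximal``; else
    one overlapping any gene body is ``intragenic``; else ``intergenic``.
    """
    windows = _tss_windows(genes, half_window)
    bodies = [g.interval for g in genes]
    categories: list[str] = []
    n_tss = n_intra = n_inter = 0
    for p in peaks:
        if any(p.interval.overlaps(w) for w in windows):
            categories.append("tss_proximal")
            n_tss += 1
        elif any(p.interval.overlaps(b) for b in bodies):
            categories.append("intragenic")
            n_intra += 1
        else:
            categories.append("intergenic")
            n_inter += 1
    return categories, LocationBreakdown(n_tss, n_intra, n_inter)


def bound_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    half_window: int = TSS_HALF_WINDOW,
) -> set[str]:
    """Genes with at least one peak overlapping their TSS ± half_window."""
    windows = _tss_windows(genes, half_window)
    bound: set[str] = set()
    for g, w in zip(genes, windows):
        if any(p.interval.overlaps(w) for p in peaks):
            bound.add(g.gene_id)
    return bound


def homology_venn(
    bound_a: set[str], bound_b: set[str], pairs: Sequence[OrthologPair]
) -> HomologyVenn:
    """Tally ortholog pairs by boundness in species A, B or both.

    Bound genes absent from every pair are species-specific and tallied in
    their own cells, mirroring the separate circles of a cross-species
    comparison where not every gene has a one-to-one partner.
    """
    paired_a = {p.gene_a for p in pairs}
    paired_b = {p.gene_b for p in pairs}
    if len(paired_a) != len(pairs) or len(paired_b) != len(pairs):
        raise ValidationError("ortholog map is not one-to-one")
    n_both = n_a_only = n_b_only = 0
    for p in pairs:
        in_a = p.gene_a in bound_a
        in_b = p.gene_b in bound_b
        if in_a and in_b:
            n_both += 1
        elif in_a:
            n_a_only += 1
        elif in_b:
            n_b_only += 1
    n_a_specific = len(bound_a - paired_a)
    n_b_specific = len(bound_b - paired_b)
    return HomologyVenn(n_both, n_a_only, n_b_only, n_a_specific, n_b_specific)


def tss_metaprofile(
    tags: Sequence[Tag],
    genes: Sequence[GeneModel],
    library_size: int,
    flank: int = 2500,
    bin: int = 25,
    extension: int = DEFAULT_EXTENSION,
    reference: int = REFERENCE_LIBRARY,
) -> CoverageProfile:
    """Average strand-oriented coverage around TSSs, depth-normalized.

    For each gene, the elongated-tag pileup over [TSS − flank, TSS + flank)
    is oriented so positive offsets run downstream of transcription; the
    per-bin mean coverage is averaged over genes and multiplied by the
    normalization factor ``reference / library_size``. Windows truncated by
    the chromosome start contribute only their valid bases (per-base
    weights, not zero padding). The profile is exactly invariant under
    duplicating every tag while doubling ``library_size``.
    """
    if flank % bin != 0:
        raise ValidationError(f"flank ({flank}) must be divisible by bin ({bin})")
    if library_size < 1:
        raise ValidationError("library_size must be >= 1")
    n_bins = 2 * flank // bin
    bin_offsets = list(range(-flank, flank, bin))
    if not genes:
        return CoverageProfile(bin_offsets, [0.0] * n_bins, 0, library_size)

    # genome-wide pileup per chromosome, computed once
    by_chrom: dict[str, list[Tag]] = {}
    for t in tags:
        by_chrom.setdefault(t.chrom, []).append(t)
    extents: dict[str, int] = {}
    for g in genes:
        extents[g.interval.chrom] = max(
            extents.get(g.interval.chrom, 0), g.tss + flank + 1
        )
    for chrom, ts in by_chrom.items():
        for t in ts:
            extents[chrom] = max(extents.get(chrom, 0), t.five_prime + extension)
    pileups: dict[str, np.ndarray] = {}
    for chrom, length in extents.items():
        delta = np.zeros(length + 1, dtype=np.int64)
        for t in by_chrom.get(chrom, ()):  # elongated footprints
            fp = elongate(t, extension)
            delta[fp.start] += 1
            delta[min(fp.end, length)] -= 1
        pileups[chrom] = np.cumsum(delta[:-1])

    total = np.zeros(2 * flank, dtype=np.float64)
    weight = np.zeros(2 * flank, dtype=np.float64)
    for g in genes:
        cov = pileups.get(g.interval.chrom)
        win = np.full(2 * flank, np.nan)
        if g.strand == "+":
            lo, hi = g.tss - flank, g.tss + flank
            src_lo = max(0, lo)
            if cov is not None and hi > src_lo:
                win[src_lo - lo : hi - lo] = cov[src_lo:hi]
        else:
            # genome window [tss − flank + 1, tss + flank + 1), reversed, so
            # that oriented offset o reads genome base tss − o
            lo, hi = g.tss - flank + 1, g.tss + flank + 1
            src_lo = max(0, lo)
            if cov is not None and hi > src_lo:
                win[src_lo - lo : hi - lo] = cov[src_lo:hi]
            win = win[::-1]
        valid = ~np.isnan(win)
        total[valid] += win[valid]
        weight[valid] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        per_base = np.where(weight > 0, total / np.maximum(weight, 1.0), 0.0)
    per_bin = per_base.reshape(n_bins, bin).mean(axis=1)
    factor = normalization_factor(library_size, reference)
    values = (per_bin * factor).tolist()
    return CoverageProfile(bin_offsets, values, len(genes), library_size)


def tss_count_distribution(
    tags: Sequence[Tag],
    tss_sets: Mapping[str, Iterable[str]],
    genes: Sequence[GeneModel],
    half_window: int = TSS_HALF_WINDOW,
) -> dict[str, pd.DataFrame]:
    """Empirical tag-count distributions over labelled TSS sets.

    For each label, counts tags (5′-in-window) in every member gene's TSS ±
    half_window and returns a DataFrame with columns ``tag_count`` (sorted
    ascending) and ``cumulative_fraction``, suitable for plotting one curve
    per set — e.g. all TSSs against the subset carrying peaks.
    """
    by_id = {g.gene_id: g for g in genes}
    idx = TagIndex(tags)
    out: dict[str, pd.DataFrame] = {}
    for label, members in tss_sets.items():
        ids = sorted(set(members))
        unknown = [gid for gid in ids if gid not in by_id]
        if unknown:
            raise ValidationError(f"unknown gene ids in TSS set {label!r}: {unknown[:5]}")
        counts = np.sort(
            np.array(
                [
                    idx.count_five_prime_in(
                        window_around(by_id[g].interval.chrom, by_id[g].tss, half_window)
                    )
                    for g in ids
                ],
                dtype=np.int64,
            )
        )
        n = len(counts)
        cum = (np.arange(1, n + 1) / n) if n else np.array([])
        out[label] = pd.DataFrame({"tag_count": counts, "cumulative_fraction": cum})
    return out
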