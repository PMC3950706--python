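"""Synthetic ChIP-Seq study generator with a ground-truth table.

Emulates the data regime the pipeline assumes: uniform Poisson background
tags on both strands; planted peaks whose tag 5′ ends are strand-shifted
by half the elongation distance around a true summit (so elongate-and-pile
is the correct summit estimator); per-dataset enrichment fold multipliers
with designated "shared" (near-equal occupancy) and "discordant" (one
dataset several-fold higher) peak classes; PCR-duplicate bursts replicating
single start positions; control libraries with optional artifact hotspots —
dense tag clusters exceeding the control-exclusion threshold that survive
duplicate filtering because no single start position is over-represented;
a gene annotation in which a controllable fraction of planted peaks falls
inside TSS ± 1250 bp; a one-to-one ortholog map to a second synthetic
species with correlated boundness; and gene sets enriched for bound genes.

All randomness flows from one seeded generator; identical designs produce
byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ChipConcordError, GeneModel, GeneSet, Interval, OrthologPair, Tag, ValidationError
from . import io as cio

__all__ = [
    "SimulationError",
    "SimulationDesign",
    "TruthTable",
    "SimulationResult",
    "simulate",
    "write_truth",
    "read_truth",
]

# geometry constants of the generator (documented in the methods note)
TAG_JITTER_SD = 35.0        # sd of tag 5' placement around the strand-shifted offset, bp
TRUTH_HALF_WIDTH = 150      # planted-peak truth interval is summit +/- 150 bp
MIN_SUMMIT_SPACING = 1500   # bp between planted summits
TSS_CLEARANCE = 3000        # min distance of non-TSS peaks / hotspots from any TSS, bp
HOTSPOT_CLUSTER_HALF = 100  # control artifact tags spread over center +/- 100 bp
EDGE_MARGIN = 8000          # bp kept free of genes/peaks at chromosome ends
B_BOUND_GIVEN_A = 0.6       # P(species-B ortholog bound | species-A gene bound)
B_BOUND_GIVEN_NOT_A = 0.1


class SimulationError(ChipConcordError):
    """The requested design cannot be realized (e.g. peaks do not fit)."""


def _default_folds() -> dict[str, dict[str, float]]:
    # three datasets mirroring an endogenous ChIP plus two tagged-construct
    # ChIPs; shared peaks differ by <= 1.5-fold, discordant peaks are 8-fold
    # enriched in the first dataset only
    return {
        "endogenous": {"shared": 1.0, "discordant": 8.0},
        "tagged_wt": {"shared": 1.2, "discordant": 1.0},
        "tagged_mut": {"shared": 0.9, "discordant": 1.0},
    }


@dataclass(slots=True)
class SimulationDesign:
    """Parameters of one synthetic study.

    ``background_rate`` is tags per bp pooled over both strands;
    ``peak_depth`` is the expected tag count per planted peak per dataset
    before the fold multiplier; ``duplicate_burst`` is (per-tag probability
    of amplification, burst group size); ``control_hotspots`` counts
    artifact loci planted with >100 control tags and matched treatment
    enrichment; ``frac_tss_peaks`` of the planted peaks fall inside
    TSS ± 1250 bp windows.
    """

    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 500_000)])
    n_genes: int = 60
    n_peaks: int = 40
    frac_tss_peaks: float = 0.8
    background_rate: float = 0.02
    peak_depth: float = 100.0
    dataset_folds: dict[str, dict[str, float]] = field(default_factory=_default_folds)
    frac_discordant: float = 0.25
    duplicate_burst: tuple[float, int] = (0.001, 12)
    control_hotspots: int = 3
    ortholog_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("frac_tss_peaks", self.frac_tss_peaks),
            ("frac_discordant", self.frac_discordant),
            ("ortholog_frac", self.ortholog_frac),
            ("duplicate probability", self.duplicate_burst[0]),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {frac}")
        if self.background_rate < 0 or self.peak_depth < 0:
            raise ValidationError("rates must be non-negative")
        if self.n_peaks > 0 and not self.dataset_folds:
            raise ValidationError("dataset_folds must name at least one dataset")
        for label, folds in self.dataset_folds.items():
            for klass in ("shared", "discordant"):
                if klass not in folds:
                    raise ValidationError(f"dataset {label!r} missing fold for {klass!r}")

    @property
    def labels(self) -> list[str]:
        return sorted(self.dataset_folds)

    def to_json(self) -> str:
        d = asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["duplicate_burst"] = list(self.duplicate_burst)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationDesign":
        d = json.loads(text)
        d["genome"] = [(c, int(l)) for c, l in d["genome"]]
        d["duplicate_burst"] = tuple(d["duplicate_burst"])
        return cls(**d)


@dataclass(slots=True, eq=False)
class TruthTable:
    """Ground truth of one simulation, as plain tables.

    ``peaks``: chrom, start, end, summit, peak_class, location_truth and
    one fold_<dataset> column per dataset. ``genes``: per-gene boundness
    flags at the 1250 and 10000 bp half-windows, ortholog assignment and
    species-B boundness. ``duplicates``: amplified start positions per
    dataset. ``hotspots``: control artifact loci with their planted control
    tag counts.
    """

    peaks: pd.DataFrame
    genes: pd.DataFrame
    duplicates: pd.DataFrame
    hotspots: pd.DataFrame

    def equals(self, other: "TruthTable") -> bool:
        return (
            self.peaks.equals(other.peaks)
            and self.genes.equals(other.genes)
            and self.duplicates.equals(other.duplicates)
            and self.hotspots.equals(other.hotspots)
        )


@dataclass(slots=True)
class SimulationResult:
    design: SimulationDesign
    genome: dict[str, str]
    genes: list[GeneModel]
    orthologs: list[OrthologPair]
    gene_sets: list[GeneSet]
    tags: dict[str, list[Tag]]      # ChIP datasets, keyed by label
    controls: dict[str, list[Tag]]  # "igg" and "mock_flag" control libraries
    bound_species_b: set[str]
    truth: TruthTable


def _poisson_background(
    rng: np.random.Generator, genome: Sequence[tuple[str, int]], rate: float
) -> list[Tag]:
    tags: list[Tag] = []
    for chrom, length in genome:
        for strand in ("+", "-"):
            n = rng.poisson(rate * length / 2.0)
            positions = np.sort(rng.integers(0, length, size=n))
            tags.extend(Tag(chrom, int(p), strand) for p in positions)
    return tags


def _peak_tags(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    summit: int,
    depth: float,
    extension: int = 200,
) -> list[Tag]:
    n = rng.poisson(depth)
    half = extension // 2
    out: list[Tag] = []
    for _ in range(n):
        jitter = int(round(rng.normal(0.0, TAG_JITTER_SD)))
        if rng.random() < 0.5:
            fp = summit - half + jitter
            strand = "+"
        else:
            fp = summit + half - 1 + jitter
            strand = "-"
        out.append(Tag(chrom, int(np.clip(fp, 0, chrom_len - 1)), strand))
    return out


def _place_genes(
    rng: np.random.Generator, genome: Sequence[tuple[str, int]], n_genes: int
) -> list[GeneModel]:
    total = sum(length for _, length in genome)
    genes: list[GeneModel] = []
    remaining = n_genes
    for i, (chrom, length) in enumerate(genome):
        usable = length - 2 * EDGE_MARGIN
        if usable <= 0:
            raise SimulationError(f"chromosome {chrom} too short for gene placement")
        n_here = remaining if i == len(genome) - 1 else min(
            remaining, int(round(n_genes * length / total))
        )
        if n_here == 0:
            continue
        spacing = usable / n_here
        if spacing < 2 * MIN_SUMMIT_SPACING:
            raise SimulationError(
                f"{n_here} genes do not fit on {chrom} with adequate spacing"
            )
        for j in range(n_here):
            anchor = EDGE_MARGIN + int(j * spacing + rng.uniform(0.1, 0.3) * spacing)
            body_len = int(rng.integers(2000, 6001))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = anchor, min(anchor + body_len, length)
            else:
                start, end = max(0, anchor - body_len + 1), anchor + 1
            genes.append(GeneModel(f"g{len(genes):04d}", Interval(chrom, start, end), strand))
        remaining -= n_here
    if remaining:
        raise SimulationError("could not allocate all genes to chromosomes")
    return genes


def _far_from(position: int, others: Sequence[int], min_dist: int) -> bool:
    return all(abs(position - o) >= min_dist for o in others)


def simulate(design: SimulationDesign, out_dir: str | None = None) -> SimulationResult:
    """Generate one synthetic study; optionally write all files to ``out_dir``.

    Written outputs (all plain text): per-dataset and per-control BED6 tag
    files, gene models TSV, ortholog map TSV, genome FASTA, GMT gene sets,
    a species-B bound-gene list, the design JSON and the truth tables.
    """
    rng = np.random.default_rng(design.seed)
    chrom_len = dict(design.genome)
    labels = design.labels

    genome_seq = {
        chrom: "".join(rng.choice(list("ACGT"), size=length))
        for chrom, length in design.genome
    }
    genes = _place_genes(rng, design.genome, design.n_genes) if design.n_genes else []
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.interval.chrom, []).append(g.tss)

    # --- hotspot loci: control artifacts with matched treatment enrichment
    hotspot_centers: list[tuple[str, int]] = []
    for _ in range(design.control_hotspots):
        for attempt in range(10_000):
            chrom, length = design.genome[int(rng.integers(0, len(design.genome)))]
            c = int(rng.integers(EDGE_MARGIN, length - EDGE_MARGIN))
            if _far_from(c, tss_by_chrom.get(chrom, []), TSS_CLEARANCE) and _far_from(
                c, [p for ch, p in hotspot_centers if ch == chrom], 2 * MIN_SUMMIT_SPACING
            ):
                hotspot_centers.append((chrom, c))
                break
        else:
            raise SimulationError("could not place control hotspots")

    # --- planted peak summits
    n_tss_peaks = int(round(design.frac_tss_peaks * design.n_peaks))
    if n_tss_peaks > len(genes):
        raise SimulationError("more TSS-proximal peaks requested than genes available")
    peak_rows: list[dict] = []
    chosen = rng.choice(len(genes), size=n_tss_peaks, replace=False) if n_tss_peaks else []
    for gi in sorted(int(x) for x in chosen):
        g = genes[gi]
        summit = g.tss + int(rng.integers(-1000, 1001))
        peak_rows.append({"chrom": g.interval.chrom, "summit": summit})
    placed_by_chrom: dict[str, list[int]] = {}
    for row in peak_rows:
        placed_by_chrom.setdefault(row["chrom"], []).append(row["summit"])
    for _ in range(design.n_peaks - n_tss_peaks):
        for attempt in range(20_000):
            chrom, length = design.genome[int(rng.integers(0, len(design.genome)))]
            s = int(rng.integers(EDGE_MARGIN, length - EDGE_MARGIN))
            if (
                _far_from(s, tss_by_chrom.get(chrom, []), TSS_CLEARANCE)
                and _far_from(s, placed_by_chrom.get(chrom, []), MIN_SUMMIT_SPACING)
                and _far_from(s, [p for ch, p in hotspot_centers if ch == chrom], 2000)
            ):
                peak_rows.append({"chrom": chrom, "summit": s})
                placed_by_chrom.setdefault(chrom, []).append(s)
                break
        else:
            raise SimulationError(
                f"could not place {design.n_peaks} non-overlapping peaks in this genome"
            )

    n_disc = int(round(design.frac_discordant * len(peak_rows)))
    disc_idx = set(
        int(x) for x in rng.choice(len(peak_rows), size=n_disc, replace=False)
    ) if peak_rows else set()
    gene_bodies = [(g.interval.chrom, g.interval.start, g.interval.end) for g in genes]
    for i, row in enumerate(peak_rows):
        row["start"] = row["summit"] - TRUTH_HALF_WIDTH
        row["end"] = row["summit"] + TRUTH_HALF_WIDTH + 1
        row["peak_class"] = "discordant" if i in disc_idx else "shared"
        near_tss = any(
            abs(row["summit"] - t) <= 1250 + TRUTH_HALF_WIDTH
            for t in tss_by_chrom.get(row["chrom"], [])
        )
        in_body = any(
            ch == row["chrom"] and s < row["end"] and row["start"] < e
            for ch, s, e in gene_bodies
        )
        row["location_truth"] = (
            "tss_proximal" if near_tss else "intragenic" if in_body else "intergenic"
        )
        for label in labels:
            row[f"fold_{label}"] = design.dataset_folds[label][row["peak_class"]]

    # --- tag libraries
    tags: dict[str, list[Tag]] = {}
    dup_rows: list[dict] = []
    dup_prob, dup_size = design.duplicate_burst
    for label in labels:
        lib = _poisson_background(rng, design.genome, design.background_rate)
        for row in peak_rows:
            lib.extend(
                _peak_tags(
                    rng,
                    row["chrom"],
                    chrom_len[row["chrom"]],
                    row["summit"],
                    design.peak_depth * row[f"fold_{label}"],
                )
            )
        for chrom, c in hotspot_centers:  # artifact loci look enriched in every ChIP
            lib.extend(_peak_tags(rng, chrom, chrom_len[chrom], c, design.peak_depth))
        if dup_prob > 0 and lib:
            burst = rng.random(len(lib)) < dup_prob
            for bi in np.flatnonzero(burst):
                t = lib[int(bi)]
                lib.extend([t] * (dup_size - 1))
                dup_rows.append(
                    {
                        "dataset": label,
                        "chrom": t.chrom,
                        "strand": t.strand,
                        "position": t.five_prime,
                        "size": dup_size,
                    }
                )
        tags[label] = lib

    # --- control libraries: clean IgG; mock-FLAG carries the artifact hotspots
    controls: dict[str, list[Tag]] = {}
    controls["igg"] = _poisson_background(rng, design.genome, design.background_rate)
    mock = _poisson_background(rng, design.genome, design.background_rate)
    hotspot_rows: list[dict] = []
    for chrom, c in hotspot_centers:
        n_art = int(rng.integers(130, 181))
        offsets = rng.integers(-HOTSPOT_CLUSTER_HALF, HOTSPOT_CLUSTER_HALF + 1, size=n_art)
        strands = rng.random(n_art) < 0.5
        mock.extend(
            Tag(chrom, int(np.clip(c + o, 0, chrom_len[chrom] - 1)), "+" if s else "-")
            for o, s in zip(offsets, strands)
        )
        hotspot_rows.append({"chrom": chrom, "center": c, "n_control_tags": n_art})
    controls["mock_flag"] = mock

    # --- ortholog map and species-B boundness
    truth_peak_ivs = [
        Interval(r["chrom"], max(0, r["start"]), r["end"]) for r in peak_rows
    ]

    def _bound(gene: GeneModel, half: int) -> bool:
        w_start, w_end = max(0, gene.tss - half), gene.tss + half + 1
        return any(
            iv.chrom == gene.interval.chrom and iv.start < w_end and w_start < iv.end
            for iv in truth_peak_ivs
        )

    gene_rows: list[dict] = []
    orthologs: list[OrthologPair] = []
    bound_species_b: set[str] = set()
    for g in genes:
        b1250 = _bound(g, 1250)
        b10k = _bound(g, 10_000)
        has_orth = bool(rng.random() < design.ortholog_frac)
        orth_id = f"sB_{g.gene_id}" if has_orth else ""
        bound_b = False
        if has_orth:
            orthologs.append(OrthologPair(g.gene_id, orth_id))
            p_b = B_BOUND_GIVEN_A if b10k else B_BOUND_GIVEN_NOT_A
            bound_b = bool(rng.random() < p_b)
            if bound_b:
                bound_species_b.add(orth_id)
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "bound_1250": int(b1250),
                "bound_10000": int(b10k),
                "ortholog_id": orth_id,
                "bound_species_b": int(bound_b),
            }
        )

    # --- gene sets: one enriched for bound genes, the rest uniform draws
    gene_sets: list[GeneSet] = []
    if genes:
        bound_ids = [r["gene_id"] for r in gene_rows if r["bound_1250"]]
        other_ids = [r["gene_id"] for r in gene_rows if not r["bound_1250"]]
        size = max(5, min(15, len(genes) // 4))
        n_from_bound = min(len(bound_ids), int(round(0.8 * size)))
        members = list(
            rng.choice(bound_ids, size=n_from_bound, replace=False)
        ) + list(
            rng.choice(other_ids, size=min(len(other_ids), size - n_from_bound), replace=False)
        )
        gene_sets.append(GeneSet("bound_biased_set", frozenset(members)))
        all_ids = [g.gene_id for g in genes]
        for i in range(4):
            members = rng.choice(all_ids, size=size, replace=False)
            gene_sets.append(GeneSet(f"random_set_{i + 1}", frozenset(members)))

    truth = TruthTable(
        peaks=pd.DataFrame(
            peak_rows,
            columns=["chrom", "start", "end", "summit", "peak_class", "location_truth"]
            + [f"fold_{label}" for label in labels],
        ),
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "bound_1250", "bound_10000", "ortholog_id", "bound_species_b"],
        ),
        duplicates=pd.DataFrame(
            dup_rows, columns=["dataset", "chrom", "strand", "position", "size"]
        ),
        hotspots=pd.DataFrame(hotspot_rows, columns=["chrom", "center", "n_control_tags"]),
    )
    result = SimulationResult(
        design, genome_seq, genes, orthologs, gene_sets, tags, controls, bound_species_b, truth
    )
    if out_dir is not None:
        _write_result(result, out_dir)
    return result


def _write_result(result: SimulationResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for label, lib in sorted(result.tags.items()):
        cio.write_tags(os.path.join(out_dir, f"{label}.tags.bed"), lib)
    for label, lib in sorted(result.controls.items()):
        cio.write_tags(os.path.join(out_dir, f"control_{label}.tags.bed"), lib)
    cio.write_gene_models(os.path.join(out_dir, "genes.tsv"), result.genes)
    cio.write_ortholog_map(os.path.join(out_dir, "orthologs.tsv"), result.orthologs)
    cio.write_fasta(os.path.join(out_dir, "genome.fa"), sorted(result.genome.items()))
    if result.gene_sets:
        cio.write_gene_sets(os.path.join(out_dir, "gene_sets.gmt"), result.gene_sets)
    with open(os.path.join(out_dir, "bound_species_b.txt"), "wt") as fh:
        for gid in sorted(result.bound_species_b):
            fh.write(gid + "\n")
    with open(os.path.join(out_dir, "design.json"), "wt") as fh:
        fh.write(result.design.to_json() + "\n")
    write_truth(result.truth, os.path.join(out_dir, "truth"))


_TRUTH_FILES = ("peaks", "genes", "duplicates", "hotspots")


def write_truth(truth: TruthTable, out_dir: str) -> None:
    """Write the truth tables as TSV; lossless against :func:`read_truth`."""
    os.makedirs(out_dir, exist_ok=True)
    for name in _TRUTH_FILES:
        df: pd.DataFrame = getattr(truth, name)
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)


def read_truth(out_dir: str) -> TruthTable:
    frames = {}
    for name in _TRUTH_FILES:
        path = os.path.join(out_dir, f"{name}.tsv")
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ortholog_id": str})
        if "ortholog_id" in df.columns:
            df["ortholog_id"] = df["ortholog_id"].fillna("")
        frames[name] = df
    return TruthTable(**frames)
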