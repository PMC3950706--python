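"""End-to-end pipeline orchestration with a reproducible run manifest.

Stage order: (simulate or ingest) → duplicate filter → peak calling →
control exclusion → FDR selection → multi-dataset concordance (merge,
normalized counts, fold-tolerance Venn, summits, window export) → gene
annotation (location breakdown, bound genes, metaprofile, TSS count
distributions) → cross-species ortholog Venn → gene-set enrichment.
Every intermediate is written as plain text under the output directory and
the manifest records per-stage record counts and output checksums, so a
rerun with identical config and seed is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

from . import io as cio
from .annotation import (
    bound_genes,
    classify_locations,
    homology_venn,
    tss_count_distribution,
    tss_metaprofile,
)
from .concordance import (
    compute_summit,
    fold_membership,
    merge_peak_sets,
    region_counts,
    summit_windows,
    venn_partition,
)
from .enrichment import fisher_enrichment
from .model import ChipConcordError, ConfigurationError, Interval, ValidationError
from .peaks import CallerParams, call_peaks, exclude_by_control, filter_fdr
from .simulate import SimulationDesign, simulate
from .tags import filter_tags

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(ChipConcordError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(slots=True)
class RunConfig:
    """Declarative configuration of one pipeline run.

    Either ``simulate_design`` generates the inputs under the output
    directory, or explicit input paths are given. All thresholds default to
    the analysis constants: at most 2 reads per start position, censoring
    above 7, >100 control tags for exclusion, FDR ≤ 0.001, TSS windows
    ±1250 bp (±10 kb cross-species), 200 bp elongation, ±150 bp summit
    windows, normalization to 20 million reads, fold tolerances 2, 3, 4.
    """

    output_dir: str = "chipconcord_out"
    seed: int = 0
    simulate_design: Optional[SimulationDesign] = None
    tag_files: dict[str, str] = field(default_factory=dict)
    control_files: dict[str, str] = field(default_factory=dict)
    genes_path: Optional[str] = None
    orthologs_path: Optional[str] = None
    genome_fasta: Optional[str] = None
    gene_sets_path: Optional[str] = None
    bound_species_b_path: Optional[str] = None
    caller_control: Optional[str] = None  # control label the caller tests against

    max_per_start: int = 2
    censor_above: int = 7
    extension: int = 200
    control_threshold: int = 100
    fdr: float = 0.001
    tss_half_window: int = 1250
    cross_species_half_window: int = 10_000
    summit_half_width: int = 150
    reference_reads: int = 20_000_000
    folds: tuple[float, ...] = (2.0, 3.0, 4.0)
    caller_window: int = 300
    caller_step: int = 100
    caller_pvalue: float = 1e-5
    metaprofile_flank: int = 2500
    metaprofile_bin: int = 25

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"fdr cutoff must lie in [0, 1], got {self.fdr}")
        if self.max_per_start < 1 or self.censor_above < self.max_per_start:
            raise ValidationError("need max_per_start >= 1 and censor_above >= max_per_start")
        if any(k < 1 for k in self.folds):
            raise ValidationError("fold tolerances must be >= 1")
        if self.simulate_design is None and not self.tag_files:
            raise ConfigurationError("either simulate_design or tag_files must be given")

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("simulate_design") is not None:
            d["simulate_design"] = SimulationDesign.from_json(json.dumps(d["simulate_design"]))
        if "folds" in d:
            d["folds"] = tuple(d["folds"])
        return cls(**d)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_record(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("output_dir")  # path-independent manifests
    if config.simulate_design is not None:
        d["simulate_design"] = json.loads(config.simulate_design.to_json())
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return (and write) the manifest."""
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {"config": _config_record(config), "stages": []}
    outputs: list[str] = []

    def out_path(name: str) -> str:
        path = os.path.join(config.output_dir, name)
        outputs.append(path)
        return path

    def record(stage: str, **counts) -> None:
        manifest["stages"].append({"stage": stage, "status": "ok", **counts})

    stage = "inputs"
    try:
        if config.simulate_design is not None:
            design = config.simulate_design
            sim = simulate(design, out_dir=os.path.join(config.output_dir, "inputs"))
            tag_sets = sim.tags
            control_sets = sim.controls
            genes = sim.genes
            orthologs = sim.orthologs
            gene_sets = sim.gene_sets
            genome_fasta = os.path.join(config.output_dir, "inputs", "genome.fa")
            bound_b = sim.bound_species_b
        else:
            tag_sets = {lbl: cio.read_tags(p) for lbl, p in sorted(config.tag_files.items())}
            control_sets = {
                lbl: cio.read_tags(p) for lbl, p in sorted(config.control_files.items())
            }
            genes = cio.read_gene_models(config.genes_path) if config.genes_path else []
            orthologs = (
                cio.read_ortholog_map(config.orthologs_path) if config.orthologs_path else []
            )
            gene_sets = (
                cio.read_gene_sets(config.gene_sets_path) if config.gene_sets_path else []
            )
            genome_fasta = config.genome_fasta
            bound_b = set()
            if config.bound_species_b_path:
                with open(config.bound_species_b_path) as fh:
                    bound_b = {line.strip() for line in fh if line.strip()}
        record(
            stage,
            n_datasets=len(tag_sets),
            n_controls=len(control_sets),
            n_genes=len(genes),
            n_ortholog_pairs=len(orthologs),
            n_gene_sets=len(gene_sets),
            tags_per_dataset={lbl: len(t) for lbl, t in sorted(tag_sets.items())},
        )

        stage = "filter_tags"
        filtered: dict[str, list] = {}
        library_sizes: dict[str, int] = {}
        reports = {}
        for lbl, lib in sorted(tag_sets.items()):
            kept, rep = filter_tags(lib, config.max_per_start, config.censor_above)
            filtered[lbl] = kept
            library_sizes[lbl] = rep.n_retained
            reports[lbl] = rep
            cio.write_tags(out_path(f"filtered_{lbl}.tags.bed"), kept)
        filtered_controls: dict[str, list] = {}
        for lbl, lib in sorted(control_sets.items()):
            kept, rep = filter_tags(lib, config.max_per_start, config.censor_above)
            filtered_controls[lbl] = kept
            reports[f"control_{lbl}"] = rep
        with open(out_path("filter_reports.json"), "wt") as fh:
            json.dump(
                {
                    lbl: {
                        "n_input": r.n_input,
                        "n_retained": r.n_retained,
                        "n_duplicates_removed": r.n_duplicates_removed,
                        "n_censored": r.n_censored,
                        "n_censored_positions": len(r.censored_positions),
                    }
                    for lbl, r in sorted(reports.items())
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        record(stage, usable_reads=dict(sorted(library_sizes.items())))

        stage = "call_peaks"
        genome_size = sum(
            dict(config.simulate_design.genome).values()
        ) if config.simulate_design else max(
            t.five_prime for lib in tag_sets.values() for t in lib
        ) + 1
        params = CallerParams(
            genome_size=genome_size,
            window=config.caller_window,
            step=config.caller_step,
            pvalue_cutoff=config.caller_pvalue,
            fdr_cutoff=config.fdr,
        )
        ctrl_label = config.caller_control
        if ctrl_label is None:
            ctrl_label = "igg" if "igg" in filtered_controls else (
                sorted(filtered_controls)[0] if filtered_controls else None
            )
        caller_control = filtered_controls.get(ctrl_label, []) if ctrl_label else []
        called = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for lbl, lib in sorted(filtered.items()):
                called[lbl] = call_peaks(lib, caller_control, params)
        record(stage, n_called={lbl: len(p) for lbl, p in sorted(called.items())})

        stage = "select_peaks"
        selected = {}
        n_excluded = {}
        for lbl, pks in sorted(called.items()):
            kept, excluded = exclude_by_control(
                pks, filtered_controls, config.control_threshold
            )
            sel = filter_fdr(kept, config.fdr)
            selected[lbl] = sel
            n_excluded[lbl] = len(excluded)
            cio.write_peaks(out_path(f"peaks_{lbl}.tsv"), sel)
        record(
            stage,
            n_excluded_by_control=dict(sorted(n_excluded.items())),
            n_selected={lbl: len(p) for lbl, p in sorted(selected.items())},
        )

        stage = "concordance"
        regions = merge_peak_sets(selected)
        region_counts(regions, filtered, library_sizes, config.reference_reads)
        venns = {}
        for k in config.folds:
            for r in regions:
                fold_membership(r, k)
            venns[k] = venn_partition(regions, k)
        with open(out_path("merged_regions.tsv"), "wt") as fh:
            labels = sorted(filtered)
            fh.write(
                "# chrom\tstart\tend\tcontributors\t"
                + "\t".join(f"count_{l}" for l in labels)
                + "\t"
                + "\t".join(f"members_k{k:g}" for k in config.folds)
                + "\n# counts normalized to "
                f"{config.reference_reads} reads; members within k-fold of max\n"
            )
            for r in regions:
                fh.write(
                    f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                    + ",".join(sorted(r.contributing_datasets))
                    + "\t"
                    + "\t".join(f"{r.counts[l]:.4f}" for l in labels)
                    + "\t"
                    + "\t".join(
                        ",".join(sorted(r.membership[k])) for k in config.folds
                    )
                    + "\n"
                )
        with open(out_path("venn_cells.tsv"), "wt") as fh:
            fh.write("# k\tcell\tn_regions\n")
            for k, vp in sorted(venns.items()):
                for cell, n in sorted(vp.cells.items(), key=lambda kv: sorted(kv[0])):
                    fh.write(f"{k:g}\t{','.join(sorted(cell))}\t{n}\n")
        record(
            stage,
            n_merged_regions=len(regions),
            all_datasets_cell={
                f"k={k:g}": venns[k].cell(sorted(filtered)) for k in config.folds
            },
        )

        stage = "summits"
        pooled = [t for lbl in sorted(filtered) for t in filtered[lbl]]
        summits = [
            compute_summit(r.interval, pooled, config.extension) for r in regions
        ]
        with open(out_path("summits.bed"), "wt") as fh:
            for i, s in enumerate(summits):
                fh.write(
                    f"{s.region.chrom}\t{s.position}\t{s.position + 1}"
                    f"\tsummit{i}\t{s.height}\t.\n"
                )
        windows = summit_windows(summits, config.summit_half_width)
        if genome_fasta:
            seqs = cio.extract_sequences(genome_fasta, windows)
            cio.write_fasta(out_path("summit_windows.fa"), seqs)
        record(stage, n_summits=len(summits))

        stage = "annotation"
        primary = sorted(selected)[0] if selected else None
        a_bound: set[str] = set()
        if primary is not None and genes:
            pks = selected[primary]
            categories, breakdown = classify_locations(pks, genes, config.tss_half_window)
            a_bound = bound_genes(pks, genes, config.tss_half_window)
            with open(out_path("location_breakdown.tsv"), "wt") as fh:
                f = breakdown.fractions
                fh.write("# category\tn_peaks\tfraction\n")
                fh.write(f"tss_proximal\t{breakdown.n_tss_proximal}\t{f[0]:.6f}\n")
                fh.write(f"intragenic\t{breakdown.n_intragenic}\t{f[1]:.6f}\n")
                fh.write(f"intergenic\t{breakdown.n_intergenic}\t{f[2]:.6f}\n")
            with open(out_path("bound_genes.txt"), "wt") as fh:
                for gid in sorted(a_bound):
                    fh.write(gid + "\n")
            profile = tss_metaprofile(
                filtered[primary],
                genes,
                library_sizes[primary],
                config.metaprofile_flank,
                config.metaprofile_bin,
                config.extension,
                config.reference_reads,
            )
            with open(out_path("tss_metaprofile.tsv"), "wt") as fh:
                fh.write(
                    "# offset_bin_start\tmean_coverage\n"
                    f"# averaged over {profile.n_tss} TSSs, normalized to "
                    f"{config.reference_reads} reads (library {profile.library_size})\n"
                )
                for off, v in zip(profile.bin_offsets, profile.values):
                    fh.write(f"{off}\t{v:.6f}\n")
            dists = tss_count_distribution(
                filtered[primary],
                {"all": [g.gene_id for g in genes], "bound": sorted(a_bound)},
                genes,
                config.tss_half_window,
            )
            for lbl, df in sorted(dists.items()):
                df.to_csv(out_path(f"tss_counts_{lbl}.tsv"), sep="\t", index=False)
            record(
                stage,
                dataset=primary,
                breakdown={
                    "tss_proximal": breakdown.n_tss_proximal,
                    "intragenic": breakdown.n_intragenic,
                    "intergenic": breakdown.n_intergenic,
                },
                n_bound_genes=len(a_bound),
            )
        else:
            record(stage, skipped="no genes or no peak sets")

        stage = "homology"
        if orthologs and primary is not None and genes:
            bound_a_10k = bound_genes(
                selected[primary], genes, config.cross_species_half_window
            )
            hv = homology_venn(bound_a_10k, bound_b, orthologs)
            with open(out_path("homology_venn.tsv"), "wt") as fh:
                fh.write("# cell\tn_genes\n")
                fh.write(f"both\t{hv.n_both}\n")
                fh.write(f"a_only\t{hv.n_a_only}\n")
                fh.write(f"b_only\t{hv.n_b_only}\n")
                fh.write(f"a_specific\t{hv.n_a_specific}\n")
                fh.write(f"b_specific\t{hv.n_b_specific}\n")
            record(stage, both=hv.n_both, a_only=hv.n_a_only, b_only=hv.n_b_only)
        else:
            record(stage, skipped="no ortholog map")

        stage = "enrichment"
        if gene_sets and a_bound:
            universe = set().union(*(s.members for s in gene_sets))
            universe &= {g.gene_id for g in genes}
            bound_in_universe = a_bound & universe
            results = fisher_enrichment(bound_in_universe, universe, gene_sets)
            with open(out_path("enrichment.tsv"), "wt") as fh:
                fh.write("# set\tk_overlap\tK_set\tn_bound\tN_universe\tp\tq\n")
                for r in results:
                    fh.write(
                        f"{r.set_name}\t{r.k_overlap}\t{r.K_set}\t{r.n_bound}"
                        f"\t{r.N_universe}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
                    )
            record(
                stage,
                n_sets=len(results),
                min_q=min(r.q_value for r in results) if results else None,
            )
        else:
            record(stage, skipped="no gene sets or no bound genes")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # input files written by the simulator are part of the reproducibility contract
    input_dir = os.path.join(config.output_dir, "inputs")
    if os.path.isdir(input_dir):
        for root, _dirs, files in os.walk(input_dir):
            for f in sorted(files):
                if not f.endswith(".fai"):
                    outputs.append(os.path.join(root, f))
    manifest["checksums"] = {
        os.path.relpath(p, config.output_dir): _sha256(p) for p in sorted(set(outputs))
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
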