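"""Readers and writers for every file format the pipeline touches.

Formats: BED6 for tags, narrowPeak or a documented TSV dialect for peaks,
TSV or minimal GTF for gene models, two-column TSV for ortholog maps, GMT
for gene sets, FASTA for genome sequence and summit-window export. All TSV
outputs carry a ``#``-commented header naming columns and conventions.

Every reader/writer pair is a bijection on valid records (round-trip
identity); this is property-tested at the module boundary.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Sequence

import pyfaidx

from .model import (
    ConfigurationError,
    GeneModel,
    GeneSet,
    Interval,
    OrthologPair,
    ParseError,
    Peak,
    Tag,
    ValidationError,
)

__all__ = [
    "read_tags",
    "write_tags",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gene_sets",
    "write_gene_sets",
    "extract_sequences",
    "read_fasta",
    "write_fasta",
]

# Peak TSV dialect columns, in order. fdr is a fraction in [0, 1] unless a
# percent-scale column is declared explicitly on read.
PEAK_TSV_COLUMNS = ("chrom", "start", "end", "score", "fdr", "tag_count")


def _data_lines(path: str) -> Iterable[tuple[int, str]]:
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track "):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# tags (BED6)
# ---------------------------------------------------------------------------

def read_tags(path: str, dialect: str = "bed6") -> list[Tag]:
    """Read aligned reads from BED6 and reduce each to a Tag.

    The 5′ end is the BED ``start`` for + reads and ``end − 1`` for − reads.
    Record order is preserved.
    """
    if dialect != "bed6":
        raise ConfigurationError(f"unknown tag dialect {dialect!r}")
    tags: list[Tag] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(
                f"BED6 record needs 6 fields, got {len(fields)}", path, lineno
            )
        chrom, start_s, end_s, _name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", path, lineno)
        if strand not in ("+", "-"):
            raise ValidationError(
                f"unknown strand symbol {strand!r} ({path}, line {lineno})"
            )
        if end <= start:
            raise ParseError(f"empty interval [{start}, {end})", path, lineno)
        five_prime = start if strand == "+" else end - 1
        tags.append(Tag(chrom, five_prime, strand))
    return tags


def write_tags(path: str, tags: Sequence[Tag], read_length: int = 36) -> None:
    """Write tags as BED6, reconstructing a fixed-length read footprint.

    + tags span [five_prime, five_prime + read_length); − tags span
    [five_prime − read_length + 1, five_prime + 1), clipped at 0, so
    ``read_tags`` recovers the identical 5′ coordinates.
    """
    with open(path, "wt") as fh:
        for i, t in enumerate(tags):
            if t.strand == "+":
                start, end = t.five_prime, t.five_prime + read_length
            else:
                start, end = max(0, t.five_prime - read_length + 1), t.five_prime + 1
            fh.write(f"{t.chrom}\t{start}\t{end}\ttag{i}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# peaks (narrowPeak / TSV dialect)
# ---------------------------------------------------------------------------

def read_peaks(
    path: str,
    dialect: str = "tsv",
    dataset_id: str = "",
    fdr_scale: str | None = None,
) -> list[Peak]:
    """Read called peaks.

    dialect ``narrowPeak``: the ENCODE 10-column format; the qValue column
    holds the FDR on a −log10 scale (``fdr = 10**(−q)``) unless another
    ``fdr_scale`` is declared. dialect ``tsv``: the documented columns
    chrom, start, end, score, fdr, tag_count with fdr as a fraction; a
    percent-scale column must be declared via ``fdr_scale='percent'`` and is
    divided by 100. Intervals are 0-based half-open in both dialects.
    """
    if dialect not in ("narrowPeak", "tsv"):
        raise ConfigurationError(f"unknown peak dialect {dialect!r}")
    if fdr_scale is None:
        fdr_scale = "neglog10" if dialect == "narrowPeak" else "fraction"
    if fdr_scale not in ("fraction", "percent", "neglog10"):
        raise ConfigurationError(f"unknown fdr_scale {fdr_scale!r}")

    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        try:
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise ParseError("narrowPeak record needs 10 fields", path, lineno)
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                score = float(fields[6])  # signalValue carries the caller score
                raw_fdr = float(fields[8])
                tag_count = None
            else:
                if len(fields) < 5:
                    raise ConfigurationError(
                        f"peak TSV needs columns {PEAK_TSV_COLUMNS} "
                        f"(FDR column missing? {path}, line {lineno})"
                    )
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                score = float(fields[3])
                raw_fdr = float(fields[4])
                tag_count = (
                    int(fields[5]) if len(fields) > 5 and fields[5] not in ("", ".") else None
                )
        except ParseError:
            raise
        except ConfigurationError:
            raise
        except ValueError as exc:
            raise ParseError(f"malformed peak record ({exc})", path, lineno)

        if fdr_scale == "neglog10":
            fdr = 10.0 ** (-raw_fdr)
        elif fdr_scale == "percent":
            fdr = raw_fdr / 100.0
        else:
            fdr = raw_fdr
        peaks.append(
            Peak(Interval(chrom, start, end), score, min(fdr, 1.0), tag_count, dataset_id)
        )
    return peaks


def write_peaks(path: str, peaks: Sequence[Peak], dialect: str = "tsv") -> None:
    """Write peaks in the documented TSV dialect or as narrowPeak."""
    if dialect not in ("narrowPeak", "tsv"):
        raise ConfigurationError(f"unknown peak dialect {dialect!r}")
    with open(path, "wt") as fh:
        if dialect == "tsv":
            fh.write(
                "# chrom\tstart\tend\tscore\tfdr\ttag_count\n"
                "# 0-based half-open intervals; fdr is a fraction in [0,1]\n"
            )
            for p in peaks:
                tc = "." if p.tag_count is None else str(p.tag_count)
                fdr = "." if p.fdr is None else repr(p.fdr)
                fh.write(
                    f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                    f"\t{p.score!r}\t{fdr}\t{tc}\n"
                )
        else:
            for i, p in enumerate(peaks):
                fdr = 1.0 if p.fdr is None else p.fdr
                neglog_q = 999.0 if fdr <= 0 else -math.log10(fdr)
                fh.write(
                    f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                    f"\tpeak{i}\t0\t.\t{p.score!r}\t-1\t{neglog_q!r}\t-1\n"
                )


# ---------------------------------------------------------------------------
# gene models (TSV / minimal GTF)
# ---------------------------------------------------------------------------

def read_gene_models(path: str, dialect: str | None = None) -> list[GeneModel]:
    """Read gene models from a 5-column TSV or a minimal GTF.

    TSV columns: gene_id, chrom, strand, start, end (0-based half-open).
    GTF ``gene`` features use 1-based inclusive coordinates and are
    converted; gene_id is taken from the ``gene_id "..."`` attribute.
    Duplicate gene identifiers are rejected.
    """
    if dialect is None:
        dialect = "gtf" if path.endswith((".gtf", ".gff")) else "tsv"
    if dialect not in ("tsv", "gtf"):
        raise ConfigurationError(f"unknown gene-model dialect {dialect!r}")

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        try:
            if dialect == "tsv":
                gene_id, chrom, strand, start_s, end_s = fields[:5]
                start, end = int(start_s), int(end_s)
            else:
                if len(fields) < 9:
                    raise ParseError("GTF record needs 9 fields", path, lineno)
                if fields[2] != "gene":
                    continue
                chrom, strand = fields[0], fields[6]
                start, end = int(fields[3]) - 1, int(fields[4])  # 1-based inclusive -> half-open
                gene_id = _gtf_attribute(fields[8], "gene_id")
                if gene_id is None:
                    raise ParseError("gene_id attribute missing", path, lineno)
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"malformed gene record ({exc})", path, lineno)
        if gene_id in seen:
            raise ValidationError(f"duplicate gene_id {gene_id!r} ({path}, line {lineno})")
        seen.add(gene_id)
        genes.append(GeneModel(gene_id, Interval(chrom, start, end), strand))
    return genes


def _gtf_attribute(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


def write_gene_models(path: str, genes: Sequence[GeneModel]) -> None:
    with open(path, "wt") as fh:
        fh.write("# gene_id\tchrom\tstrand\tstart\tend\n# 0-based half-open gene bodies\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}"
                f"\t{g.interval.start}\t{g.interval.end}\n"
            )


# ---------------------------------------------------------------------------
# ortholog map / gene sets
# ---------------------------------------------------------------------------

def read_ortholog_map(path: str) -> list[OrthologPair]:
    """Read a two-column TSV of one-to-one ortholog pairs.

    A gene appearing in more than one pair violates the one-to-one,
    bidirectional contract and is rejected.
    """
    pairs: list[OrthologPair] = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("ortholog map needs two columns", path, lineno)
        a, b = fields[0], fields[1]
        if a in seen_a or b in seen_b:
            raise ValidationError(
                f"gene in more than one ortholog pair ({a!r}/{b!r}; {path}, line {lineno})"
            )
        seen_a.add(a)
        seen_b.add(b)
        pairs.append(OrthologPair(a, b))
    return pairs


def write_ortholog_map(path: str, pairs: Sequence[OrthologPair]) -> None:
    with open(path, "wt") as fh:
        fh.write("# gene_a\tgene_b\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\n")


def read_gene_sets(path: str) -> list[GeneSet]:
    """Read GMT gene sets (name, description, members...); members deduplicated."""
    sets: list[GeneSet] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError("GMT record needs name, description, >=1 member", path, lineno)
        name = fields[0]
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ParseError(f"gene set {name!r} has no members", path, lineno)
        sets.append(GeneSet(name, members))
    return sets


def write_gene_sets(path: str, sets: Sequence[GeneSet]) -> None:
    with open(path, "wt") as fh:
        for s in sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def extract_sequences(
    fasta: "str | pyfaidx.Fasta", intervals: Iterable[Interval]
) -> list[tuple[str, str]]:
    """Extract one sequence per interval from an indexed genome FASTA.

    Intervals are clipped at chromosome bounds; the record id
    ``chrom:start-end`` reports the clipped coordinates actually extracted.
    A chromosome absent from the FASTA raises ``LookupError``.
    """
    fa = pyfaidx.Fasta(fasta) if isinstance(fasta, str) else fasta
    records: list[tuple[str, str]] = []
    for iv in intervals:
        if iv.chrom not in fa:
            raise LookupError(f"chromosome {iv.chrom!r} absent from FASTA")
        chrom_len = len(fa[iv.chrom])
        start = max(0, iv.start)
        end = min(chrom_len, iv.end)
        if end <= start:
            raise ValidationError(
                f"interval [{iv.start}, {iv.end}) lies outside {iv.chrom} (length {chrom_len})"
            )
        seq = str(fa[iv.chrom][start:end])
        records.append((f"{iv.chrom}:{start}-{end}", seq))
    return records


def read_fasta(path: str) -> dict[str, str]:
    """Read a whole FASTA into a name → sequence mapping (small genomes only)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    # refresh any stale .fai so later pyfaidx opens see the new content
    fai = path + ".fai"
    if os.path.exists(fai):
        os.remove(fai)
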