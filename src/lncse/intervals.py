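"""Genomic interval arithmetic and annotation handling.

All coordinates are 0-based, half-open (BED convention). Conversion to/from
1-based coordinates happens only at the GFF3 boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "Gene",
    "AnnotationSet",
    "tss_of",
    "promoter_window",
    "overlaps",
    "count_overlapping",
    "intersect_any",
    "subtract_blacklist",
    "union_length",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_annotation",
    "write_annotation",
    "read_gff3",
    "read_go_map",
    "write_go_map",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A signal-bearing region, e.g. a MACS2-style H3K27ac peak.

    ``signal`` is the mean read density over the peak (arbitrary units);
    ``qvalue`` is the peak caller's FDR-adjusted significance.
    """

    interval: GenomicInterval
    name: str = "."
    signal: float = 0.0
    qvalue: float = 1.0

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("peak signal must be >= 0")
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError("qvalue must lie in [0, 1]")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    name: str
    biotype: str  # "protein_coding" | "lncRNA"
    interval: GenomicInterval


def tss_of(gene: Gene) -> int:
    """Transcription start site of a stranded gene record.

    For plus-strand genes the TSS is ``start``; for minus-strand genes it is
    ``end - 1`` (the last covered base in 0-based coordinates). An unstranded
    record has no TSS.
    """
    strand = gene.interval.strand
    if strand == "+":
        return gene.interval.start
    if strand == "-":
        return gene.interval.end - 1
    raise ValueError(f"TSS undefined for unstranded gene {gene.gene_id!r}")


def promoter_window(gene: Gene, halfwidth: int = 1000) -> GenomicInterval:
    """``[TSS - halfwidth, TSS + halfwidth + 1)``, clipped at zero."""
    tss = tss_of(gene)
    return GenomicInterval(
        gene.interval.chrom, max(0, tss - halfwidth), tss + halfwidth + 1
    )


@dataclass
class AnnotationSet:
    """Gene records plus a GO term -> gene-id map."""

    genes: list[Gene]
    go_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self.genes)

    def by_biotype(self, biotype: str) -> list[Gene]:
        return [g for g in self.genes if g.biotype == biotype]

    @property
    def lncrnas(self) -> list[Gene]:
        return self.by_biotype("lncRNA")

    @property
    def coding_genes(self) -> list[Gene]:
        return self.by_biotype("protein_coding")


# ---------------------------------------------------------------------------
# set-level interval operations


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: adjacency ([0,10) vs [10,20)) is not overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def intersect_any(query: GenomicInterval, refs: Iterable[GenomicInterval]) -> bool:
    return any(overlaps(query, r) for r in refs)


def count_overlapping(
    queries: Sequence[GenomicInterval], refs: Sequence[GenomicInterval]
) -> int:
    """Number of query intervals overlapping at least one reference interval."""
    return sum(1 for q in queries if intersect_any(q, refs))


def subtract_blacklist(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> list[Peak]:
    """Remove every peak overlapping >= 1 bp of the blacklist (whole-peak removal)."""
    return [p for p in peaks if not intersect_any(p.interval, blacklist)]


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of intervals (per chromosome)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


# ---------------------------------------------------------------------------
# readers / writers


def write_bed_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6+1: chrom, start, end, name, signal, strand, qvalue."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in peaks:
            iv = p.interval
            w.writerow(
                [iv.chrom, iv.start, iv.end, p.name, repr(p.signal), iv.strand, repr(p.qvalue)]
            )


def read_bed_peaks(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            signal = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 else "."
            qvalue = float(f[6]) if len(f) > 6 else 1.0
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), name, signal, qvalue)
            )
    return peaks


def write_bed_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for iv in intervals:
            w.writerow([iv.chrom, iv.start, iv.end])


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_annotation(ann: AnnotationSet, path: str | Path) -> None:
    """TSV: gene_id, name, biotype, chrom, start, end, strand (with header)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "name", "biotype", "chrom", "start", "end", "strand"])
        for g in ann.genes:
            iv = g.interval
            w.writerow([g.gene_id, g.name, g.biotype, iv.chrom, iv.start, iv.end, iv.strand])


def read_annotation(path: str | Path, go_path: str | Path | None = None) -> AnnotationSet:
    genes = []
    with open(path) as fh:
        rd = csv.reader(fh, delimiter="\t")
        header = next(rd)
        idx = {c: i for i, c in enumerate(header)}
        for row in rd:
            genes.append(
                Gene(
                    row[idx["gene_id"]],
                    row[idx["name"]],
                    row[idx["biotype"]],
                    GenomicInterval(
                        row[idx["chrom"]],
                        int(row[idx["start"]]),
                        int(row[idx["end"]]),
                        row[idx["strand"]],
                    ),
                )
            )
    go_map = read_go_map(go_path) if go_path is not None else {}
    return AnnotationSet(genes, go_map)


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV ``term<TAB>gene_id`` -> {term: set of gene ids}."""
    go: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            term, gene_id = line.rstrip("\n").split("\t")[:2]
            if term == "term" and gene_id == "gene_id":
                continue  # tolerate a header
            go.setdefault(term, set()).add(gene_id)
    return go


def write_go_map(go_map: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term", "gene_id"])
        for term in sorted(go_map):
            for gid in sorted(go_map[term]):
                w.writerow([term, gid])


def read_gff3(path: str | Path) -> AnnotationSet:
    """Minimal GFF3 gene reader.

    Keeps ``gene`` features; tolerates missing attributes other than a gene
    identifier (``gene_id`` or ``ID``). GFF3 is 1-based inclusive; coordinates
    are converted to 0-based half-open here.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = {}
            for item in f[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            gene_id = attrs.get("gene_id") or attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"GFF3 gene feature without gene_id/ID: {line!r}")
            genes.append(
                Gene(
                    gene_id,
                    attrs.get("Name", gene_id),
                    attrs.get("biotype", attrs.get("gene_type", ".")),
                    GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]),
                )
            )
    return AnnotationSet(genes)
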