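"""Union-exon read counting.

Assigns aligned reads to genes by overlap with the union of each gene's
exons (htseq-count "union" mode semantics): a read overlapping the exon
union of exactly one gene counts for that gene; a read overlapping the
unions of two or more genes is ambiguous and counts for none; a read
overlapping no union is no-feature.

Coordinates are 0-based half-open internally. GTF is read and written as
1-based inclusive with conversion at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AlignedRead",
    "CountMatrix",
    "CountingStats",
    "union_exon_model",
    "count_reads",
    "read_gtf_exons",
    "write_gtf",
    "read_bed_reads",
    "write_bed_reads",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignedRead:
    """A single aligned read reduced to one genomic interval (no CIGAR)."""

    read_id: str
    interval: GenomicInterval


class GeneModel:
    """Per-gene disjoint sorted exon-union intervals, each gene on one chromosome."""

    def __init__(self, exon_union: Mapping[str, Sequence[GenomicInterval]]):
        self._genes: dict[str, tuple[GenomicInterval, ...]] = {}
        for gene, ivs in exon_union.items():
            ivs = tuple(sorted(ivs, key=lambda iv: (iv.start, iv.end)))
            if not ivs:
                raise ValueError(f"gene {gene} has no exons")
            chroms = {iv.chrom for iv in ivs}
            if len(chroms) > 1:
                raise ValueError(
                    f"gene {gene} has exons on multiple chromosomes: {sorted(chroms)}"
                )
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"gene {gene} exon-union intervals overlap")
            self._genes[gene] = ivs

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def exons(self, gene: str) -> tuple[GenomicInterval, ...]:
        return self._genes[gene]

    def union_length(self, gene: str) -> int:
        return sum(len(iv) for iv in self._genes[gene])

    def items(self):
        return self._genes.items()


class CountMatrix:
    """Non-negative integer gene x sample counts with a condition label per sample."""

    def __init__(self, counts: pd.DataFrame, conditions: Mapping[str, str] | pd.Series):
        counts = counts.copy()
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("gene and sample identifiers must be unique")
        values = counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype("int64")
        conditions = pd.Series(dict(conditions) if not isinstance(conditions, pd.Series) else conditions)
        missing = [s for s in counts.columns if s not in conditions.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.conditions = conditions.reindex(counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    def to_tsv(self, counts_path, conditions_path=None) -> None:
        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        if conditions_path is not None:
            self.conditions.rename("condition").rename_axis("sample").to_csv(
                conditions_path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, counts_path, conditions_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_path, sep="\t", index_col=0)["condition"]
        return cls(counts, cond)


@dataclass
class CountingStats:
    """Per-sample read-fate tallies; assigned + no_feature + ambiguous == total."""

    assigned: int = 0
    no_feature: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.no_feature + self.ambiguous


def union_exon_model(
    exon_records: Iterable[tuple[str, GenomicInterval]]
) -> GeneModel:
    """Merge each gene's exons into a minimal disjoint sorted interval set.

    Raises ValueError naming the gene if its exons span multiple chromosomes.
    """
    per_gene: dict[str, list[GenomicInterval]] = {}
    for gene, iv in exon_records:
        per_gene.setdefault(gene, []).append(iv)
    if not per_gene:
        raise ValueError("no exon records supplied")
    union: dict[str, list[GenomicInterval]] = {}
    for gene, ivs in per_gene.items():
        chroms = {iv.chrom for iv in ivs}
        if len(chroms) > 1:
            raise ValueError(
                f"gene {gene} has exons on multiple chromosomes: {sorted(chroms)}"
            )
        strand = ivs[0].strand
        merged: list[list[int]] = []
        for iv in sorted(ivs, key=lambda iv: (iv.start, iv.end)):
            if merged and iv.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        union[gene] = [
            GenomicInterval(ivs[0].chrom, s, e, strand) for s, e in merged
        ]
    return GeneModel(union)


def _build_trees(model: GeneModel, stranded: bool) -> dict:
    """One IntervalTree per chromosome (or per chromosome+strand) with gene payloads."""
    trees: dict = {}
    for gene, ivs in model.items():
        for iv in ivs:
            key = (iv.chrom, iv.strand) if stranded else iv.chrom
            trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, gene)
    return trees


def count_reads(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    model: GeneModel,
    min_overlap: int = 1,
    mode: str = "union",
    stranded: bool = False,
    conditions: Mapping[str, str] | None = None,
) -> tuple[CountMatrix, dict[str, CountingStats]]:
    """Accumulate per-gene read counts under the union-overlap rule.

    Each read is assigned to exactly one of: a single gene (>= ``min_overlap``
    bases intersect that gene's exon union and no other gene's), no_feature,
    or ambiguous (qualifying overlap with two or more genes).
    """
    if mode != "union":
        raise ValueError(f"unknown counting mode {mode!r}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = _build_trees(model, stranded)
    genes = model.gene_ids
    counts = pd.DataFrame(0, index=genes, columns=list(reads_by_sample), dtype="int64")
    stats: dict[str, CountingStats] = {}
    for sample, reads in reads_by_sample.items():
        st = CountingStats()
        for read in reads:
            iv = read.interval
            key = (iv.chrom, iv.strand) if stranded else iv.chrom
            tree = trees.get(key)
            overlap_by_gene: dict[str, int] = {}
            if tree is not None:
                for hit in tree.overlap(iv.start, iv.end):
                    ob = min(iv.end, hit.end) - max(iv.start, hit.begin)
                    overlap_by_gene[hit.data] = overlap_by_gene.get(hit.data, 0) + ob
            qualifying = [g for g, ob in overlap_by_gene.items() if ob >= min_overlap]
            if len(qualifying) == 1:
                counts.loc[qualifying[0], sample] += 1
                st.assigned += 1
            elif len(qualifying) == 0:
                st.no_feature += 1
            else:
                st.ambiguous += 1
        stats[sample] = st
    if conditions is None:
        conditions = {s: "unassigned" for s in reads_by_sample}
    return CountMatrix(counts, conditions), stats


# --- GTF / BED boundary formats -------------------------------------------
# GTF exon features carry 1-based inclusive coordinates and a gene_id
# attribute; conversion to the internal 0-based half-open convention happens
# here and nowhere else.

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gtf_exons(path) -> list[tuple[str, GenomicInterval]]:
    """Read (gene_id, exon interval) records from a GTF file."""
    records: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _source, _feature, start, end, _score, strand, _frame, attrs = fields[:9]
            m = _GENE_ID_RE.search(attrs)
            if not m:
                raise ValueError(f"GTF exon line without gene_id attribute: {line!r}")
            records.append(
                (m.group(1), GenomicInterval(chrom, int(start) - 1, int(end), strand))
            )
    if not records:
        raise ValueError(f"no exon records found in {path}")
    return records


def write_gtf(model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        for gene, ivs in sorted(model.items()):
            for iv in ivs:
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            "crossde",
                            "exon",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            f'gene_id "{gene}";',
                        ]
                    )
                    + "\n"
                )


def read_bed_reads(path) -> list[AlignedRead]:
    """Read aligned reads from a BED6 file (chrom, start, end, name, score, strand)."""
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            reads.append(AlignedRead(name, GenomicInterval(chrom, int(start), int(end), strand)))
    return reads


def write_bed_reads(reads: Sequence[AlignedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            iv = read.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{read.read_id}\t0\t{iv.strand}\n")
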