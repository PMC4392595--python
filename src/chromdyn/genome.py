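"""Genome and gene-model containers plus their plain-text round-trips.

Coordinates are 0-based half-open throughout (BED convention). A gene model
is deliberately minimal — chrom, strand, TSS and a sorted list of
non-overlapping exons — because every downstream computation (promoter
windows, RPKM exonic lengths, genomic-context annotation) needs only those.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidParameterError, ValidationError


@dataclass(frozen=True)
class Genome:
    """An ordered set of named chromosomes with sizes in bp."""

    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_sizes):
            raise InvalidParameterError("names and sizes must have equal length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise InvalidParameterError("chromosome names must be unique")
        if any(s <= 0 for s in self.chrom_sizes):
            raise InvalidParameterError("chromosome sizes must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_sizes))

    @property
    def total_size(self) -> int:
        return int(sum(self.chrom_sizes))

    def size_of(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[self.chrom_names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def to_chrom_sizes(self, path: str | Path) -> None:
        """Write a two-column chrom.sizes TSV."""
        with open(path, "w") as fh:
            for name, size in zip(self.chrom_names, self.chrom_sizes):
                fh.write(f"{name}\t{size}\n")

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "Genome":
        names: list[str] = []
        sizes: list[int] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValidationError(f"{path}:{lineno}: expected 2 columns")
                try:
                    size = int(parts[1])
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: size {parts[1]!r} is not an integer"
                    ) from None
                names.append(parts[0])
                sizes.append(size)
        return cls(tuple(names), tuple(sizes))


@dataclass
class GeneModel:
    """A gene with strand-aware TSS and non-overlapping sorted exons.

    ``baseline_mean`` is the expected RNA-seq read count per million
    sequenced reads when the gene is in its reference (day 2) state.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    baseline_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
        for s, e in ex:
            if not 0 <= s < e:
                raise ValidationError(f"gene {self.gene_id}: bad exon [{s},{e})")
        self.exons = ex
        if ex:
            expected = ex[0][0] if self.strand == "+" else ex[-1][1]
            if self.tss != expected:
                raise ValidationError(
                    f"gene {self.gene_id}: TSS {self.tss} does not match the "
                    f"5'-most exon boundary {expected} on strand {self.strand}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    """BED6-like gene table with an exon block column (start-end;start-end)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            exons = ";".join(f"{a}-{b}" for a, b in g.exons)
            fh.write(
                f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t{g.baseline_mean:.6g}\t"
                f"{g.strand}\t{g.tss}\t{exons}\n"
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValidationError(f"{path}:{lineno}: expected 8 columns")
            try:
                exons = [
                    (int(a), int(b))
                    for a, b in (blk.split("-") for blk in parts[7].split(";"))
                ]
                genes.append(
                    GeneModel(
                        gene_id=parts[3],
                        chrom=parts[0],
                        strand=parts[5],
                        tss=int(parts[6]),
                        exons=exons,
                        baseline_mean=float(parts[4]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return genes
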