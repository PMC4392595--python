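"""Genomic interval algebra: the shared currency of peaks, enhancers, domains.

All coordinates are 0-based half-open ``[start, end)``. Overlap means
sharing at least 1 bp unless stated otherwise. Distances to a TSS are
measured from the nearest interval edge (0 if the TSS falls inside the
interval); genomic-context annotation uses the interval midpoint.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    InvalidParameterError,
    PlacementError,
    ValidationError,
)
from .genome import GeneModel, Genome

PROMOTER_WINDOW = 2500  # bp each side of the TSS


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def as_tuple(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """An ordered collection of intervals, optionally bound to a genome."""

    def __init__(
        self,
        intervals: Sequence[GenomicInterval] = (),
        genome: Genome | None = None,
        validate_bounds: bool = True,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome = genome
        if genome is not None and validate_bounds:
            for iv in self.intervals:
                if iv.chrom not in genome:
                    raise ValidationError(f"interval on unknown chromosome {iv.chrom}")
                if iv.end > genome.size_of(iv.chrom):
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome size {genome.size_of(iv.chrom)}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "IntervalSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(ivs, self.genome, validate_bounds=False)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for lst in out.values():
            lst.sort(key=lambda iv: (iv.start, iv.end))
        return out

    # ---- plain-text IO ---------------------------------------------------
    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fields = [iv.chrom, str(iv.start), str(iv.end)]
                if iv.name is not None or iv.score is not None or iv.strand is not None:
                    fields += [
                        iv.name if iv.name is not None else ".",
                        f"{iv.score:.6g}" if iv.score is not None else "0",
                        iv.strand if iv.strand is not None else ".",
                    ]
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def from_bed(cls, path: str | Path, genome: Genome | None = None) -> "IntervalSet":
        ivs: list[GenomicInterval] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(f"{path}:{lineno}: expected >=3 BED columns")
                try:
                    iv = GenomicInterval(
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        name=parts[3] if len(parts) > 3 and parts[3] != "." else None,
                        score=float(parts[4]) if len(parts) > 4 else None,
                        strand=parts[5] if len(parts) > 5 and parts[5] != "." else None,
                    )
                except (ValueError, ValidationError) as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from None
                ivs.append(iv)
        return cls(ivs, genome)


def _require_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ConsistencyError("interval sets are bound to different genomes")


def merge_intervals(iset: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge intervals closer than or equal to ``gap`` bp apart.

    Output intervals are pairwise separated by more than ``gap`` and cover
    the union of the input (plus bridged gaps).
    """
    if gap < 0:
        raise InvalidParameterError("gap must be non-negative")
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(iset.by_chrom().items()):
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e <= gap:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalSet(merged, iset.genome, validate_bounds=False)


def overlaps_any(
    query: IntervalSet, reference: IntervalSet
) -> tuple[np.ndarray, float]:
    """Flag each query interval that shares >=1 bp with any reference interval.

    Returns the per-query boolean flags and the flagged fraction of the
    query set (0.0 for an empty query).
    """
    _require_same_genome(query, reference)
    ref = reference.by_chrom()
    flags = np.zeros(len(query), dtype=bool)
    starts = {c: np.array([iv.start for iv in lst]) for c, lst in ref.items()}
    # max-end prefix makes the sweep robust to contained intervals
    maxends = {
        c: np.maximum.accumulate([iv.end for iv in lst]) for c, lst in ref.items()
    }
    for i, iv in enumerate(query):
        if iv.chrom not in ref:
            continue
        s = starts[iv.chrom]
        j = int(np.searchsorted(s, iv.end, side="left"))  # refs with start < end
        if j == 0:
            continue
        flags[i] = maxends[iv.chrom][j - 1] > iv.start
    frac = float(flags.mean()) if len(query) else 0.0
    return flags, frac


def distance_to_nearest_tss(
    intervals: IntervalSet, genes: Sequence[GeneModel]
) -> list[tuple[int, str]]:
    """Edge-to-TSS distance (bp) and nearest gene per interval.

    Distance is 0 when a TSS lies inside the interval. Ties are broken by
    the lexicographically smaller gene_id, deterministically.
    """
    if not genes:
        raise InvalidParameterError("gene list must be non-empty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for lst in by_chrom.values():
        lst.sort()
    out: list[tuple[int, str]] = []
    big = max((g.tss for g in genes), default=0) + 10**12
    for iv in intervals:
        cands = by_chrom.get(iv.chrom)
        if cands is None:
            out.append((big, ""))
            continue
        tss_arr = np.array([t for t, _ in cands])
        # gap in bp between the TSS and the nearest interval edge;
        # 0 when the TSS falls inside [start, end)
        d = np.where(
            tss_arr < iv.start,
            iv.start - tss_arr,
            np.where(tss_arr >= iv.end, tss_arr - iv.end, 0),
        )
        dmin = int(d.min())
        winner = min(cands[j][1] for j in np.flatnonzero(d == dmin))
        out.append((dmin, winner))
    return out


def partition_by_tss_distance(
    intervals: IntervalSet,
    genes: Sequence[GeneModel],
    cutoff: int = PROMOTER_WINDOW,
) -> tuple[IntervalSet, IntervalSet]:
    """Split into (proximal, distal) by TSS distance; proximal is <= cutoff."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    dists = distance_to_nearest_tss(intervals, genes)
    prox = [iv for iv, (d, _) in zip(intervals, dists) if d <= cutoff]
    dist = [iv for iv, (d, _) in zip(intervals, dists) if d > cutoff]
    return (
        IntervalSet(prox, intervals.genome, validate_bounds=False),
        IntervalSet(dist, intervals.genome, validate_bounds=False),
    )


CONTEXT_CATEGORIES = ("promoter", "exon", "intron", "intergenic")


def annotate_genomic_context(
    intervals: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_window: int = PROMOTER_WINDOW,
) -> tuple[list[str], dict[str, int]]:
    """Classify each interval's midpoint: promoter > exon > intron > intergenic.

    Promoter means within ``promoter_window`` bp of a TSS; exon/intron are
    judged against gene exon structure; everything else is intergenic.
    """
    labels: list[str] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for iv in intervals:
        mid = iv.midpoint
        label = "intergenic"
        in_exon = in_intron = in_promoter = False
        for g in genes_by_chrom.get(iv.chrom, ()):
            if abs(mid - g.tss) <= promoter_window:
                in_promoter = True
                break
            span_s, span_e = g.span
            if span_s <= mid < span_e:
                if any(s <= mid < e for s, e in g.exons):
                    in_exon = True
                else:
                    in_intron = True
        if in_promoter:
            label = "promoter"
        elif in_exon:
            label = "exon"
        elif in_intron:
            label = "intron"
        labels.append(label)
    counts = {c: labels.count(c) for c in CONTEXT_CATEGORIES}
    return labels, counts


def _allowed_segments(
    chrom_size: int, length: int, excluded: list[GenomicInterval]
) -> list[tuple[int, int]]:
    """Half-open segments of allowed start positions for an interval of
    ``length`` that must avoid every excluded interval."""
    lo, hi = 0, chrom_size - length + 1  # starts in [lo, hi)
    if hi <= lo:
        return []
    # an excluded [s, e) forbids starts in [s - length + 1, e)
    forb = sorted((max(lo, s - length + 1), min(hi, e)) for s, e in
                  ((iv.start, iv.end) for iv in excluded))
    segs: list[tuple[int, int]] = []
    cur = lo
    for s, e in forb:
        if e <= cur:
            continue
        if s > cur:
            segs.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        segs.append((cur, hi))
    return segs


def shuffle_intervals(
    intervals: IntervalSet,
    genome: Genome,
    excluded: IntervalSet | None = None,
    seed: int | np.random.Generator = 0,
) -> IntervalSet:
    """Random re-placement preserving each interval's chromosome and length.

    Start positions are drawn uniformly from all positions where the
    interval fits inside the chromosome without touching ``excluded``.
    The allowed-position set is computed exactly, so no rejection loop is
    needed; infeasible placement raises :class:`PlacementError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl_by_chrom = (excluded or IntervalSet()).by_chrom()
    out: list[GenomicInterval] = []
    for iv in intervals:
        segs = _allowed_segments(
            genome.size_of(iv.chrom), len(iv), excl_by_chrom.get(iv.chrom, [])
        )
        if not segs:
            raise PlacementError(
                f"no feasible placement for a {len(iv)} bp interval on {iv.chrom}"
            )
        sizes = np.array([e - s for s, e in segs])
        total = int(sizes.sum())
        pos = int(rng.integers(total))
        for (s, _), sz in zip(segs, sizes):
            if pos < sz:
                start = s + pos
                break
            pos -= int(sz)
        out.append(GenomicInterval(iv.chrom, start, start + len(iv), name=iv.name))
    return IntervalSet(out, genome, validate_bounds=False)
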