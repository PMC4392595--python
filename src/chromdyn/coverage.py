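"""Fixed-width binned read coverage and its normalizations.

A :class:`BinnedCoverage` holds one integer count vector per chromosome at a
fixed bin width, plus the library size (total reads). Density is reported as
reads per bin per million sequenced reads. ``window_sums`` integrates the
track over arbitrary base-pair windows, pro-rating partially covered edge
bins, so downstream stages (enhancer densities, heatmap matrices) stay
exact and deterministic regardless of bin alignment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError, ValidationError
from .genome import Genome


@dataclass
class BinnedCoverage:
    genome: Genome
    bin_size: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise InvalidParameterError("bin_size must be positive")
        for chrom in self.genome.chrom_names:
            n = math.ceil(self.genome.size_of(chrom) / self.bin_size)
            if chrom not in self.counts:
                self.counts[chrom] = np.zeros(n, dtype=np.int64)
            elif len(self.counts[chrom]) != n:
                raise ValidationError(
                    f"{chrom}: expected {n} bins, got {len(self.counts[chrom])}"
                )

    @property
    def library_size(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def normalized(self) -> dict[str, np.ndarray]:
        """Reads per bin per million sequenced reads."""
        lib = self.library_size
        if lib <= 0:
            raise InvalidParameterError("cannot normalize a zero-read library")
        return {c: v * (1e6 / lib) for c, v in self.counts.items()}

    def window_sums(
        self, chrom: str, starts: Sequence[int], ends: Sequence[int]
    ) -> np.ndarray:
        """Raw-count mass of half-open bp windows, edge bins pro-rated.

        Windows may extend past chromosome ends; out-of-range spans
        contribute zero (used by heatmap flanks near chromosome edges).
        """
        v = self.counts[chrom].astype(float)
        n = len(v)
        # cumulative mass at bin boundaries: C[k] = sum of first k bins
        cum = np.concatenate([[0.0], np.cumsum(v)])

        def mass_at(pos_bp: np.ndarray) -> np.ndarray:
            """Cumulative mass from chromosome start to bp position."""
            pos = np.clip(pos_bp, 0, None).astype(float)
            b = np.minimum(pos / self.bin_size, n)
            k = np.floor(b).astype(int)
            frac = b - k
            return cum[k] + np.where(k < n, v[np.minimum(k, n - 1)] * frac, 0.0)

        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        if np.any(e < s):
            raise InvalidParameterError("window end precedes start")
        return mass_at(e) - mass_at(s)

    # ---- bedGraph round-trip --------------------------------------------
    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.genome.chrom_names:
                size = self.genome.size_of(chrom)
                v = self.counts[chrom]
                for i, c in enumerate(v):
                    if c == 0:
                        continue
                    s = i * self.bin_size
                    fh.write(f"{chrom}\t{s}\t{min(s + self.bin_size, size)}\t{int(c)}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, genome: Genome, bin_size: int
    ) -> "BinnedCoverage":
        cov = cls(genome, bin_size)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValidationError(f"{path}:{lineno}: expected 4 columns")
                chrom, s, e, val = parts[0], int(parts[1]), int(parts[2]), parts[3]
                if chrom not in genome:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if s % bin_size != 0:
                    raise ValidationError(
                        f"{path}:{lineno}: start {s} not aligned to bin {bin_size}"
                    )
                cov.counts[chrom][s // bin_size] = int(val)
        return cov


def bin_reads(
    read_positions: Mapping[str, Sequence[int]],
    genome: Genome,
    bin_size: int,
    duplicate_cap: int | None = None,
) -> BinnedCoverage:
    """Bin single-bp read positions into fixed-width counts.

    ``duplicate_cap`` limits how many reads may share one exact position
    before binning (mirrors the duplicate filter applied to sequencing
    libraries); ``None`` disables the cap.
    """
    cov = BinnedCoverage(genome, bin_size)
    for chrom, positions in read_positions.items():
        if chrom not in genome:
            raise ValidationError(f"reads on unknown chromosome {chrom!r}")
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size == 0:
            continue
        size = genome.size_of(chrom)
        bad = (pos < 0) | (pos >= size)
        if bad.any():
            offenders = pos[bad][:5].tolist()
            raise ValidationError(
                f"{chrom}: {int(bad.sum())} read position(s) out of bounds "
                f"(first offenders: {offenders})"
            )
        if duplicate_cap is not None:
            if duplicate_cap <= 0:
                raise InvalidParameterError("duplicate_cap must be positive")
            uniq, cnt = np.unique(pos, return_counts=True)
            cnt = np.minimum(cnt, duplicate_cap)
            binned = np.bincount(uniq // bin_size, weights=cnt,
                                 minlength=len(cov.counts[chrom]))
        else:
            binned = np.bincount(pos // bin_size, minlength=len(cov.counts[chrom]))
        cov.counts[chrom] = cov.counts[chrom] + binned.astype(np.int64)
    return cov


def read_positions_from_bed(path: str | Path) -> dict[str, list[int]]:
    """Load single-bp read positions (5' ends) from a BED of reads."""
    from .intervals import IntervalSet

    out: dict[str, list[int]] = {}
    for iv in IntervalSet.from_bed(path):
        pos = iv.start if iv.strand != "-" else iv.end - 1
        out.setdefault(iv.chrom, []).append(pos)
    return out


def normalize_density(coverage: BinnedCoverage) -> dict[str, np.ndarray]:
    """Per-bin reads-per-bin-per-million (thin functional alias)."""
    return coverage.normalized()
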