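"""Input-corrected Poisson peak calling and replicate handling.

The caller slides a fixed window over binned coverage and tests the ChIP
count in each window against a local Poisson expectation derived from the
input (control) track: ``lambda_local = max(lambda_floor,
input_window_count * chip_library / input_library)``, with a genome-wide
floor ``lambda_floor = chip_library * window / genome_size`` so that
input dropouts can never make a window trivially significant. Upper-tail
Poisson p-values are corrected by Benjamini-Hochberg across all tested
windows; significant windows are merged into regions.

High-confidence regions across biological replicates are defined by
intersecting the two replicate peak sets: any pair of peaks sharing >=1 bp
contributes the union of the pair, so every reported region is supported by
a statistically enriched peak in both replicates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import BinnedCoverage
from .errors import ConsistencyError, DegenerateInputError, InvalidParameterError
from .genome import Genome
from .intervals import GenomicInterval, IntervalSet, merge_intervals


@dataclass
class PeakCallingParams:
    window_size: int = 500
    step: int = 25
    q_threshold: float = 0.01
    merge_gap: int = 100
    duplicate_cap: int = 50
    lambda_floor: float | None = None  # None: genome-wide expectation

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise InvalidParameterError("q_threshold must be in (0, 1)")
        if self.window_size <= 0 or self.step <= 0 or self.merge_gap < 0:
            raise InvalidParameterError("window_size/step/merge_gap invalid")


@dataclass
class Peak:
    interval: GenomicInterval
    summit: int
    chip_count: float
    lambda_local: float
    p_raw: float
    q_bh: float

    @property
    def fold_enrichment(self) -> float:
        return self.chip_count / self.lambda_local if self.lambda_local > 0 else np.inf


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    genome: Genome | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> IntervalSet:
        return IntervalSet(
            [p.interval for p in self.peaks], self.genome, validate_bounds=False
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in self.peaks],
                "start": [p.interval.start for p in self.peaks],
                "end": [p.interval.end for p in self.peaks],
                "summit": [p.summit for p in self.peaks],
                "chip_count": [p.chip_count for p in self.peaks],
                "lambda_local": [p.lambda_local for p in self.peaks],
                "fold_enrichment": [p.fold_enrichment for p in self.peaks],
                "p_raw": [p.p_raw for p in self.peaks],
                "q_bh": [p.q_bh for p in self.peaks],
            }
        )

    def to_narrowpeak(self, path: str | Path) -> None:
        """BED6+4: summit offset, fold, -log10 p, -log10 q."""
        with open(path, "w") as fh:
            for i, p in enumerate(self.peaks):
                iv = p.interval
                mlp = -np.log10(max(p.p_raw, 1e-300))
                mlq = -np.log10(max(p.q_bh, 1e-300))
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t"
                    f"{min(1000, int(10 * p.fold_enrichment))}\t.\t"
                    f"{p.fold_enrichment:.4f}\t{mlp:.4f}\t{mlq:.4f}\t"
                    f"{p.summit - iv.start}\n"
                )


def _window_starts(n_bins: int, win_bins: int, step_bins: int) -> np.ndarray:
    last = max(0, n_bins - win_bins)
    return np.arange(0, last + 1, step_bins)


def scan_windows(
    chip: BinnedCoverage,
    input_track: BinnedCoverage,
    params: PeakCallingParams | None = None,
) -> pd.DataFrame:
    """Sliding-window scan: per-window ChIP count, local Poisson
    expectation, raw upper-tail p and BH q. The caller thresholds and
    merges this scan; it is public so that calibration studies can measure
    per-window false-call rates directly."""
    params = params or PeakCallingParams()
    if chip.genome != input_track.genome or chip.bin_size != input_track.bin_size:
        raise ConsistencyError("chip and input tracks must share genome and bin size")
    if params.window_size < chip.bin_size or params.window_size % chip.bin_size:
        raise InvalidParameterError("window_size must be a multiple of bin_size")
    if params.step % chip.bin_size:
        raise InvalidParameterError("step must be a multiple of bin_size")
    lib_chip = chip.library_size
    lib_input = input_track.library_size
    if lib_input <= 0:
        raise InvalidParameterError(
            "input library is empty; the model is input-corrected and "
            "requires a control track"
        )
    genome = chip.genome
    win_bins = params.window_size // chip.bin_size
    step_bins = params.step // chip.bin_size
    ratio = lib_chip / lib_input
    lam_floor = (
        params.lambda_floor
        if params.lambda_floor is not None
        else lib_chip * params.window_size / genome.total_size
    )

    chroms: list[str] = []
    start_bps: list[np.ndarray] = []
    ks: list[np.ndarray] = []
    lams: list[np.ndarray] = []
    for chrom in genome.chrom_names:
        c = chip.counts[chrom]
        b = input_track.counts[chrom]
        n = len(c)
        cum_c = np.concatenate([[0], np.cumsum(c)])
        cum_b = np.concatenate([[0], np.cumsum(b)])
        starts = _window_starts(n, win_bins, step_bins)
        ends = np.minimum(starts + win_bins, n)
        chroms.extend([chrom] * len(starts))
        start_bps.append(starts * chip.bin_size)
        ks.append(cum_c[ends] - cum_c[starts])
        lams.append(np.maximum(lam_floor, (cum_b[ends] - cum_b[starts]) * ratio))
    k_arr = np.concatenate(ks).astype(float)
    lam_arr = np.concatenate(lams)
    p_arr = stats.poisson.sf(k_arr - 1, lam_arr)  # P(X >= k)
    _, q_arr, _, _ = multipletests(p_arr, method="fdr_bh")
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(start_bps),
            "chip_count": k_arr,
            "lambda_local": lam_arr,
            "p_raw": p_arr,
            "q_bh": q_arr,
        }
    )


def call_enriched_regions(
    chip: BinnedCoverage,
    input_track: BinnedCoverage,
    params: PeakCallingParams | None = None,
) -> PeakSet:
    """Call enriched regions from a ChIP track against its input control."""
    params = params or PeakCallingParams()
    scan = scan_windows(chip, input_track, params)
    genome = chip.genome
    lib_chip = chip.library_size
    ratio = lib_chip / input_track.library_size
    lam_floor = (
        params.lambda_floor
        if params.lambda_floor is not None
        else lib_chip * params.window_size / genome.total_size
    )
    sig = scan[scan["q_bh"] <= params.q_threshold]
    if sig.empty:
        return PeakSet([], genome)
    sig_ivs = [
        GenomicInterval(
            r.chrom,
            int(r.start),
            min(int(r.start) + params.window_size, genome.size_of(r.chrom)),
        )
        for r in sig.itertuples()
    ]
    merged = merge_intervals(IntervalSet(sig_ivs, genome), gap=params.merge_gap)

    # per-window minimum q within each merged region
    win_index: dict[str, list[tuple[int, float, float]]] = {}
    for r in scan.itertuples():
        win_index.setdefault(r.chrom, []).append((int(r.start), r.p_raw, r.q_bh))

    peaks: list[Peak] = []
    for iv in merged:
        c = chip.counts[iv.chrom]
        s_bin = iv.start // chip.bin_size
        e_bin = (iv.end + chip.bin_size - 1) // chip.bin_size
        seg = c[s_bin:e_bin]
        summit_bin = s_bin + int(np.argmax(seg))
        summit = summit_bin * chip.bin_size + chip.bin_size // 2
        chip_count = float(chip.window_sums(iv.chrom, [iv.start], [iv.end])[0])
        input_count = float(input_track.window_sums(iv.chrom, [iv.start], [iv.end])[0])
        lam_region = max(lam_floor * len(iv) / params.window_size, input_count * ratio)
        p_region = float(stats.poisson.sf(round(chip_count) - 1, lam_region))
        q_min = min(
            (q for (ws, _, q) in win_index[iv.chrom]
             if iv.start - params.window_size < ws < iv.end),
            default=1.0,
        )
        peaks.append(
            Peak(
                interval=iv,
                summit=summit,
                chip_count=chip_count,
                lambda_local=lam_region,
                p_raw=p_region,
                q_bh=float(q_min),
            )
        )
    return PeakSet(peaks, genome)


def intersect_replicates(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """High-confidence regions supported by both replicates.

    Every overlapping pair (>=1 bp) contributes the union span of the pair;
    unions are then merged. Commutative, and every output interval overlaps
    at least one peak in each replicate by construction.
    """
    if rep1.genome is not None and rep2.genome is not None and rep1.genome != rep2.genome:
        raise ConsistencyError("replicate peak sets are on different genomes")
    genome = rep1.genome or rep2.genome
    a_by_chrom = rep1.intervals().by_chrom()
    unions: list[GenomicInterval] = []
    for p2 in rep2:
        iv2 = p2.interval
        for iv1 in a_by_chrom.get(iv2.chrom, ()):
            if iv1.start < iv2.end and iv2.start < iv1.end:
                u = GenomicInterval(
                    iv2.chrom, min(iv1.start, iv2.start), max(iv1.end, iv2.end)
                )
                unions.append(u)
    if not unions:
        return PeakSet([], genome)
    merged = merge_intervals(IntervalSet(unions, genome), gap=0)

    # carry summary stats from the supporting peaks of both replicates
    peaks: list[Peak] = []
    for iv in merged:
        support = [
            p for p in list(rep1) + list(rep2) if p.interval.overlaps(iv)
        ]
        best = min(support, key=lambda p: p.p_raw)
        peaks.append(
            Peak(
                interval=iv,
                summit=best.summit,
                chip_count=sum(p.chip_count for p in support),
                lambda_local=sum(p.lambda_local for p in support),
                p_raw=best.p_raw,
                q_bh=min(p.q_bh for p in support),
            )
        )
    return PeakSet(peaks, genome)


def signal_correlation(
    track_a: BinnedCoverage,
    track_b: BinnedCoverage,
    regions: IntervalSet,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Pearson r (and r^2) of log2 per-region normalized densities."""
    if len(regions) < 3:
        raise DegenerateInputError("need at least 3 regions for a correlation")
    vals = []
    for track in (track_a, track_b):
        lib = track.library_size
        per_region = np.array(
            [
                float(track.window_sums(iv.chrom, [iv.start], [iv.end])[0])
                for iv in regions
            ]
        )
        vals.append(np.log2(per_region * 1e6 / lib + pseudocount))
    r = float(stats.pearsonr(vals[0], vals[1])[0])
    return r, r * r
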