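"""Enhancer prediction, activation dynamics, and super-enhancer stitching.

Putative enhancers are H3K27ac-enriched regions lying strictly more than
2.5 kb from every TSS. A mesodermal enhancer is classified *static* when it
shares >=1 bp with an H3K27ac region of the precursor (ESC) state and
*activated* otherwise. Differential acetylation is the per-enhancer
log2((KO + c) / (ctrl + c)) of per-million-normalized H3K27ac density,
where density sums every coverage bin fully or partially inside the
interval (partial bins counted in full).

Super-enhancers follow the rank-signal ("ROSE"-style) construction: peaks
outside the TSS exclusion zone are stitched within a stitching distance,
ranked by input-subtracted signal, and the cutoff is placed where the
tangent of the rank-signal curve, with both axes scaled to [0, 1], has
slope 1; regions above the cutoff are flagged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import BinnedCoverage
from .errors import DegenerateInputError, InvalidParameterError
from .genome import GeneModel
from .intervals import (
    GenomicInterval,
    IntervalSet,
    distance_to_nearest_tss,
    merge_intervals,
    overlaps_any,
    partition_by_tss_distance,
)
from .peaks import PeakSet

DISTAL_CUTOFF = 2500
DEFAULT_PSEUDOCOUNT = 1.0  # normalized units


@dataclass
class SuperEnhancerParams:
    stitch_distance: int = 12500
    tss_exclusion: int = 2500

    def __post_init__(self) -> None:
        if self.stitch_distance <= 0:
            raise InvalidParameterError("stitch_distance must be positive")


def _interval_frame(ivs: IntervalSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
        }
    )


def frame_to_intervals(df: pd.DataFrame, genome=None) -> IntervalSet:
    return IntervalSet(
        [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()
        ],
        genome,
        validate_bounds=False,
    )


def region_density(track: BinnedCoverage, df: pd.DataFrame) -> np.ndarray:
    """Per-region normalized density: whole-bin sums over touched bins."""
    norm = track.normalized()
    out = np.empty(len(df))
    for i, r in enumerate(df.itertuples()):
        v = norm[str(r.chrom)]
        lo = int(r.start) // track.bin_size
        hi = min(len(v), -(-int(r.end) // track.bin_size))
        out[i] = float(v[lo:hi].sum())
    return out


def predict_enhancers(
    h3k27ac_peaks: PeakSet,
    genes: Sequence[GeneModel],
    cutoff: int = DISTAL_CUTOFF,
) -> tuple[pd.DataFrame, IntervalSet]:
    """Split H3K27ac peaks into putative enhancers (distal) and a
    promoter-proximal remainder. Returns (enhancer table, proximal set)."""
    proximal, distal = partition_by_tss_distance(
        h3k27ac_peaks.intervals(), genes, cutoff=cutoff
    )
    table = _interval_frame(distal)
    table["dynamics"] = pd.Series(dtype=object)
    table["brg1_bound"] = False
    table["is_super"] = False
    return table, proximal


def classify_dynamics(
    enhancers: pd.DataFrame, esc_h3k27ac_regions: IntervalSet
) -> pd.Series:
    """'static' when sharing >=1 bp with a precursor-state H3K27ac region,
    'activated' otherwise."""
    if len(esc_h3k27ac_regions) == 0:
        warnings.warn(
            "empty precursor H3K27ac set: every enhancer classified as activated",
            stacklevel=2,
        )
        return pd.Series("activated", index=enhancers.index, name="dynamics")
    flags, _ = overlaps_any(frame_to_intervals(enhancers), esc_h3k27ac_regions)
    return pd.Series(
        np.where(flags, "static", "activated"), index=enhancers.index, name="dynamics"
    )


def flag_brg1_bound(enhancers: pd.DataFrame, brg1_regions: IntervalSet) -> pd.Series:
    flags, _ = overlaps_any(frame_to_intervals(enhancers), brg1_regions)
    return pd.Series(flags, index=enhancers.index, name="brg1_bound")


def differential_acetylation(
    enhancers: pd.DataFrame,
    ctrl_track: BinnedCoverage,
    ko_track: BinnedCoverage,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-enhancer KO-vs-control H3K27ac log2FC plus cohort medians.

    Cohorts reported: all enhancers, activated, static, remodeler-bound,
    unbound, and (when a ``near_downregulated`` column is present) the
    enhancers nearest to significantly downregulated genes.
    """
    out = enhancers.copy()
    out["density_ctrl"] = region_density(ctrl_track, out)
    out["density_ko"] = region_density(ko_track, out)
    out["log2fc_k27ac"] = np.log2(
        (out["density_ko"] + pseudocount) / (out["density_ctrl"] + pseudocount)
    )
    medians: dict[str, float] = {"all": float(out["log2fc_k27ac"].median())}
    if "dynamics" in out and out["dynamics"].notna().any():
        for cls in ("activated", "static"):
            sel = out.loc[out["dynamics"] == cls, "log2fc_k27ac"]
            medians[cls] = float(sel.median()) if len(sel) else float("nan")
    if "brg1_bound" in out:
        for label, mask in (
            ("brg1_bound", out["brg1_bound"].astype(bool)),
            ("unbound", ~out["brg1_bound"].astype(bool)),
        ):
            sel = out.loc[mask, "log2fc_k27ac"]
            medians[label] = float(sel.median()) if len(sel) else float("nan")
    if "near_downregulated" in out:
        sel = out.loc[out["near_downregulated"].astype(bool), "log2fc_k27ac"]
        medians["near_downregulated"] = float(sel.median()) if len(sel) else float("nan")
    return out, medians


def assign_nearest_gene(
    enhancers: pd.DataFrame,
    genes: Sequence[GeneModel],
    expression: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Attach each enhancer's nearest gene (by TSS distance, ties to the
    smaller gene_id) and, given a differential-expression table, that
    gene's log2FC; returns the table and the Pearson correlation between
    enhancer acetylation change and nearest-gene expression change
    (NaN when either column is unavailable)."""
    out = enhancers.copy()
    dists = distance_to_nearest_tss(frame_to_intervals(out), genes)
    out["nearest_gene"] = [g for _, g in dists]
    out["tss_distance"] = [d for d, _ in dists]
    corr = float("nan")
    if expression is not None:
        lfc = expression["log2fc"]
        out["gene_log2fc"] = [
            lfc.get(g, np.nan) for g in out["nearest_gene"]
        ]
        if "log2fc_k27ac" in out:
            ok = out[["log2fc_k27ac", "gene_log2fc"]].dropna()
            if len(ok) >= 3:
                corr = float(
                    stats.pearsonr(ok["log2fc_k27ac"], ok["gene_log2fc"])[0]
                )
    return out, corr


@dataclass
class SuperEnhancerResult:
    table: pd.DataFrame  # stitched regions: chrom/start/end/signal/rank/is_super
    cutoff_signal: float
    cutoff_index: int  # rank-curve index (ascending order) of the tangent point


def rank_signal_cutoff(signal: np.ndarray) -> tuple[float, int]:
    """Slope-1 tangent cutoff on the scaled ascending rank-signal curve.

    Both axes are scaled to [0, 1]; for the (convex, increasing) curve the
    tangent point of a slope-1 support line is where ``y - x`` attains its
    minimum. Returns (signal value at the tangent point, index in the
    ascending order).
    """
    n = len(signal)
    if n < 3:
        raise DegenerateInputError("need at least 3 regions to place a cutoff")
    srt = np.sort(signal)
    span = srt[-1] - srt[0]
    if span <= 0:
        raise DegenerateInputError("all signals equal; cutoff undefined")
    x = np.arange(n) / (n - 1)
    y = (srt - srt[0]) / span
    idx = int(np.argmin(y - x))
    return float(srt[idx]), idx


def stitch_super_enhancers(
    h3k27ac_peaks: PeakSet,
    ctrl_track: BinnedCoverage,
    genes: Sequence[GeneModel],
    params: SuperEnhancerParams | None = None,
    input_track: BinnedCoverage | None = None,
) -> SuperEnhancerResult:
    """Stitch distal peaks and flag those above the rank-curve cutoff."""
    params = params or SuperEnhancerParams()
    _, distal = partition_by_tss_distance(
        h3k27ac_peaks.intervals(), genes, cutoff=params.tss_exclusion
    )
    stitched = merge_intervals(distal, gap=params.stitch_distance)
    df = _interval_frame(stitched)
    if len(df) < 3:
        raise DegenerateInputError("fewer than 3 stitched regions; cutoff undefined")
    signal = region_density(ctrl_track, df)
    if input_track is not None:
        signal = np.maximum(0.0, signal - region_density(input_track, df))
    df["signal"] = signal
    cutoff, idx = rank_signal_cutoff(signal)
    df["is_super"] = df["signal"] > cutoff
    df["rank"] = df["signal"].rank(ascending=False, method="first").astype(int)
    return SuperEnhancerResult(
        table=df.sort_values("rank").reset_index(drop=True),
        cutoff_signal=cutoff,
        cutoff_index=idx,
    )
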