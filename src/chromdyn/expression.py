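"""RPKM, differential expression, and induction/dependence integration.

Differential calls follow the joint rule used throughout the analysis:
a gene is differential when its BH-adjusted p-value (FDR) is <= 1% *and*
its expression changes at least twofold.

The default per-gene test (``method="nb"``) is a Wald test on the log rate
ratio of pooled counts with library-size offsets and a global
overdispersion term estimated from within-condition replicate variability
by the method of moments (negative-binomial variance ``m + d*m^2``):
``var(log-ratio) ~ 1/k_a + 1/k_b + 2*d_hat/n_reps``. With a single
replicate per condition the dispersion is unidentifiable and taken as 0,
which reduces the test to a plain log-ratio z-test. Two alternatives are
kept for transparency and cross-checks: ``method="binomial"`` — the exact
two-sided binomial on the split ``Binomial(k_a + k_b,
lib_b/(lib_a+lib_b))`` — and its normal approximation ``method="normal"``.
The binomial split test is exact under pure Poisson sampling but
anticonservative in the presence of biological replicate variability,
which is why it is not the default.

Log2 fold changes are shrunken with a pseudocount of 0.5 reads per library
so that zero counts stay finite. ``log2fc`` is always condition_b relative
to condition_a; ``status`` 'up'/'down' describes condition_b.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, InvalidParameterError, ValidationError
from .genome import GeneModel

DEFAULT_FDR = 0.01
DEFAULT_MIN_FOLD = 2.0
EXPRESSION_FLOOR_RPKM = 0.5
LOG2FC_PSEUDOCOUNT = 0.5  # reads per library


def compute_rpkm(
    counts: Mapping[str, int],
    gene_models: Sequence[GeneModel],
    library_size: int | None = None,
) -> pd.Series:
    """Reads per kilobase of exon per million mapped reads."""
    if library_size is None:
        library_size = int(sum(counts.values()))
    if library_size <= 0:
        raise InvalidParameterError("library_size must be positive")
    out = {}
    for g in gene_models:
        if g.exonic_length <= 0:
            raise ValidationError(f"gene {g.gene_id} has zero exonic length")
        k = counts.get(g.gene_id, 0)
        out[g.gene_id] = k * 1e9 / (library_size * g.exonic_length)
    return pd.Series(out, name="rpkm")


def filter_expressed(
    rpkm_by_condition: pd.DataFrame, floor: float = EXPRESSION_FLOOR_RPKM
) -> pd.Index:
    """Genes expressed at >= ``floor`` RPKM in at least one condition."""
    keep = (rpkm_by_condition >= floor).any(axis=1)
    return rpkm_by_condition.index[keep]


def _pool(replicates: Sequence[Mapping[str, int]]) -> pd.Series:
    frames = [pd.Series(r, dtype=float) for r in replicates]
    return pd.concat(frames, axis=1).fillna(0).sum(axis=1)


def estimate_dispersion(*replicate_sets: Sequence[Mapping[str, int]]) -> float:
    """Moment estimate of the global NB dispersion from replicate scatter.

    For each condition with >= 2 replicates, per-gene library-scaled rates
    ``x_r`` have E[s^2] ~ mean + d * mean^2, so each adequately expressed
    gene yields a moment estimate ``(s^2 - mean) / mean^2``; their plain
    mean across genes and conditions weighs genes equally, which keeps the
    estimator stable under heavy-tailed expression levels (a total-sum
    ratio is dominated by the handful of most-expressed genes). Clipped at
    0; returns 0.0 when no condition has replicates.
    """
    per_gene: list[np.ndarray] = []
    for reps in replicate_sets:
        if len(reps) < 2:
            continue
        frames = [pd.Series(r, dtype=float) for r in reps]
        mat = pd.concat(frames, axis=1).fillna(0)
        libs = mat.sum(axis=0).to_numpy()
        if (libs <= 0).any():
            continue
        scaled = mat.to_numpy() * (libs.mean() / libs)
        m = scaled.mean(axis=1)
        s2 = scaled.var(axis=1, ddof=1)
        keep = m >= 25  # Poisson noise swamps the signal below this
        per_gene.append((s2[keep] - m[keep]) / m[keep] ** 2)
    if not per_gene:
        return 0.0
    vals = np.concatenate(per_gene)
    return max(0.0, float(vals.mean())) if len(vals) else 0.0


def differential_expression(
    counts_a: Sequence[Mapping[str, int]],
    counts_b: Sequence[Mapping[str, int]],
    fdr: float = DEFAULT_FDR,
    min_fold: float = DEFAULT_MIN_FOLD,
    method: str = "nb",
) -> pd.DataFrame:
    """Two-condition differential test on pooled replicate counts.

    Parameters
    ----------
    counts_a, counts_b
        One mapping gene_id -> count per replicate of each condition.
    method
        ``"nb"`` (default): Wald log-ratio test with replicate-estimated
        global dispersion; ``"binomial"``: exact split test (Poisson
        sampling only); ``"normal"``: z approximation of the split test.

    Returns a frame indexed by gene with columns ``count_a``, ``count_b``,
    ``log2fc`` (b over a), ``p``, ``q``, ``status``.
    """
    if not counts_a or not counts_b:
        raise InvalidParameterError("each condition needs at least one replicate")
    if method not in ("nb", "binomial", "normal"):
        raise InvalidParameterError(f"unknown method {method!r}")
    ka = _pool(counts_a)
    kb = _pool(counts_b)
    genes = ka.index.union(kb.index)
    ka = ka.reindex(genes, fill_value=0)
    kb = kb.reindex(genes, fill_value=0)
    lib_a, lib_b = float(ka.sum()), float(kb.sum())
    if lib_a <= 0 or lib_b <= 0:
        raise InvalidParameterError("zero library size in one condition")
    p0 = lib_b / (lib_a + lib_b)

    n = (ka + kb).to_numpy()
    k = kb.to_numpy()
    pvals = np.ones(len(genes))
    tested = n > 0
    if method == "binomial":
        for i in np.flatnonzero(tested):
            pvals[i] = stats.binomtest(int(k[i]), int(n[i]), p0).pvalue
    elif method == "normal":
        mu = n[tested] * p0
        sd = np.sqrt(n[tested] * p0 * (1 - p0))
        z = (k[tested] - mu) / np.where(sd > 0, sd, 1.0)
        pvals[tested] = 2 * stats.norm.sf(np.abs(z))
    else:  # nb
        d_hat = estimate_dispersion(counts_a, counts_b)
        n_reps = min(len(counts_a), len(counts_b))
        c = LOG2FC_PSEUDOCOUNT
        ka_t, kb_t = ka.to_numpy()[tested], kb.to_numpy()[tested]
        lratio = np.log(((kb_t + c) / lib_b) / ((ka_t + c) / lib_a))
        var = 1.0 / (ka_t + c) + 1.0 / (kb_t + c) + 2.0 * d_hat / n_reps
        z = lratio / np.sqrt(var)
        pvals[tested] = 2 * stats.norm.sf(np.abs(z))

    q = np.ones(len(genes))
    if tested.any():
        _, q_t, _, _ = multipletests(pvals[tested], method="fdr_bh")
        q[tested] = q_t

    c = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2(((kb + c) / lib_b) / ((ka + c) / lib_a))
    min_lfc = np.log2(min_fold)
    status = np.where(
        (q <= fdr) & (log2fc >= min_lfc),
        "up",
        np.where((q <= fdr) & (log2fc <= -min_lfc), "down", "unchanged"),
    )
    status[~tested] = "unchanged"
    return pd.DataFrame(
        {
            "count_a": ka,
            "count_b": kb,
            "log2fc": log2fc,
            "p": pvals,
            "q": q,
            "status": status,
        },
        index=genes,
    )


def classify_induction(induction_table: pd.DataFrame) -> pd.Series:
    """Map a day4-control-vs-day2 differential table to induction classes.

    'activated' = significantly higher at day 4, 'repressed' = lower,
    'static' otherwise.
    """
    mapping = {"up": "activated", "down": "repressed", "unchanged": "static"}
    return induction_table["status"].map(mapping).rename("induction_status")


@dataclass
class DependenceOverlap:
    contingency: pd.DataFrame  # induction class x KO status counts
    fractions: dict[str, float]  # e.g. activated_down = P(ko down | activated)
    rank_positions: pd.DataFrame  # induction-rank of each KO-affected gene


def dependence_overlap(
    induction_table: pd.DataFrame, ko_table: pd.DataFrame
) -> DependenceOverlap:
    """Cross the induction classification with the knockout differential.

    Reports, per induction class, the fraction of genes whose expression is
    reduced (or increased) in the knockout, plus the positions of those
    genes along the induction fold-change ranking (for rank-ordered
    visualizations of remodeler dependence).
    """
    if not induction_table.index.equals(ko_table.index):
        common = induction_table.index.intersection(ko_table.index)
        if len(common) != len(induction_table) or len(common) != len(ko_table):
            raise ConsistencyError(
                "induction and knockout tables must share a gene universe"
            )
        ko_table = ko_table.loc[induction_table.index]
    ind = classify_induction(induction_table)
    ko = ko_table["status"]
    contingency = pd.crosstab(ind, ko).reindex(
        index=["activated", "repressed", "static"],
        columns=["down", "up", "unchanged"],
        fill_value=0,
    )
    fractions: dict[str, float] = {}
    for cls in ("activated", "repressed", "static"):
        denom = int(contingency.loc[cls].sum())
        for direction in ("down", "up"):
            frac = contingency.loc[cls, direction] / denom if denom else 0.0
            fractions[f"{cls}_{direction}"] = float(frac)

    order = induction_table["log2fc"].sort_values(ascending=False)
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index, name="rank")
    affected = ko[ko != "unchanged"].index
    rank_positions = pd.DataFrame(
        {"rank": ranks.loc[affected], "ko_status": ko.loc[affected]}
    ).sort_values("rank")
    return DependenceOverlap(contingency, fractions, rank_positions)


# ---- plain-text IO --------------------------------------------------------

def write_counts_tsv(counts: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(counts):
            fh.write(f"{gid}\t{int(counts[gid])}\n")


def read_counts_tsv(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = int(parts[1])
    return out
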