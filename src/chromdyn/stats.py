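"""Region-set and gene-set significance machinery.

* Permutation overlap test: the observed statistic is the fraction of query
  intervals sharing >=1 bp with the reference; the null re-places each
  query interval uniformly on its own chromosome (length preserved), and
  the empirical p-value uses the add-one rule
  ``p = (1 + #{null >= observed}) / (n_perm + 1)`` so it is never zero.
* Hypergeometric enrichment: exact upper-tail P(X >= k).
* Chi-squared independence on a 2x2 table, Pearson form, no continuity
  correction by default.
* Paired rank test: the paired analogue of the Mann-Whitney comparison is
  computed as the Wilcoxon signed-rank test; the exact null distribution
  of W+ (mid-ranks for ties, zero differences dropped) is built by
  convolution for n <= 25 — equivalent to enumerating all 2^n sign
  assignments — with a tie-corrected normal approximation above.
* PWM motif enrichment: a region is a hit when any window on either strand
  reaches ``score_fraction`` of the motif's maximal log-odds score; hits
  are compared between bound and background region sets by one-sided
  Fisher tests with BH correction across motifs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    ValidationError,
)
from .genome import Genome
from .intervals import IntervalSet, overlaps_any, shuffle_intervals


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: int


def permutation_overlap_test(
    query: IntervalSet,
    reference: IntervalSet,
    genome: Genome,
    excluded: IntervalSet | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Empirical overlap enrichment of ``query`` against ``reference``."""
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    _, observed = overlaps_any(query, reference)
    rng = np.random.default_rng(seed)
    nq = len(query)
    null = np.empty(n_perm)
    if excluded is None or len(excluded) == 0:
        # fast path: uniform starts drawn directly, overlap vectorized
        ref = reference.by_chrom()
        ref_starts = {c: np.array([iv.start for iv in lst]) for c, lst in ref.items()}
        ref_maxend = {
            c: np.maximum.accumulate([iv.end for iv in lst]) for c, lst in ref.items()
        }
        q_chrom = [iv.chrom for iv in query]
        q_len = np.array([len(iv) for iv in query])
        q_max = np.array([genome.size_of(c) for c in q_chrom]) - q_len + 1
        if np.any(q_max <= 0):
            raise InvalidParameterError("query interval longer than its chromosome")
        by_c: dict[str, np.ndarray] = {}
        for c in set(q_chrom):
            by_c[c] = np.flatnonzero(np.array(q_chrom) == c)
        for i in range(n_perm):
            starts = rng.integers(0, q_max)
            ends = starts + q_len
            hits = 0
            for c, idx in by_c.items():
                if c not in ref_starts:
                    continue
                rs, rme = ref_starts[c], ref_maxend[c]
                j = np.searchsorted(rs, ends[idx], side="left")
                ok = j > 0
                hits += int(np.count_nonzero(rme[np.maximum(j - 1, 0)][ok] > starts[idx][ok]))
            null[i] = hits / nq if nq else 0.0
    else:
        for i in range(n_perm):
            shuffled = shuffle_intervals(query, genome, excluded, seed=rng)
            _, null[i] = overlaps_any(shuffled, reference)
    p = (1 + int(np.count_nonzero(null >= observed))) / (n_perm + 1)
    return PermutationResult(observed, null, float(p), n_perm, seed)


def hypergeometric_enrichment(
    hits_in_set: int, set_size: int, hits_in_universe: int, universe_size: int
) -> float:
    """Upper-tail P(X >= hits_in_set) of drawing ``set_size`` items without
    replacement from a universe containing ``hits_in_universe`` hits."""
    k, s, K, N = hits_in_set, set_size, hits_in_universe, universe_size
    if not (0 <= k <= s <= N and k <= K <= N):
        raise ValidationError(
            f"inconsistent counts: k={k}, set={s}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, s))


def chisq_independence(
    table: Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero margin: chi-squared undefined")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), int(dof), float(p)


_EXACT_N_MAX = 25


def _signed_rank_null(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled W+ over all 2^n sign assignments."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def paired_rank_test(
    values_ctrl: Sequence[float], values_ko: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired rank test (Wilcoxon signed-rank) on ko - ctrl.

    Returns (W+, two-sided p). Zero differences are dropped; ties get
    mid-ranks. Exact convolution null for n <= 25, tie-corrected normal
    approximation beyond.
    """
    a = np.asarray(values_ctrl, dtype=float)
    b = np.asarray(values_ko, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("paired vectors must have equal length")
    d = b - a
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _EXACT_N_MAX:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_null(doubled)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        p = min(1.0, 2 * min(p_ge, p_le))
    else:
        mean = n * (n + 1) / 4
        tie_table = pd.Series(ranks).value_counts().to_numpy()
        var = n * (n + 1) * (2 * n + 1) / 24 - (tie_table**3 - tie_table).sum() / 48
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return w_plus, float(p)


# ---- PWM motif enrichment -------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # L x 4 base probabilities (A, C, G, T)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"PWM {self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValidationError(f"PWM {self.motif_id}: length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError(f"PWM {self.motif_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, eps: float = 1e-4) -> np.ndarray:
        bg = np.asarray(self.background)
        return np.log2((self.matrix + eps) / (bg + eps))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background)


def pwm_from_counts(motif_id: str, counts: np.ndarray,
                    pseudocount: float = 0.5) -> PWM:
    c = np.asarray(counts, dtype=float) + pseudocount
    return PWM(motif_id, c / c.sum(axis=1, keepdims=True))


def pwm_from_consensus(motif_id: str, consensus: str, p: float = 0.94) -> PWM:
    """Sharp PWM placing probability ``p`` on each consensus base."""
    L = len(consensus)
    m = np.full((L, 4), (1 - p) / 3)
    for i, b in enumerate(consensus.upper()):
        m[i, _BASE_INDEX[b]] = p
    return PWM(motif_id, m)


def read_jaspar_pwms(path: str | Path) -> list[PWM]:
    """Read JASPAR-format plain-text matrices (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    out: list[PWM] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            out.append(pwm_from_counts(m.matrix_id or m.name, counts))
    return out


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().encode().translate(bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))),
        dtype=np.uint8,
    )


def _scan_hit(seq: str, lo_fwd: np.ndarray, lo_rev: np.ndarray,
              threshold: float) -> bool:
    L = lo_fwd.shape[0]
    enc = _encode(seq)
    if len(enc) < L:
        return False
    win = np.lib.stride_tricks.sliding_window_view(enc, L)
    pos_idx = np.arange(L)
    for lo in (lo_fwd, lo_rev):
        scores = lo[pos_idx, win].sum(axis=1)
        if scores.max() >= threshold:
            return True
    return False


def motif_enrichment(
    pwms: Sequence[PWM],
    bound_seqs: Sequence[str],
    background_seqs: Sequence[str],
    score_fraction: float = 0.85,
) -> pd.DataFrame:
    """Per-motif hit-rate fold change, Fisher p, and BH q.

    Regions shorter than a motif are skipped for that motif and counted in
    the ``skipped`` column.
    """
    if not 0 < score_fraction <= 1:
        raise InvalidParameterError("score_fraction must be in (0, 1]")
    rows = []
    for pwm in pwms:
        lo_f = pwm.log_odds()
        lo_r = pwm.reverse_complement().log_odds()
        thr = score_fraction * lo_f.max(axis=1).sum()
        L = len(pwm)
        skipped = sum(1 for s in bound_seqs if len(s) < L) + sum(
            1 for s in background_seqs if len(s) < L
        )
        hb = sum(_scan_hit(s, lo_f, lo_r, thr) for s in bound_seqs if len(s) >= L)
        nb = sum(1 for s in bound_seqs if len(s) >= L)
        hg = sum(_scan_hit(s, lo_f, lo_r, thr) for s in background_seqs if len(s) >= L)
        ng = sum(1 for s in background_seqs if len(s) >= L)
        _, p = stats.fisher_exact([[hb, nb - hb], [hg, ng - hg]], alternative="greater")
        rate_b = hb / nb if nb else 0.0
        rate_g = hg / ng if ng else 0.0
        fold = rate_b / rate_g if rate_g > 0 else (np.inf if rate_b > 0 else 1.0)
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "hits_bound": hb,
                "n_bound": nb,
                "hits_background": hg,
                "n_background": ng,
                "fold": fold,
                "p": float(p),
                "skipped": skipped,
            }
        )
    df = pd.DataFrame(rows).set_index("motif_id")
    if len(df):
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q_bh"] = q
    else:
        df["q_bh"] = pd.Series(dtype=float)
    return df
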