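"""Replication studies that measure the pipeline against planted truth.

Each function runs a self-contained study — simulation under the package's
study conditions (scaled down where many seeds are replicated), analysis
through the public pipeline stages, and a comparison against the planted
ground truth — and returns plain floats. They back both the validation
test-suite and the reproduction script, so the numbers those report are
always recomputed from scratch.
"""
from __future__ import annotations

import itertools
import json
import math
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .config import load_config
from .density import composite_profile, density_matrix, partition_by_density
from .expression import differential_expression
from .genome import Genome
from .intervals import GenomicInterval, IntervalSet, overlaps_any
from .peaks import (
    PeakCallingParams,
    call_enriched_regions,
    intersect_replicates,
    scan_windows,
)
from .pipeline import enhancer_dynamics_medians, run_integrate, run_simulate
from .simulate import (
    ExpressionEffect,
    SimulationParams,
    make_gene_models,
    make_genome,
    plant_regulatory_landscape,
    simulate_chip_track,
    simulate_rnaseq_counts,
)
from .stats import (
    chisq_independence,
    hypergeometric_enrichment,
    paired_rank_test,
    permutation_overlap_test,
)

# reduced-scale landscape used where a study replicates over many seeds;
# per-Mb densities and all condition parameters match the full defaults
REDUCED_SIM = {
    "n_chroms": 1,
    "chrom_size": 5_000_000,
    "n_genes": 150,
    "n_static": 25,
    "n_activated": 25,
    "n_esc_only": 8,
    "n_polycomb": 12,
}


def _empty_truth(genome, seed):
    return plant_regulatory_landscape(
        genome, [], 0, 0, 0, 0.0, 1.0, seed=seed,
        n_polycomb=0, n_repressed_genes=0, n_nonpolycomb_up=0,
    )


def peak_caller_calibration(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Background-only false-call rate (10 Mb, depth 1e6 per track) and
    planted-peak sensitivity at fold-enrichment 8."""
    fprs = []
    for i in range(n_seeds):
        genome = make_genome(2, 5_000_000, seed + i)
        truth = _empty_truth(genome, seed + i)
        params = SimulationParams(read_depth=1_000_000, seed=seed + i)
        chip = simulate_chip_track(truth, "input", "ctrl", 2, params)
        inp = simulate_chip_track(truth, "input", "ctrl", 1, params)
        scan = scan_windows(chip, inp, PeakCallingParams())
        fprs.append(float((scan["q_bh"] <= 0.01).mean()))
    # sensitivity on planted fold-8 peaks
    genome = make_genome(2, 5_000_000, seed)
    truth = plant_regulatory_landscape(
        genome, [], n_static=40, n_activated=0, n_esc_only=0,
        frac_brg1_bound=1.0, delta_bound=1.0, seed=seed,
        frac_brg1_bound_static=1.0, base_enrichment=8.0,
        n_polycomb=0, n_repressed_genes=0, n_nonpolycomb_up=0,
    )
    params = SimulationParams(read_depth=1_000_000, seed=seed)
    chip = simulate_chip_track(truth, "h3k27ac", "ctrl", 1, params)
    inp = simulate_chip_track(truth, "input", "ctrl", 1, params)
    peaks = call_enriched_regions(chip, inp)
    truth_ivs = IntervalSet([e.interval for e in truth.enhancers])
    _, sens = overlaps_any(truth_ivs, peaks.intervals())
    return {
        "fpr_mean": float(np.mean(fprs)),
        "fpr_max": float(np.max(fprs)),
        "sensitivity_fold8": float(sens),
        "n_seeds": n_seeds,
    }


def replicate_intersection_study(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Subset property of replicate intersection over simulated pairs."""
    fractions = []
    for i in range(n_seeds):
        genome = make_genome(1, 2_000_000, seed + i)
        truth = plant_regulatory_landscape(
            genome, [], n_static=15, n_activated=0, n_esc_only=0,
            frac_brg1_bound=1.0, delta_bound=1.0, seed=seed + i,
            frac_brg1_bound_static=1.0, base_enrichment=8.0,
            n_polycomb=0, n_repressed_genes=0, n_nonpolycomb_up=0,
        )
        params = SimulationParams(read_depth=400_000, seed=seed + i)
        inp = simulate_chip_track(truth, "input", "ctrl", 1, params)
        reps = [
            call_enriched_regions(
                simulate_chip_track(truth, "brg1", "ctrl", r, params), inp
            )
            for r in (1, 2)
        ]
        merged = intersect_replicates(reps[0], reps[1])
        if len(merged) == 0:
            continue
        for rep in reps:
            _, frac = overlaps_any(merged.intervals(), rep.intervals())
            fractions.append(frac)
    return {
        "min_fraction_supported_by_both": float(min(fractions)),
        "n_pairs": n_seeds,
    }


def permutation_calibration(seed: int = 0, n_datasets: int = 200) -> dict[str, float]:
    """KS uniformity of permutation p-values under independent nulls."""
    genome = Genome(("chr1",), (1_000_000,))
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_datasets):
        q = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 500)
             for s in rng.integers(0, 999_000, 150)]
        )
        ref = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 2000)
             for s in rng.integers(0, 990_000, 60)]
        )
        res = permutation_overlap_test(
            q, ref, genome, n_perm=99, seed=int(rng.integers(2**31))
        )
        pvals.append(res.p)
    ks = sps.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_datasets": n_datasets}


def engineered_overlap_test(seed: int = 0, n_perm: int = 10_000) -> dict[str, float]:
    """A 68%-overlap query against a reference covering ~10% of the genome:
    the empirical p-value hits the add-one floor 1/(n_perm+1)."""
    genome = Genome(("chr1",), (10_000_000,))
    ref = IntervalSet(
        [GenomicInterval("chr1", i * 100_000, i * 100_000 + 10_000)
         for i in range(100)]
    )
    query = []
    for i in range(68):  # centered inside reference blocks
        query.append(GenomicInterval("chr1", i * 100_000 + 4000, i * 100_000 + 5000))
    for i in range(32):  # placed in the gaps
        query.append(GenomicInterval("chr1", i * 100_000 + 50_000, i * 100_000 + 51_000))
    res = permutation_overlap_test(
        IntervalSet(query), ref, genome, n_perm=n_perm, seed=seed
    )
    return {
        "observed_overlap": res.observed,
        "p": res.p,
        "expected_floor": 1.0 / (n_perm + 1),
        "n_perm": n_perm,
    }


def exact_oracle_checks() -> dict[str, float]:
    """Closed-form/enumeration oracles for the exact statistics."""
    # hypergeometric tail vs combinatorial enumeration, universe <= 30
    max_err = 0.0
    n_checked = 0
    for N in range(1, 31):
        for K in range(N + 1):
            for s in range(N + 1):
                for k in range(max(0, K + s - N), min(K, s) + 1):
                    oracle = sum(
                        math.comb(K, j) * math.comb(N - K, s - j)
                        for j in range(k, min(K, s) + 1)
                    ) / math.comb(N, s)
                    got = hypergeometric_enrichment(k, s, K, N)
                    max_err = max(max_err, abs(got - oracle))
                    n_checked += 1
    # signed-rank exact mode vs 2^n sign-flip brute force
    rng = np.random.default_rng(0)
    wil_err = 0.0
    for n in range(4, 13):
        d = np.round(rng.normal(0.4, 1, n), 1)
        d[d == 0] = 0.1
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ge = le = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            ge += w >= w_obs
            le += w <= w_obs
        brute = min(1.0, 2 * min(ge, le) / 2**n)
        _, p = paired_rank_test(np.zeros(n), d)
        wil_err = max(wil_err, abs(p - brute))
    chi2, _, _ = chisq_independence([[20, 5], [5, 20]])
    return {
        "hypergeom_max_abs_err": float(max_err),
        "hypergeom_n_checked": n_checked,
        "signed_rank_max_abs_err": float(wil_err),
        "chisq_20_5_5_20": float(chi2),
    }


def de_threshold_study(seed: int = 0) -> dict[str, float]:
    """Sensitivity/FDR at the differential-expression thresholds with 300
    planted 4-fold genes among 2000 (2 replicates, dispersion 0.05), plus
    the null call rate with no planted effects."""
    genome = make_genome(3, 10_000_000, seed)
    genes = make_gene_models(genome, 2000, 5000, seed)
    truth = _empty_truth(genome, seed)
    rng = np.random.default_rng(seed)
    planted = rng.choice([g.gene_id for g in genes], 300, replace=False)
    for i, gid in enumerate(planted):
        truth.expression_effects[gid] = ExpressionEffect(
            0.0, 2.0 if i % 2 == 0 else -2.0
        )
    params = SimulationParams(read_depth=2_000_000, seed=seed)

    def _reps(cond):
        return [simulate_rnaseq_counts(truth, genes, cond, r, params) for r in (1, 2)]

    table = differential_expression(_reps("day4_ctrl"), _reps("day4_ko"))
    called = set(table.index[table["status"] != "unchanged"])
    tp = called & set(planted)
    sensitivity = len(tp) / len(planted)
    fdr = (len(called) - len(tp)) / max(1, len(called))

    null_truth = _empty_truth(genome, seed + 1)
    nparams = SimulationParams(read_depth=2_000_000, seed=seed + 1)
    null_table = differential_expression(
        [simulate_rnaseq_counts(null_truth, genes, "day4_ctrl", r, nparams) for r in (1, 2)],
        [simulate_rnaseq_counts(null_truth, genes, "day4_ko", r, nparams) for r in (1, 2)],
    )
    null_rate = float((null_table["status"] != "unchanged").mean())
    return {
        "sensitivity": float(sensitivity),
        "fdr": float(fdr),
        "null_call_rate": null_rate,
        "n_planted": 300,
        "n_genes": 2000,
    }


def enhancer_dynamics_study(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Cohort acetylation-change medians at the default study conditions
    plus a multi-seed sign test of bound-below-unbound at reduced scale."""
    cfg = load_config(overrides={"seed": seed})
    single = enhancer_dynamics_medians(cfg)
    bound_below = 0
    act_meds, stat_meds = [], []
    for i in range(n_seeds):
        rcfg = load_config(
            overrides={"seed": seed + 1 + i, "simulation": dict(REDUCED_SIM)}
        )
        m = enhancer_dynamics_medians(rcfg)
        act_meds.append(m["activated"])
        stat_meds.append(m["static"])
        bound_below += m["brg1_bound"] < m["unbound"]
    sign_p = float(sps.binomtest(bound_below, n_seeds, 0.5).pvalue)
    return {
        "activated_median_log2fc": single["activated"],
        "static_median_log2fc": single["static"],
        "all_median_log2fc": single["all"],
        "bound_median_log2fc": single["brg1_bound"],
        "unbound_median_log2fc": single["unbound"],
        "enhancer_recovery": single["recovery"],
        "label_accuracy": single["label_accuracy"],
        "bound_below_unbound_seeds": bound_below,
        "sign_test_p": sign_p,
        "n_seeds": n_seeds,
        "activated_median_mean_across_seeds": float(np.mean(act_meds)),
        "static_median_mean_across_seeds": float(np.mean(stat_meds)),
    }


def polycomb_partition_study(seed: int = 0) -> dict[str, float]:
    """Group I recovery of planted Polycomb genes and the control-vs-KO
    H3K27me3 contrast at their promoters."""
    genome = make_genome(1, 5_000_000, seed)
    genes = make_gene_models(genome, 300, 5000, seed)
    truth = plant_regulatory_landscape(
        genome, genes, n_static=10, n_activated=10, n_esc_only=0,
        frac_brg1_bound=0.8, delta_bound=0.5, seed=seed,
        n_polycomb=50, n_repressed_genes=0, n_nonpolycomb_up=30,
    )
    params = SimulationParams(read_depth=1_000_000, seed=seed)
    me3_ctrl = simulate_chip_track(truth, "h3k27me3", "ctrl", 1, params)
    me3_ko = simulate_chip_track(truth, "h3k27me3", "ko", 1, params)
    ac_ctrl = simulate_chip_track(truth, "h3k27ac", "ctrl", 1, params)
    up_ids = {g for g, e in truth.expression_effects.items() if e.ko > 0}
    up_genes = [g for g in genes if g.gene_id in up_ids]
    ids = [g.gene_id for g in up_genes]
    m_me3 = density_matrix(up_genes, me3_ctrl, "tss", 5000, 100)
    m_ac = density_matrix(up_genes, ac_ctrl, "tss", 5000, 100)
    part = partition_by_density(ids, m_me3, m_ac)
    polycomb_ids = {p.gene_id for p in truth.polycomb_genes}
    group1 = set(part.labels.index[part.labels == "I"])
    recall = len(group1 & polycomb_ids) / len(polycomb_ids)
    g1_genes = [g for g in up_genes if g.gene_id in group1]
    m1_ctrl = density_matrix(g1_genes, me3_ctrl, "tss", 5000, 100)
    m1_ko = density_matrix(g1_genes, me3_ko, "tss", 5000, 100)
    _, paired_p = paired_rank_test(m1_ctrl.row_sums(), m1_ko.row_sums())
    prof_ctrl = composite_profile(m1_ctrl)["mean"].to_numpy()
    prof_ko = composite_profile(m1_ko)["mean"].to_numpy()
    central = slice(40, 60)  # ±1 kb around the TSS
    return {
        "group1_recall": float(recall),
        "paired_rank_p": float(paired_p),
        "central_profile_ratio": float(
            prof_ko[central].mean() / prof_ctrl[central].mean()
        ),
        "n_polycomb": len(polycomb_ids),
    }


def determinism_study(seed: int, workdir: str | Path) -> dict[str, float]:
    """Two full simulate+integrate runs with one seed: identical checksums."""
    workdir = Path(workdir)
    manifests = []
    for tag in ("a", "b"):
        cfg = load_config(
            overrides={
                "seed": seed,
                "outdir": str(workdir / tag),
                "simulation": dict(REDUCED_SIM),
                "stats": {"n_perm": 500},
            }
        )
        run_simulate(cfg)
        rdir = run_integrate(cfg)
        sim_manifest = json.loads(
            (Path(cfg["outdir"]) / "sim" / "manifest.json").read_text()
        )["files"]
        res_manifest = json.loads((rdir / "manifest.json").read_text())["files"]
        manifests.append((sim_manifest, res_manifest))
    identical = manifests[0] == manifests[1]
    return {"identical_checksums": float(identical)}
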