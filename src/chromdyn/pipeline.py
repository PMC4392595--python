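"""End-to-end orchestration: simulate a dataset, run every analysis stage,
and assemble the integrated report.

``simulate_dataset``/``integrate`` are the in-memory core; ``run_simulate``
and ``run_integrate`` are their disk-backed counterparts used by the CLI,
which communicate only through declared files (chrom.sizes, gene table,
bedGraph tracks, count TSVs) plus a JSON manifest of checksums. The
integration stage never reads the planted truth — truth files exist solely
so that callers can evaluate recovery.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enhancers as enh_mod
from . import expression as expr_mod
from .coverage import BinnedCoverage
from .density import density_matrix, partition_by_density
from .errors import StageDependencyError
from .genome import Genome, read_gene_table, write_gene_table
from .intervals import IntervalSet, annotate_genomic_context
from .peaks import (
    PeakCallingParams,
    PeakSet,
    call_enriched_regions,
    intersect_replicates,
    signal_correlation,
)
from .simulate import (
    RNA_CONDITIONS,
    RegulatoryTruth,
    SimulationParams,
    make_gene_models,
    make_genome,
    plant_regulatory_landscape,
    simulate_chip_track,
    simulate_rnaseq_counts,
)
from .stats import chisq_independence, hypergeometric_enrichment, paired_rank_test
from .stats import permutation_overlap_test


@dataclass
class Dataset:
    genome: Genome
    genes: list
    truth: RegulatoryTruth | None
    tracks: dict[tuple[str, str, int], BinnedCoverage]
    counts: dict[tuple[str, int], dict[str, int]]


def _chip_params(sim: dict, seed: int) -> SimulationParams:
    return SimulationParams(
        bin_size=sim["bin_size"],
        read_depth=sim["chip_depth"],
        peak_halfwidth=sim["peak_halfwidth"],
        rna_dispersion=sim["rna_dispersion"],
        seed=seed,
    )


def simulate_dataset(cfg: dict) -> Dataset:
    sim = cfg["simulation"]
    seed = cfg["seed"]
    genome = make_genome(sim["n_chroms"], sim["chrom_size"], seed)
    genes = make_gene_models(genome, sim["n_genes"], sim["gene_min_spacing"], seed)
    truth = plant_regulatory_landscape(
        genome,
        genes,
        n_static=sim["n_static"],
        n_activated=sim["n_activated"],
        n_esc_only=sim["n_esc_only"],
        frac_brg1_bound=sim["frac_brg1_bound"],
        delta_bound=sim["delta_bound"],
        seed=seed,
        frac_brg1_bound_static=sim["frac_brg1_bound_static"],
        base_enrichment=sim["base_enrichment"],
        n_polycomb=sim["n_polycomb"],
        k27me3_enrichment=sim["k27me3_enrichment"],
        ko_decay=sim["ko_decay"],
    )
    params = _chip_params(sim, seed)
    rna_params = SimulationParams(
        bin_size=sim["bin_size"],
        read_depth=sim["rna_depth"],
        rna_dispersion=sim["rna_dispersion"],
        seed=seed,
    )
    nrep = sim["n_replicates"]
    track_plan = (
        [("h3k27ac", "ctrl", r) for r in range(1, nrep + 1)]
        + [("h3k27ac", "ko", r) for r in range(1, nrep + 1)]
        + [("h3k27ac", "esc", 1)]
        + [("brg1", "ctrl", r) for r in range(1, nrep + 1)]
        + [("h3k27me3", "ctrl", 1), ("h3k27me3", "ko", 1)]
        + [("suz12", "ctrl", 1), ("suz12", "ko", 1)]
        + [("input", "ctrl", 1)]
    )
    tracks = {
        key: simulate_chip_track(truth, key[0], key[1], key[2], params)
        for key in track_plan
    }
    counts = {
        (cond, r): simulate_rnaseq_counts(truth, genes, cond, r, rna_params)
        for cond in RNA_CONDITIONS
        for r in range(1, nrep + 1)
    }
    return Dataset(genome, genes, truth, tracks, counts)


def pool_tracks(tracks: list[BinnedCoverage]) -> BinnedCoverage:
    out = BinnedCoverage(tracks[0].genome, tracks[0].bin_size)
    for t in tracks:
        for chrom, v in t.counts.items():
            out.counts[chrom] = out.counts[chrom] + v
    return out


@dataclass
class IntegrationResult:
    ko_table: pd.DataFrame
    induction_table: pd.DataFrame
    brg1_regions: PeakSet
    k27ac_regions: PeakSet
    esc_regions: PeakSet
    context_counts: dict[str, int]
    enhancer_table: pd.DataFrame
    cohort_medians: dict[str, float]
    enhancer_expression_corr: float
    permutation: object
    hypergeom_p: float
    chisq: tuple[float, int, float]
    super_enhancers: object
    replicate_r2: float
    partition: object
    paired_rank: tuple[float, float]
    dependence: object
    summary: dict = field(default_factory=dict)


def integrate(data: Dataset, cfg: dict) -> IntegrationResult:
    pc = cfg["peak_calling"]
    ex = cfg["expression"]
    en = cfg["enhancers"]
    st = cfg["stats"]
    de = cfg["density"]
    genome, genes = data.genome, data.genes
    nrep = cfg["simulation"]["n_replicates"]

    # ---- expression ------------------------------------------------------
    rpkm = pd.DataFrame(
        {
            cond: expr_mod.compute_rpkm(
                {
                    g: sum(data.counts[(cond, r)].get(g, 0) for r in range(1, nrep + 1))
                    for g in (gg.gene_id for gg in genes)
                },
                genes,
            )
            for cond in RNA_CONDITIONS
        }
    )
    expressed = expr_mod.filter_expressed(rpkm, floor=ex["rpkm_floor"])

    def _reps(cond):
        return [
            {g: data.counts[(cond, r)].get(g, 0) for g in expressed}
            for r in range(1, nrep + 1)
        ]

    ko_table = expr_mod.differential_expression(
        _reps("day4_ctrl"), _reps("day4_ko"),
        fdr=ex["fdr"], min_fold=ex["min_fold"], method=ex["method"],
    )
    induction_table = expr_mod.differential_expression(
        _reps("day2"), _reps("day4_ctrl"),
        fdr=ex["fdr"], min_fold=ex["min_fold"], method=ex["method"],
    )
    dependence = expr_mod.dependence_overlap(induction_table, ko_table)

    # ---- peak calling ----------------------------------------------------
    params = PeakCallingParams(
        window_size=pc["window_size"], step=pc["step"],
        q_threshold=pc["q_threshold"], merge_gap=pc["merge_gap"],
        duplicate_cap=pc["duplicate_cap"],
    )
    inp = data.tracks[("input", "ctrl", 1)]
    brg1_reps = [
        call_enriched_regions(data.tracks[("brg1", "ctrl", r)], inp, params)
        for r in range(1, nrep + 1)
    ]
    brg1_regions = (
        intersect_replicates(brg1_reps[0], brg1_reps[1])
        if len(brg1_reps) > 1 else brg1_reps[0]
    )
    k27ac_reps = [
        call_enriched_regions(data.tracks[("h3k27ac", "ctrl", r)], inp, params)
        for r in range(1, nrep + 1)
    ]
    k27ac_regions = (
        intersect_replicates(k27ac_reps[0], k27ac_reps[1])
        if len(k27ac_reps) > 1 else k27ac_reps[0]
    )
    esc_regions = call_enriched_regions(
        data.tracks[("h3k27ac", "esc", 1)], inp, params
    )
    _, context_counts = annotate_genomic_context(brg1_regions.intervals(), genes)
    replicate_r2 = float("nan")
    if len(brg1_reps) > 1 and len(k27ac_regions) >= 3:
        _, replicate_r2 = signal_correlation(
            data.tracks[("brg1", "ctrl", 1)],
            data.tracks[("brg1", "ctrl", 2)],
            k27ac_regions.intervals(),
        )

    # ---- enhancer dynamics ----------------------------------------------
    enh_table, _prox = enh_mod.predict_enhancers(
        k27ac_regions, genes, cutoff=en["distal_cutoff"]
    )
    enh_table["dynamics"] = enh_mod.classify_dynamics(
        enh_table, esc_regions.intervals()
    )
    enh_table["brg1_bound"] = enh_mod.flag_brg1_bound(
        enh_table, brg1_regions.intervals()
    )
    ctrl_ac = pool_tracks(
        [data.tracks[("h3k27ac", "ctrl", r)] for r in range(1, nrep + 1)]
    )
    ko_ac = pool_tracks(
        [data.tracks[("h3k27ac", "ko", r)] for r in range(1, nrep + 1)]
    )
    enh_table, _ = enh_mod.assign_nearest_gene(enh_table, genes, ko_table)
    down_genes = set(ko_table.index[ko_table["status"] == "down"])
    enh_table["near_downregulated"] = enh_table["nearest_gene"].isin(down_genes)
    enh_table, cohort_medians = enh_mod.differential_acetylation(
        enh_table, ctrl_ac, ko_ac, pseudocount=en["pseudocount"]
    )
    enh_table, expr_corr = enh_mod.assign_nearest_gene(enh_table, genes, ko_table)

    # ---- region statistics ----------------------------------------------
    from .intervals import partition_by_tss_distance

    _, brg1_distal = partition_by_tss_distance(
        brg1_regions.intervals(), genes, cutoff=en["distal_cutoff"]
    )
    enh_ivs = enh_mod.frame_to_intervals(enh_table, genome)
    permutation = permutation_overlap_test(
        brg1_distal, enh_ivs, genome,
        n_perm=st["n_perm"], seed=cfg["seed"] + st["perm_seed_offset"],
    )
    n_enh = len(enh_table)
    bound = enh_table["brg1_bound"].astype(bool)
    near_down = enh_table["near_downregulated"].astype(bool)
    hypergeom_p = (
        hypergeometric_enrichment(
            int((bound & near_down).sum()), int(near_down.sum()),
            int(bound.sum()), n_enh,
        )
        if n_enh and near_down.any() else float("nan")
    )
    dyn = enh_table["dynamics"]
    table2x2 = [
        [int(((dyn == "activated") & bound).sum()),
         int(((dyn == "activated") & ~bound).sum())],
        [int(((dyn == "static") & bound).sum()),
         int(((dyn == "static") & ~bound).sum())],
    ]
    try:
        chisq = chisq_independence(table2x2)
    except Exception:
        chisq = (float("nan"), 1, float("nan"))
    try:
        supers = enh_mod.stitch_super_enhancers(
            k27ac_regions, ctrl_ac, genes,
            enh_mod.SuperEnhancerParams(
                stitch_distance=en["stitch_distance"],
                tss_exclusion=en["tss_exclusion"],
            ),
            input_track=inp,
        )
    except Exception:
        supers = None

    # ---- Polycomb / group I-II ------------------------------------------
    up_genes = [g for g in genes if ko_table.get("status", pd.Series()).get(g.gene_id) == "up"]
    partition = None
    paired = (float("nan"), float("nan"))
    if len(up_genes) >= 4:
        me3_ctrl = data.tracks[("h3k27me3", "ctrl", 1)]
        me3_ko = data.tracks[("h3k27me3", "ko", 1)]
        m_me3 = density_matrix(up_genes, me3_ctrl, "tss", de["flank"], de["n_bins"])
        m_ac = density_matrix(up_genes, ctrl_ac, "tss", de["flank"], de["n_bins"])
        ids = [g.gene_id for g in up_genes]
        try:
            partition = partition_by_density(ids, m_me3, m_ac)
            group1 = [g for g in up_genes if partition.labels[g.gene_id] == "I"]
            if group1:
                m1_ctrl = density_matrix(group1, me3_ctrl, "tss", de["flank"], de["n_bins"])
                m1_ko = density_matrix(group1, me3_ko, "tss", de["flank"], de["n_bins"])
                paired = paired_rank_test(m1_ctrl.row_sums(), m1_ko.row_sums())
        except Exception:
            partition = None

    n_super = int(supers.table["is_super"].sum()) if supers is not None else 0
    summary = {
        "n_genes_expressed": int(len(expressed)),
        "n_ko_down": int((ko_table["status"] == "down").sum()),
        "n_ko_up": int((ko_table["status"] == "up").sum()),
        "n_brg1_regions": len(brg1_regions),
        "n_k27ac_regions": len(k27ac_regions),
        "n_enhancers": n_enh,
        "n_activated": int((dyn == "activated").sum()),
        "n_static": int((dyn == "static").sum()),
        "frac_brg1_distal_overlap_enhancers": permutation.observed,
        "permutation_p": permutation.p,
        "hypergeom_p": hypergeom_p,
        "chisq_p": chisq[2],
        "median_log2fc_all": cohort_medians.get("all", float("nan")),
        "median_log2fc_activated": cohort_medians.get("activated", float("nan")),
        "median_log2fc_static": cohort_medians.get("static", float("nan")),
        "median_log2fc_bound": cohort_medians.get("brg1_bound", float("nan")),
        "median_log2fc_unbound": cohort_medians.get("unbound", float("nan")),
        "enhancer_expression_corr": expr_corr,
        "replicate_r2": replicate_r2,
        "n_super_enhancers": n_super,
        "group1_size": int((partition.labels == "I").sum()) if partition else 0,
        "paired_rank_p": paired[1],
        "context_counts": context_counts,
    }
    return IntegrationResult(
        ko_table=ko_table,
        induction_table=induction_table,
        brg1_regions=brg1_regions,
        k27ac_regions=k27ac_regions,
        esc_regions=esc_regions,
        context_counts=context_counts,
        enhancer_table=enh_table,
        cohort_medians=cohort_medians,
        enhancer_expression_corr=expr_corr,
        permutation=permutation,
        hypergeom_p=hypergeom_p,
        chisq=chisq,
        super_enhancers=supers,
        replicate_r2=replicate_r2,
        partition=partition,
        paired_rank=paired,
        dependence=dependence,
        summary=summary,
    )


def enhancer_dynamics_medians(cfg: dict) -> dict[str, float]:
    """Simulate only the tracks the enhancer-dynamics stages need and
    return the cohort log2FC medians (plus classification accuracy against
    the planted truth). A light-weight path for multi-seed replication
    studies that would not profit from the full integration."""
    sim = cfg["simulation"]
    pc = cfg["peak_calling"]
    en = cfg["enhancers"]
    seed = cfg["seed"]
    genome = make_genome(sim["n_chroms"], sim["chrom_size"], seed)
    genes = make_gene_models(genome, sim["n_genes"], sim["gene_min_spacing"], seed)
    truth = plant_regulatory_landscape(
        genome, genes,
        n_static=sim["n_static"], n_activated=sim["n_activated"],
        n_esc_only=sim["n_esc_only"], frac_brg1_bound=sim["frac_brg1_bound"],
        delta_bound=sim["delta_bound"], seed=seed,
        frac_brg1_bound_static=sim["frac_brg1_bound_static"],
        base_enrichment=sim["base_enrichment"],
        n_polycomb=sim["n_polycomb"],
        k27me3_enrichment=sim["k27me3_enrichment"], ko_decay=sim["ko_decay"],
    )
    params = _chip_params(sim, seed)
    t = {
        key: simulate_chip_track(truth, *key, params)
        for key in [
            ("h3k27ac", "ctrl", 1), ("h3k27ac", "ctrl", 2),
            ("h3k27ac", "ko", 1), ("h3k27ac", "ko", 2),
            ("h3k27ac", "esc", 1),
            ("brg1", "ctrl", 1), ("brg1", "ctrl", 2),
            ("input", "ctrl", 1),
        ]
    }
    pparams = PeakCallingParams(
        window_size=pc["window_size"], step=pc["step"],
        q_threshold=pc["q_threshold"], merge_gap=pc["merge_gap"],
        duplicate_cap=pc["duplicate_cap"],
    )
    inp = t[("input", "ctrl", 1)]
    k27 = intersect_replicates(
        call_enriched_regions(t[("h3k27ac", "ctrl", 1)], inp, pparams),
        call_enriched_regions(t[("h3k27ac", "ctrl", 2)], inp, pparams),
    )
    brg1 = intersect_replicates(
        call_enriched_regions(t[("brg1", "ctrl", 1)], inp, pparams),
        call_enriched_regions(t[("brg1", "ctrl", 2)], inp, pparams),
    )
    esc = call_enriched_regions(t[("h3k27ac", "esc", 1)], inp, pparams)
    enh_table, _ = enh_mod.predict_enhancers(k27, genes, cutoff=en["distal_cutoff"])
    enh_table["dynamics"] = enh_mod.classify_dynamics(enh_table, esc.intervals())
    enh_table["brg1_bound"] = enh_mod.flag_brg1_bound(enh_table, brg1.intervals())
    ctrl_ac = pool_tracks([t[("h3k27ac", "ctrl", 1)], t[("h3k27ac", "ctrl", 2)]])
    ko_ac = pool_tracks([t[("h3k27ac", "ko", 1)], t[("h3k27ac", "ko", 2)]])
    enh_table, medians = enh_mod.differential_acetylation(
        enh_table, ctrl_ac, ko_ac, pseudocount=en["pseudocount"]
    )
    # truth comparison: label accuracy and planted-enhancer recovery
    from .intervals import overlaps_any

    meso_truth = [e for e in truth.enhancers if e.eclass in ("static", "activated")]
    truth_ivs = IntervalSet([e.interval for e in meso_truth], genome,
                            validate_bounds=False)
    flags, recovered = overlaps_any(truth_ivs, enh_mod.frame_to_intervals(enh_table))
    pred_ivs = enh_mod.frame_to_intervals(enh_table)
    correct = 0
    matched = 0
    for i, row in enumerate(enh_table.itertuples()):
        best = None
        for e in meso_truth:
            if e.interval.overlaps(pred_ivs[i]):
                best = e
                break
        if best is not None:
            matched += 1
            if best.eclass == row.dynamics:
                correct += 1
    medians = dict(medians)
    medians["recovery"] = float(recovered)
    medians["label_accuracy"] = correct / matched if matched else float("nan")
    return medians


# ---- disk-backed stages ---------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: dict, files: list[Path]) -> Path:
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def run_simulate(cfg: dict, outdir: str | Path | None = None) -> Path:
    """Simulate and write the full dataset; returns the dataset directory."""
    outdir = Path(outdir or cfg["outdir"]) / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg)
    files: list[Path] = []

    p = outdir / "genome.chrom.sizes"
    data.genome.to_chrom_sizes(p)
    files.append(p)
    p = outdir / "genes.tsv"
    write_gene_table(data.genes, p)
    files.append(p)

    truth = data.truth
    p = outdir / "truth_enhancers.bed"
    with open(p, "w") as fh:
        for e in truth.enhancers:
            iv = e.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{e.base_enrichment:g}\t.\t{e.eclass}\t{int(e.brg1_bound)}\t"
                f"{e.delta:g}\t{e.linked_gene}\n"
            )
    files.append(p)
    p = outdir / "truth_polycomb.tsv"
    with open(p, "w") as fh:
        for pg in truth.polycomb_genes:
            fh.write(f"{pg.gene_id}\t{pg.k27me3_enrichment:g}\t{pg.ko_decay:g}\n")
    files.append(p)
    p = outdir / "truth_effects.tsv"
    with open(p, "w") as fh:
        for gid in sorted(truth.expression_effects):
            eff = truth.expression_effects[gid]
            fh.write(f"{gid}\t{eff.induction:g}\t{eff.ko:g}\n")
    files.append(p)

    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for (mark, cond, rep), cov in data.tracks.items():
        p = tracks_dir / f"{mark}_{cond}_rep{rep}.bedgraph"
        cov.to_bedgraph(p)
        files.append(p)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    for (cond, rep), counts in data.counts.items():
        p = counts_dir / f"{cond}_rep{rep}.tsv"
        expr_mod.write_counts_tsv(counts, p)
        files.append(p)

    _write_manifest(outdir, cfg, files)
    return outdir


def load_dataset(sim_dir: str | Path, cfg: dict) -> Dataset:
    """Read a simulated dataset back from its declared files (truth not
    loaded: the analysis stages must not see it)."""
    sim_dir = Path(sim_dir)
    if not (sim_dir / "genome.chrom.sizes").exists():
        raise StageDependencyError(
            f"missing simulate output in {sim_dir}; run the simulate stage first"
        )
    genome = Genome.from_chrom_sizes(sim_dir / "genome.chrom.sizes")
    genes = read_gene_table(sim_dir / "genes.tsv")
    bin_size = cfg["simulation"]["bin_size"]
    tracks: dict[tuple[str, str, int], BinnedCoverage] = {}
    for p in sorted((sim_dir / "tracks").glob("*.bedgraph")):
        mark, cond, rep = p.stem.rsplit("_", 2)[0], p.stem.split("_")[-2], int(
            p.stem.rsplit("rep", 1)[1]
        )
        tracks[(mark, cond, rep)] = BinnedCoverage.from_bedgraph(p, genome, bin_size)
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for p in sorted((sim_dir / "counts").glob("*.tsv")):
        cond, rep = p.stem.rsplit("_rep", 1)
        counts[(cond, int(rep))] = expr_mod.read_counts_tsv(p)
    return Dataset(genome, genes, None, tracks, counts)


def run_integrate(cfg: dict, outdir: str | Path | None = None) -> Path:
    """Run every analysis stage on a simulated dataset directory and write
    the integrated tables plus a markdown report."""
    base = Path(outdir or cfg["outdir"])
    data = load_dataset(base / "sim", cfg)
    res = integrate(data, cfg)
    rdir = base / "results"
    rdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def _save(df: pd.DataFrame, name: str) -> None:
        p = rdir / name
        df.to_csv(p, sep="\t")
        files.append(p)

    _save(res.ko_table, "de_ko_vs_ctrl.tsv")
    _save(res.induction_table, "de_day4_vs_day2.tsv")
    _save(res.brg1_regions.to_frame(), "brg1_regions.tsv")
    _save(res.enhancer_table, "enhancers.tsv")
    _save(res.dependence.contingency, "dependence_contingency.tsv")
    if res.super_enhancers is not None:
        _save(res.super_enhancers.table, "super_enhancers.tsv")
    if res.partition is not None:
        _save(res.partition.labels.to_frame(), "gene_groups.tsv")
    _save(pd.Series(res.cohort_medians, name="median_log2fc").to_frame(),
          "cohort_medians.tsv")

    p = rdir / "summary.json"
    with open(p, "w") as fh:
        json.dump(res.summary, fh, indent=2, sort_keys=True, default=float)
    files.append(p)
    p = rdir / "report.md"
    with open(p, "w") as fh:
        fh.write(render_report(res))
    files.append(p)
    _write_manifest(rdir, cfg, files)
    return rdir


def render_report(res: IntegrationResult) -> str:
    s = res.summary
    lines = [
        "# Integrated chromatin-dynamics report",
        "",
        "## Differential expression",
        f"- expressed genes: {s['n_genes_expressed']}",
        f"- knockout: {s['n_ko_down']} down, {s['n_ko_up']} up "
        "(FDR <= 1%, fold >= 2)",
        "",
        "## Remodeler-bound regions",
        f"- high-confidence regions (both replicates): {s['n_brg1_regions']}",
        f"- genomic context: {s['context_counts']}",
        f"- replicate signal correlation r^2 = {s['replicate_r2']:.3f}",
        "",
        "## Enhancers",
        f"- putative distal enhancers: {s['n_enhancers']} "
        f"({s['n_activated']} activated, {s['n_static']} static)",
        f"- distal remodeler regions overlapping enhancers: "
        f"{s['frac_brg1_distal_overlap_enhancers']:.3f} "
        f"(permutation p = {s['permutation_p']:.3g})",
        f"- H3K27ac log2FC medians: all {s['median_log2fc_all']:.3f}, "
        f"activated {s['median_log2fc_activated']:.3f}, "
        f"static {s['median_log2fc_static']:.3f}, "
        f"bound {s['median_log2fc_bound']:.3f}, "
        f"unbound {s['median_log2fc_unbound']:.3f}",
        f"- enhancer/expression log2FC correlation r = "
        f"{s['enhancer_expression_corr']:.3f}",
        f"- bound-enhancer enrichment near downregulated genes: "
        f"hypergeometric p = {s['hypergeom_p']:.3g}",
        f"- activated-vs-static remodeler occupancy: chi-squared p = "
        f"{s['chisq_p']:.3g}",
        f"- super-enhancers: {s['n_super_enhancers']}",
        "",
        "## Polycomb domains",
        f"- group I (high H3K27me3) genes among derepressed: {s['group1_size']}",
        f"- control vs knockout H3K27me3 at group I promoters: paired "
        f"rank p = {s['paired_rank_p']:.3g}",
        "",
    ]
    return "\n".join(lines)
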