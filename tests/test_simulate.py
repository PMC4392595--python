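"""Generator: genome/gene placement, planted landscape, track statistics."""
import numpy as np
import pytest

from chromdyn.errors import CapacityError, InvalidParameterError
from chromdyn.intervals import IntervalSet, distance_to_nearest_tss
from chromdyn.simulate import (
    SimulationParams,
    make_gene_models,
    make_genome,
    plant_regulatory_landscape,
    simulate_chip_track,
    simulate_rnaseq_counts,
)


class TestMakeGenome:
    def test_total_size_and_names(self):
        g = make_genome(3, 10_000_000, seed=1)
        assert g.total_size == 30_000_000
        assert g.chrom_names == ("chr1", "chr2", "chr3")

    def test_minimal_case(self):
        g = make_genome(1, 100_000, seed=7)
        assert g.chrom_sizes == (100_000,)

    def test_deterministic(self):
        assert make_genome(2, 200_000, seed=1) == make_genome(2, 200_000, seed=1)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            make_genome(0, 100_000, 1)
        with pytest.raises(InvalidParameterError):
            make_genome(1, 10_000, 1)


class TestMakeGeneModels:
    def test_spacing_respected_by_scan(self):
        g = make_genome(3, 10_000_000, seed=1)
        genes = make_gene_models(g, 2000, 5000, seed=1)
        assert len(genes) == 2000
        by_chrom: dict[str, list[int]] = {}
        for gene in genes:
            by_chrom.setdefault(gene.chrom, []).append(gene.tss)
        for tsss in by_chrom.values():
            tsss.sort()
            assert all(b - a >= 5000 for a, b in zip(tsss, tsss[1:]))

    def test_single_gene_and_empty(self):
        g = make_genome(1, 100_000, seed=1)
        assert len(make_gene_models(g, 1, 0, seed=1)) == 1
        assert make_gene_models(g, 0, 0, seed=1) == []

    def test_infeasible_packing_raises(self):
        g = make_genome(1, 100_000, seed=1)
        with pytest.raises(CapacityError):
            make_gene_models(g, 50, 60_000, seed=1)

    def test_tss_matches_strand_convention(self):
        g = make_genome(1, 2_000_000, seed=2)
        for gene in make_gene_models(g, 50, 5000, seed=2):
            if gene.strand == "+":
                assert gene.tss == gene.exons[0][0]
            else:
                assert gene.tss == gene.exons[-1][1]


class TestPlantLandscape:
    def test_counts_by_class_and_flag(self, small_genome, toy_genes):
        truth = plant_regulatory_landscape(
            small_genome, toy_genes, 200, 200, 50, 0.5, 0.5, seed=1,
            frac_brg1_bound_static=0.5,
        )
        assert len(truth.enhancers) == 450
        activated = [e for e in truth.enhancers if e.eclass == "activated"]
        assert len(activated) == 200
        bound_act = [e for e in activated if e.brg1_bound]
        # Bernoulli(0.5) draws over 200 activated enhancers
        assert 70 <= len(bound_act) <= 130
        assert all(e.delta == 0.5 for e in bound_act)
        assert all(e.delta == 1.0 for e in activated if not e.brg1_bound)

    def test_no_bound_flags_when_fraction_zero(self, small_genome, toy_genes):
        truth = plant_regulatory_landscape(
            small_genome, toy_genes, 20, 20, 5, 0.0, 0.5, seed=1,
            frac_brg1_bound_static=0.0,
        )
        assert not any(e.brg1_bound for e in truth.enhancers)
        assert all(e.delta == 1.0 for e in truth.enhancers)

    def test_no_activated_class_when_zero(self, small_genome, toy_genes):
        truth = plant_regulatory_landscape(
            small_genome, toy_genes, 20, 0, 5, 0.5, 0.5, seed=1
        )
        assert not any(e.eclass == "activated" for e in truth.enhancers)

    def test_enhancers_distal_and_disjoint(self, toy_truth, toy_genes):
        ivs = IntervalSet([e.interval for e in toy_truth.enhancers])
        for d, _ in distance_to_nearest_tss(ivs, toy_genes):
            assert d > 2500
        s = sorted(ivs, key=lambda v: (v.chrom, v.start))
        for a, b in zip(s, s[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_linked_genes_exist(self, toy_truth, toy_genes):
        ids = {g.gene_id for g in toy_genes}
        for e in toy_truth.enhancers:
            if e.eclass in ("static", "activated"):
                assert e.linked_gene in ids

    def test_delta_only_on_bound_activated(self, toy_truth):
        for e in toy_truth.enhancers:
            if not (e.brg1_bound and e.eclass == "activated"):
                assert e.delta == 1.0

    def test_invalid_delta(self, small_genome, toy_genes):
        with pytest.raises(InvalidParameterError):
            plant_regulatory_landscape(
                small_genome, toy_genes, 5, 5, 0, 0.5, 0.0, seed=1
            )


class TestChipTracks:
    def test_input_track_mean_matches_background(self, toy_truth, sim_params):
        cov = simulate_chip_track(toy_truth, "input", "ctrl", 1, sim_params)
        genome = toy_truth.genome
        expected_rate = sim_params.read_depth / genome.total_size
        mean_bin = cov.library_size / sum(len(v) for v in cov.counts.values())
        assert mean_bin == pytest.approx(expected_rate * sim_params.bin_size, rel=0.02)

    def test_total_depth_within_tolerance(self, toy_truth, sim_params):
        for mark, cond in [("h3k27ac", "ctrl"), ("h3k27me3", "ko"), ("brg1", "ctrl")]:
            cov = simulate_chip_track(toy_truth, mark, cond, 1, sim_params)
            assert abs(cov.library_size - sim_params.read_depth) < 0.05 * sim_params.read_depth

    def test_deterministic_given_seed(self, toy_truth, sim_params):
        a = simulate_chip_track(toy_truth, "h3k27ac", "ctrl", 1, sim_params)
        b = simulate_chip_track(toy_truth, "h3k27ac", "ctrl", 1, sim_params)
        assert all(np.array_equal(a.counts[c], b.counts[c]) for c in a.counts)

    def test_replicates_differ(self, toy_truth, sim_params):
        a = simulate_chip_track(toy_truth, "h3k27ac", "ctrl", 1, sim_params)
        b = simulate_chip_track(toy_truth, "h3k27ac", "ctrl", 2, sim_params)
        assert any(not np.array_equal(a.counts[c], b.counts[c]) for c in a.counts)

    def test_unknown_mark_and_condition(self, toy_truth, sim_params):
        with pytest.raises(InvalidParameterError):
            simulate_chip_track(toy_truth, "h3k9me3", "ctrl", 1, sim_params)
        with pytest.raises(InvalidParameterError):
            simulate_chip_track(toy_truth, "h3k27me3", "esc", 1, sim_params)

    @staticmethod
    def _enhancer_signal(truth, cov, enhancer, params):
        iv = enhancer.interval
        mid = iv.midpoint
        lo, hi = mid - params.peak_halfwidth, mid + params.peak_halfwidth
        raw = float(cov.window_sums(iv.chrom, [lo], [hi])[0])
        bg = cov.library_size / truth.genome.total_size * (hi - lo)
        return raw - bg

    def test_activated_enhancer_silent_in_esc(self, toy_truth, sim_params):
        esc = simulate_chip_track(toy_truth, "h3k27ac", "esc", 1, sim_params)
        genome = toy_truth.genome
        for e in toy_truth.enhancers:
            if e.eclass != "activated":
                continue
            iv = e.interval
            count = float(esc.window_sums(iv.chrom, [iv.start], [iv.end])[0])
            bg = esc.library_size / genome.total_size * len(iv)
            # background level: within 6 sd of the Poisson expectation
            assert count < bg + 6 * np.sqrt(bg)

    def test_ko_enrichment_scales_with_delta(self, toy_truth, sim_params):
        ctrl = simulate_chip_track(toy_truth, "h3k27ac", "ctrl", 1, sim_params)
        ko = simulate_chip_track(toy_truth, "h3k27ac", "ko", 1, sim_params)
        bound = [
            e for e in toy_truth.enhancers
            if e.eclass == "activated" and e.brg1_bound
        ]
        assert bound
        sig_ctrl = sum(self._enhancer_signal(toy_truth, ctrl, e, sim_params) for e in bound)
        sig_ko = sum(self._enhancer_signal(toy_truth, ko, e, sim_params) for e in bound)
        assert sig_ko / sig_ctrl == pytest.approx(0.5, abs=0.12)


class TestRnaCounts:
    def test_induction_effect_on_mean(self, toy_truth, toy_genes):
        induced = [
            gid for gid, eff in toy_truth.expression_effects.items()
            if eff.induction == 2.0
        ]
        assert induced
        means = {"day2": 0.0, "day4_ctrl": 0.0}
        n_mc = 200
        for cond in means:
            tot = 0.0
            for rep in range(n_mc):
                params = SimulationParams(read_depth=1_000_000, seed=rep)
                counts = simulate_rnaseq_counts(toy_truth, toy_genes, cond, 1, params)
                tot += sum(counts[g] for g in induced)
            means[cond] = tot / n_mc
        assert means["day4_ctrl"] / means["day2"] == pytest.approx(4.0, rel=0.1)

    def test_zero_effects_share_means(self, small_genome, toy_genes):
        truth = plant_regulatory_landscape(
            small_genome, toy_genes, 0, 0, 0, 0.0, 1.0, seed=1,
            n_polycomb=0, n_repressed_genes=0, n_nonpolycomb_up=0,
        )
        assert not truth.expression_effects
        p = SimulationParams(read_depth=1_000_000, seed=3)
        a = simulate_rnaseq_counts(truth, toy_genes, "day2", 1, p)
        b = simulate_rnaseq_counts(truth, toy_genes, "day4_ko", 1, p)
        ta, tb = sum(a.values()), sum(b.values())
        assert abs(ta - tb) < 0.1 * ta

    def test_depth_scaling(self, toy_truth, toy_genes):
        p1 = SimulationParams(read_depth=500_000, seed=3)
        p2 = SimulationParams(read_depth=1_000_000, seed=3)
        c1 = simulate_rnaseq_counts(toy_truth, toy_genes, "day2", 1, p1)
        c2 = simulate_rnaseq_counts(toy_truth, toy_genes, "day2", 1, p2)
        assert sum(c2.values()) / sum(c1.values()) == pytest.approx(2.0, rel=0.05)

    def test_deterministic(self, toy_truth, toy_genes, sim_params):
        a = simulate_rnaseq_counts(toy_truth, toy_genes, "day2", 1, sim_params)
        b = simulate_rnaseq_counts(toy_truth, toy_genes, "day2", 1, sim_params)
        assert a == b

    def test_invalid_condition(self, toy_truth, toy_genes, sim_params):
        with pytest.raises(InvalidParameterError):
            simulate_rnaseq_counts(toy_truth, toy_genes, "day3", 1, sim_params)
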