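"""Synthetic chromatin landscapes with planted ground truth.

The generator builds a toy genome, gene models, and a planted regulatory
landscape, then emits ChIP/input coverage tracks and RNA-seq counts whose
statistical structure matches what the downstream analysis assumes:

* ChIP tracks are Poisson counts over a uniform background plus triangular
  enrichment kernels at planted features. An enhancer's ``base_enrichment``
  is its mean fold-enrichment over background across its own footprint.
* Enhancers come in three dynamics classes — ``static`` (acetylated in both
  the precursor and the differentiated state), ``activated`` (acetylated
  only after differentiation), and ``esc_only`` (precursor-specific).
  Remodeler-bound activated enhancers lose acetylation in the knockout by a
  multiplicative factor ``delta`` in (0, 1].
* Polycomb-marked genes carry broad H3K27me3/Suz12 promoter domains whose
  knockout signal decays by ``ko_decay``; their expression is derepressed.
* RNA-seq counts are negative binomial around baseline means modulated by
  per-gene induction and knockout log2 effects tied to the enhancer truth.

Everything is deterministic given the master seed: per-track generators are
spawned from ``numpy.random.SeedSequence(seed, spawn_key=...)`` with a fixed
track-id table, so each track is reproducible and independent of the others.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coverage import BinnedCoverage
from .errors import CapacityError, InvalidParameterError
from .genome import GeneModel, Genome
from .intervals import GenomicInterval, IntervalSet, _allowed_segments

MARKS = ("h3k27ac", "h3k27me3", "brg1", "suz12", "input")
CHIP_CONDITIONS = ("ctrl", "ko", "esc")
RNA_CONDITIONS = ("day2", "day4_ctrl", "day4_ko")

# which conditions exist per mark: ESC state is simulated only for H3K27ac
# (needed to classify static vs activated enhancers) and for input
_MARK_CONDITIONS = {
    "h3k27ac": ("ctrl", "ko", "esc"),
    "h3k27me3": ("ctrl", "ko"),
    "brg1": ("ctrl", "ko"),
    "suz12": ("ctrl", "ko"),
    "input": ("ctrl", "ko", "esc"),
}

_PROMOTER_FOLD = 6.0  # H3K27ac fold at acetylated promoters
_PROMOTER_HALFWIDTH = 750
_POLYCOMB_HALFWIDTH = 2000
_SUZ12_SCALE = 0.6  # Suz12 enrichment relative to H3K27me3
_KO_BRG1_RESIDUAL = 0.1  # Brg1 signal remaining after its own deletion


@dataclass
class SimulationParams:
    """Knobs of the track and count simulators.

    ``background_rate`` (reads/bp) may be ``None``, in which case it is
    derived so that background plus planted kernels integrate to
    ``read_depth``; when given explicitly the whole rate field is rescaled
    to the requested depth instead.
    """

    bin_size: int = 25
    read_depth: int = 1_000_000
    background_rate: float | None = None
    peak_halfwidth: int = 500
    rna_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.read_depth <= 0 or self.peak_halfwidth <= 0:
            raise InvalidParameterError("bin_size, read_depth, peak_halfwidth must be positive")
        if self.background_rate is not None and self.background_rate <= 0:
            raise InvalidParameterError("background_rate must be positive")
        if self.rna_dispersion < 0:
            raise InvalidParameterError("rna_dispersion must be non-negative")


@dataclass
class Enhancer:
    interval: GenomicInterval
    eclass: str  # static | activated | esc_only
    brg1_bound: bool
    base_enrichment: float
    delta: float  # multiplier on KO H3K27ac; 1 = no remodeler dependence
    linked_gene: str


@dataclass
class PolycombGene:
    gene_id: str
    k27me3_enrichment: float
    ko_decay: float


@dataclass
class ExpressionEffect:
    induction: float = 0.0  # log2FC day4_ctrl vs day2
    ko: float = 0.0  # additional log2FC day4_ko vs day4_ctrl


@dataclass
class RegulatoryTruth:
    genome: Genome
    genes: list[GeneModel]
    enhancers: list[Enhancer]
    polycomb_genes: list[PolycombGene]
    expression_effects: dict[str, ExpressionEffect]
    promoter_acetylated: set[str] = field(default_factory=set)

    def enhancer_set(self, eclass: str | None = None) -> IntervalSet:
        ivs = [
            e.interval
            for e in self.enhancers
            if eclass is None or e.eclass == eclass
        ]
        return IntervalSet(ivs, self.genome, validate_bounds=False)


def make_genome(n_chroms: int, size_bp: int, seed: int = 0) -> Genome:
    """Equal-sized toy chromosomes chr1..chrN."""
    if n_chroms < 1 or size_bp < 10**5:
        raise InvalidParameterError("need n_chroms >= 1 and size_bp >= 1e5")
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    return Genome(names, tuple(int(size_bp) for _ in range(n_chroms)))


_MAX_GENE_SPAN = 8000


def make_gene_models(
    genome: Genome, n_genes: int, min_spacing: int, seed: int = 0
) -> list[GeneModel]:
    """Place genes with pairwise TSS spacing >= ``min_spacing``.

    Gene bodies (up to ~8 kb) are laid out left-to-right; the TSS sits at
    the left span edge for + genes and the right edge for − genes, so
    placement enforces spacing on the whole span to guarantee the TSS
    spacing regardless of strand.
    """
    if n_genes < 0 or min_spacing < 0:
        raise InvalidParameterError("n_genes and min_spacing must be non-negative")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    eff = min_spacing + _MAX_GENE_SPAN
    total = genome.total_size
    if n_genes * min_spacing > total:
        raise CapacityError(
            f"cannot place {n_genes} genes with {min_spacing} bp spacing "
            f"in a {total} bp genome"
        )
    # allocate genes to chromosomes proportional to size
    sizes = np.array(genome.chrom_sizes, dtype=float)
    alloc = np.floor(sizes / total * n_genes).astype(int)
    for i in np.argsort(-sizes):
        if alloc.sum() >= n_genes:
            break
        alloc[i] += n_genes - alloc.sum()
    genes: list[GeneModel] = []
    gid = 0
    ndigits = max(4, len(str(n_genes)))
    for chrom, size, n_c in zip(genome.chrom_names, genome.chrom_sizes, alloc):
        if n_c == 0:
            continue
        slack = size - _MAX_GENE_SPAN - n_c * eff
        if slack < 0:
            raise CapacityError(
                f"{chrom}: cannot fit {n_c} genes with spacing {min_spacing}"
            )
        offsets = np.sort(rng.uniform(0, slack, size=n_c))
        starts = (offsets + np.arange(n_c) * eff).astype(int)
        for pos in starts:
            n_ex = int(rng.integers(1, 5))
            ex_lens = rng.integers(200, 1200, size=n_ex)
            intron_lens = rng.integers(500, 2000, size=max(0, n_ex - 1))
            span = int(ex_lens.sum() + intron_lens.sum())
            if span > _MAX_GENE_SPAN:  # trim to the placement guarantee
                ex_lens = np.maximum(200, ex_lens * _MAX_GENE_SPAN // (2 * span))
                intron_lens = np.maximum(500, intron_lens * _MAX_GENE_SPAN // (2 * span))
            exons = []
            cur = int(pos)
            for k, el in enumerate(ex_lens):
                exons.append((cur, cur + int(el)))
                cur += int(el)
                if k < len(intron_lens):
                    cur += int(intron_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            tss = exons[0][0] if strand == "+" else exons[-1][1]
            baseline = float(np.exp(rng.normal(math.log(50.0), 1.0)))
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:0{ndigits}d}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    exons=exons,
                    baseline_mean=baseline,
                )
            )
            gid += 1
    return genes


def plant_regulatory_landscape(
    genome: Genome,
    genes: list[GeneModel],
    n_static: int = 150,
    n_activated: int = 150,
    n_esc_only: int = 50,
    frac_brg1_bound: float = 0.8,
    delta_bound: float = 0.5,
    seed: int = 0,
    *,
    frac_brg1_bound_static: float | None = 0.2,
    base_enrichment: float = 30.0,
    width_range: tuple[int, int] = (400, 1500),
    enhancer_spacing: int = 2000,
    tss_clearance: int = 2500,
    n_polycomb: int = 50,
    k27me3_enrichment: float = 10.0,
    ko_decay: float = 0.5,
    n_repressed_genes: int = 100,
    frac_repressed_dependent: float = 0.02,
    n_nonpolycomb_up: int = 30,
    induction_lfc: float = 2.0,
) -> RegulatoryTruth:
    """Plant enhancers, Polycomb domains and linked expression effects.

    Enhancers are placed strictly more than ``tss_clearance`` bp from every
    TSS (so they are distal by the promoter-window definition) and at least
    ``enhancer_spacing`` bp apart. Remodeler-binding flags are drawn for the
    given fraction of activated enhancers and, separately, of static
    enhancers (``frac_brg1_bound_static``, defaulting lower to encode the
    enrichment of remodeler binding at dynamically activated elements);
    precursor-specific enhancers are never bound. Bound activated enhancers
    receive ``delta = delta_bound``; everything else keeps ``delta = 1``.

    A gene linked to a remodeler-dependent activated enhancer is induced by
    ``induction_lfc`` during differentiation and loses that induction in
    the knockout: its KO effect is ``-2 * (1 - delta) * induction_lfc``.
    """
    if not 0 < delta_bound <= 1:
        raise InvalidParameterError("delta_bound must be in (0, 1]")
    if not 0 <= frac_brg1_bound <= 1:
        raise InvalidParameterError("frac_brg1_bound must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if frac_brg1_bound_static is None:
        frac_brg1_bound_static = frac_brg1_bound

    # exclusion zones: promoter windows (slightly widened so that the
    # strict ">2.5 kb distal" criterion holds at the boundary) plus
    # already-placed enhancers with their spacing buffer
    exclusions: dict[str, list[GenomicInterval]] = {c: [] for c in genome.chrom_names}
    for g in genes:
        lo = max(0, g.tss - tss_clearance - 1)
        hi = min(genome.size_of(g.chrom), g.tss + tss_clearance + 2)
        exclusions[g.chrom].append(GenomicInterval(g.chrom, lo, hi))

    sizes = np.array(genome.chrom_sizes, dtype=float)
    placed: list[tuple[GenomicInterval, str]] = []
    classes = ["static"] * n_static + ["activated"] * n_activated + ["esc_only"] * n_esc_only
    for eclass in classes:
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        order = rng.permutation(len(genome.chrom_names))
        # try chromosomes in random order, largest-capacity first fallback
        start = None
        for ci in order:
            chrom = genome.chrom_names[ci]
            segs = _allowed_segments(
                int(sizes[ci]), width, sorted(exclusions[chrom], key=lambda iv: iv.start)
            )
            if not segs:
                continue
            seg_sizes = np.array([e - s for s, e in segs])
            pos = int(rng.integers(seg_sizes.sum()))
            for (s, _), sz in zip(segs, seg_sizes):
                if pos < sz:
                    start = s + pos
                    break
                pos -= int(sz)
            break
        if start is None:
            raise CapacityError("cannot place a distal enhancer; genome too gene-dense")
        iv = GenomicInterval(chrom, start, start + width)
        placed.append((iv, eclass))
        buf_lo = max(0, start - enhancer_spacing)
        buf_hi = min(genome.size_of(chrom), start + width + enhancer_spacing)
        exclusions[chrom].append(GenomicInterval(chrom, buf_lo, buf_hi))

    from .intervals import distance_to_nearest_tss  # local to avoid cycle at import

    iv_set = IntervalSet([iv for iv, _ in placed], genome, validate_bounds=False)
    nearest = distance_to_nearest_tss(iv_set, genes) if genes else [(0, "")] * len(placed)

    enhancers: list[Enhancer] = []
    for k, ((iv, eclass), (_, gid)) in enumerate(zip(placed, nearest)):
        if eclass == "activated":
            bound = bool(rng.random() < frac_brg1_bound)
        elif eclass == "static":
            bound = bool(rng.random() < frac_brg1_bound_static)
        else:
            bound = False
        delta = delta_bound if (bound and eclass == "activated") else 1.0
        iv.name = f"enh{k:05d}_{eclass}"
        enhancers.append(
            Enhancer(iv, eclass, bound, float(base_enrichment), float(delta), gid)
        )

    # expression effects tied to the enhancer truth
    effects: dict[str, ExpressionEffect] = {}
    for e in enhancers:
        if e.eclass != "activated" or not e.linked_gene:
            continue
        eff = effects.setdefault(e.linked_gene, ExpressionEffect())
        eff.induction = induction_lfc
        ko = -2.0 * (1.0 - e.delta) * induction_lfc
        eff.ko = min(eff.ko, ko)

    unused = [g.gene_id for g in genes if g.gene_id not in effects]
    rng.shuffle(unused)
    take = lambda n: [unused.pop() for _ in range(min(n, len(unused)))]

    for gid in take(n_repressed_genes):
        dep = rng.random() < frac_repressed_dependent
        ko = -2.0 * (1.0 - delta_bound) * induction_lfc if dep else 0.0
        effects[gid] = ExpressionEffect(induction=-induction_lfc, ko=ko)

    polycomb: list[PolycombGene] = []
    for gid in take(n_polycomb):
        polycomb.append(PolycombGene(gid, float(k27me3_enrichment), float(ko_decay)))
        effects[gid] = ExpressionEffect(induction=0.0, ko=4.0 * (1.0 - ko_decay))

    nonpoly_up = set(take(n_nonpolycomb_up))
    for gid in nonpoly_up:
        effects[gid] = ExpressionEffect(induction=0.0, ko=2.0)

    # acetylated promoters: the more-expressed half of non-Polycomb genes,
    # plus every non-Polycomb derepressed gene (group II analogue)
    poly_ids = {p.gene_id for p in polycomb}
    nonpoly = [g for g in genes if g.gene_id not in poly_ids]
    if nonpoly:
        med = float(np.median([g.baseline_mean for g in nonpoly]))
        promoter_ac = {g.gene_id for g in nonpoly if g.baseline_mean >= med}
    else:
        promoter_ac = set()
    promoter_ac |= nonpoly_up

    return RegulatoryTruth(
        genome=genome,
        genes=genes,
        enhancers=enhancers,
        polycomb_genes=polycomb,
        expression_effects=effects,
        promoter_acetylated=promoter_ac,
    )


def _track_rng(params: SimulationParams, mark: str, condition: str, replicate: int
               ) -> np.random.Generator:
    key = (MARKS.index(mark), CHIP_CONDITIONS.index(condition), int(replicate))
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=key))


def _triangle_weights(summit: int, halfwidth: int, bin_size: int, n_bins: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Bin indices and weights (summing to 1) of a triangular kernel."""
    lo = max(0, (summit - halfwidth) // bin_size)
    hi = min(n_bins - 1, (summit + halfwidth) // bin_size)
    idx = np.arange(lo, hi + 1)
    centers = idx * bin_size + bin_size / 2.0
    w = np.maximum(0.0, 1.0 - np.abs(centers - summit) / halfwidth)
    total = w.sum()
    if total <= 0:  # kernel narrower than a bin: all mass in the summit bin
        idx = np.array([min(n_bins - 1, summit // bin_size)])
        w = np.array([1.0])
        total = 1.0
    return idx, w / total


def _planted_kernels(
    truth: RegulatoryTruth, mark: str, condition: str, params: SimulationParams
) -> list[tuple[str, int, int, float]]:
    """(chrom, summit, halfwidth, mass-per-unit-background) kernels.

    The mass unit is ``(fold - 1) * width`` bp of background-equivalent
    signal, so multiplying by the background rate yields expected reads.
    """
    kernels: list[tuple[str, int, int, float]] = []
    gene_by_id = {g.gene_id: g for g in truth.genes}

    def enhancer_scale(e: Enhancer) -> float:
        if mark == "h3k27ac":
            present = {
                "static": ("ctrl", "ko", "esc"),
                "activated": ("ctrl", "ko"),
                "esc_only": ("esc",),
            }[e.eclass]
            if condition not in present:
                return 0.0
            if condition == "ko" and e.eclass == "activated":
                return e.delta
            return 1.0
        if mark == "brg1":
            if not e.brg1_bound:
                return 0.0
            return _KO_BRG1_RESIDUAL if condition == "ko" else 1.0
        return 0.0

    if mark in ("h3k27ac", "brg1"):
        for e in truth.enhancers:
            scale = enhancer_scale(e)
            if scale <= 0:
                continue
            w = len(e.interval)
            mass = (e.base_enrichment - 1.0) * w * scale
            kernels.append(
                (e.interval.chrom, e.interval.midpoint, params.peak_halfwidth, mass)
            )
    if mark == "h3k27ac":
        for gid in truth.promoter_acetylated:
            g = gene_by_id.get(gid)
            if g is None:
                continue
            w = 2 * _PROMOTER_HALFWIDTH
            mass = (_PROMOTER_FOLD - 1.0) * w
            kernels.append((g.chrom, g.tss, _PROMOTER_HALFWIDTH, mass))
    if mark in ("h3k27me3", "suz12"):
        scale_mark = _SUZ12_SCALE if mark == "suz12" else 1.0
        for p in truth.polycomb_genes:
            g = gene_by_id.get(p.gene_id)
            if g is None:
                continue
            decay = p.ko_decay if condition == "ko" else 1.0
            w = 2 * _POLYCOMB_HALFWIDTH
            mass = (p.k27me3_enrichment - 1.0) * w * scale_mark * decay
            kernels.append((g.chrom, g.tss, _POLYCOMB_HALFWIDTH, mass))
    return kernels


def simulate_chip_track(
    truth: RegulatoryTruth,
    mark: str,
    condition: str,
    replicate: int = 1,
    params: SimulationParams | None = None,
) -> BinnedCoverage:
    """Poisson coverage for one mark x condition x replicate track."""
    params = params or SimulationParams()
    if mark not in MARKS:
        raise InvalidParameterError(f"unknown mark {mark!r}; choose from {MARKS}")
    if condition not in _MARK_CONDITIONS[mark]:
        raise InvalidParameterError(
            f"mark {mark!r} is not simulated in condition {condition!r}"
        )
    genome = truth.genome
    kernels = _planted_kernels(truth, mark, condition, params)
    kernel_mass_units = sum(m for *_, m in kernels)  # in background-equivalents

    if params.background_rate is None:
        bg = params.read_depth / (genome.total_size + kernel_mass_units)
        scale = 1.0
    else:
        bg = params.background_rate
        expected = bg * (genome.total_size + kernel_mass_units)
        scale = params.read_depth / expected
    if bg <= 0:
        raise InvalidParameterError("background rate collapsed to zero")

    rng = _track_rng(params, mark, condition, replicate)
    cov = BinnedCoverage(genome, params.bin_size)
    for chrom in genome.chrom_names:
        n_bins = len(cov.counts[chrom])
        rate = np.full(n_bins, bg * params.bin_size, dtype=float)
        # last bin may be short
        tail = genome.size_of(chrom) - (n_bins - 1) * params.bin_size
        rate[-1] = bg * tail
        for kchrom, summit, hw, mass in kernels:
            if kchrom != chrom:
                continue
            idx, w = _triangle_weights(summit, hw, params.bin_size, n_bins)
            rate[idx] += mass * bg * w
        cov.counts[chrom] = rng.poisson(rate * scale).astype(np.int64)
    return cov


def simulate_rnaseq_counts(
    truth: RegulatoryTruth,
    genes: list[GeneModel],
    condition: str,
    replicate: int = 1,
    params: SimulationParams | None = None,
) -> dict[str, int]:
    """Negative-binomial gene counts for one RNA-seq library."""
    params = params or SimulationParams()
    if condition not in RNA_CONDITIONS:
        raise InvalidParameterError(
            f"condition must be one of {RNA_CONDITIONS}, got {condition!r}"
        )
    key = (50 + RNA_CONDITIONS.index(condition), int(replicate))
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=key))
    depth_factor = params.read_depth / 1e6
    d = params.rna_dispersion
    counts: dict[str, int] = {}
    for g in genes:
        eff = truth.expression_effects.get(g.gene_id, ExpressionEffect())
        lfc = 0.0
        if condition == "day4_ctrl":
            lfc = eff.induction
        elif condition == "day4_ko":
            lfc = eff.induction + eff.ko
        mean = g.baseline_mean * (2.0**lfc) * depth_factor
        if d <= 0 or mean <= 0:
            counts[g.gene_id] = int(rng.poisson(mean))
        else:
            p = 1.0 / (1.0 + d * mean)
            counts[g.gene_id] = int(rng.negative_binomial(1.0 / d, p))
    return counts


# ---- synthetic region sequences (for motif enrichment) --------------------

_BASES = np.array(list("ACGT"))


def random_sequences(n: int, length: int, seed: int = 0,
                     base_probs: tuple[float, float, float, float] = (0.25,) * 4
                     ) -> list[str]:
    """IID random DNA region sequences (synthetic stand-ins for extracted
    genomic sequence)."""
    rng = np.random.default_rng(seed)
    probs = np.asarray(base_probs, dtype=float)
    probs = probs / probs.sum()
    return [
        "".join(_BASES[rng.choice(4, size=length, p=probs)]) for _ in range(n)
    ]


_COMP = str.maketrans("ACGT", "TGCA")


def plant_motif(sequences: list[str], motif: str, rate: float, seed: int = 0
                ) -> list[str]:
    """Insert ``motif`` (forward or reverse-complement, random position)
    into a ``rate`` fraction of sequences."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for s in sequences:
        if rng.random() < rate and len(s) >= len(motif):
            m = motif if rng.random() < 0.5 else motif.translate(_COMP)[::-1]
            pos = int(rng.integers(0, len(s) - len(m) + 1))
            s = s[:pos] + m + s[pos + len(m):]
        out.append(s)
    return out
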