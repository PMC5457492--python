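"""Synthetic paired-screen generator with known ground truth.

Builds desk-scale genomes whose structure mirrors the situations the
analysis modules are meant to detect: genes with one to three CAGE-style
TSS peaks (the highest is the primary), divergent gene pairs sharing a
promoter within 1 kb, copy-number-amplified gene blocks, planted
multi-copy sequences, and an AAVS1-like safe-harbor region.  From a
library designed against such a genome it simulates pooled-screen read
counts for both modalities:

* growth is exponential: a guide with fitness f (log2 per doubling)
  changes its pool share by 2^(f * doublings) over the screen;
* cutting (Cas9) guides inherit their target gene's fitness effect through
  exon disruption and additionally pay a gene-independent cleavage-
  toxicity cost per genomic cut site beyond the first, where cut sites
  are perfect-match loci weighted by local copy number;
* CRISPRi (KRAB-dCas9) guides inherit the gene effect scaled by a
  distance-dependent knockdown efficiency (a Gaussian bump peaking
  ~100 bp downstream of the TSS), silence both genes of a shared
  bidirectional promoter, and pay no cutting toxicity;
* the early time point is a multinomial draw from a log-normal pool
  representation; the late time point adds negative-binomial
  overdispersion; replicates are independent draws.

Defaults describe a clean 300-gene screen (30 essential genes, 4 guides
per gene, 500x depth, duplicate screens over 10 population doublings, a
21-day-screen proxy).  ``SimConfig.confound()`` switches on the two
artifact mechanisms (20 amplified genes at CN 8 in two amplicons, 20
bidirectional pairs) at the scale used by the confound analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confounds import find_occurrences
from .efficiency_model import (
    EfficiencyModel,
    GuideActivation,
    KernelConfig,
    fit_distance_svm,
    signed_tss_distance,
)
from .library_design import assemble_library
from .screen_io import (
    CountMatrix,
    GenomeModel,
    SgRNARecord,
    TSSRecord,
    infer_sample_meta,
    rank_tss,
)

MODALITIES = ("cas9", "krab_dcas9")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated paired screen."""

    n_genes: int = 300
    n_essential: int = 30
    guides_per_gene: int = 4
    essential_effect: float = 0.3  # log2 fitness cost per doubling
    effect_jitter: float = 0.2  # relative spread of per-gene effects

    n_amplified: int = 0
    amplicon_cn: int = 8
    n_bidirectional_pairs: int = 0
    bidirectional_min_dist: int = 300
    bidirectional_max_dist: int = 800

    curve_center: float = 100.0  # bp downstream of the TSS
    curve_width: float = 150.0  # full width at half maximum, bp
    cutting_toxicity_per_site: float = 0.02  # log2 cost per extra cut site per doubling

    doublings: int = 10  # proxy for a 21-day screen
    sequencing_depth: int = 500  # mean reads per guide per sample
    dispersion: float = 0.05  # negative-binomial overdispersion alpha
    replicates: int = 2
    library_sigma: float = 0.5  # log-normal spread of pool representation

    n_aavs1: int = 267
    n_nontargeting: int = 714
    gene_spacing: int = 4000
    n_multicopy: int = 3

    def __post_init__(self) -> None:
        for name in (
            "essential_effect",
            "cutting_toxicity_per_site",
            "dispersion",
            "library_sigma",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.n_essential > self.n_genes:
            raise SimulationError("more essential genes than genes")

    def efficiency_curve(self, d) -> np.ndarray | float:
        """True knockdown efficiency in [0, 1] as a function of distance."""
        sigma = self.curve_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-((np.asarray(d, dtype=float) - self.curve_center) ** 2) / (2 * sigma**2))

    @classmethod
    def confound(cls, **overrides) -> "SimConfig":
        """Preset with both artifact mechanisms on (amplicons + coupling)."""
        base = dict(n_amplified=20, n_bidirectional_pairs=20)
        base.update(overrides)
        return cls(**base)


@dataclass
class SimTruth:
    """Everything the simulator knows that an analyst would have to infer."""

    gene_effects: dict[str, float]
    essential_genes: set[str]
    amplified_genes: set[str]
    coupling: dict[str, str]  # gene -> partner sharing its primary promoter
    tss_records: list[TSSRecord]
    exons_by_gene: dict[str, list[tuple[str, int, int]]]
    aavs1_region: tuple[str, int, int]
    multicopy_seqs: list[str]
    genome: GenomeModel | None = None
    _cut_cache: dict[str, float] = field(default_factory=dict)

    def cut_weight(self, rec: SgRNARecord) -> float:
        """Copy-number-weighted count of perfect-match cut sites."""
        if rec.spacer_id not in self._cut_cache:
            if not rec.chrom or self.genome is None:
                w = 0.0
            else:
                w = float(
                    sum(
                        self.genome.cn_at(chrom, pos)
                        for chrom, pos, _ in find_occurrences(rec.spacer_seq, self.genome)
                    )
                )
            self._cut_cache[rec.spacer_id] = w
        return self._cut_cache[rec.spacer_id]


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def make_genome(
    cfg: SimConfig, seed: int = 0
) -> tuple[GenomeModel, list[TSSRecord], dict[str, list[tuple[str, int, int]]], SimTruth]:
    """Build a genome, TSS annotation, exon intervals and ground truth.

    Layout: one contig; genes occupy evenly spaced slots; each
    bidirectional pair shares one slot (divergent TSSs 300-800 bp apart,
    minus-strand gene on the left); amplified genes sit in two contiguous
    slot blocks covered by elevated-CN segments; an AAVS1-like safe-harbor
    region and a few planted duplicate sequences live in gene-free margins.
    """
    rng = np.random.default_rng(seed)
    names = [f"G{i:04d}" for i in range(cfg.n_genes)]
    essential = names[: cfg.n_essential]
    n_bi = cfg.n_bidirectional_pairs
    if cfg.n_essential + n_bi + cfg.n_amplified > cfg.n_genes:
        raise SimulationError("gene budget too small for requested pairs and amplicons")
    # pair an essential gene with a dedicated non-essential partner where
    # possible; excess pairs couple two non-essential genes
    pool = iter(names[cfg.n_essential :])
    pair_left = [essential[k] if k < len(essential) else next(pool) for k in range(n_bi)]
    partners = [next(pool) for _ in range(n_bi)]
    amp_list = [next(pool) for _ in range(cfg.n_amplified)]
    amplified = set(amp_list)

    placed = set(pair_left) | set(partners) | amplified
    other_singles = [g for g in names if g not in placed]
    # slot order: pairs, buffer single, amplicon block 1, singles, amplicon
    # block 2, remaining singles
    half = (len(amp_list) + 1) // 2
    amp1, amp2 = amp_list[:half], amp_list[half:]
    slot_plan: list[tuple[str, ...]] = [
        (left, right) for left, right in zip(pair_left, partners)
    ]
    buffer1, rest = other_singles[:1], other_singles[1:]
    buffer2, rest = rest[:1], rest[1:]
    slot_plan += [(g,) for g in buffer1]
    slot_plan += [(g,) for g in amp1]
    slot_plan += [(g,) for g in buffer2]
    slot_plan += [(g,) for g in amp2]
    slot_plan += [(g,) for g in rest]

    margin = 6000
    n_slots = len(slot_plan)
    contig_len = 2 * margin + n_slots * cfg.gene_spacing
    chrom = "chr1"
    seq = _random_dna(rng, contig_len)

    # plant duplicate sequences in the left margin for multiplicity tests
    seq_arr = bytearray(seq, "ascii")
    multicopy = []
    for m in range(cfg.n_multicopy):
        unit = _random_dna(rng, 60)
        multicopy.append(unit)
        for copy_i in range(2):
            pos = 200 + m * 400 + copy_i * 150
            seq_arr[pos : pos + 60] = unit.encode()
    seq = seq_arr.decode()

    aavs1_region = (chrom, margin - 4000, margin - 2000)

    tss_records: list[TSSRecord] = []
    exons_by_gene: dict[str, list[tuple[str, int, int]]] = {}
    amp_anchor_span: dict[str, int] = {}

    def add_gene(gene: str, anchor: int, strand: str, n_tss: int, shared: bool) -> None:
        sign = 1 if strand == "+" else -1
        heights = [float(rng.uniform(60, 100)), float(rng.uniform(20, 50)), float(rng.uniform(5, 15))]
        for k in range(n_tss):
            tss_records.append(
                TSSRecord(
                    gene=gene,
                    chrom=chrom,
                    position=anchor + sign * 450 * k,
                    strand=strand,
                    peak_height=heights[k],
                )
            )
        # coding exons downstream of (and excluding) the first exon; they
        # stay within +/-1800 bp of the anchor so amplicon segments can
        # cover a gene's exons without touching its neighbours
        exons_by_gene[gene] = [
            tuple(sorted((anchor + sign * 1200, anchor + sign * 1400))),
            tuple(sorted((anchor + sign * 1600, anchor + sign * 1800))),
        ]
        exons_by_gene[gene] = [(chrom, a, b) for a, b in exons_by_gene[gene]]

    coupling: dict[str, str] = {}
    for i, slot in enumerate(slot_plan):
        anchor = margin + i * cfg.gene_spacing + cfg.gene_spacing // 2
        if len(slot) == 2:
            left, right = slot
            dist = int(rng.integers(cfg.bidirectional_min_dist, cfg.bidirectional_max_dist + 1))
            add_gene(left, anchor, "-", 1, shared=True)
            add_gene(right, anchor + dist, "+", 1, shared=True)
            coupling[left] = right
            coupling[right] = left
        else:
            gene = slot[0]
            strand = "+" if rng.random() < 0.5 else "-"
            n_tss = int(rng.integers(1, 4))
            add_gene(gene, anchor, strand, n_tss, shared=False)
            if gene in amplified:
                amp_anchor_span[gene] = anchor

    cn_segments = []
    for block in (amp1, amp2):
        if not block:
            continue
        anchors = [amp_anchor_span[g] for g in block]
        cn_segments.append(
            (chrom, min(anchors) - 2000, max(anchors) + 2000, cfg.amplicon_cn)
        )

    genome = GenomeModel(sequences={chrom: seq}, copy_number=cn_segments)
    tss_records = rank_tss(tss_records)

    effects = {}
    for g in names:
        if g in set(essential):
            effects[g] = -cfg.essential_effect * float(
                rng.uniform(1 - cfg.effect_jitter, 1 + cfg.effect_jitter)
            )
        else:
            effects[g] = 0.0

    truth = SimTruth(
        gene_effects=effects,
        essential_genes=set(essential),
        amplified_genes=amplified,
        coupling=coupling,
        tss_records=tss_records,
        exons_by_gene=exons_by_gene,
        aavs1_region=aavs1_region,
        multicopy_seqs=multicopy,
        genome=genome,
    )
    return genome, tss_records, exons_by_gene, truth


# ---------------------------------------------------------------------------
# Efficiency-model training data drawn from the true curve
# ---------------------------------------------------------------------------


def synthetic_training_set(
    cfg: SimConfig,
    seed: int = 0,
    n_genes: int = 40,
    guides_per_gene: int = 12,
    noise_sd: float = 0.1,
) -> list[GuideActivation]:
    """Activation-score training examples sampled from the true curve."""
    rng = np.random.default_rng(seed)
    out = []
    for gi in range(n_genes):
        gene = f"T{gi:03d}"
        for j in range(guides_per_gene):
            d = int(rng.integers(-200, 201))
            score = float(cfg.efficiency_curve(d) + rng.normal(0, noise_sd))
            out.append(
                GuideActivation(
                    spacer_id=f"{gene}_{j:02d}", gene=gene, d_x=d, activation_score=score
                )
            )
    return out


def train_synthetic_model(
    cfg: SimConfig, seed: int = 0, kernel_cfg: KernelConfig | None = None
) -> EfficiencyModel:
    return fit_distance_svm(synthetic_training_set(cfg, seed=seed), kernel_cfg)


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------


def _tss_map(truth: SimTruth) -> dict[tuple[str, int], TSSRecord]:
    return {(t.gene, t.rank_within_gene): t for t in truth.tss_records}


def guide_fitness(
    library: list[SgRNARecord], truth: SimTruth, modality: str, cfg: SimConfig
) -> np.ndarray:
    """True per-guide fitness (log2 change in pool share per doubling)."""
    if modality not in MODALITIES:
        raise SimulationError(f"unknown modality {modality!r}")
    tmap = _tss_map(truth)
    f = np.zeros(len(library))
    for i, rec in enumerate(library):
        if modality == "cas9":
            if rec.target_class == "exon":
                f[i] += truth.gene_effects.get(rec.target_gene, 0.0)
            cuts = truth.cut_weight(rec)
            f[i] -= cfg.cutting_toxicity_per_site * max(cuts - 1.0, 0.0)
        else:
            if rec.target_class.startswith("tss_"):
                tss = tmap.get((rec.target_gene, rec.tss_rank))
                if tss is None:
                    raise SimulationError(
                        f"guide {rec.spacer_id} references unknown TSS "
                        f"({rec.target_gene}, rank {rec.tss_rank})"
                    )
                kd = float(cfg.efficiency_curve(signed_tss_distance(rec, tss)))
                f[i] += truth.gene_effects.get(rec.target_gene, 0.0) * kd
                if rec.tss_rank == 1 and rec.target_gene in truth.coupling:
                    partner = truth.coupling[rec.target_gene]
                    f[i] += truth.gene_effects.get(partner, 0.0) * kd
    return f


def _sample_counts(
    fitness: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = fitness.size
    total = cfg.sequencing_depth * n
    w = rng.lognormal(0.0, cfg.library_sigma, size=n)
    p_early = w / w.sum()
    w_late = w * np.exp2(fitness * cfg.doublings)
    p_late = w_late / w_late.sum()
    cols = {}
    for r in range(1, cfg.replicates + 1):
        cols[f"early.rep{r}"] = rng.multinomial(total, p_early)
    for r in range(1, cfg.replicates + 1):
        mu = total * p_late
        if cfg.dispersion > 0:
            lam = rng.gamma(1.0 / cfg.dispersion, mu * cfg.dispersion)
        else:
            lam = mu
        cols[f"late.rep{r}"] = rng.poisson(lam)
    return pd.DataFrame(cols)


def simulate_screen(
    library: list[SgRNARecord],
    truth: SimTruth,
    modality: str,
    cfg: SimConfig,
    seed: int = 0,
) -> CountMatrix:
    """Early/late replicated read counts for one screening modality."""
    rng = np.random.default_rng(seed)
    fitness = guide_fitness(library, truth, modality, cfg)
    df = _sample_counts(fitness, cfg, rng)
    df.index = pd.Index([r.spacer_id for r in library], name="sgrna_id")
    return CountMatrix(counts=df, sample_meta=infer_sample_meta(list(df.columns)))


def rescue_screen(
    library: list[SgRNARecord],
    truth: SimTruth,
    modality: str,
    cfg: SimConfig,
    sentinel: str,
    selection_strength: float = 0.5,
    seed: int = 0,
) -> CountMatrix:
    """Positive-selection screen: a drug kills every cell unless the
    sentinel gene is disabled (6TG/HPRT1-style rescue).

    Guides escape the penalty in proportion to how completely they disable
    the sentinel: exon guides fully in the cutting modality, TSS guides in
    proportion to their knockdown efficiency in either modality (targeted
    (d)Cas9 at a TSS blocks transcription whether or not it cuts).  With
    zero selection strength this reduces exactly to ``simulate_screen``.
    """
    if not any(r.target_gene == sentinel for r in library):
        raise SimulationError(f"sentinel gene {sentinel!r} has no guides in the library")
    rng = np.random.default_rng(seed)
    fitness = guide_fitness(library, truth, modality, cfg)
    tmap = _tss_map(truth)
    for i, rec in enumerate(library):
        disabled = 0.0
        if rec.target_gene == sentinel:
            if rec.target_class == "exon" and modality == "cas9":
                disabled = 1.0
            elif rec.target_class.startswith("tss_"):
                tss = tmap[(rec.target_gene, rec.tss_rank)]
                disabled = float(cfg.efficiency_curve(signed_tss_distance(rec, tss)))
        fitness[i] -= selection_strength * (1.0 - disabled)
    df = _sample_counts(fitness, cfg, rng)
    df.index = pd.Index([r.spacer_id for r in library], name="sgrna_id")
    return CountMatrix(counts=df, sample_meta=infer_sample_meta(list(df.columns)))


# ---------------------------------------------------------------------------
# One-call experiment bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    cfg: SimConfig
    genome: GenomeModel
    tss_records: list[TSSRecord]
    library: list[SgRNARecord]
    truth: SimTruth
    model: EfficiencyModel
    counts: dict[str, CountMatrix]


def simulate_experiment(
    cfg: SimConfig,
    seed: int = 0,
    modalities: tuple[str, ...] = MODALITIES,
    with_exons: bool = True,
) -> SimulatedExperiment:
    """Genome -> model -> designed library -> paired screens, end to end."""
    rng = np.random.default_rng(seed)
    s_genome, s_model, s_lib = (int(rng.integers(2**31)) for _ in range(3))
    genome, tss_records, exons, truth = make_genome(cfg, seed=s_genome)
    model = train_synthetic_model(cfg, seed=s_model)
    tss_by_gene: dict[str, list[TSSRecord]] = {}
    for t in tss_records:
        tss_by_gene.setdefault(t.gene, []).append(t)
    library = assemble_library(
        genes=sorted(truth.gene_effects),
        genome=genome,
        tss_by_gene=tss_by_gene,
        model=model,
        exons_by_gene=exons,
        n_per_tss=cfg.guides_per_gene,
        tss_per_gene=1,
        n_exon=cfg.guides_per_gene if with_exons else 0,
        aavs1_region=truth.aavs1_region,
        n_aavs1=cfg.n_aavs1,
        n_nontargeting=cfg.n_nontargeting,
        seed=s_lib,
    )
    counts = {
        m: simulate_screen(library, truth, m, cfg, seed=int(rng.integers(2**31)))
        for m in modalities
    }
    return SimulatedExperiment(
        cfg=cfg,
        genome=genome,
        tss_records=tss_records,
        library=library,
        truth=truth,
        model=model,
        counts=counts,
    )
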