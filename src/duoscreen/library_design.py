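"""CRISPRi library design from a genome and CAGE-style TSS annotation.

For each gene up to three TSSs (the highest CAGE peaks) are targeted.
Candidates are every 20-nt spacer immediately 5' of an NGG whose PAM 'N'
lies within +/-200 bp of the TSS, on either strand.  Candidates are
excluded when the spacer perfectly matches more than one genomic locus,
contains four consecutive T's (a Pol III terminator), or is at least 80%
G/C; survivors are ranked by the fitted distance-efficiency model and the
top n kept (7 in the multi-TSS design, 5 for a genome-scale library).
Exon guides for cutting screens are NGG-only: every PAM site in the coding
exons (first exon excluded), subsampled to ~50 per gene.

Multimapping is determined by exhaustive exact string search over both
strands — exact, and fast enough for the desk-scale genomes this package
simulates; a real genome would plug in an external aligner through the
same ``GenomeIndex`` interface.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .efficiency_model import EfficiencyModel, signed_tss_distance
from .screen_io import (
    GenomeModel,
    ScreenIOError,
    SgRNARecord,
    TSSRecord,
    revcomp,
)

SPACER_LEN = 20
DEFAULT_WINDOW = 200
GC_MAX_FRACTION = 0.80  # inclusive: >=80% C or G is excluded
POLY_T = "TTTT"


@dataclass
class CandidateGuide:
    spacer_seq: str
    chrom: str
    pam_n_position: int
    strand: str
    tss: TSSRecord
    d_x: int
    flags: set[str] = field(default_factory=set)
    predicted_score: float | None = None

    @property
    def passes_filters(self) -> bool:
        return not self.flags


class GenomeIndex:
    """Exact 20-mer occurrence counts over both strands of a genome."""

    def __init__(self, genome: GenomeModel, k: int = SPACER_LEN):
        self.k = k
        counts: Counter[str] = Counter()
        for seq in genome.sequences.values():
            for strand_seq in (seq, revcomp(seq)):
                for i in range(len(strand_seq) - k + 1):
                    counts[strand_seq[i : i + k]] += 1
        self._counts = counts

    def occurrences(self, spacer: str) -> int:
        if len(spacer) != self.k:
            raise ScreenIOError(f"expected {self.k}-mer, got {len(spacer)}-mer")
        return self._counts[spacer]


def iter_pam_sites(seq: str, chrom: str):
    """Yield (pam_n_position, strand, spacer) for every NGG site with a
    full-length spacer, on both strands of one contig."""
    n = len(seq)
    # plus strand: spacer at [p-20, p), PAM = seq[p:p+3] with GG at p+1,p+2
    for p in range(SPACER_LEN, n - 2):
        if seq[p + 1] == "G" and seq[p + 2] == "G":
            yield p, "+", seq[p - SPACER_LEN : p]
    # minus strand: PAM 'N' at genomic q, motif reads NGG 5'->3' on the
    # reverse strand, i.e. forward-strand "CC" at q-2,q-1; spacer is the
    # reverse complement of the 20 nt genomically right of q
    for q in range(2, n - SPACER_LEN):
        if seq[q - 2] == "C" and seq[q - 1] == "C":
            yield q, "-", revcomp(seq[q + 1 : q + 1 + SPACER_LEN])


def select_tss(tss_records: list[TSSRecord], k: int = 3) -> list[TSSRecord]:
    """Top-k TSSs of one gene by CAGE peak height (rank 1 = primary)."""
    if not tss_records:
        raise ScreenIOError("no TSS records to select from")
    ordered = sorted(tss_records, key=lambda r: (-r.peak_height, r.position))
    return ordered[:k]


def enumerate_candidates(
    genome: GenomeModel, tss: TSSRecord, window: int = DEFAULT_WINDOW
) -> list[CandidateGuide]:
    """All NGG-anchored guides whose PAM 'N' lies within +/-window of the
    TSS (inclusive both ends); truncated at contig boundaries."""
    if tss.chrom not in genome.sequences:
        raise ScreenIOError(f"TSS contig {tss.chrom!r} not in genome")
    seq = genome.sequences[tss.chrom]
    lo = max(0, tss.position - window)
    hi = min(len(seq), tss.position + window + 1)
    # scan a sequence slab wide enough to hold spacer + PAM on either strand
    slab_lo = max(0, lo - SPACER_LEN - 2)
    slab_hi = min(len(seq), hi + SPACER_LEN + 2)
    out = []
    for local_p, strand, spacer in iter_pam_sites(seq[slab_lo:slab_hi], tss.chrom):
        p = local_p + slab_lo
        if not (lo <= p < hi):
            continue
        guide = SgRNARecord(
            spacer_id="cand",
            spacer_seq=spacer,
            chrom=tss.chrom,
            cut_anchor=p,
            strand=strand,
            target_gene=tss.gene,
            target_class="tss_1" if tss.rank_within_gene == 1 else f"tss_{tss.rank_within_gene}",
            tss_rank=tss.rank_within_gene,
        )
        out.append(
            CandidateGuide(
                spacer_seq=spacer,
                chrom=tss.chrom,
                pam_n_position=p,
                strand=strand,
                tss=tss,
                d_x=signed_tss_distance(guide, tss),
            )
        )
    out.sort(key=lambda c: (c.pam_n_position, c.strand))
    return out


def gc_fraction(spacer: str) -> float:
    return (spacer.count("G") + spacer.count("C")) / len(spacer)


def filter_candidates(
    cands: list[CandidateGuide],
    genome: GenomeModel | None = None,
    index: GenomeIndex | None = None,
) -> list[CandidateGuide]:
    """Set exclusion flags in place: multimap (perfect match at >1 genomic
    locus, both strands), polyT (contains TTTT), gc_high (>=80% G/C)."""
    if index is None:
        if genome is None:
            raise ScreenIOError("need a genome or a prebuilt index for filtering")
        index = GenomeIndex(genome)
    for c in cands:
        if index.occurrences(c.spacer_seq) > 1:
            c.flags.add("multimap")
        if POLY_T in c.spacer_seq:
            c.flags.add("polyT")
        if gc_fraction(c.spacer_seq) >= GC_MAX_FRACTION:
            c.flags.add("gc_high")
    return cands


def rank_and_pick(
    cands: list[CandidateGuide], model: EfficiencyModel, n: int
) -> list[CandidateGuide]:
    """Top-n unflagged candidates by predicted efficiency (ties broken by
    coordinate for determinism); may return fewer than n."""
    clean = [c for c in cands if c.passes_filters]
    for c in clean:
        c.predicted_score = float(model.predict(c.d_x))
    clean.sort(key=lambda c: (-c.predicted_score, c.pam_n_position, c.strand))
    return clean[:n]


def design_exon_tiling(
    genome: GenomeModel,
    exon_intervals: list[tuple[str, int, int]],
    n: int = 50,
    seed: int = 0,
) -> list[CandidateGuide]:
    """NGG-only exon guides, uniformly subsampled to n when supply exceeds n.

    ``exon_intervals`` must already exclude the first exon; the only
    selection criterion is an NGG with its PAM 'N' inside an interval.
    """
    sites = []
    for chrom, start, end in exon_intervals:
        if chrom not in genome.sequences:
            raise ScreenIOError(f"exon contig {chrom!r} not in genome")
        seq = genome.sequences[chrom]
        slab_lo = max(0, start - SPACER_LEN - 2)
        slab_hi = min(len(seq), end + SPACER_LEN + 2)
        for local_p, strand, spacer in iter_pam_sites(seq[slab_lo:slab_hi], chrom):
            p = local_p + slab_lo
            if start <= p < end:
                sites.append((chrom, p, strand, spacer))
    sites.sort()
    if len(sites) > n:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(sites), size=n, replace=False))
        sites = [sites[i] for i in keep]
    dummy_tss = TSSRecord(gene="", chrom="", position=0, strand="+", peak_height=0.0)
    return [
        CandidateGuide(
            spacer_seq=spacer,
            chrom=chrom,
            pam_n_position=p,
            strand=strand,
            tss=dummy_tss,
            d_x=0,
        )
        for chrom, p, strand, spacer in sites
    ]


def _random_clean_spacers(
    index: GenomeIndex, n: int, rng: np.random.Generator, max_tries: int = 200
) -> list[str]:
    """Random 20-mers with zero perfect matches in the genome."""
    out: list[str] = []
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        batch = ["".join(rng.choice(bases, SPACER_LEN)) for _ in range(max(8, n))]
        for sp in batch:
            if index.occurrences(sp) == 0 and revcomp(sp) != sp and POLY_T not in sp:
                out.append(sp)
                if len(out) == n:
                    return out
    raise ScreenIOError(f"could not generate {n} genome-free nontargeting spacers")


def assemble_library(
    genes: list[str],
    genome: GenomeModel,
    tss_by_gene: dict[str, list[TSSRecord]],
    model: EfficiencyModel,
    exons_by_gene: dict[str, list[tuple[str, int, int]]] | None = None,
    n_per_tss: int = 7,
    tss_per_gene: int = 3,
    n_exon: int = 0,
    aavs1_region: tuple[str, int, int] | None = None,
    n_aavs1: int = 0,
    n_nontargeting: int = 0,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> list[SgRNARecord]:
    """Assemble a full screen library as validated records.

    Per gene: up to ``tss_per_gene`` TSSs, each with the model's top
    ``n_per_tss`` filtered candidates; optional NGG-only exon guides;
    AAVS1-locus cutting controls (NGG enumeration in the given safe-harbor
    region); and non-targeting spacers guaranteed absent from the genome.
    """
    rng = np.random.default_rng(seed)
    index = GenomeIndex(genome)
    records: list[SgRNARecord] = []

    for gene in genes:
        if gene not in tss_by_gene:
            raise ScreenIOError(f"no TSS annotation for gene {gene!r}")
        for tss in select_tss(tss_by_gene[gene], k=tss_per_gene):
            cands = enumerate_candidates(genome, tss, window=window)
            picks = rank_and_pick(filter_candidates(cands, index=index), model, n_per_tss)
            for j, c in enumerate(picks, 1):
                records.append(
                    SgRNARecord(
                        spacer_id=f"{gene}_tss{tss.rank_within_gene}_{j:02d}",
                        spacer_seq=c.spacer_seq,
                        chrom=c.chrom,
                        cut_anchor=c.pam_n_position,
                        strand=c.strand,
                        target_gene=gene,
                        target_class=f"tss_{tss.rank_within_gene}",
                        tss_rank=tss.rank_within_gene,
                    )
                )
        if n_exon and exons_by_gene and gene in exons_by_gene:
            exon_guides = design_exon_tiling(
                genome, exons_by_gene[gene], n=n_exon, seed=int(rng.integers(2**31))
            )
            for j, c in enumerate(exon_guides, 1):
                records.append(
                    SgRNARecord(
                        spacer_id=f"{gene}_exon_{j:02d}",
                        spacer_seq=c.spacer_seq,
                        chrom=c.chrom,
                        cut_anchor=c.pam_n_position,
                        strand=c.strand,
                        target_gene=gene,
                        target_class="exon",
                    )
                )

    if n_aavs1:
        if aavs1_region is None:
            raise ScreenIOError("n_aavs1 > 0 requires an AAVS1 safe-harbor region")
        chrom, start, end = aavs1_region
        picks = design_exon_tiling(
            genome, [(chrom, start, end)], n=n_aavs1, seed=int(rng.integers(2**31))
        )
        for j, c in enumerate(picks, 1):
            records.append(
                SgRNARecord(
                    spacer_id=f"AAVS1_{j:03d}",
                    spacer_seq=c.spacer_seq,
                    chrom=c.chrom,
                    cut_anchor=c.pam_n_position,
                    strand=c.strand,
                    target_gene="",
                    target_class="aavs1",
                )
            )

    for j, sp in enumerate(_random_clean_spacers(index, n_nontargeting, rng), 1):
        records.append(
            SgRNARecord(spacer_id=f"NT_{j:03d}", spacer_seq=sp, target_class="nontargeting")
        )
    return records
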