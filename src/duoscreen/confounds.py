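"""Modality-specific artifact analyses for paired cutting/CRISPRi screens.

Cutting screens (active Cas9) and CRISPRi screens (KRAB-dCas9) fail in
different ways.  Cas9 cleavage is toxic in proportion to the number of
genomic cut sites, so guides that multimap — or land in copy-number
amplified regions — deplete without any gene-level effect.  KRAB-dCas9
silences a promoter region rather than a single gene, so genes sharing a
bidirectional promoter (divergent TSSs within ~1 kb) score as false
positives when their neighbour is essential.  The functions here quantify
both failure modes: target-multiplicity effects, amplicon gene scans,
essential-call categorization with Fisher enrichment, bidirectional-
promoter detection, and essentiality as a function of distance to the
nearest known-essential gene.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quant import FoldChangeVector
from .screen_io import GenomeModel, ScreenIOError, SgRNARecord, TSSRecord, primary_tss, revcomp

DEFAULT_MULTIPLICITY_BINS = ((1, 1), (2, 5), (6, None))
DEFAULT_PROXIMITY_BINS = ((0, 1_000), (1_000, 10_000), (10_000, None))
PARTIAL_SEED_LEN = 12  # PAM-proximal 3' nucleotides used for partial matching


@dataclass(frozen=True)
class GeneCategory:
    gene: str
    category: str  # both | cas9_only | krab_only | neither


@dataclass(frozen=True)
class PromoterPair:
    gene_a: str
    gene_b: str
    tss_distance: int
    orientation: str  # divergent | convergent | tandem


# ---------------------------------------------------------------------------
# Target multiplicity
# ---------------------------------------------------------------------------


def find_occurrences(spacer: str, genome: GenomeModel) -> list[tuple[str, int, str]]:
    """All perfect-match loci of a spacer, both strands, as
    (chrom, start_of_protospacer_on_forward_strand, strand)."""
    hits = []
    for chrom, seq in genome.sequences.items():
        for pattern, strand in ((spacer, "+"), (revcomp(spacer), "-")):
            start = seq.find(pattern)
            while start != -1:
                hits.append((chrom, start, strand))
                start = seq.find(pattern, start + 1)
    return hits


def _hamming_hits(pattern: str, seq: str, max_mm: int) -> int:
    if len(seq) < len(pattern):
        return 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, len(pattern))
    return int(np.count_nonzero((windows != pat).sum(axis=1) <= max_mm))


def target_multiplicity(spacer: str, genome: GenomeModel, mode: str = "exact") -> int:
    """Number of genomic loci matching a spacer under a matching mode.

    ``exact``: perfect 20-mer matches; ``one_mismatch``: loci within
    Hamming distance 1; ``partial``: exact matches of the PAM-proximal
    3' 12-nt seed only.  Both strands are always scanned.
    """
    if mode == "exact":
        return len(find_occurrences(spacer, genome))
    if mode == "one_mismatch":
        total = 0
        for seq in genome.sequences.values():
            total += _hamming_hits(spacer, seq, 1)
            total += _hamming_hits(revcomp(spacer), seq, 1)
        return total
    if mode == "partial":
        if len(spacer) < PARTIAL_SEED_LEN:
            raise ScreenIOError(
                f"spacer shorter than the {PARTIAL_SEED_LEN}-nt partial seed"
            )
        return len(find_occurrences(spacer[-PARTIAL_SEED_LEN:], genome))
    raise ScreenIOError(f"unknown multiplicity mode {mode!r}")


def multiplicity_effect(
    lfc_by_modality: dict[str, FoldChangeVector],
    library: list[SgRNARecord],
    multiplicities: dict[str, int],
    bins=DEFAULT_MULTIPLICITY_BINS,
) -> pd.DataFrame:
    """Median/IQR fold-change per target-multiplicity bin and modality.

    Rows are emitted only for non-empty bins; a bin absent from the output
    is empty for that modality.
    """

    def bin_label(lo, hi):
        if lo == hi:
            return str(lo)
        return f"{lo}-{hi}" if hi is not None else f">={lo}"

    rows = []
    targeting = [r.spacer_id for r in library if r.spacer_id in multiplicities]
    for modality, fc in lfc_by_modality.items():
        for lo, hi in bins:
            ids = [
                s
                for s in targeting
                if multiplicities[s] >= lo
                and (hi is None or multiplicities[s] <= hi)
                and s in fc.lfc.index
            ]
            if not ids:
                continue
            vals = fc.lfc.loc[ids].to_numpy(dtype=float)
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "modality": modality,
                    "bin": bin_label(lo, hi),
                    "n": len(ids),
                    "median_lfc": med,
                    "q25": q25,
                    "q75": q75,
                }
            )
    return pd.DataFrame(rows, columns=["modality", "bin", "n", "median_lfc", "q25", "q75"])


# ---------------------------------------------------------------------------
# Amplicon scans
# ---------------------------------------------------------------------------


def amplicon_scan(
    lfc: FoldChangeVector,
    library: list[SgRNARecord],
    genes: list[str],
    modality: str,
) -> dict[str, float]:
    """Per-gene mean fold-change across a genomic region.

    A gene's score is the mean fold-change of its exon guides in a cutting
    screen or its primary-TSS guides in a CRISPRi screen; genes with no
    scored guides of the required class are omitted (missing, not errors).
    """
    cls = {"cas9": "exon", "krab_dcas9": "tss_1"}.get(modality)
    if cls is None:
        raise ScreenIOError(f"unknown modality {modality!r}")
    out = {}
    for gene in genes:
        ids = [
            r.spacer_id
            for r in library
            if r.target_gene == gene and r.target_class == cls and r.spacer_id in lfc.lfc.index
        ]
        if ids:
            out[gene] = float(lfc.lfc.loc[ids].mean())
    return out


def amplified_genes(
    tss_records: list[TSSRecord],
    genome: GenomeModel,
    min_cn: int = 4,
) -> set[str]:
    """Genes whose primary TSS lies in a segment with copy number >= min_cn."""
    out = set()
    for gene, tss in primary_tss(tss_records).items():
        if genome.cn_at(tss.chrom, tss.position) >= min_cn:
            out.add(gene)
    return out


# ---------------------------------------------------------------------------
# Category analysis
# ---------------------------------------------------------------------------


def categorize_genes(
    cas9_calls: set[str], krab_calls: set[str], universe: set[str]
) -> list[GeneCategory]:
    """Partition the gene universe by which modality called it essential."""
    if not (cas9_calls <= universe and krab_calls <= universe):
        raise ScreenIOError("call sets must be subsets of the gene universe")
    out = []
    for gene in sorted(universe):
        in_c, in_k = gene in cas9_calls, gene in krab_calls
        category = (
            "both" if in_c and in_k else "cas9_only" if in_c else "krab_only" if in_k else "neither"
        )
        out.append(GeneCategory(gene=gene, category=category))
    return out


def category_sets(categories: list[GeneCategory]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {"both": set(), "cas9_only": set(), "krab_only": set(), "neither": set()}
    for gc in categories:
        out[gc.category].add(gc.gene)
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided P sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding the observed table's.  A
    zero cell gets the Haldane 0.5 correction for the odds ratio only.
    """
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    if min(a, b, c, d) == 0:
        orat = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orat = a * d / (b * c)
    return float(orat), p


def fisher_enrichment(
    category_members: set[str], property_members: set[str], universe: set[str]
) -> tuple[float, float]:
    """Fisher's exact enrichment of a gene property within a category.

    Builds the 2x2 table {in/out of category} x {has/lacks property} over
    the universe and returns (odds ratio, two-sided P).
    """
    if not universe:
        raise ScreenIOError("empty gene universe")
    if not (category_members <= universe and property_members <= universe):
        raise ScreenIOError("member sets must be subsets of the universe")
    a = len(category_members & property_members)
    b = len(category_members - property_members)
    c = len(property_members - category_members)
    d = len(universe) - a - b - c
    return fisher_exact_2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# Bidirectional promoters & proximity bias
# ---------------------------------------------------------------------------


def detect_bidirectional(
    tss_records: list[TSSRecord], max_dist: int = 1_000
) -> tuple[list[PromoterPair], float]:
    """Divergent primary-TSS pairs within max_dist, and the fraction of
    genes participating in at least one such pair.

    A pair is bidirectional when the two genes sit on opposite strands
    with each transcribing away from the other (the minus-strand gene on
    the left), i.e. they could share one promoter region.
    """
    prim = primary_tss(tss_records)
    genes = sorted(prim)
    pairs = []
    in_pair: set[str] = set()
    for ga, gb in itertools.combinations(genes, 2):
        ta, tb = prim[ga], prim[gb]
        if ta.chrom != tb.chrom:
            continue
        left, right = (ta, tb) if ta.position <= tb.position else (tb, ta)
        dist = right.position - left.position
        if left.strand == right.strand:
            orientation = "tandem"
        elif left.strand == "-" and right.strand == "+":
            orientation = "divergent"
        else:
            orientation = "convergent"
        if orientation == "divergent" and dist <= max_dist:
            pairs.append(
                PromoterPair(
                    gene_a=left.gene, gene_b=right.gene, tss_distance=dist, orientation=orientation
                )
            )
            in_pair.update((ga, gb))
    fraction = len(in_pair) / len(genes) if genes else 0.0
    return pairs, fraction


def bidirectional_genes(tss_records: list[TSSRecord], max_dist: int = 1_000) -> set[str]:
    pairs, _ = detect_bidirectional(tss_records, max_dist=max_dist)
    out: set[str] = set()
    for p in pairs:
        out.update((p.gene_a, p.gene_b))
    return out


def proximity_to_essential(
    tss_records: list[TSSRecord],
    essential: set[str],
    krab_calls: set[str],
    bins=DEFAULT_PROXIMITY_BINS,
) -> pd.DataFrame:
    """Fraction of non-reference genes called essential, binned by the
    distance from their primary TSS to the nearest reference-essential
    gene's primary TSS.  Bins with no genes appear with NaN fraction."""
    prim = primary_tss(tss_records)
    ess_tss = [(t.chrom, t.position) for g, t in prim.items() if g in essential]
    rows = []
    dist_by_gene = {}
    for gene, tss in prim.items():
        if gene in essential:
            continue
        ds = [abs(tss.position - p) for c, p in ess_tss if c == tss.chrom]
        dist_by_gene[gene] = min(ds) if ds else np.inf

    def bin_label(lo, hi):
        return f"[{lo},{hi})" if hi is not None else f"[{lo},inf)"

    for lo, hi in bins:
        members = [
            g
            for g, d in dist_by_gene.items()
            if d >= lo and (hi is None or d < hi) and np.isfinite(d)
        ]
        frac = (
            sum(g in krab_calls for g in members) / len(members) if members else np.nan
        )
        rows.append({"bin": bin_label(lo, hi), "n": len(members), "fraction_called": frac})
    return pd.DataFrame(rows, columns=["bin", "n", "fraction_called"])
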