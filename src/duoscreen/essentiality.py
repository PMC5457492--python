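"""Gene essentiality calling against AAVS1 cutting controls.

AAVS1 ("safe-harbor") guides cut DNA but disrupt no gene, so their
fold-change distribution captures every gene-independent effect of the
modality — including Cas9 cleavage toxicity — and serves as the null.  A
gene is scored by the mean log fold-change of its guides against that null:

    z_g = (m_g - m_AAVS) / (sigma_AAVS / sqrt(N_g))

with the one-sided lower-tail normal P (essentiality manifests as guide
depletion).  Cutting screens score a gene by its exon guides; CRISPRi
screens by guides at the primary TSS (highest CAGE peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .quant import FoldChangeVector
from .screen_io import SgRNARecord

#: guide classes that score a gene in each screening modality
MODE_CLASSES = {"exon": ("exon",), "primary_tss": ("tss_1",)}


class EssentialityError(ValueError):
    pass


@dataclass(frozen=True)
class ControlStats:
    """Mean/SD of AAVS1-control guide fold-changes (the null distribution)."""

    m_aavs: float
    sigma_aavs: float
    n_controls: int


@dataclass(frozen=True)
class GeneScore:
    gene: str
    mode: str
    n_g: int
    m_g: float
    z: float
    p: float


def control_stats(lfc: FoldChangeVector, library: list[SgRNARecord]) -> ControlStats:
    """Sample mean and SD (n-1 denominator) of AAVS1 guide fold-changes."""
    ids = [r.spacer_id for r in library if r.target_class == "aavs1"]
    ids = [i for i in ids if i in lfc.lfc.index]
    if len(ids) < 2:
        raise EssentialityError(f"need >=2 AAVS1 control guides with lfc, got {len(ids)}")
    vals = lfc.lfc.loc[ids].to_numpy(dtype=float)
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise EssentialityError("degenerate AAVS1 control spread (sigma = 0)")
    return ControlStats(m_aavs=float(vals.mean()), sigma_aavs=sd, n_controls=len(ids))


def gene_zscore(
    lfc: FoldChangeVector,
    library: list[SgRNARecord],
    gene: str,
    mode: str,
    cs: ControlStats,
) -> GeneScore:
    """Z score of one gene's mean guide fold-change against the control null."""
    if mode not in MODE_CLASSES:
        raise EssentialityError(f"unknown mode {mode!r}")
    classes = MODE_CLASSES[mode]
    ids = [
        r.spacer_id
        for r in library
        if r.target_gene == gene and r.target_class in classes
    ]
    ids = [i for i in ids if i in lfc.lfc.index]
    if not ids:
        raise EssentialityError(f"gene {gene!r} has no scored {mode} guides")
    m_g = float(lfc.lfc.loc[ids].mean())
    n_g = len(ids)
    z = (m_g - cs.m_aavs) / (cs.sigma_aavs / np.sqrt(n_g))
    return GeneScore(gene=gene, mode=mode, n_g=n_g, m_g=m_g, z=float(z), p=float(stats.norm.cdf(z)))


def score_genes(
    lfc: FoldChangeVector,
    library: list[SgRNARecord],
    mode: str,
    cs: ControlStats | None = None,
) -> list[GeneScore]:
    """Score every gene that has guides of the requested mode."""
    if cs is None:
        cs = control_stats(lfc, library)
    classes = MODE_CLASSES[mode]
    genes = sorted(
        {r.target_gene for r in library if r.target_gene and r.target_class in classes}
    )
    return [gene_zscore(lfc, library, g, mode, cs) for g in genes]


def call_essential(scores: list[GeneScore], p_threshold: float = 0.01) -> set[str]:
    """Genes with P strictly below the threshold."""
    return {s.gene for s in scores if s.p < p_threshold}


def sensitivity(calls: set[str], reference: set[str]) -> float:
    """Fraction of a reference essential-gene set recovered by the calls."""
    if not reference:
        raise EssentialityError("empty reference set")
    return len(calls & reference) / len(reference)


def empirical_fdr(calls: set[str], truth: set[str]) -> float:
    """Fraction of calls not in the true set (0.0 for no calls)."""
    if not calls:
        return 0.0
    return len(calls - truth) / len(calls)


def effective_fraction(
    guide_lfc,
    null_lfc,
    q: float = 0.05,
) -> float:
    """Fraction of guides depleted below the q-quantile of the control null.

    Operationalizes "effective sgRNA" without a fixed fold-change cutoff:
    a guide counts as effective when its fold-change falls below the level
    that only a fraction q of negative-control guides reach.
    """
    guides = np.asarray(guide_lfc, dtype=float)
    nulls = np.asarray(null_lfc, dtype=float)
    if guides.size == 0:
        raise EssentialityError("empty guide set")
    if nulls.size == 0:
        raise EssentialityError("empty null set")
    if q <= 0:
        return 0.0
    cutoff = np.quantile(nulls, q)
    return float(np.mean(guides < cutoff))
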