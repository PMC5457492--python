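"""Count normalization, log abundance and log fold-change.

Each sample is normalized by the trimmed mean (10th-90th percentile,
inclusive, linear interpolation) of its non-specific control guide counts —
a robust scale factor chosen because positive-selection screens routinely
leave a handful of guides holding most of the reads.  Abundance is

    y_ij = log2(x_ij / c_j + eps),    eps = 0.05 by default,

where c_j is the per-sample control trimmed mean and eps stabilizes the
transform for small counts (zero-count guides stay finite and are kept).
Replicates are merged by averaging y in log space, and the log fold-change
of a guide is the difference of merged log abundances between a late and an
early condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_io import CountMatrix, ScreenIOError, SgRNARecord

DEFAULT_EPSILON = 0.05


class QuantError(ValueError):
    """Normalization is undefined for the given input."""


@dataclass
class AbundanceMatrix:
    """epsilon-stabilized log2 abundances with per-sample norm factors."""

    log_abundance: pd.DataFrame  # sgRNAs x samples (or conditions after merge)
    norm_factors: pd.Series
    epsilon: float
    sample_meta: pd.DataFrame

    @property
    def sgrna_ids(self) -> list[str]:
        return list(self.log_abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log_abundance.columns)


@dataclass
class FoldChangeVector:
    """Per-guide log2 fold-change between two conditions (late minus early)."""

    lfc: pd.Series  # index: sgrna_id
    condition_pair: tuple[str, str]

    @property
    def sgrna_ids(self) -> list[str]:
        return list(self.lfc.index)


def trimmed_mean_factor(
    control_counts, lo_pct: float = 10.0, hi_pct: float = 90.0
) -> float:
    """Mean of control counts within the [lo_pct, hi_pct] percentile band.

    Percentile bounds use linear interpolation and are inclusive, so a
    constant list returns its constant and a single extreme outlier among
    >=20 controls never moves the factor.
    """
    arr = np.asarray(control_counts, dtype=float)
    if arr.size == 0:
        raise QuantError("no control counts to normalize against")
    if np.all(arr == 0):
        raise QuantError("all control counts are zero; normalization undefined")
    lo, hi = np.percentile(arr, [lo_pct, hi_pct])
    kept = arr[(arr >= lo) & (arr <= hi)]
    if kept.size == 0:
        # with very few distinct values the interpolated band can exclude
        # everything; fall back to the untrimmed mean
        kept = arr
    return float(kept.mean())


def log_abundance(
    counts: CountMatrix,
    controls: set[str] | list[str],
    epsilon: float = DEFAULT_EPSILON,
) -> AbundanceMatrix:
    """Per-sample control-normalized log2 abundance y = log2(x/c + eps)."""
    controls = list(controls)
    if not controls:
        raise QuantError("empty control set")
    missing = set(controls) - set(counts.sgrna_ids)
    if missing:
        raise ScreenIOError(f"control guides absent from count matrix: {sorted(missing)}")
    factors = {}
    for sample in counts.sample_ids:
        factors[sample] = trimmed_mean_factor(counts.counts.loc[controls, sample])
    c = pd.Series(factors)
    y = np.log2(counts.counts / c + epsilon)
    return AbundanceMatrix(
        log_abundance=y,
        norm_factors=c,
        epsilon=epsilon,
        sample_meta=counts.sample_meta.copy(),
    )


def controls_from_library(
    library: list[SgRNARecord], target_class: str = "nontargeting"
) -> list[str]:
    """Spacer ids of the library's guides of one control class."""
    return [r.spacer_id for r in library if r.target_class == target_class]


def merge_replicates(
    ab: AbundanceMatrix, groups: dict[str, list[str]] | None = None
) -> AbundanceMatrix:
    """Average log abundance across replicates of each condition.

    By default the grouping comes from ``sample_meta``; an explicit
    ``condition -> samples`` map overrides it.
    """
    if groups is None:
        groups = {
            cond: list(sub.index)
            for cond, sub in ab.sample_meta.groupby("condition", sort=False)
        }
    merged = {}
    for cond, samples in groups.items():
        if not samples:
            raise QuantError(f"condition {cond!r} has no samples")
        unknown = set(samples) - set(ab.sample_ids)
        if unknown:
            raise QuantError(f"condition {cond!r} references unknown samples {sorted(unknown)}")
        merged[cond] = ab.log_abundance[samples].mean(axis=1)
    meta = pd.DataFrame(
        {"condition": list(merged), "replicate": ""},
        index=pd.Index(list(merged), name="sample"),
    )
    return AbundanceMatrix(
        log_abundance=pd.DataFrame(merged),
        norm_factors=ab.norm_factors,
        epsilon=ab.epsilon,
        sample_meta=meta,
    )


def log_fold_change(ab: AbundanceMatrix, early: str, late: str) -> FoldChangeVector:
    """lfc_i = y_i,late - y_i,early on the merged abundance matrix."""
    for cond in (early, late):
        if cond not in ab.log_abundance.columns:
            raise QuantError(f"condition {cond!r} not present (merge replicates first?)")
    return FoldChangeVector(
        lfc=ab.log_abundance[late] - ab.log_abundance[early],
        condition_pair=(early, late),
    )


def screen_lfc(
    counts: CountMatrix,
    library: list[SgRNARecord],
    early: str = "early",
    late: str = "late",
    epsilon: float = DEFAULT_EPSILON,
) -> FoldChangeVector:
    """Convenience pipeline: normalize, merge replicates, take fold-changes."""
    ab = log_abundance(counts, controls_from_library(library), epsilon=epsilon)
    return log_fold_change(merge_replicates(ab), early, late)
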