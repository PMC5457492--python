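# Methods

This note documents the models, the defaults and the judgment calls behind
`duoscreen`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Normalization and fold-change (`quant`)

Counts are normalized per sample by the trimmed mean (10th–90th
percentile, inclusive bounds, linear interpolation) of the non-targeting
control guides. Trimming makes the factor insensitive to the handful of
massively enriched guides that dominate positive-selection screens; the
magnitude of a trimmed-out outlier never enters the factor. With fewer
than roughly three distinct control values the interpolated band can
exclude every observation; the factor then falls back to the untrimmed
mean rather than failing. An all-zero control set is an error, since no
scale is identified.

The abundance transform is `y = log2(x/c + ε)` with `ε = 0.05`. The
stabilizer is added *inside* the ratio, so it acts as an abundance floor
of ε relative to the control-typical level: a zero-count guide sits at
`log2 ε ≈ −4.32`, and measured depletion compresses as a guide approaches
that floor (a 2⁻³-fold depleted guide reads ≈ −2.5 rather than −3). Log
base 2 makes fold-changes directly interpretable as doublings. Zero-count
guides are retained, not filtered — that is what ε is for. The CLI records
the exact transform in its output metadata.

Replicates are merged by the arithmetic mean of y (log space), and
`lfc = y_late − y_early`. Both choices are linear, so merging commutes
with the fold-change difference.

## Essentiality Z-test (`essentiality`)

AAVS1 safe-harbor guides cut chromatin but disrupt no gene, so their
fold-change distribution absorbs every gene-independent effect of a
modality, including baseline cleavage toxicity in cutting screens. The
control mean and SD (sample SD, n−1) define the null; a gene's score is

    z = (m_g − m_AAVS) / (σ_AAVS / √N_g),

with the one-sided lower-tail normal P, because essentiality manifests as
guide depletion. The per-gene √N_g standard error makes the statistic
calibrated when guides are exchangeable with controls: on a simulated
global-null screen, ~1% of genes reach P < 0.01 (the acceptance suite
checks this within binomial 99% bounds at 500 genes). The flip side of
calibration is that P < 0.01 over hundreds of true-null genes *must*
produce ≈ 1% false calls, so a single modality's empirical FDR at
desk scale (270 null genes, 30 essential) hovers near 0.08. The
high-confidence call set is therefore the intersection of the two
modalities' calls — a gene must deplete in both the cutting and the
CRISPRi screen — which drives the expected FDR to ≈ 10⁻² of a percent
while keeping sensitivity, and is the recommended reporting set. The
acceptance suite asserts per-modality sensitivity ≥ 0.9 and
intersection-set FDR ≤ 0.05; per-modality FDRs are reported alongside.

No multiple-testing correction is applied by default (the threshold is a
fixed P < 0.01); `call_essential` accepts any threshold for users who
prefer an adjusted one.

"Effective" guides have no standard definition; here a guide is effective
when its fold-change falls below the q-quantile (default q = 0.05) of the
negative-control fold-changes. This is control-calibrated, so it
transfers across screens of different depth and noise without a fixed
fold-change cutoff; q is exposed.

## Distance–efficiency model (`efficiency_model`)

CRISPRi efficiency is treated as a 1-D non-linear function of the signed
distance d from the PAM 'N' to the TSS (negative upstream, sign follows
gene strand). The regressor is support-vector ε-regression with a
Gaussian RBF kernel — the minimal smooth model for a scalar covariate.
Defaults: tube width ε = 0.1; RBF length scale and C chosen by an inner
deterministic 3-fold CV over a small grid (length scales 25/50/100/200 bp,
C 1/10). Predictions outside the training distance range are clamped to
the nearest edge value; RBF extrapolation otherwise decays to the
intercept and would fabricate structure. Models serialize to JSON
(support distances, dual coefficients, intercept, γ, domain) and reload to
bit-identical predictions because prediction is evaluated from those
stored arrays directly.

Training-set refinement keeps a gene only if it appears in both gene
annotations supplied (RefSeq- and FANTOM-style), has ≥ 7 guides, and has
an activation-score IQR strictly greater than 0.5 — genes with fewer or
more uniform guides cannot separate efficient from inefficient distances.
Cross-validation splits *genes* (2/3 train, 1/3 test), never guides of
one gene across the split, and scores by the Spearman correlation between
predicted and observed activation within each held-out gene, averaged;
within-gene rank correlation is scale-free and unaffected by gene-level
activation offsets. The split seed is a single integer recorded with the
result.

## Library design (`library_design`)

Per gene, up to 3 TSSs by descending CAGE peak height (ties to the
smaller coordinate, for determinism); candidates are 20-nt spacers 5′ of
NGG with the PAM 'N' within ±200 bp of the TSS, inclusive, both strands.
The window is anchored on the PAM 'N' to match the distance convention of
the efficiency model. Exclusion flags: perfect-match occurrence count
> 1 over both genome strands (multimap), a TTTT run (Pol III terminator),
and G+C ≥ 80% (inclusive). The flags are computed independently, so
filter order cannot matter. Survivors are ranked by predicted efficiency,
ties again by coordinate. Multiplicity is determined by exhaustive exact
string search (a 20-mer index over both strands) — exact and fast on the
desk-scale genomes this package simulates and tests with; for a real
genome the `GenomeIndex` seam is where an external aligner would plug in.
Exon guides for cutting screens are deliberately criterion-free (any NGG
in the supplied coding exons, first exon excluded), uniformly subsampled
to ~50 with a recorded seed. Non-targeting spacers are drawn at random
and accepted only at zero perfect matches.

## Confound analyses (`confounds`)

Target multiplicity supports exact matching, Hamming-distance-1 matching,
and a partial mode that matches only the PAM-proximal 3′ 12-nt seed
(PAM-proximal sequence dominates Cas9 recognition; the seed length is a
parameter since no single value is canonical). A "bidirectional promoter"
is operationalized as two genes on opposite strands, each transcribing
away from the other (minus-strand gene on the left), with primary TSSs
≤ 1 kb apart; convergent and tandem arrangements at any distance do not
qualify. An "amplified gene" has its primary TSS inside a copy-number
segment with CN ≥ 4 (configurable). Fisher's exact test is the standard
two-sided form (sum of all fixed-margin tables with probability ≤ the
observed table's — verified against full hypergeometric enumeration for
every table with N ≤ 30); a zero cell gets the Haldane 0.5 correction for
the odds ratio only, never for P.

## Simulator (`synthetic_data`)

The generator emulates the mechanisms the analyses detect, with ground
truth retained. Genome layout: one contig, genes in 4-kb slots;
bidirectional pairs share a slot with divergent TSSs 300–800 bp apart;
amplified genes occupy two contiguous slot blocks covered by CN segments
(default CN 8); an AAVS1-like safe-harbor region and planted duplicate
60-mers sit in gene-free margins. Each unpaired gene gets 1–3 TSSs with
strictly ordered peak heights and two short coding exons 1.2–1.8 kb
downstream of the TSS.

Growth model: a guide with fitness f (log2 pool-share change per
doubling) multiplies its representation by 2^(f·D) over D doublings
(default D = 10, a proxy for a ~3-week screen). Cutting-screen fitness is
the gene effect for exon guides minus a cleavage-toxicity cost of 0.02
per doubling per cut site beyond the first, where cut sites are
perfect-match loci weighted by local copy number (so a unique guide in a
CN-8 amplicon pays 7 × 0.02 per doubling — enough to flag amplified genes
at P < 0.01 without swamping true effects, mirroring the magnitude gap
between toxicity and true essentiality). CRISPRi fitness is the gene
effect scaled by the knockdown efficiency curve, plus the same term for
the partner gene when the target shares a bidirectional promoter; no
toxicity. The efficiency curve is a Gaussian bump centred +100 bp
downstream of the TSS with 150 bp full width at half maximum — a narrow
accessibility window around the nucleosome-depleted region downstream of
the TSS.

Counts: library representation is log-normal (σ = 0.5); the early sample
is a multinomial draw at depth × n_guides total reads; the late sample is
negative-binomial (Gamma–Poisson) around the grown, renormalized
representation with shared dispersion α = 0.05; replicates are
independent draws. Defaults describe the clean study condition: 300
genes, 30 essential (fitness cost 0.3 log2/doubling ± 20% per-gene
jitter), 4 guides per gene per class, 267 AAVS1 and 714 non-targeting
controls, depth 500×, 2 replicates. `SimConfig.confound()` adds the two
artifact mechanisms (20 amplified genes at CN 8, 20 bidirectional pairs
each coupling an essential gene to a non-essential partner) — the scale
used by the confound analyses. The rescue generator models
positive selection: a drug penalty applies to every guide except in
proportion to how completely it disables a sentinel gene (exon guides
fully, in cutting mode; TSS guides per their knockdown efficiency in
either mode, since a TSS-bound Cas9 blocks transcription whether or not
it cuts).

What the simulator does *not* emulate: spacer-sequence-dependent
activity, chromatin context beyond the distance curve, variable
per-guide cutting efficiency, multi-locus toxicity saturation, infection
(MOI) stochastics, and genome scale. Passing tests therefore validate
the statistical machinery and the direction/magnitude of the modelled
mechanisms, not performance on real human screens.

## Problem sizes and runtime

The test and acceptance workloads are sized for a single CPU: null
calibration at 500 genes × 4 guides; recovery and confound analyses at
the 300-gene default; the design-gain comparison at 60 genes × 30
essential averaged over 10 seeds; Fisher-vs-enumeration over all ~5,500
tables with N ≤ 30. The full suite runs in under two minutes; the
acceptance script in about one.

## Known limitations

* The ε floor biases large depletions toward zero; rank-based downstream
  analyses are unaffected, but absolute fold-changes below ≈ −4 are not
  measurable.
* The Z-test inherits normality from guide averaging; genes with 1–2
  guides have heavier-tailed nulls than the normal P assumes.
* Exact-match multiplicity ignores tolerant off-target binding; the
  one-mismatch and seed modes bound it from either side but are not a
  substitute for a full off-target score.
* The bidirectional-coupling mechanism silences both genes with equal
  efficiency; real shared promoters are often asymmetric.
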