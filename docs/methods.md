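# Methods

This note documents the statistical models, conventions and design choices
behind `lncnet`, and what the synthetic-cohort generator does and does not
emulate.

## Differential expression

Counts are modelled as negative binomial, `K_ij ~ NB(mean = s_j μ_i,
dispersion = α_i)` with `Var = μ + α μ²`.

**Size factors.** Median-of-ratios: for sample `j`,
`s_j = median_i (K_ij / g_i)` over genes with all-positive counts, where
`g_i` is the gene's geometric mean across samples; factors are rescaled to
geometric mean 1. If no gene is positive in every sample the pipeline falls
back to library-size ratios with a warning. RPKM
(`count / (library size/10⁶) / (length/10³)`) is computed for inspection
only; testing always uses raw counts plus size factors.

**Wald test.** Per gene, with normalised counts `q_ij = K_ij / s_j` and
group means `m_P`, `m_C`:

* `log2FC = log2((m_P + c)/(m_C + c))` with pseudocount `c = 0.5`
  normalised counts, which keeps fold changes finite and standard errors
  non-degenerate at n = 5 per group;
* dispersion by method of moments on normalised counts pooled within groups
  (`s² − μ`)/`μ²` with residual df = n − 2, floored at `α_min = 0.01`;
* the delta-method standard error
  `SE² = Σ_g (m_g + α m_g²) / n_g / ((m_g + c) ln 2)²` over the two groups,
  Wald statistic `log2FC / SE`, two-sided normal p-value;
* genes with all-zero counts are excluded from testing and from the
  multiple-testing family;
* Benjamini–Hochberg adjustment, by default in two separate families (mRNA
  and lncRNA, mirroring how DEmRNAs and DElncRNAs are reported separately);
  a joint family is available (`bh_family="joint"`).

A gene is differentially expressed iff `|log2FC| > 1` **and** adjusted
`P < 0.05`, both strict.

This is deliberately a *minimal* NB pipeline. It shares DESeq2's model and
normalisation but none of its refinements — no Cox–Reid dispersion
estimation, no dispersion or fold-change shrinkage, no independent filtering
— so exact numerical parity with DESeq2 is not expected and not claimed. A
cross-check test verifies that both call the same strong planted effects
with the same signs.

## Coexpression

Pearson correlation of `log2(normalised counts + 1)` across all samples of
both groups, for every DE lncRNA × DE mRNA pair. The log transform is the
standard variance-stabilising choice for counts; correlating raw normalised
counts is available (`coexpr_transform="none"`). The p-value uses the exact
t transform `t = r √((n−2)/(1−r²))` with df = n − 2 (deterministic and
appropriate at n = 10; permutation nulls are out of scope); `|r| = 1` maps
to `p = 0`. A pair is coexpressed iff `|r| > 0.9` and `p < 0.01`. Constant
expression rows have undefined correlation and are skipped with a warning.

Because correlation is computed across both groups pooled, any two genes
with strong fold changes share the group-mean signal and correlate to a
degree set by their gene-specific variability. This is a property of the
method, not an artifact of the simulator; it is why coexpression lists
always contain group-effect-driven pairs beyond mechanistically linked ones.

## Network layers

**cis.** Genomic distance is the gap between gene-body intervals (0-based
half-open internally; GTF input converted on read, converted back on
write): 0 when the bodies overlap or abut, otherwise the number of bases
strictly between them; genes on different chromosomes are incomparable and
never cis. The window is `≤ 100 000 bp` inclusive and strand-agnostic — a
symmetric "down- or upstream" window anchored on gene bodies, not TSSs.

**trans.** For each (lncRNA, TF): universe `N` = all DEmRNAs, category `K` =
the TF's targets within the universe, draw `n` = the lncRNA's coexpressed
DEmRNAs, observed overlap `k`; `P(X ≥ k)` by the exact hypergeometric upper
tail; BH across all performed (lncRNA, TF) tests; retained at adjusted
`P < 0.05`, with the overlap genes reported as the trans targets. Tests with
`K = 0` or `n = 0` are skipped. TF names are opaque set labels.

**ceRNA.** For each coexpressed pair with `r > 0`, one triple per miRNA that
targets both members according to the interaction table. The positive-sign
requirement is an assumption of this package: the sponge model implies
co-directional expression of the lncRNA and the de-repressed mRNA. It can be
lifted (`ce_positive_only=False`). miRNA interactions come from an input
table by default; a canonical seed-match scanner (6mer, 7mer-A1, 7mer-m8,
8mer sites against miRNA positions 2–8, U/T-equivalent, case-insensitive)
is provided so the stage is testable without an external predictor —
thermodynamic or conservation scoring is intentionally out of scope.

## Enrichment

Plain hypergeometric over-representation of the DEmRNA list against GMT
terms, BH across terms, universe = all mRNAs that entered DE testing
(nonzero counts). DAVID's modified Fisher (EASE) score is *not* reproduced;
plain ORA is the common denominator of the usual tools. Output is sorted
deterministically by (adjusted p, p, term name).

## qPCR

`ΔCt = Ct(target) − Ct(reference)`; the calibrator is the mean control-group
ΔCt per target, `ΔΔCt = ΔCt − calibrator`, relative quantity `2^−ΔΔCt` (so
the control group's geometric-mean RQ is 1 by construction). Technical
replicates are mean-collapsed per (sample, target) first. The group
comparison is a pooled-variance Student t-test on ΔCt values — the
approximately normal log2 scale — rather than on `2^−ΔΔCt`; this is a
documented choice, with RQ-scale and ΔCt-scale dispersions both reported
because published error bars can be either. The per-target qPCR
`log2FC = −(mean patient ΔCt − mean control ΔCt)` exactly. Concordance with
sequencing reports per-target sign agreement and the Pearson correlation of
the two log2FC vectors (≥ 3 shared targets). Amplification-efficiency
correction (Pfaffl) is out of scope.

## Synthetic cohorts

The generator emulates the data shapes the pipeline consumes at the scale of
the motivating study — 5 patients vs 5 controls, 800 mRNAs + 200 lncRNAs —
and plants recoverable truth for every stage. Counts are drawn from
`NB(mean = s_j · μ_i · 2^(log2FC_i · patient_j + o_ij), α_i)` with log-normal
base means (median 100, log-sd 1), gamma dispersions (mean 0.1, floor 0.01)
and log-normal true size factors (sd 0.15).

The latent log2 offset `o_ij` carries the biological structure:

* members of a planted coexpression group share
  `o = σ_lat (√ρ · z + √(1−ρ) · ε)` with `σ_lat = 0.7` log2 units and target
  correlation `ρ = 0.98`; the anticorrelated control pair flips the sign of
  `z` (and of its fold change);
* every other gene gets an independent biological latent of `σ_bio = 0.9`
  log2 units. Without such gene-specific variability every pair of strong DE
  genes would correlate near 0.9 through the shared group effect alone and
  the trans layer's overlap test would drown in group-driven coexpression;
  real cohorts always carry this variability.

Two deliberate departures from naive sampling make the planted truth exact
rather than approximate:

* latents are **group-centred**, so the realised group-mean difference of a
  null gene is exactly zero and of a planted gene exactly its configured
  log2FC — calibration measurements (false-positive fraction, empirical
  FDR) then measure the test, not the generator's luck;
* planted-group latents are **bounded** (uniform with unit variance) so a
  single extreme sample cannot dominate a pair member's within-group
  variance estimate at n = 5.

Planted structure: 4 cis pairs at exactly 50 kb, 2 same-chromosome pairs at
250 kb and 1 cross-chromosome pair (all coexpressed — they must appear in
the coexpression layer and must *not* appear cis), 3 shared-miRNA triples,
1 anticorrelated shared-miRNA pair (must not become a ceRNA triple), one hub
lncRNA whose 8 coexpressed mRNAs form the planted TF's target set (plus 5
decoy TFs and 15 decoy miRNAs), one planted enriched term among 10 decoys,
and 100 + 24 free DE genes at `|log2FC| ∈ {1.5, 2, 3}` with 85%
downregulated, matching the downregulation-dominated profile of
bone-marrow-failure cohorts. Pair members use base mean 500 and dispersion
0.01 so the target correlation survives counting noise, and are planted at
log2FC −3. Genes are laid out so planted distances are exact and all other
gene pairs sit > 100 kb apart; emitted GTF round-trips reproduce the planted
distances exactly. qPCR Ct values are
`baseline − log2FC · patient + N(0, 0.3)` cycles with a flat reference gene;
the validation panel is six well-expressed downregulated planted genes
(3 mRNA, 3 lncRNA) spanning the three effect magnitudes, so the seq-vs-qPCR
correlation has genuine spread.

What the generator does **not** emulate: read-level artifacts (GC bias,
mappability), batch effects, outlier samples, correlated miRNA expression,
annotation errors, or library-preparation variability beyond a scalar size
factor. Passing the planted-recovery tests therefore demonstrates that the
pipeline's inference is correct under its own model assumptions at the
study's sample size — not that those assumptions hold in any particular
real dataset.

## Problem sizes and determinism

Test-suite and acceptance-script cohorts use 1000 genes (the default) or
reduced 120–160-gene cohorts where many replicates are simulated; null
calibration uses 1000 genes and 1000 independent null pairs. All randomness
flows from a single seeded NumPy generator per cohort; same-seed runs are
byte-identical, including every emitted file.

## Known limitations

* The NB Wald test is anticonservative in principle at n = 5 with noisy
  moment dispersions; BH and the fold-change filter keep the realised
  false-positive fraction well under control in calibration runs, but
  borderline effects (|log2FC| ≈ 1.5 at low expression) have modest power.
* The 100 kb cis rule uses gene bodies, not TSSs, and ignores strand; a
  TSS-anchored directional window would classify some boundary pairs
  differently.
* The hypergeometric trans test inherits the coexpression list's
  group-effect-driven pairs into its draw set `n`, which dilutes overlaps;
  it is exact only conditional on that list.
* ceRNA inference from shared predicted sites is a necessary-condition
  screen, not evidence of sponging.
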