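# Methods

`rhexpress` implements the genomic analysis of a cytokine-stimulated
reconstructed human epidermis (RHE) experiment and its downstream
clinical validation: which genes does IL-17 (or IL-22, IFN-γ) induce in
a stratified keratinocyte culture, and do those genes normalize in
psoriatic lesions when the cytokine is blocked therapeutically?  The
package operates entirely on normalized log2 expression matrices;
array-level preprocessing (background correction, normalization, spatial
QC) is out of scope and assumed done upstream.

## Differential expression: the moderated paired t-test

The RHE design is paired: each tissue donor contributes one untreated
and one cytokine-treated culture.  For probe g with per-pair log2
differences x_g1..x_gn (n pairs), let m_g and s_g² be their sample mean
and variance (df = n − 1).  With only 4 pairs, per-probe variance
estimates are unstable, so variances are shrunk toward a prior fitted
across all probes.  The model is the standard empirical-Bayes hierarchy:

    x_gi ~ N(δ_g, σ_g²),    σ_g² ~ s0² · d0 / χ²_{d0},

giving the posterior variance and moderated statistic

    s̃_g² = (d0·s0² + df·s_g²) / (d0 + df),
    t_g  = m_g / sqrt(s̃_g² / n),     t_g ~ t_{df + d0} under δ_g = 0.

`d0 = 0` reduces to the ordinary paired t-test; `d0 = ∞` tests against
the common variance s0² with a normal reference.  The prior is fitted by
moments on the log scale: with e_g = log s_g² − ψ(df/2) + log(df/2),
the excess of Var(e) over ψ′(df/2) identifies ψ′(d0/2), solved by a
Newton iteration on the trigamma function; s0² then comes from the mean
of e with the d0 bias correction.  When the observed dispersion does not
exceed chi-square sampling noise the fit degenerates to d0 = ∞ with s0²
the geometric mean of the variances (this matches the reference
Bioconductor implementation, which one test cross-checks via Rscript).

p-values are adjusted by Benjamini–Hochberg step-up (delegated to
statsmodels); a probe is a DEG when |FCH| > 1.5 and FDR < 0.1, both
strict, where FCH is the signed linear fold change sign(m)·2^|m|
(|FCH| > 1.5 ⇔ |m| > log2 1.5).  Before testing, probes must show
expression above 3 log2 units in at least one sample and SD above 0.1
(both strict, SD with denominator n − 1); filtering precedes pairing.

## Probe/gene duality and platform restriction

Array platforms measure probe-sets; several probe-sets may interrogate
one gene, so DEG counts are reported both ways.  A gene is
up-regulated iff at least one of its probes is an up-DEG; genes hit in
both directions stay in both sets and are surfaced as conflicts
(the resolution is genuinely open; keeping both is the conservative
choice).  When comparing against cohorts profiled on a smaller platform
whose probe universe is a subset of the RHE platform, DEG sets are
restricted to the smaller platform's probes first and gene sets
recomputed from the survivors.  Venn partitions over 2–3 labelled gene
sets enumerate all 2^k − 1 membership signatures; regions are disjoint
and sum to the union by construction (asserted at run time).

## Pre-ranked GSEA

Genes are ranked by signed log2 fold change; multi-probe genes take the
probe of maximal |log2 FCH| (deterministic, probe-id tie-break).  The
enrichment score is the weighted Kolmogorov–Smirnov statistic: the
running sum gains |metric|^w (normalized over the set's hits) at member
positions and loses 1/(N − n_members) elsewhere; ES is the extreme
deviation, with exact magnitude ties resolved to the positive side.  At
w = 0 this is the classical KS statistic (tested against brute-force
enumeration); the default is w = 1.

With 4 pairs, phenotype permutation cannot produce enough distinct
relabellings, so significance uses gene-sampling permutation: each
set's null ES comes from re-drawing member genes uniformly from the
ranked universe (1,000 draws by default, seeded).  NES divides ES by
the mean same-sign null |ES|; the nominal p is the same-sign null tail,
reported at the resolution 1/n_perm (and flagged) when no permutation
is at least as extreme; the FDR q normalizes null and observed NES into
positive/negative pools in the standard way and is capped at 1.

## Recovery scoring

For a cohort with non-lesional (NL), lesional-baseline and
lesional-week-2 samples in several treatment arms, each scored gene
gets a baseline dysregulation d = mean(LS baseline) − mean(NL) (or a
supplied meta-analysis effect, which overrides the matrix estimate), a
treatment effect t = mean over patients of the within-patient (week2 −
baseline) change (pairing within patient first — the pooled alternative
is not equivalent under missingness and was rejected), and an
improvement of −t/d·100 percent.  Positive improvement moves toward NL;
overshoot (>100) and worsening (<0) are reported unclipped.  Genes with
|d| < 0.1 log2 are excluded rather than divided (listed, never silently
dropped).  A gene is improved when improvement ≥ 75% (inclusive — "at
least 75%" read literally; the threshold is a parameter).  Arms are
summarized by the proportion of eligible genes improved and by
mean(−sign(d)·t), the average log2 movement toward NL, also
exponentiated to a fold change.  The non-improved genes are exported as
the residual-disease profile.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
on the log2 scale with Gaussian noise (log-normal on the raw scale,
matching the character of GCRMA-style output):

* **Paired experiment** — value = μ_g + subject_i + δ_g·[treated ∧
  responsive] + ε, ε ~ N(0, σ_g²), with σ_g² drawn from the scaled
  inverse chi-square prior (defaults d0 = 4, s0² = 0.05 (log2)²),
  baselines μ_g ~ N(7, 2²), an additive subject effect (SD 0.3) that
  makes the paired test strictly more powerful than the unpaired one,
  responsive fraction π = 0.1, planted |δ| ~ |N(1.5, 0.25²)| with 66%
  up — the up/down ratio of the RHE response.  Defaults: 10,000 probes
  shared between the two platform tiers plus 2,000 on the larger tier
  only, 4 pairs.  `s0_sq = 0` is the exact noiseless limit.  Variances
  are floored at 1e-8 to avoid degenerate division.
* **Annotation** — each gene owns 1–3 probes; probes never cross the
  shared/plus-only boundary, so the plus-only count is exact.
* **Cohort** — 3 arms × 10 patients, each contributing NL, LS-baseline
  and LS-week-2 samples; dysregulated genes get d ~ ±|N(2.2, 0.5²)|
  (2:1 up:down) and per-gene recovery fractions r ~ Beta(α, β) of the
  arm: week2 = baseline − r·d + noise (SD 0.05).  Arm defaults:
  IL-17 blockade Beta(8.5, 2) so P(r ≥ 0.75) ≈ 0.73; TNF blockade
  Beta(1.0, 0.85) so P(r ≥ 0.75) = 0.25^0.85 ≈ 0.31; placebo r ≡ 0.
  A gene-level Beta cannot simultaneously match a partial-responder
  arm's improved-proportion and its mean log2 recovery; the proportion
  scale was preferred.  Recovery fractions are drawn per gene, not per
  patient, because the scoring is gene-level.

Ground truth (responsive probes, true effects, true variances,
dysregulation and recovery fractions) is recorded so the pipeline can
be scored for sensitivity, false-discovery proportion and parameter
recovery.  Identical config + seed gives byte-identical output; all
randomness fans out from one seed via spawned `SeedSequence` children.

What the generator does **not** emulate: probe-level hybridization,
normalization artifacts, correlated noise across probes of one gene,
batch effects, patient-level random effects in the cohort, or heavy
tails.  Passing tests therefore demonstrate correctness of the
statistics under the model's own assumptions, not robustness of the
original biological conclusions to real-array artifacts.

## Numerical choices and degenerate inputs

* Trigamma inverse by Newton iteration (relative tolerance 1e-10), with
  asymptotic branches below 1e-6 and above 1e7.
* Zero posterior variance: t = ±∞ with p = 0 when the mean difference
  is nonzero, t = 0 / p = 1 when it is zero.
* Exact-zero p-values are floored at the smallest positive float before
  BH adjustment.
* DEG tables sort by |FCH| descending with lexicographic probe-id
  tie-break; ranked lists by metric descending with gene-id tie-break —
  all output orderings are deterministic.
* Sets overlapping a ranked list completely or not at all have no
  defined ES and are dropped with a notice, not scored.
* If every hit metric is zero at w = 1, the ES step falls back to equal
  weights rather than dividing by zero.

## Problem sizes

The default study design (12,000 probes, 4 pairs, 1,000 permutations,
3 × 10-patient arms) runs the whole pipeline in about two seconds.
Test-suite simulations use 5,000 probes for calibration/power checks,
20,000 variances for prior recovery, and 2,000 dysregulated genes for
recovery-fraction checks; the exhaustive ES-vs-KS enumeration covers
every member placement for list lengths up to 17 and dense plus random
placements for 18–20.
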