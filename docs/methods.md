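# Methods

This note documents the models, defaults and design choices behind
splicegrade, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` do not
themselves compute.

## Pipeline boundary and data model

The pipeline starts at transcript-level quantification tables
(`Name/Length/EffectiveLength/TPM/NumReads` per sample) and a GENCODE-dialect
GTF; read QC, trimming and quantification are upstream tools and out of
scope. Abundances are converted to length-scaled counts: for transcript *i*
in sample *s*, c′ᵢₛ = TPMᵢₛ · L̄ᵢ with L̄ᵢ the mean effective length across
samples, then each column is rescaled by one factor so its sum equals the
sample's original estimated-fragment total. This makes counts proportional
to transcript molarity while preserving per-sample depth; with effective
lengths constant across samples the transformation is exactly
count-preserving. Zero effective lengths are clamped to 1 bp with a warning.
Gene-level matrices are sums of member-transcript rows (counts and TPM),
in first-appearance order; feature order is deterministic everywhere and
never depends on hash order.

Transcript biotypes are collapsed onto five codes — Pc (protein coding),
NMD (nonsense-mediated-decay prone), PT (processed transcript), RI (retained
intron), other — accepting both `transcript_type` (GENCODE) and
`transcript_biotype` (Ensembl) attribute keys, first match wins.

## Filtering and normalization

A transcript is expressed within a tissue when CPM ≥ `min_cpm` (default 1)
in ≥ `min_samples` (default 4) samples; samples are pooled across all diet
groups of the tissue, the reading consistent with 4 being the smallest group
size. A gene is expressed iff ≥ 1 member transcript is. Filtering uses raw
library sizes because it precedes normalization. The filter is monotone:
relaxing either threshold can only enlarge the kept set.

TMM follows the canonical published algorithm: reference sample = the one
whose CPM upper quartile is closest to the mean upper quartile; for each
sample vs the reference, genes with a zero in either member are dropped,
M = log₂ ratio of relative abundances, A = mean log abundance; 30% of the M
tails and 5% of the A tails are rank-trimmed; remaining M are averaged with
inverse delta-method variance weights
(Nₛ−cₛ)/(Nₛcₛ) + (Nᵣ−cᵣ)/(Nᵣcᵣ); the factor is 2^(weighted mean) and
factors are rescaled to geometric mean 1. The implementation reproduces the
reference R implementation to printed precision (checked by a test that
shells out to it when available). Note that because the precision weights
depend on absolute counts, factors are only approximately invariant to
rescaling a single library (the M-values themselves are exactly invariant).

## Differential expression

log₂-CPM uses prior count 0.5 against TMM-effective library sizes:
y = log₂((c + 0.5)/(L̃ + 1)·10⁶). The mean–variance trend is estimated from
an unweighted group-means fit: lowess (span 0.5, 4 robustness iterations) of
√(residual sd) on fitted mean log-count, flat extrapolation outside the
fitted range; each observation's weight is predicted-sd⁻⁴ evaluated at its
fitted log-count. An optional single multiplicative per-sample quality
weight (one round of gene-averaged weighted residual-variance ratios,
geometric mean 1) can be folded in; it is off by default to keep the default
path simple and reproducible — the fully iterated variant found in other
toolchains is deliberately not implemented.

Per feature, weighted least squares under a samples × groups indicator
design yields exact WLS quantities; contrasts are treatment-mean minus
control-mean for every dose level against the control group (a `24AL`-style
extra control may be present in the data; it is simply never contrasted).
Empirical-Bayes moderation models s² ~ s₀²·F(d, d₀); (d₀, s₀²) are estimated
by matching the mean and variance of log s² (closed forms in digamma/
trigamma, trigamma inverted by Newton iteration). Equal variances drive the
estimator to the d₀ = ∞ branch deterministically. Moderated
t = β̂/(SE·sₚₒₛₜ) is referred to a t distribution on d₀ + d df (normal limit
when d₀ = ∞). BH adjustment is applied within each
(tissue, feature-level, contrast) family. Calls use strict inequalities,
FDR < α (default 0.05) and |log₂FC| > τ (default 0.5); features exactly at a
boundary are never called. Setting α = 1 disables the FDR gate (otherwise an
adjusted p of exactly 1 could never satisfy a strict inequality), which is
the documented way to export unfiltered tables.

## Differential transcript usage and splicing

Ψ is computed on TPM of the expressed isoforms: Ψᵢₛ = TPMᵢₛ/Σⱼ TPMⱼₛ over the
gene's members, undefined where the gene total is zero. ΔΨ averages Ψ per
sample and then differences group means (not a ratio of group-total TPM; the
per-sample averaging is isolated in one function should the alternative ever
be needed), requiring ≥ `min_valid` (default 3) defined values per group.

The DTU p-value is built from the expression fit rather than from Ψ
directly: for isoform *j* of gene *g*, the deviation of its contrast log₂FC
from the gene's precision-weighted (w = 1/SE², moderated SEs) average, with
the leave-weight variance correction Var = SEⱼ²(1 − wⱼ/Σw), referred to the
moderated df. This construction is what makes gene-level Simes combination
of member p-values coherent, with ΔΨ acting as the effect-size filter — a
common expression shift moves all member β's equally and cancels exactly, so
splicing calls are invariant to pure DE (verified on simulations). Zero SEs
(noiseless degenerate input) produce p = 0 with a warning; p-values that
underflow to 0 are clamped to the smallest positive float before BH.
Single-isoform genes are untestable for usage change and are excluded from
DTU/DAS while remaining in DE. The DTU call direction is the sign of ΔΨ; the
5% threshold applies to |ΔΨ| (reduced inclusion is reported as DTU-down).
BH families are all tested isoforms (respectively all testable genes) of one
tissue × contrast.

## Integration layers

DE∩DAS co-regulation uses the exact upper-tail hypergeometric P(X ≥ k) with
the universe = genes passing the expression filter in that tissue — the null
must condition on testability, and the universe is configurable by passing a
different id set. Combination matrices follow UpSet semantics (exclusive
subset counts summing to the union size; an inclusive mode is available).
Cross-tissue comparisons are keyed by gene/isoform identifiers; only the
splicing-regulator list is symbol-keyed, since such lists are assembled from
ontology queries. Unresolvable symbols are reported, not fatal. "Unique
DEGs across doses" means the union over contrasts. The dose-trend summary
flags, per tissue × layer, whether counts are non-decreasing along the
ordered doses.

## Synthetic data generator

The generator emulates the targeted study design: six tissues, an *ad
libitum* control plus four graded restriction levels with group sizes
(8, 8, 8, 7, 9), genes carrying 1–10 isoforms (majority single/few-isoform),
and negative-binomial counts. Expected fragment counts are
μᵢₛ = Lₛ · θ_g · fold_g(dose) · uᵢ(dose) · ℓᵢ / Σ(…ℓ) with Lₛ a lognormal
library size (mean 10⁷, CV 0.1 — modest depth, as in older bulk libraries),
θ_g lognormal relative gene abundances (σ = 1.5), u the within-gene usage
vector (Dirichlet(2) baseline), ℓ effective lengths (lengths uniform
0.5–5 kb minus 200 bp); counts are gamma-Poisson with a single global
dispersion φ (default 0.05, variance μ + φμ²; the literature reports no
noise model for the target design, so this standard RNA-seq assumption is a
convention, not an estimate). TPM is recomputed from the sampled counts
exactly as a quantifier reports it, so written fixtures round-trip through
the importer bit-for-bit in the equal-effective-length case.

Planted differential expression multiplies a gene's abundance by
2^(log₂FC·f(dose)); planted usage switches move ΔΨ·f(dose) of proportion
from exactly one losing to one gaining isoform, leaving others untouched —
the simplest mechanism producing isoform-pair switch profiles. f is linear
in dose by default (effects broadly proportional to restriction level), with
a step option for threshold-like responses at the two highest doses. When
the switch pair is chosen automatically, the least-used isoform gains and
the most-used loses; if the loser's baseline usage cannot absorb the full
shift it is topped up (mass taken proportionally from the others) so the
planted trajectory stays inside [0, 1]. Explicitly specified infeasible
pairs are an error. Effect-size helpers spread magnitudes evenly over a
range (default log₂FC 0.7–2.0, ΔΨ 0.08–0.30) — a graded mix of weak and
strong responders, so detection counts keep growing with dose instead of
saturating. Ground truth (per-gene log₂FC, per-isoform ΔΨ, boolean labels
at each dose) is emitted alongside.

Randomness is organized as one master seed: annotation, structural
parameters and per-tissue sampling noise live on separate derived streams,
and tissue streams are spawned children, so adding tissues never perturbs
existing ones and fixtures are byte-identical for a fixed seed.

What the generator does **not** model: positional/GC bias, correlated
inter-gene structure, quantification uncertainty (bootstrap replicates),
batch effects, or sex differences. Passing tests therefore demonstrate
statistical correctness of the pipeline under a clean NB world, not
robustness to those real-data artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script use deliberately compact designs —
2000 genes for null calibration, 800 genes for power, 6 tissues × 400–500
genes for the dose-response and end-to-end checks — chosen as the smallest
sizes at which the Monte-Carlo error bands (3×SE) are informative.
Tolerances: closed-form operations match independent oracles to 1e-8; the
unmoderated pipeline matches brute-force WLS to 1e-10; stochastic checks use
3×binomial-SE bands. Ties in BH are preserved by a stable sort; Simes caps
at 1; the trigamma inversion iterates Newton steps to a 1e-10 relative
tolerance with closed-form guards at both extremes.

## Known limitations

- The DTU test inherits the limitations of isoform-level analysis: it cannot
  distinguish alternative splicing from isoform-specific transcriptional
  regulation, and event-level classification (exon skipping, intron
  retention as events) is explicitly out of scope.
- Quality weights are a single-round approximation, not the iterated
  original.
- The simulator's feasibility top-up slightly biases baseline usage of
  auto-chosen switch genes toward the planted loser; user-specified pairs
  avoid this.
- BH is applied per contrast; families are not pooled across doses or
  tissues, so cross-family comparisons of FDR values are informal.
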