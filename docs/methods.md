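# Methods

## Setting and data

The package analyses the causal effect of HDL cholesterol efflux capacity
(CEC, in SD units) on six binary cardiovascular outcomes using two-sample
summary-data Mendelian randomization. The bundled instrument is six SNPs at
five lipid-biology loci (*LPL*, *LIPC*, *CETP*, *APOA1/C3/A4/A5*,
*APOE/C1/C2/C4*) from a CEC GWAS of up to 5,293 European-ancestry
individuals; outcome associations come from CARDIoGRAMplusC4D (CAD
60,801/123,504 cases/controls; MI 43,677/128,199) and MEGASTROKE (ischemic
stroke 40,585/406,111; subtype cases 34,217 LAS / 5,386 SVS / 7,193 CES).
rs141622900 alone is the primary instrument; the other five SNPs
(mutually independent, r² < 0.1) form the sensitivity instrument. All
tables ship verbatim as TSV inside the package; outcome tables carry no
allele frequencies, so harmonization of bundled data rests on allele
letters and the exposure EAF is carried onto each instrument.

## Harmonization

Exposure and outcome rows are aligned to a common effect allele: swapped
alleles negate the outcome beta and complement the frequency; strand flips
are resolved through base complements. Palindromic variants (A/T, C/G) are
dropped, with a log message, when both allele frequencies lie within a
window around 0.5 (default ±0.08, i.e. EAF ∈ (0.42, 0.58) — the common
conservative choice; configurable) because letters and complements are then
indistinguishable; outside the window the frequencies decide orientation,
and with no outcome frequency at all the variant is kept on letter
alignment and flagged. Harmonizing an already-aligned pair is a no-op, and
two successive flips restore the original orientation (tested as a
property). A p-value printed as exactly 0 in a source table is stored as
absent rather than rejected; quoted p-values inconsistent with
2·Φ(−|β/σ|) beyond print rounding raise a warning, never an error.

## Estimators and conventions

All weights are first-order ("NOME"): the exposure SE is carried on every
instrument but does not enter any weight. This matches the convention under
which the published confidence intervals reproduce, and understates
uncertainty slightly when instruments are weak — documented limitation.

- **IVW** defaults to the fixed-effect variance model. The analysis this
  package reproduces describes multiplicative random effects, but its
  printed intervals (e.g. CAD 0.79–0.90) match fixed-effect SEs, so fixed
  is the default and `variance_model="multiplicative"` (SE inflated by
  max(1, √(Q/(k−1)))) is available. The closed-form weight combination is
  checked against an independent through-origin WLS fit (statsmodels) to
  1e-12 in the tests.
- **MR-Egger** orients every instrument to β̂X ≥ 0, fits WLS with intercept
  and weights 1/σY², and scales the coefficient covariance by
  RSS_w/(k−2) **without** a floor at 1 — the unfloored convention is what
  reproduces the published intercept interval. Inference is normal-based.
- **Medians** interpolate the ordered ratio estimates at p = 0.5 of the
  standardized cumulative weights pⱼ = (Σ_{i≤j}wᵢ − wⱼ/2)/Σw, clamping to
  the extreme ratio when 0.5 falls outside [p₁, p_k]; ties are broken by a
  stable sort on snp_id. SEs come from a parametric bootstrap (default
  1000 replicates) resampling both β̂X and β̂Y from their normal sampling
  distributions; the generator seed is an explicit argument and results
  are bit-reproducible at fixed seed and replicate count.
- **Multivariable IVW** regresses β̂Y on the full exposure-effect matrix
  without intercept, weights 1/σY², covariance inv(X′WX) with no residual
  scaling — chosen so a single-exposure fit reduces *identically* to
  fixed-effect IVW. Rank deficiency raises an error naming dependent
  columns. The bundled data include no covariate GWAS effects, so this
  estimator is validated on synthetic designs only.
- **z-quantile** is fixed at 1.959964 everywhere; odds ratios are shown to
  2 decimals, Egger intercepts to 3, Q to 1, I² as integer percent in
  rendered reports, while TSV/JSON serializations keep full precision.
- p-values below 1e-300 are rendered "<1e-300"; no continuity corrections
  anywhere.

## Heterogeneity

Cochran Q uses the ratio estimates and weights β̂Xᵢ²/σYᵢ² about the
fixed-effect IVW estimate, df = k−1; I² = max(0, (Q−df)/Q), defined 0 at
Q = 0. Per-SNP contributions wᵢ(θ̂ᵢ−θ̂)² are returned and sum to Q. Q is
invariant under common rescaling of all exposure effects (the
exposure-unit ambiguity), tested as a property. Between-outcome
comparisons apply the same fixed-effect machinery to per-outcome causal
estimates with their **fixed-model** SEs — the choice under which the
published between-outcome I² values (80–93%) reproduce. No pooling across
outcomes is performed: the statistic tests difference, nothing more.

## Instrument strength and power

Per-SNP variance explained is 2β̂X²·m(1−m) with m the minor-allele
frequency min(EAF, 1−EAF); the instrument F statistic is
(r²/k)/((1−r²)/(n−k−1)). Power for a binary outcome uses the
normal-approximation non-centrality form
Φ(√(N·r²·p(1−p))·|ln OR| − z_{1−α/2}) with p the case fraction (cases
divided by the "up to N" GWAS total — the combination that reproduces the
published power figures); at OR = 1 it evaluates to α/2 by construction,
the one tail the formula tracks, and this is documented rather than raised.
No simulation-based power and no weak-instrument bias corrections are
provided.

Two print-precision quirks of the source analysis are reproduced as
computed, not as printed: the five-SNP variance explained evaluates to
4.30% from the five table rows (5.18% over all six; the text prints 5.3%),
and the two power-grid entries at OR 0.70 evaluate to 69.4% and 81.2%
(printed 70% and 82%); the labels attaching F = 59.2 / 45.9 to the 1-SNP /
5-SNP instruments appear transposed relative to what the formula yields,
so both computations are exposed and neither label is guessed.

## Synthetic data

The generator draws summary statistics directly from their asymptotic
sampling distributions — no individual-level genotypes — which suffices to
validate every estimator in the package and is orders of magnitude faster.
Per SNP: MAF uniform on (0.05, 0.5); true exposure effect |N(0, 0.2²)|,
coded to the exposure-increasing allele as published instrument tables are
(this is also what makes *directional* pleiotropy well-defined — a direct
effect of fixed sign on that allele); true outcome effect θ·b + α with α
zero for valid SNPs and N(±mean, sd²) for the invalid fraction (signs
mixed under balanced, one-sided under directional pleiotropy); observed
effects add noise with SEs 1/√(2f(1−f)·n_exp) and
1/√(2f(1−f)·N·p(1−p)). Defaults mirror the bundled study design:
exposure n = 5,293; outcome 60,801/123,504; θ = ln 0.85; 50 SNPs. An
optional flag scrambles outcome allele orientation to exercise
harmonization. The generator omits linkage disequilibrium, sample overlap,
winner's curse in instrument selection, and allele-frequency differences
between samples — a green recovery test therefore establishes estimator
correctness under the stated sampling model, not robustness to those
phenomena.

One property deserves note: under directional pleiotropy the weighted
median is *consistent* (bias of order the per-SNP ratio SE, vanishing as
GWAS sample sizes grow, provided valid instruments hold >50% of the
weight in that dataset) but not unbiased at finite sample size — its mean
across replicates sits a few thousandths above the truth because the 0.5
weight quantile falls near the upper edge of the valid cluster. The test
suite therefore checks the 1/√n decay of the conditional bias against the
flat bias of IVW, rather than demanding the mean equal the truth to
Monte-Carlo error.

## Known limitations

- First-order weights ignore exposure-side uncertainty (see above).
- The bundled outcome tables lack EAFs, so palindromic screening on the
  bundled data is impossible in principle; none of the six SNPs is
  palindromic, so this is moot here.
- The single-SNP odds ratios shown in the source analysis's figure are not
  derivable from its printed instrument table (they imply a different
  exposure beta); this package computes from the printed tables, and
  scale-invariant statistics (Q, I², p-values) are unaffected.
- Multivariable MR lacks real covariate inputs (not published); only the
  estimator is provided.
- No LD-aware methods, no MR-PRESSO/mode-based estimators, no Steiger
  filtering: the implemented method set is exactly the one the analysis
  used.
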