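# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices that matter for reproducing results.

## Synthetic summary data

**GWAS pairs** (`simulate.simulate_mr_pair`). Traits are standardized, so a
variant with allele frequency p in a study of N samples has
SE = 1/√(2p(1−p)N); N therefore controls instrument strength exactly as the
F statistic expects. True instrument effects are drawn with |z| uniform on
(z_gw+2, z_gw+12) above the genome-wide threshold; when sampling noise would
push an observed z below threshold the true effect is rescaled upward while
keeping the realized noise draw, so runtime is bounded (no rejection
sampling) and the truth record stores realized effects. Outcome effects
follow b_y = β b_x + sign(b_x)·α·1[invalid] + η with α ~ N(pleio_mean,
pleio_sd²) and η ~ N(0, het_sd²). Direct effects are expressed relative to
the exposure-increasing allele — the orientation under which "directional"
pleiotropy is defined and under which the Egger intercept estimates the mean
direct effect. MAFs are uniform on (0.05, 0.5); palindromic allele pairs are
assigned with probability 0.2 and outcome rows report the swapped allele
pair with probability 0.2, so harmonization filtering and sign-flipping are
exercised on every simulated pair.

**QTL loci** (`simulate_qtl_locus`). Marginal z-scores follow
z ~ MVN(RΛ, R) with R an AR(1) LD matrix (ρ = 0.8 by default) and Λ the
causal non-centrality (b√N at causal variants). The pleiotropy model places
one causal variant for both traits; the linkage model places two variants
two positions apart with ρ chosen so their r² equals `r2_linkage` exactly;
the null model has no GWAS signal. Loci use exactly two causal variants in
the linkage model; multi-causal loci are a known limitation.

**Expression studies** (`simulate_expression_study`). Gene variances are
scaled inverse chi-square d₀s₀²/χ²_{d₀} — the same family the moderation
stage assumes — with defaults d₀ = 4, s₀² = 0.25 (moderate heterogeneity on
a log2 microarray-like scale). DE genes receive a log2FC of
N(logfc_mean, logfc_sd²) with random sign in cases. Optional batch offsets
are pure location shifts on two batches balanced across groups.

What the generators do **not** emulate: real LD panels, winner's-curse
selection of instruments, population stratification, correlated pleiotropy
(violating InSIDE), probe-level microarray artifacts, or count-based RNA-seq
noise. Passing tests therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not robustness to every failure mode
of real cohorts.

## Two-sample MR

- IVW is a weighted regression of b_y on b_x through the origin with weights
  1/se_y². Random effects are multiplicative: SE inflated by
  √max(1, Q/(k−1)) — inflation floored at one so the random-effects SE is
  never below the fixed-effects SE. k = 1 reduces exactly to the Wald ratio.
  Two-sided normal p-values.
- MR-Egger first orients all b_x ≥ 0 (flipping the paired b_y), then fits a
  free intercept by weighted least squares; over-dispersion is estimated with
  k−2 df, floored at one, and inference uses the t distribution on k−2 df.
- Weighted median: per-SNP Wald ratios with delta-method SEs
  (se_y/|b_x|, first-order); the estimate interpolates the weighted 50th
  percentile; the SE is a seeded parametric bootstrap perturbing both effect
  vectors by their SEs (default 1000 draws, seed 42).
- Cochran's Q uses the ratio form Q = Σwⱼ(rⱼ−β̂)², wⱼ = 1/se(rⱼ)², which is
  algebraically identical to the regression residual form; df = k−1.
- Radial outliers: a SNP's Q contribution compared with χ²₁ at α/k
  (Bonferroni by default); a refit without outliers is attached.
- The global pleiotropy test simulates the null of the observed
  leave-one-out residual sum of squares (both effect vectors redrawn from
  the fitted model), with +1-smoothed empirical p. The distortion test of
  the original outlier-correction procedure is omitted — only the global
  test and outlier flags enter the screening logic.
- `run_mr_suite` chains select → clump → harmonize → min-SNP check → all
  estimators on the identical harmonized set, logs a funnel of counts, and
  analyses the swapped direction to populate `reverse_ivw_p`.

Design choices where conventions differ across the ecosystem: the
palindromic ambiguity window is EAF ∈ [0.42, 0.58] (inclusive); clumping
ties at equal p break by smaller genomic position; the clump window is
±window_kb around an accepted SNP on the same chromosome; aggregate R² uses
the standardized-trait per-SNP variance 2p(1−p)β² (per-instrument F values
can be derived from the same helper by calling it with k = 1); a missing EAF
on a palindromic SNP drops the SNP.

## Prioritization

BH is applied once over all primary IVW p-values of the battery, both
directions pooled. The screen flags are: IVW p < 0.05; sign agreement
between weighted-median and IVW estimates (sign only — a zero estimate is
treated as concordant with anything, a degenerate case that is logged);
Egger intercept p > 0.05; Q p > 0.05. Tier logic: any failed
robustness condition (weighted-median concordance, Egger, Q) → non_robust;
otherwise IVW p ≥ 0.05 → null; otherwise q < 0.05 separates high_confidence
from suggestive. A significant reverse-direction IVW is reported as a caveat
and demotes the tier only in strict mode (`strict_reverse=True`), because
reverse causality is an interpretive caveat rather than a screen condition
in the default rules. Representatives are ranked by tier, ascending q,
ascending IVW p, descending instrument count, then lexicographic pair id
for determinism.

## SMR and HEIDI

T_SMR = z_g²z_q²/(z_g²+z_q²) is bounded by the weaker z² (harmonic form);
se(b_SMR) = |b_SMR|/√T_SMR. HEIDI selects SNPs with r² to the top SNP in
(0.05, 0.9) and QTL z² ≥ 10, strongest first, capped at 20 — the defaults of
the standard SMR tooling, assumed because the eligibility windows are a
convention rather than part of the statistic. The deviations
d_i = b_SMR(i) − b_SMR(top) get a delta-method covariance from the
LD-implied covariances of the two independent studies; the p-value is the
tail probability of Σz_d² under the correlated chi-square null, evaluated by
seeded Monte-Carlo sampling of the fitted multivariate normal (20,000 draws
by default — stable to about ±0.01 near the 0.05 boundary; a saddlepoint
approximation would be faster but adds nothing at this decision boundary).
Singular correlation matrices are ridge-regularized with a warning.

Significance tiers per association: Bonferroni (p < 0.05/m with m the number
of probes tested per trait × dataset pool), else suggestive (p < 10⁻⁵, the
conventional suggestive GWAS level), else nominal (p < 0.05), else none.
Gene tiers over HEIDI-passing records: Tier 1 = support from ≥ 2
modality/dataset combinations, concordant directions, and at least one
Bonferroni record; Tier 2 = any remaining gene with a Bonferroni record;
Tier 3 = the rest. Methylation signs are excluded from the concordance
requirement by default (their direction is not interpretable against
expression without annotation); this is configurable.

## Differential expression

Batch correction is a per-gene location adjustment (each batch mean moved to
the grand mean), refused when batch is perfectly confounded with group. This
deliberately replaces a full empirical-Bayes location–scale correction: the
scientific surface tested downstream is the DE statistics and their
integration, and the simulated batches are pure location shifts. The
moderation prior (d₀, s₀²) is estimated by the standard closed-form
log-variance moment method: matching the mean and variance of
log s²_g to the scaled-F model via digamma/trigamma, with the trigamma
equation inverted by Newton iteration (tolerance 10⁻⁸). When the observed
log-variance dispersion does not exceed its sampling component the estimate
is d₀ = ∞ with s₀² = mean(s²_g) (each s² is unbiased for s₀² in that limit)
and all posterior variances collapse to s₀². Moderated t uses d₀+d_g df
(normal when d₀ = ∞); genes with zero posterior variance get p = 1 when the
difference is also zero, flagged degenerate.

## Machine learning

The no-leakage contract is structural: within each stratified fold the
standardizer and SMOTE see only the training partition, and the test
partition stays imbalanced. `cv_evaluate` exposes a `test_transform` hook
and per-fold scaler parameters precisely so this contract can be probed
(corrupting test rows must leave the fitted scalers bit-identical). SMOTE
interpolates x_i + u(x_nn − x_i) among the k = 5 nearest minority
neighbors, truncating k to minority−1 with a warning. The default panel
spans linear (logistic regression), tree-ensemble (random forest, gradient
boosting), kernel (RBF SVM with calibrated probabilities), neighbor (kNN)
and shallow-neural (one-hidden-layer MLP) families; the panel is a config
surface, not a fixed list. Hyperparameter search is seeded random search
over declared grids with an inner validation split maximizing ROC-AUC — the
evaluation contract, not the optimizer brand, is the tested surface.
Importance extraction is hierarchical: |coefficients|, then impurity
importances, then seeded permutation importance; profiles are L1-normalized
(sum to one) before averaging across the top-5 models by mean macro F1, and
per-dataset profiles are averaged into the overall score in [0, 1].

## Evidence integration

Final Evidence Score = overall importance + 0.5 × (number of cohorts with
nominal p < 0.05, strict). Nominal rather than adjusted p is the default for
the count, with an adjusted-p mode available. The single-cell Evidence Score
min-max normalizes three per-gene components — significant-hit breadth,
max |logFC|, min −log10 adjusted p capped at 300 (so reported p = 0 maps to
the cap) — and combines them with weights (1, 0.5, 0.5). The combination
rule is a documented default, fully configurable; published score values
from other analyses are not reproducible without their exact rule.
Candidate selection is strictly greater than 1.0. Sign discordance reports
all context pairs where one gene is significantly dysregulated in opposite
directions, with a neuron-vs-glia flag when a cell-class map is provided.

## Pipeline scale and determinism

The demo battery runs six exposure–outcome pairs (two with planted causal
effects of 0.15 and 0.12 in the neurocognitive → sleep direction, four
null), 40 instruments each at N = 150,000; eight SMR loci across
eQTL/pQTL/mQTL including one linkage and two null architectures; three
expression cohorts of 400 genes (20 cases / 40 controls, 10% DE, one cohort
with a planted batch shift); and a 20-gene candidate panel for the ML stage.
These sizes keep a full run around half a minute while leaving every
statistical contrast well-powered; all of them are config fields. Every
random draw descends from the config seed; outputs are tidy TSV with fixed
float formatting and JSON with sorted keys and no timestamps, so a rerun
under the same config is byte-identical, which the manifest (config hash +
per-file SHA-256) makes checkable.

## Known limitations

No multivariable MR, Steiger filtering, or contamination-mixture
estimators; no strand inference or proxy-SNP lookup; no BESD parsing or
trans-QTL analysis; no probe annotation databases (probe → gene maps are
plain inputs); no network/enrichment or docking stages. The HEIDI
implementation assumes the LD matrix is shared between the QTL and GWAS
studies, as the test itself does.
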