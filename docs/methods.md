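# Methods

This note documents the statistical procedures implemented in `oenomet`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Colorimetry

Wine color is handled in CIE 1976 L\*a\*b\* space. From measured L\*,
a\*, b\* the package derives chroma C\*ab = sqrt(a\*² + b\*²), hue angle
h_ab = atan2(b\*, a\*) mapped to [0°, 360°), and the CIE76 total color
difference ΔE\*ab = sqrt(ΔL\*² + Δa\*² + Δb\*²) against a configurable
reference (default: the wine with maximal L\*, i.e. the brightest wine,
which for red-wine panels is typically the *Vitis vinifera* style
against which darker amur-grape wines are contrasted). ΔE is a Euclidean
norm, hence symmetric, non-negative and triangle-inequality-consistent;
the tests verify all three properties plus two-decimal agreement with a
published wine color table.

An optional `absorbance_to_lab` route estimates L\*, a\*, b\* from the
four absorbances (450, 520, 570, 630 nm) commonly read on tenfold-diluted
wine. It treats the four transmittances as a four-point sample of the
visible spectrum, weights them with the CIE 1931 2° color-matching
functions under D65, and converts XYZ → Lab. This is a coarse
approximation of the full 400–700 nm integration; it is flagged
approximate, excluded from the primary path, and the pipeline always
prefers measured L\*, a\*, b\*. Raising the dilution factor reconstructs
the undiluted wine, so L\* is monotone non-increasing in it.

## Univariate statistics

* **ANOVA**: classical one-way F. All-identical observations give the
  documented convention F = 0, p = 1.
* **Duncan's multiple range test**: means are ordered; the range of each
  contiguous span of p means is compared against the least significant
  range LSR(p) = q(α_p, p, df_err) · sqrt(MSE/n_h), with studentized-range
  quantiles at Duncan's protection levels α_p = 1 − (1 − α)^(p−1) and n_h
  the harmonic mean group size. Spans inside an accepted (homogeneous)
  wider span are protected, per the classical stepwise rule. Letters are
  assigned to the maximal homogeneous spans, largest mean first, so
  groups share a letter iff the procedure did not separate them; a
  brute-force re-implementation of the range decisions cross-checks the
  letter display in the tests.
* **t-test**: two-sided pooled-variance Student's t on log₁₀
  intensities. With n = 3 per group a pooled-variance test is the
  standard metabolomics choice. Degenerate conventions: zero pooled
  variance gives p = 1 (equal means) or p = 0 (unequal).
* **Transforms**: intensities of exactly 0 are treated as missing and
  imputed with half the metabolite's minimum positive value before
  log₁₀; z-scoring is per metabolite, with constant rows mapping to
  zeros.
* **Clustering/heatmap defaults**: Euclidean distance on z-scored rows,
  average linkage, scipy's deterministic lowest-index tie-breaking.

## PCA and OPLS-DA

PCA is SVD-based on column-centered (optionally autoscaled) data with a
deterministic sign convention (largest-magnitude loading positive).

OPLS-DA follows the single-response orthogonal projection scheme: the
predictive weight w ∝ X'y; each orthogonal component is extracted from
the loading's component orthogonal to w and deflated from X; one
predictive component is then fit on the filtered matrix. Orthogonal
scores are uncorrelated with the class vector by construction (verified
to 1e-8). Defaults: unit-variance scaling of log₁₀ intensities
(SIMCA-style), one orthogonal component, class coding {0, 1} centered.

* **Q²** comes from stratified k-fold cross-validation (default 7
  folds, capped at the sample count; deterministic round-robin
  assignment per class). Test folds are orthogonality-filtered with the
  training loadings before prediction.
* **VIP** is computed so that mean VIP² = 1 exactly. The default
  "total" variant weights the predictive component by its explained Y
  sum-of-squares and each orthogonal component by its explained X
  share (a total-variation VIP for OPLS); a "predictive-only"
  toggle gives the classical single-component VIP. With ten planted
  variables out of 100 at n = 10, the null VIP threshold is ||w||²/p ≈
  0.18 on squared class correlation, so roughly one null variable in
  five exceeds VIP 1 — the conjunction with the t-test is what controls
  the screen's false positives, not VIP alone.
* **Permutation validation** refits under uniform label permutations,
  excluding draws that reproduce the original split or its mirror (with
  3–5 samples per class the label space is small enough that such
  ties would otherwise be frequent). The pass criterion is that the
  original Q² strictly exceeds every permuted Q²; R²Y is reported but
  does not gate, because small-n/large-p permuted models reach R²Y ≈ 1
  by overfitting — which is precisely the pathology Q² exposes. The
  conventional Q²-intercept diagnostic is reported, also not gating.

## Differential screen

A metabolite is differential for an ordered comparison "former vs
latter" when VIP ≥ 1 (from the two-class OPLS-DA of exactly those two
groups) **and** t-test p < 0.05 — raw p-values by default, matching
standard practice for this screen; a Benjamini–Hochberg option exists
but is off. Fold change is log₂ of raw (unlogged) group means,
latter/former; direction "up" means higher in the latter group.
Orientation is anti-symmetric by construction (n_up of A→B equals
n_down of B→A). Venn regions over up to six significant sets are exact
membership tallies; the core is the full intersection. A variety's
characteristic metabolites are those significant in *every* pairwise
comparison against it; the biomarker flag additionally requires the
variety to hold the maximal group mean (a metabolite uniquely depleted
in one variety is characteristic of it but not a biomarker).

## Co-abundance network

Unsigned weighted network on log₁₀ intensities: adjacency
a_ij = |cor(x_i, x_j)|^β with β = 6, TOM similarity
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), and
1 − TOM as the clustering dissimilarity. Soft-threshold selection
reports, per candidate β, the signed scale-free fit index (R² of the
log-binned connectivity distribution, sign-flipped for increasing fits)
and mean connectivity, recommending the smallest β reaching R² = 0.8.

Module detection is a simplified dynamic cut of the average-linkage
dendrogram, chosen deliberately over the full hybrid branch-decomposition
algorithm, which is out of proportion for ≤ ~1200 metabolites and 18
samples:

1. cut at 0.99 × the maximum merge height;
2. branches with ≥ `min_module_size` (default 50) members become
   modules, colors assigned by descending size over the conventional
   palette (turquoise, blue, brown, …), everything else grey;
3. optional attachment of unassigned metabolites to the nearest module
   when their mean TOM dissimilarity to it falls below the cut;
4. a module-membership cleanup: members whose |cor(profile, module
   eigengene)| (kME) is below 0.5 revert to grey, iterated to a fixed
   point; modules that fall below the size rule are demoted to grey.

Module eigengenes are first right-singular vectors of the z-scored
member profiles over samples, sign-oriented positively with the module
mean profile; modules whose eigengenes correlate at ≥ 0.75 (merge cut
height 0.25) are merged iteratively until a fixed point, recomputing
eigengenes each round. Module–trait association is Pearson r of each
eigengene against each trait broadcast from variety level to its
samples (traits are measured once per wine), with two-sided p from
t = r·sqrt(n−2)/sqrt(1−r²). Grey is reported in module counts and in
the module–trait output (flagged), but never merged.

## Pathway enrichment

For a selected set (module members or differential metabolites) against
the background of all metabolites with ≥ 1 pathway annotation: the
upper hypergeometric tail P(X ≥ m) with N = annotated background size,
n = annotated selected size, M = pathway size in the background, m =
pathway ∩ set, evaluated through the survival function (log-space
stable; agrees with direct pmf summation to 1e-12 relative on a grid up
to N = 200). BH step-up FDR across pathways, significance at
FDR ≤ 0.05; the top-20-by-q slice is also emitted. Metabolites in
several pathways count once per pathway; unannotated metabolites are
excluded from both set and background.

## Synthetic-data generator

The generator emulates the study design end to end on the log₁₀ scale:

    log10 x[i, s] = baseline_i + amp · (c·f[m, s] + sqrt(1 − c²)·ε)   (module member)
    log10 x[i, s] = baseline_i + σ·ε                                  (background)
    + δ[i, v]                                                         (planted shift)

with baseline_i ~ N(6, 1) (peak areas ~10⁵–10⁷), module amplitude
amp = 0.25, background noise σ = 0.2, and metabolite–factor correlation
c = 0.8 (pairwise within-module correlation c² = 0.64). Module latent
factors have a variety-level component plus replicate scatter
(sd 0.4 before standardisation). The variety-level factor levels are
centered and Gram–Schmidt orthogonalised: with only six varieties, two
independent Gaussian level vectors frequently correlate above the 0.75
eigengene-merge threshold by pure chance, which would collapse two
intentionally distinct modules into one; orthogonal levels make
"distinct planted modules" actually hold.

Defaults mirror the target design: 6 varieties × 3 replicates + 3 QC,
600 metabolites, four modules of sizes 120/100/80/60. Thirty
differential metabolites per variety are planted outside modules
(shift ±4 pooled SD on the log scale, random sign), so the screening and
module-recovery tests stay independent; a flag allows overlap. QC
samples are the arithmetic mean of all wine-sample intensity profiles
times 10^N(0, 0.02) noise, mimicking a pooled-mixture QC — they land
inside the wine-sample PCA cloud, as a QC should. Traits are linear in
the variety-level factors (taste scores centered near 7 on the 0–10
scale, color coordinates on their natural scales) plus Gaussian noise,
clipped to [0, 10] for taste attributes. The pathway map annotates 85%
of metabolites with 30 random pathways (sizes 10–40) plus one planted
pathway of 20 members, 75% drawn from the largest module.

**Evaluation scope.** Two planted structures necessarily interact: a
module member carries real between-variety effects through its
variety-structured latent factor, and a 4-SD single-variety shift
creates genuine co-abundance with whichever factor is extreme in that
variety (measured kME 0.6–0.8). Parameter-recovery tests therefore score
the screen on background (non-module) metabolites and module recovery
(adjusted Rand index) excluding planted differential metabolites —
both restrictions are taken from generator ground truth, never from
fitted results. Under the default conditions the pipeline achieves
pooled screen recall ≥ 0.9 and precision ≥ 0.8, module ARI ≥ 0.8,
recovers every planted module–trait link of |r| ≥ 0.8 at p < 0.05, and
ranks the planted pathway first at FDR ≤ 0.05.

**What the generator does not emulate**: chromatographic/batch drift,
heteroscedastic or missing-not-at-random peaks, correlated compound
classes, non-Gaussian trait noise, and panel-level sensory variance.
Passing recovery tests therefore demonstrates the pipeline's
correctness under a clean multiplicative model, not robustness to
instrument artefacts.

## Reproducibility and problem sizes

Every random draw flows from one seed; the pipeline derives per-stage
child seeds by a fixed CRC-based derivation, so a rerun with the same
config is byte-identical, and permutation tests are reproducible given
their seed. The test suite runs the full default bundle (600
metabolites) for recovery checks, a 1000-metabolite zero-effect bundle
for type-I-error calibration, and ten 80-variable repetitions for the
permutation null — sizes chosen to exercise the estimators well inside
a laptop-minute budget.

## Known limitations

* Two-class OPLS-DA only; multi-class questions are handled pairwise.
* Unsigned networks only; no signed/signed-hybrid option yet, and no
  block-wise decomposition for >10k features.
* The absorbance→Lab route is a labelled approximation (the four-point
  spectral sampling is crude); it is excluded from validated paths.
* Duncan letters assume exchangeable replicates within groups; no
  repeated-measures structure.
* With n = 3 replicates per wine, per-pair Q² and VIP are inevitably
  noisy; the conjunction rule and permutation guard mitigate but cannot
  remove small-n instability.
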