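# Methods

This note documents the models behind `thermoqtl`, the choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Scope and model chain

The package implements the desk side of a water-deficit introgression
program in which a drought-tolerant wild donor is crossed into an elite
recurrent parent and inbred-backcross (IBC) families are screened, mapped
and selected:

1. **Thermal phenotyping** — radiometric sensor counts → canopy
   temperature per plant.
2. **Trial models** — spatially adjusted genotype BLUPs from augmented
   greenhouse screens.
3. **QTL mapping** — composite interval mapping (CIM) by Haley–Knott
   regression on the BLUPs.
4. **Genomic prediction** — RR-BLUP marker effects and GEBVs, validated by
   leave-one-out cross-validation and by later-generation phenotypes.
5. **Selection** — a rank-sum multi-trait index over turgor and canopy
   temperature, with gain-under-selection accounting against a random
   control group.

Each analysis stage is a model object (`TrialModel`, `CIMScan`,
`RidgeBLUP`) whose `fit()` returns a results object carrying estimates,
uncertainties and a `summary()`; the generator and the selection engine
are plain functions.

## Thermal conversion and segmentation

Sensor counts convert to Celsius through the Planck-style calibration
curve

    T(raw) = PB / log(PR1 / (PR2 (raw + PO)) + PF) − 273.15,

with camera-specific constants PB, PR1, PR2, PO, PF supplied via config.
The logarithm base is a calibration field. The default is the natural
logarithm, which is what standard radiometric implementations use; a
base-10 switch is provided because the curve is sometimes quoted that way.
The round trip `temperature_to_raw ∘ raw_to_temperature` is exact to half
a count, so either base yields a self-consistent pipeline; the choice only
matters when constants calibrated under one convention are interpreted
under the other.

Canopy segmentation thresholds the *temperature* image (not raw counts)
with the MEAN method — the threshold is the arithmetic mean of all finite
pixels — and labels the cooler side as canopy by default (`polarity =
"below"`), since a transpiring canopy photographed against a board is
normally the cool region. Both polarities are first-class because the
printed-form labeling operator selects pixels *above* the threshold.
Median and Otsu thresholds are available behind the same interface for
method comparisons; for Otsu the between-class criterion plateaus across
the empty gap between modes and the middle of the plateau is returned.
The optional emissivity correction removes the reflected ambient
component in count space, `(observed − (1 − ε)·raw_reflected)/ε`; it is
off by default because where in the chain the camera applied it is not
observable from the counts alone.

## Trial mixed models

The augmented-screen model is

    Y = μ + genotype + Row + Column + ε,

all terms random, fitted by REML. Row and column levels are nested within
environment when a table spans several environments. Over-replicated
parental checks enter exactly like entries and are what make the row,
column and residual components identifiable in a single-replicate design.

The solver is EM on Henderson's mixed-model equations (convergence: the
relative change in the restricted log-likelihood below 1e-8 *and* the
variance components stationary at that scale; floors at 1e-10; 500
iterations). EM converges cleanly to interior optima — on balanced
one-way layouts it reproduces the closed-form ANOVA estimators
σ̂²_e = MSE, σ̂²_g = (MSG − MSE)/r to 1e-10 — but crawls when a component
heads for the zero boundary. A stalled fit is therefore finished by a
bounded Nelder–Mead search on the restricted likelihood in
log-variance space, warm-started from the EM state; a convergence error
(with the full iteration trace) is raised only if that also fails.

BLUPs are deviations from the intercept; per-environment BLUPs are
combined by an unweighted mean (the two screens are treated as equally
informative; nothing in the data motivates weights). Term importance is
tested by dropping one term and referring 2 Δ logLik to χ²(1) — no 50:50
boundary mixture, which makes the test conservative for variance
components — with BIC reported for both fits. Group comparisons use the
fixed model with block adjustment and Tukey's HSD:
`q(α, k, df_e) · sqrt(MSE / n_h)` with harmonic-mean group size, letters
assigned by insert-and-absorb. Ordinal turgor scores are modelled as
numeric throughout, matching common practice for 1–5 wilt scales; no
cumulative-link model is fitted.

## QTL mapping

Genetic distance and recombination fraction interconvert by the Kosambi
map function, r = ½·tanh(2d/100) (d in cM). The scan grid is every 2 cM
plus every marker. Expected donor dosage between markers comes from a
two-state (donor/recurrent homozygote) Markov chain conditioned on the
flanking genotypes with Kosambi recombination fractions; heterozygous
calls (~3 % of calls in BC₂S₃ material) contribute dosage 0.5
deterministically rather than through a diplotype HMM. When the two
flankers agree the interior dosage is pinned to the shared value
(no-double-crossover conditioning) — the unconditioned chain would give
values infinitesimally inside the interval, and the pinned form keeps
grid dosages exactly reproducing observed dosages in fully typed regions.
Missing genotypes are imputed from the nearest typed marker first.
Single-meiosis recombination fractions are used between positions with no
inflation for the multiple generations of an IBC pedigree; this is an
approximation, adequate because the map itself is estimated from the same
population.

At each position the trait is regressed on expected dosage plus cofactor
markers (forward-selected by single-marker LOD; ties broken by lowest
chromosome, position, then marker id). A cofactor within half the 40-cM
window of the test position on the same chromosome is excluded from both
the null and alternative fits. LOD = (n/2)·log₁₀(RSS₀/RSS₁); the
allele-substitution effect is the dosage coefficient (positive = donor
allele increases the trait); PVE = 100·(1 − 10^(−2·LOD/n)). Significance
uses genome-wide permutation of the phenotype against genotypes with the
inclusive (R type-1) empirical quantile of the per-permutation maximum
LOD; the permutation scans are vectorized across shuffles, so 1,000
permutations of a 160-line, ~590-position scan take well under a second.
Rank-deficient positions are flagged and scored LOD 0 rather than
aborting the scan.

## Genomic prediction

RR-BLUP treats all markers as random effects with common variance:
y = μ + Xb + e with b ~ N(0, σ²_u I). Marker scores are donor dosages
{0, 0.5, 1}, column-centered by training means, with no variance
standardization; monomorphic markers are dropped (their effects report as
zero). Variance components are REML estimates obtained by a bounded
scalar search over log₁₀ λ (λ = σ²_e/σ²_u ∈ [10⁻⁸, 10⁸], tolerance
1e-10) after rotating into the eigenbasis of XXᵀ with the intercept
projected out. Marker effects are then solved from the primal ridge
normal equations (XᵀX + λI)b = Xᵀ(y − μ̂), which stays numerically stable
as λ → 0, and GEBV = X·MV. When REML drives λ to its upper bound the fit
degrades gracefully to zero effects with a logged warning.

Cross-validation is leave-one-out with variance components refitted in
every fold. The reported r_g is the Pearson correlation between held-out
**GEBVs** and phenotypes — deliberately excluding the per-fold intercept.
The intercept of a fold differs from the others only through the held-out
observation (μ̂₋ᵢ = (nȳ − yᵢ)/(n−1)), and under a no-signal model that
leakage alone drags the correlation to exactly −1; correlating the GEBV
component keeps the null calibration honest (null traits give |r_g| ≈ 0)
and matches how GEBV accuracy is defined. Empirical (realized) accuracy
correlates training GEBVs with phenotypic BLUPs of derived lines over the
intersection of family ids.

## Selection engine

Each trait is ranked in its favorable direction (rank 1 = best: highest
turgor, lowest canopy temperature; average ranks for ties), and the
rank-sum MTI selects the smallest sums, ties broken by the smaller canopy
rank and then id. Favorable directions live in one registry
(`TRAIT_DIRECTIONS`) because sign conventions are the easiest thing to
get silently wrong. Selection intensity K is the deviation from the
population mean in SD units, signed so favorable is positive; K values
are reported but not enforced as filters. Groups replicate the standard
design: top-10 phenotypic and top-10 genomic rank-sum selections, with
families in both lists labelled `Pheno+GS` (groups disjoint) and a random
group drawn without replacement from the unselected remainder.
Co-selection is 100·|∩|/(|pheno| + |gs|). Gain is group mean minus
base-population mean, signed (favorable gain: turgor positive, canopy
temperature negative). The donor-QTL recovery check is a two-category χ²
goodness of fit against the expected 12.5 % donor frequency.

## Synthetic-data generator

The generator produces every input with known truth, under defaults that
are the study conditions this package emulates
(`simulate.study_conditions()`):

- **Map** — 12 chromosomes, ~80 cM each, 13 markers per chromosome,
  first marker at 0 cM.
- **Population** — 160 BC₂S₃ families by explicit single-seed descent:
  F₁ → two backcrosses to the recurrent homozygote → three selfings, each
  meiosis realized marker-interval by marker-interval with Kosambi
  recombination probabilities (Markov, no interference). Expected donor
  frequency (½)^(1+backcrosses) = 12.5 %; heterozygosity halves per self
  generation (0.25/2³ ≈ 3.1 % at S₃). Parental checks are fully
  homozygous dosage-0 (recurrent) and dosage-1 (donor) genotypes.
- **Trials** — two environments (summer/fall), each a 16 × 15 augmented
  layout with 36 replicates of each parent spread so every row and column
  contains a check. Phenotype = mean + QTL effects (attached to the
  nearest map marker, keeping generator and analyzer coordinates aligned)
  + a per-genotype polygenic deviate shared across environments + row +
  column + residual effects drawn per environment.
- **Traits** — variance partitions are trait-specific, matching the
  magnitudes observed for a visual turgor score (genotype ≈ 46 % of plot
  variance) and image-based canopy temperature (genotype ≈ 22 %,
  plot sd ≈ 1.6 °C). Turgor is generated on a latent liability (mean 0)
  and discretized through fixed cutpoints (−1.5, −0.5, 0.5, 1.5) onto the
  1–5 ordinal scale; the latent model behind real wilt scores is unknown,
  so symmetric cutpoints are a declared convention, not an estimate. Two
  QTLs per trait are sized to explain roughly 7–9 % of family-mean
  variance each (allele effects +0.75/+0.65 liability units for turgor,
  −1.05/−0.95 °C for canopy temperature).
- **Thermal scenes** — elliptical canopy masks, Gaussian pixel noise, and
  counts produced by the exact inverse of the calibration curve, clipped
  to 16 bits with a logged warning.

What the generator does **not** emulate: genotyping error, segregation
distortion, crossover interference, G×E beyond independent row/column
draws, spatially correlated (AR1-type) trends, non-elliptical canopies,
camera drift or vignetting. Passing tests therefore demonstrate that the
analysis recovers the truth of this idealized data-generating process at
realistic sizes and noise levels — not that it is robust to artifacts
real screens may contain.

## Problem sizes used in the checks

The simulation-based checks run at the study's own scale: n = 160
families for QTL power (100 replicates) and GS calibration (50 seeds at
h² = 0.4, 15 at 0.1 and 0.8), 50 replicates of the full
simulate→BLUP→GS→select replay, 50 null replicates with 200-permutation
thresholds, 100 thermal scenes, and 2,000 lines for population-structure
convergence. These sizes put Monte-Carlo error comfortably inside the
asserted bands while keeping the whole suite in the tens of minutes.

## Known limitations

- The EM/simplex REML solver is dense; it is sized for trials of a few
  hundred plots, not for thousands.
- LOD thresholds and PVE use the regression (RSS-ratio) form throughout;
  no mixture-model likelihood.
- CIM fits one position at a time plus cofactors; no multi-QTL joint
  model, no epistasis.
- The two-state dosage chain ignores residual heterozygosity beyond the
  fixed 0.5 contribution, and single-meiosis map distances are used for an
  inbred pedigree.
- Ordinal turgor modelled as numeric inherits the usual caveats of linear
  models on 1–5 scales (cutpoint-dependent shrinkage of extreme BLUPs).
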