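# Methods

This note documents the models behind `apmsdia`: what each stage
assumes, which parameters matter, what the simulator does and does not
emulate, and the numerical choices made where the design was open.

## Pipeline model

### Fragment detection and reliability filtering

DIA quantification yields one intensity trace per (protein, peptide,
fragment, sample). Two filters precede quantification:

1. **Detection filter** (`min_detect`, default 2). A fragment's rows in
   a condition group — a (background, condition, time) combination — are
   kept only if the fragment has at least `min_detect` non-missing
   observations in that group. Groups of the same fragment are judged
   independently, so a fragment may survive in the stimulated conditions
   and be removed at baseline. With three replicates and
   intensity-independent missingness at rate m, a whole group is removed
   with probability `3m²(1−m) + m³` (≈ 2.8% at m = 0.1); because the
   removal takes all replicates of that group with it, single-protein
   quantities can shift by the removed fragment's weight. This is a
   property of per-condition detection filtering in general, and the
   reason effect-size checks on the generator are run without
   missingness.

2. **Reliability filter** (`min_correlation` 0.25, `sd_factor` 2).
   Fragments of one peptide report the same analyte at different
   response factors, so their log2 profiles differ by constant offsets.
   Each fragment's profile is centered on its own observed mean and the
   peptide's reference profile is the per-sample median of centered
   profiles. Rule 1 drops fragments whose Pearson correlation with the
   reference over shared observed samples falls below
   `min_correlation`; correlations are left undefined (fragment kept)
   with fewer than three shared samples or zero variance. Rule 2,
   applied to the survivors against a recomputed reference, drops
   fragments whose mean absolute residual exceeds `sd_factor` times the
   standard deviation of all residuals in the peptide. Residuals are
   offset-corrected per fragment first: a constant displacement carries
   no evidence of unreliability (it can also arise purely from
   missingness shifting the centering mean in a high-contrast profile),
   so only sample-to-sample disagreement counts. An absolute tolerance
   of 1e-9 log2 units keeps numerically identical profiles together.
   Peptides with fewer than two fragments pass unchanged. The two rules
   are this package's stated interpretation of the "minimal
   correlation" and "standard deviation factor" options of
   fragment-selection tools; both are independently switchable.

### Roll-up, imputation, normalization

Peptide quantity is the sum of retained fragment intensities per
sample; protein quantity the sum of peptide quantities; a value is
missing only when every constituent is missing. Missing entries of an
analyte are imputed with the `impute_quantile` (default 0.01) quantile
of that analyte's observed values across all samples, using linear
interpolation between order statistics (the "type 7" convention —
the common default in scientific software; fixed here for
bit-stability). Note that a type-7 quantile at small q lies slightly
*above* the observed minimum (between the two smallest values), and the
operation is idempotent. Rows with no observed value cannot be imputed;
they are dropped and reported. Downstream statistics operate on
log2(quantity) after imputation, so no pseudo-count is needed.

For the dynamic analysis, quantities are divided per sample by the
bait's protein quantity in that sample (per-sample rather than
per-condition-mean normalization preserves replicate pairing).
Phosphopeptides — peptide ids carrying a modification token — are
routed to their own pseudo-protein `<protein>@<peptide>` before
differential testing so a regulated phosphoform is not averaged into
its parent; roll-ups used for bait normalization, stoichiometry and
heatmaps keep the parent protein intact.

### Protein-level inference

Per peptide, a paired t-test on replicate differences of log2
quantities (n−1 degrees of freedom, two-sided). Zero-variance
differences receive p = 1e-15 when the mean difference is non-zero
(imputation can create constant rows; a finite floor keeps aggregation
defined) and p = 1 otherwise. No variance moderation is applied at the
peptide level; a moderated statistic is an extension point.

Protein p-values use the reproducibility-optimized aggregation: with n
peptide p-values and k = ⌊n/2⌋ + 1 (upper median; the even-n convention
is not fixed by the method's sources, so it is fixed here), the protein
p-value is the Beta(k, n−k+1) CDF evaluated at the k-th smallest
peptide p-value — the exact null distribution of the median order
statistic of n uniforms, equal to the binomial tail
Σ_{j≥k} C(n,j) m^j (1−m)^{n−j}. The protein fold change is the
conventional median (mean of central pair for even n) of peptide log2
fold changes. Benjamini–Hochberg adjustment is applied per contrast
across all proteins tested in that contrast.

The aggregation assumes peptide p-values of a null protein are
independent and uniform. Uniformity requires near-normal replicate
differences — satisfied when biological noise acts multiplicatively at
the analyte level (see the simulator section); independence requires
peptide-level noise not to be dominated by a shared protein-level
component. Violations inflate the aggregated tails.

### Interactor calling

Enrichment is one-sided (bait above control): a protein is enriched in
a condition when median_log2_fc > log2(`enrichment_fc_threshold`) and
q < `enrichment_fdr` (presets: 3-fold for primary mouse T cells, 6-fold
for Jurkat; FDR 0.01). *Specific* requires enrichment in at least
`min_conditions` (default 2) distinct bait-versus-control contrasts —
"condition" here means contrast, e.g. time points; an alternative
accounting by experiment can be expressed through the contrast labels —
and no match in the contaminant list. The shipped default list contains
the eleven recurrent AP-MS background proteins removed in the
motivating study plus prefix rules KRT/MYH/MYL/TUB; it is fully
user-replaceable and matched case-insensitively, exact or by prefix.
Removed contaminants are reported, never silently dropped; the bait and
its routed phosphopeptide pseudo-entries are excluded from calling but
kept in reports. The *dynamic* gate is two-sided on bait-normalized
contrasts of stimulated versus unstimulated conditions:
|median_log2_fc| ≥ log2(2) with q < 0.05 in at least one contrast.
Both filters are monotone: raising any threshold can only shrink the
call set, and contaminant removal commutes with enrichment testing.

### Stoichiometry

iBAQ divides the mean raw protein quantity over the selected condition's
replicates by the protein's number of theoretically observable tryptic
peptides: fully tryptic digestion (cleave after K or R except before P
— the plain KP rule, not the extended exception set), zero missed
cleavages, unique peptides of length 6–30. These follow the original
iBAQ convention; none are printed in the motivating study, so all are
configurable and recorded with the results. Digestion is delegated to
pyteomics' cleavage machinery with the rule above and cross-checked in
the tests against an independent positional implementation. The
stoichiometry of a prey is prey iBAQ ÷ bait iBAQ (reported as fraction
and percent); it is invariant to global intensity rescaling. Proteins
with zero observable peptides are flagged and excluded from iBAQ. When
the bait carries a purification tag, its peptide count should be
computed on the tagged sequence; the simulator sidesteps the issue by
generating the bait sequence directly.

### SILAC origin

Per protein, the light-channel intensity is divided by the
heavy-channel intensity in each replicate pair; the reported ratio is
the mean of per-replicate ratios (matching the per-sample division
phrasing of the source procedure; the summary light/heavy intensities
are replicate means, and light_fraction = ratio/(1+ratio) is consistent
with the reported ratio). Undetected channels receive a floor equal to
the `floor_quantile` (default 0.01) quantile of all detected values
across both channels — the study's analogous rule used its
data-derived absolute value; deriving it from the quantile keeps the
rule portable, and an explicit override is accepted. Classification:
light_fraction ≥ 0.95 → T-cell exclusive, ≤ 0.05 → APC exclusive,
otherwise mixed; 0.95 is a convention standing in for the qualitative
"exclusive"/"mixed" language it encodes. An exclusive call at
threshold τ requires a detected/floor intensity ratio of at least
τ/(1−τ) (19:1 at τ = 0.95), so origin calls for proteins within ~20×
of the floor are compressed toward "mixed" — an inherent property of
floor substitution, not an implementation artifact. Replicate pairs
where a protein is undetected in both channels still contribute
floored ratios of 1; designs without an unstimulated baseline (as in
the mixed-cell screen this models) avoid diluting kinetic interactors'
ratios with such pairs.

## The simulator

The generator is the package's study-conditions oracle. Defaults mirror
the screen design it emulates: two backgrounds × five time points
(0/0.5/2/5/15 min) × three biological replicates; a bait at raw
intensity 1e6; 500 background proteins log-uniform in [1e3, 1e5]; 20
interactors; 10 sticky contaminants; lognormal biological noise with
CV 0.2; 10% missingness.

* **Intensity model.** Fragment intensity = protein abundance ×
  peptide weight × fragment weight (weights drawn once per analyte,
  normalized to sum to one within their parent) × lognormal biological
  noise shared by all fragments of a peptide (CV `cv_biological`,
  unit mean) × independent per-fragment technical noise (CV
  `cv_technical`, default 0.05). Placing biological noise at the
  peptide level reproduces the within-peptide fragment correlation the
  reliability filter assumes, and makes log2 peptide sums near-normal,
  which the df=2 paired t needs for calibration. CV values are
  simulator conventions (the study reports none).
* **Interactors.** Specific signal = bait_abundance × occupancy ×
  kinetic_profile(t), scaled by (prey peptide count ÷ bait peptide
  count) so iBAQ inverts the scaling exactly. Each interactor also has
  a non-specific carry-over level (peak specific ÷ enrichment_fold,
  default 16) present in both backgrounds; in tagged samples carry-over
  is displaced as specific binding rises, so the peak tagged signal
  equals the specific level exactly and the peak bait/control ratio
  equals the programmed fold exactly. Without carry-over, a protein
  absent from controls would lose its contrast to per-analyte
  imputation — as it would in real data. Kinetic interactors follow a
  transient recruit-and-release profile peaking at 2 min (floored at
  0.05 of peak); the rest are constitutive.
* **Contaminants** are enriched in tagged samples (default 8-fold) and
  carry keratin/myosin/tubulin-style identifiers, so only the
  blacklist — not the enrichment filter — removes them, mirroring how
  recurrent background proteins pass enrichment in real screens.
* **Sequences** are concatenations of unique 10-mers ending in K from
  an alphabet without K/R/P, so the theoretical tryptic peptide count
  equals the simulated peptide count exactly and occupancy recovery is
  a clean end-to-end test.
* **Missingness** is intensity-independent by default; an optional
  left-censoring mode raises the missing probability linearly as
  intensity falls below a threshold. **SILAC** mode splits each
  protein's signal between light and heavy channels by a programmed
  light fraction before noise. An optional phospho mode splits the
  bait's first peptide into modified/unmodified forms whose sum is
  conserved and whose phospho fraction follows a transient profile.
* **Determinism.** One integer seed drives a single generator; output
  is a pure function of the configuration.

What it does **not** emulate: chromatography and retention-time
structure, charge states, spectral interference, isotope-incorporation
artifacts, protein-level (shared-across-peptides) biological variation,
intensity-dependent CVs, and correlated missingness. Passing tests
therefore demonstrate the statistics are correct under the stated noise
model, not that real data satisfy that model; with a strong shared
protein-level noise component the beta-median aggregation would be
anticonservative.

## Benchmark configurations and observed behavior

* **Null calibration** uses 2,000 background proteins, two time points,
  no missingness (the clean null design): protein-level p-values have
  Kolmogorov–Smirnov distance ≈ 0.015–0.03 from uniform and the full
  two-filter pipeline calls zero specific interactors. With 10%
  missingness the imputation rule thickens the tails slightly
  (KS ≈ 0.08) — worth knowing when interpreting borderline q-values on
  sparse data.
* **Spike-in recovery** (20 interactors at ≥ 8-fold among 500
  background, CV 0.2, 3 replicates): sensitivity 1.0 with 0 false
  calls; all kinetic interactors flagged dynamic; sticky contaminants
  removed by the blacklist.
* **Stoichiometry recovery** for programmed occupancies
  {13%, 1.4%, 69%}: noiseless simulation recovers them exactly
  (machine precision) and preserves ranking; at CV 0.2 a single run is
  typically within ±20% relative error (per-protein SD ≈ 8–11%, to
  which detection-filter group removals contribute a heavy tail), and
  the 20-seed mean relative bias is below 1%.
* **SILAC origin** with programmed mixtures {1.0, 0.5, 0.0} at CV 0.2
  and major-interactor occupancies (0.1–0.5): 100% classification
  accuracy.

Problem sizes (2,000-protein null, 500-protein spike-in, 20-seed bias
loops at 60 background proteins) were chosen so the whole suite and the
acceptance script each run in about a minute on a single CPU while
keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* Roll-up by summation is a contract of this package; the original
  analysis delegated roll-up to external software whose exact scheme is
  not printed.
* The reliability-filter formulas are a documented interpretation of
  tool options named only by parameter in the source material.
* The per-condition detection filter removes whole replicate groups and
  can shift individual protein quantities by a fragment weight; at 10%
  missingness this dominates the tail of stoichiometry errors.
* BH is applied per contrast; no cross-contrast hierarchical control.
* The dynamic gate tests each stimulated time point against baseline
  separately; no trend or spline modeling across the time course.
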