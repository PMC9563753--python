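# Methods

This note documents the models, parameter choices, and numerical
conventions behind `sulfascreen`, and what the synthetic cohorts do and
do not establish about real data.

## Annotation chemistry

Shorthand sphingolipid names follow the `<CLASS> <C>:<DB>;O<k>` sum-level
convention (total chain carbons, double bonds, hydroxyl-type oxygens of
the ceramide part; k ∈ {2, 3, 4}).  Species-level names
(`SHexCer 18:1;O2/12:0`) are summed to sum-level keys and the original
string is kept for display; whether several isomeric species-level
signals should share one sum-level channel is unresolvable from MS1 data
alone, so each sum-level name is treated as a single channel.

Formulas are built constructively: the ceramide core C:n DB:d ;Ok is
C_n H_(2n+1−2d) N O_(k+1); SM adds phosphocholine (C5H14NO4P) net of one
condensation water; SHexCer adds one hexose (net C6H10O5) plus SO3;
SHex2Cer adds two hexoses plus SO3.  Anion m/z = monoisotopic mass of M
minus the neutral loss (H or CH3) **plus one electron mass**
(0.000549 Da): at R = 100,000 the instrument resolves ~7 mDa at m/z 700,
so the electron term is not negligible.  Monoisotopic masses come from a
built-in single-isotope table (C = 12 exactly, H = 1.00782503, ...).
Sterol sulfates are opaque identifiers whose compositions are not public;
they must carry a user-supplied formula or explicit m/z, and the default
urine panel assigns them synthetic placeholder m/z values spaced about
3 Da (≫ 50 ppm) apart.

## Peak assignment and aggregation

The matching tolerance defaults to 5 ppm (configurable); the value is an
analyst convention consistent with high-resolution Orbitrap accuracy
rather than a published constant.  Assignment resolves conflicts
globally: all (channel, peak) candidates inside the window are ranked by
|Δppm| and matched greedily, each observed peak claimable once, so when
two channels' windows overlap the nearer channel wins and the other
falls back to its next-nearest in-window peak.  Replicates (five
depositions per sample) are collapsed by the median, with unassigned
replicates counted as 0 and an even count giving the mean of the central
pair; samples with fewer than five replicates are accepted with a logged
warning.  Medians below the LOQ (default 8000 counts, the lowest
reproducible intensity) are censored to 0.

## Inclusion criteria and concentrations

Criterion 1 retains a lipid present (> 8000 counts) in at least 50 % of
samples of *both* groups — presence is assessed on the aggregated
per-sample matrix.  Criterion 2 requires a pooled-QC coefficient of
variation below 35 %, computed on raw (unimputed) QC intensities with the
sample standard deviation (n − 1).  Criterion 3 excludes a subject when
strictly more than 50 % of panel lipids are sub-LOQ or any internal
standard is sub-LOQ (high matrix effect); exclusions are reported with
reason codes.  Censored cells are then floor-imputed at 8000, molar
concentrations are intensity ratios to the class's spiked internal
standard times the spiked amount, and relative concentrations are percent
abundance within the class group (SM; sulfatides = SHexCer + SHex2Cer
together; sterol sulfates), excluding IS channels from the sums.
Downstream statistics default to the relative scale.

**Compositional caveat.**  Percent-within-class values are a composition:
a genuine change in a few channels shifts the class sum and therefore
*every* other channel of that class.  Group differences on the relative
scale are consequently not independent across lipids, and a channel whose
raw intensity is unaffected can still differ between groups.  This is a
property of the data representation, not an artifact of the tests; the
FDR-calibration test therefore operates on the raw imputed intensities,
where unaffected channels are exactly null.

## Statistics

The fold change is the Hodges–Lehmann-type estimator: the median of all
n_T × n_N pairwise ratios (robust; equals c exactly when one group is a
c-multiple of the other).  For paired tissue the same all-pairs estimator
is the default, with a per-subject-ratio median as an option.
Mann–Whitney uses the exact null distribution when both groups have ≤ 8
observations without ties, otherwise the normal approximation with tie
and continuity corrections; Wilcoxon signed-rank is exact to n = 15
without tied magnitudes.  Effect sizes: rank-biserial
r = 2U/(n_x n_y) − 1 (ties count ½) and ε² = H(n+1)/(n²−1).  The
Conover–Iman post hoc uses pooled-rank t statistics with the
tie-corrected H in the variance term, df = n − k, and BH adjustment
across the pairs (matching the global FDR policy; the post hoc adjustment
is a package convention).  Presence/absence channels (criterion-1
failures) get two-sided Fisher exact tests with a conditional-MLE odds
ratio (Haldane–Anscombe value reported for display only), or exact
binomial McNemar tests on discordant tissue pairs.  BH q-values use the
standard step-up.  Ward clustering operates on log₁₀ + Pareto-scaled
values; the merge tree is serialized to Newick, and heat-map z-scores are
per-lipid across samples.

Figure-style significance grades (large/medium/small) combine |r| ≥
0.5/0.3/0.1 with q < 0.05; these thresholds are package conventions, not
measured constants.

## Classification

Features are the 33 relative lipid concentrations plus BMI and a binary
gender indicator; missing BMI is replaced by the within-group median
(computed before splitting, on the full task cohort).  The split is
stratified 60/40 with a recorded seed; lipid features are log₁₀-
transformed, then all features are Pareto scaled ((v − mean)/√sd) with
statistics from training rows only; constant features are dropped with a
warning.  The training minority class is upsampled with replacement to
the majority count; test rows are never duplicated or reused.

The ridge objective is mean negative log-likelihood + λ‖β‖²/2 with an
unpenalized intercept, minimized by damped Newton (backtracking line
search) to gradient norm < 1e-8 with a 200-iteration cap (the cap guards
the divergent λ = 0 separable case).  The mean (not summed)
log-likelihood makes λ comparable across sample sizes.  λ is selected
from 50 log-spaced values on [1e-4, 1e2] by the highest mean out-of-fold
AUC over 5 stratified folds of the (upsampled) training set, with warm
starts along the grid, then refit on the full training set.  AUC is the
Mann–Whitney rank statistic (ties ½); its CI is DeLong's
structural-component interval; sensitivity, specificity, and accuracy at
the 0.5 probability threshold get Clopper–Pearson exact intervals.
Reports are plain JSON, fully determined by seed and configuration.

## Synthetic cohorts

Between-subject lipid intensities are log-normal (default natural-log SD
0.6, i.e. ~65 % biological CV — typical for sphingolipid panels in body
fluids), with deterministic per-channel baselines spread over about half
a decade around 10^4.6–10^5.1 counts.  Cases multiply affected channels
by stage-bracket factors: the defaults are 1.6×/2.0× (T1-2/T3-4) for
upregulated channels and 0.625×/0.5× for downregulated ones, encoding
the observed gradual stage trend; directions follow the reported
dysregulation pattern (lactosylsulfatides and polyunsaturated SHexCer up;
hydroxylated SHexCer, long-chain SM down; cortisol-like sterol sulfates
up and lithocholic-like down in urine).  Technical replicates add
multiplicative noise at 10 % CV; QC samples draw around the pooled
baseline at 15 % CV (one designated channel at 55 % CV exercises
criterion 2); rare channels are Bernoulli-present with group-specific
probabilities (the plasma lactosylsulfatide channel uses 2/207 vs 24/143)
and exercise criterion 1 and the presence analysis.  Default cohort
sizes are 207/143 (plasma), 70/100 with 3 + 24 designated low-signal
subjects (urine; suppressed globally by a 0.02 matrix-effect factor so
criterion 3 must flag exactly those 27), and 77 tissue pairs sharing a
per-subject random effect (SD 0.3) that induces the paired correlation
the signed-rank analysis assumes.  Cases skew male (65 % vs 45 %), older,
and slightly heavier, mirroring the study population; 5 % of BMI values
are missing.  Peak lists place each live channel at its theoretical m/z
times (1 + u), u uniform in ±2 ppm — a bounded mass error, so every
generated peak stays inside a 5 ppm window — plus decoy peaks kept
≥ 50 ppm from all channels.

`fully_null_config()` additionally matches the demographic distributions
and rare-channel presence between groups; this is the correct null for
classifier calibration, because the study-like defaults make gender and
BMI genuinely predictive (a "null lipidome" cohort still yields test AUC
≈ 0.6 through demographics alone).

Reproducibility: all draws derive from one `SeedSequence` per study,
split into fixed streams (cohort, intensities, replicates/QC, peaks), so
identical seed and configuration give byte-identical outputs.

**What the synthetic cohorts do not show.**  They contain no isotope
envelopes, chemical noise beyond decoys, batch or drift structure,
between-lipid correlation beyond class closure, non-log-normal tails, or
realistic effect-size heterogeneity; passing tests demonstrate the
correctness and calibration of the pipeline machinery under the assumed
data-generating model, not clinical performance.  Classifier AUCs on the
defaults (~0.94–0.99) are properties of the chosen multipliers, not
estimates of diagnostic accuracy in patients.

## Problem sizes used in checks

The automated checks use scaled study conditions chosen to exercise each
property with adequate Monte-Carlo precision: 500 null panels at n = 50/50
for type-I calibration, 500 panels with ~20 % true effects for FDR
control, 100 null replicates at n = 60/60 for DeLong CI coverage,
n = 100/100 for effect-direction recovery, and the full default cohorts
for the classification tasks.
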