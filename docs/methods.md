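# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions and the open design choices behind `methylhap`.

## Haplotype load (MHL / UMHL)

For a block of `l` consecutive CpGs, every read contributes its contiguous
sub-haplotypes (windows) of each length `i = 1..l` that lie wholly inside the
block. A window is *evaluable* only if it contains no missing call: missing
calls segment a read before windows are formed, and a read that only partly
overlaps a block contributes only its in-block windows. With `P(MH_i)` the
count-weighted fraction of evaluable length-`i` windows that are fully
methylated,

    MHL = sum_i w_i P(MH_i) / sum_i w_i ,   w_i = i ** weight_exponent.

`weight_exponent` defaults to 3. The cubic reading of the weight is
deliberate: a weight constant in `i` (e.g. `l**3`) would cancel between
numerator and denominator and make the weighting vacuous, whereas `i**3`
up-weights long consecutive runs — the property the statistic exists to
measure. The exponent is a parameter, so linear weighting (`w_i = i`) is one
flag away. UMHL is MHL of the complemented calls; the implementation shares
one code path, and `UMHL(X) == MHL(complement(X))` holds exactly.

Denominators sum only over lengths with at least one evaluable window
(avoiding 0/0); a block with no evaluable window, or with fewer than
`min_reads_detect` (default 1) overlapping reads, is *undetected* and scored
as missing. Windows are counted per read weighted by the record's read count;
an unweighted-distinct mode (`count_weighted=False`) is available because the
per-read vs per-distinct-haplotype convention is not standardised.
With a degenerate single evaluable length of 1, MHL reduces to the classical
per-site methylation frequency (beta value).

## Block discovery

Adjacent CpG pairs are linked when the squared Pearson correlation of their
binary calls, over reads covering both sites with non-missing calls, is
strictly greater than `r2_threshold` (default 0.5). Maximal runs of linked
pairs with >= 2 sites become blocks. Conventions:

* r² is computed on reads pooled across all samples by default; a
  `per_sample` mode (pair-count-weighted mean of within-sample r²) is
  provided because pooling vs per-sample estimation is a genuinely open
  choice for this method family.
* r² is undefined when fewer than `min_pairs` (default 10) reads co-cover the
  pair or either margin is constant; undefined r² breaks the chain, since a
  constant margin carries no linkage evidence.
* "Adjacent" means consecutive in the CpG index; an optional `max_gap`
  (default 500 bp) additionally breaks pairs across large genomic gaps.
* Ties at the threshold are excluded ("strictly greater"), implemented with a
  1e-12 tolerance so that a pair whose exact r² equals the threshold is not
  admitted through float rounding of the 2x2-table formula.
* Scoring also accepts a precomputed region set, so a fixed external block
  catalogue can be used instead of discovery.

## Filter cascade and marker selection

Samples must have at least `min_detected_per_sample` detected blocks; the
study-scale floor (25,000 of 225,025 regions, about 11%) is applied
proportionally to smaller catalogues via `scaled_min_detected`. Blocks must
then be detected in at least 2/3 of the retained samples and have
cross-sample SD (n−1 denominator) of at least 0.02. Both thresholds are
inclusive ("no less than"), implemented with a 1e-12 tolerance so a block
whose SD is exactly at the floor is retained despite float rounding.

Per block, groups are compared with the Wilcoxon rank-sum test (unpaired
contrasts: MVI+ vs MVI− tumours) or the signed-rank test on matched
tumour/peritumoral-normal pairs (zero differences dropped); exact p-values
are used for small untied samples and the tie-corrected normal approximation
otherwise (scipy implementations, checked in the test suite against full
permutation / sign-flip enumeration). One-sided testing runs *both*
directions as separate hyper- and hypo-methylated families with
Benjamini–Hochberg FDR control within each family; choosing the test
direction from the observed shift would double-dip. The FDR procedure is
Benjamini–Hochberg (the field default; pluggable in principle), and blocks
whose test is undefined (e.g. all paired differences zero) are excluded from
the family before adjustment. When MHL and UMHL matrices are both supplied,
selection runs independently per score kind and the marker sets are
concatenated with a `score_kind` tag. Missing values are dropped
pairwise/listwise per test, never imputed.

## Classification

Random forest with 500 trees and library defaults is the primary model; an
RBF-kernel SVM (cost 1, sigma tuned over a `2^-4..2^4` grid around the
median-heuristic value using inner CV on training folds only) is provided as
an alternative. Evaluation is repeated stratified 3-fold cross-validation
(10 repeats by default); stratification prevents single-class folds at
cohort sizes of a few dozen. Every sample receives one out-of-fold score per
repeat, each repeat yields an AUC (rank-based, ties counting 1/2), and the
95% CI is the normal approximation `mean ± 1.96·sd/√R` over repeat AUCs,
truncated to [0, 1] — the CI convention over a small number of repeats is a
design choice, and a percentile bootstrap would be a drop-in replacement.

Missing feature values are imputed with the **training control-class
(background) median** per feature, computed on the training fold only. The
pooled training median was rejected after it proved class-informative under
detection dropout: with well-separated classes the pooled median sits in the
between-class gap, so imputing it injects case-like signal into controls and
noticeably degrades tissue-to-plasma transfer. An undetected block carries
no evidence of the case-specific signal, so the background level is the
appropriate reference. Features never observed in the reference fall back to
the pooled median, then to 0.5.

Tissue-to-plasma transfer applies the tissue-trained model unchanged to the
plasma score matrix on the same marker columns (missing cells imputed with
the stored training references). MVI prediction combines MHL- and
UMHL-selected markers as tagged columns, and hard calls threshold the
across-repeat mean out-of-fold probability at 0.5 (the threshold is a
convention, not fitted). Unsupervised views (average-linkage clustering on
correlation distance of the top-100-SD blocks, plus PCA of centred data) are
deterministic.

## Survival validation

Kaplan–Meier product-limit curves and the standard two-group log-rank test
(lifelines implementations, checked against hand risk-set recomputation)
compare survival between *predicted* MVI groups, closing the loop from
methylation markers to outcome. Tied event/censoring times follow the
censored-after-events convention. Samples with unknown follow-up are
dropped. Multivariable hazard modelling is out of scope.

## Synthetic cohorts

No public data accompanies this analysis design, so the generator is a
first-class module with known ground truth. Each read in a block is a
two-state Markov chain: the first CpG is methylated with probability `theta`,
and the state toggles with probability `switch_rate` per step. `switch_rate`
directly controls haplotype consecutiveness: at 0 reads are all-or-none
(maximal MHL at fixed marginal), at 0.5 adjacent sites are independent and
expected adjacent r² is 0, so block discovery rejects. `theta = 0.5` is the
stationary point of the symmetric toggle; away from it the marginal relaxes
towards 0.5 along the read at rate `(1 - 2·switch_rate)` per step.

Cohort structure (defaults mirror the motivating study design at desk
scale): 25 normal liver tissues paired to tumours, 17 MVI− and 18 MVI+
tumour tissues, 24 healthy plasma and one plasma sample per patient, over
2,000 five-CpG blocks (the study-scale catalogue has 225,025 regions; block
count is scaled down for test speed, and the detection floor scales with
it). Key generator parameters, all per `CohortSpec`:

* `theta_low/high = 0.2/0.8`: per-block baseline methylation drawn uniformly.
* `n_diff_tumor = 20` spiked tumour-differential blocks with `tumor_shift =
  0.4` (0.5 in the strong preset), shifted towards the far side of 0.5 so a
  mix of hyper- and hypo-methylated markers arises; `n_diff_mvi = 8` MVI
  blocks shifted only in MVI+ tumours (`mvi_shift = 0.3`; 0.4 strong).
* `theta_jitter = 0.10`: per-sample, per-block Gaussian jitter on `theta`
  (clipped to [0.02, 0.98]) modelling inter-individual biological
  variability; without it every sample in a group shares one block-level
  rate and tissue scores collapse into implausible point masses. Null blocks
  draw the jitter identically in all groups, so type-I behaviour is
  unaffected.
* `mean_depth = 30` reads/block (Poisson; 50 in the strong preset),
  `detect_prob = 0.95` per sample x block (detection dropout),
  `switch_rate = 0.05`.
* `tumor_fraction = 0.3`: patient plasma draws each read from the matched
  tumour sample's realised distribution with this probability, else from a
  patient-specific normal background — a per-read ctDNA dilution model.
  At `tumor_fraction = 0` patient plasma is distributionally identical to
  healthy plasma.
* Survival: tumour patients draw event times Exponential(hazard) with
  `hazard = 0.03/month` (MVI−) vs `0.12` (MVI+; hazard ratio 4), independent
  Exponential(0.02) censoring.

What the generator does **not** emulate: genomic sequence context and CpG
density variation, bisulfite conversion errors, fragment-length and
coverage-bias structure, correlated (rather than independent) block-level
variation, batch effects, and clinical covariates. Passing tests therefore
demonstrate the correctness and internal consistency of the statistics and
the pipeline under its assumed generative model — not the clinical
performance figures attainable on real cohorts.

## Presets and problem sizes

* `default_cohort_spec` — 2,000 blocks, study-design group sizes (above).
* `marker_recovery_spec` — tissue-only, 2,000 blocks, 20 spiked blocks with
  shift 0.4, 20 normals vs 20 tumours, depth 30.
* `strong_signal_spec` — 800 blocks, shifts 0.5/0.4, depth 50, full plasma
  cohort, hazard ratio 4.
* `demo_spec` — 250 blocks, 16 normals, 8+8 tumours, depth 40, large shifts;
  small enough for interactive use and pipeline demonstrations while keeping
  the paired signed-rank stage powered (16 pairs give a minimum exact
  one-sided p of 2^-16, comfortably below the BH threshold across 250
  blocks even with detection dropout).

Block counts per preset are the package's own speed/power trade-off; every
statistic scales to larger catalogues unchanged.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open throughout; haplotype records span their
covered cytosines, block intervals extend to the last CpG's dinucleotide end
(+2). Inclusive thresholds carry a 1e-12 rounding tolerance (SD floor,
detection fraction) and the strict r² inequality excludes threshold ties with
the same tolerance. Empty groups, all-censored survival input, all-zero
paired differences, single-class AUC input and unpowered stratification all
raise typed errors rather than returning degenerate numbers. The pipeline
derives one seed per stage from the run seed (`numpy.random.SeedSequence`),
making stages individually reproducible and whole runs byte-identical.

## Known limitations

* Pooled-read r² is the only discovery estimator with a formal test oracle;
  the per-sample mode is a pragmatic weighted mean.
* The repeat-based AUC CI understates uncertainty when repeats share folds'
  training data (as all repeated-CV CIs do).
* The plasma transfer path assumes the marker columns exist in the plasma
  matrix; it imputes missing cells but refuses wholly absent markers.
* Survival validation is two-group log-rank only; no adjustment for
  covariates or competing risks.
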