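# Methods

This note documents the models, conventions and design choices behind
`idrbench`, in the order the pipeline applies them.

## Input model

A benchmark protein is a sequence of length L with a per-residue 0/1
disorder annotation and, optionally, a per-residue 0/1 binding
annotation. Binding is a *region-level* property: if any residue of an
IDR is annotated as binding, the whole IDR counts as a binding IDR. A
predictor contributes per-residue propensities in [0,1] (scores
marginally outside the interval, by at most 0.05, are clamped with a
warning; larger excursions are treated as file corruption). All
coordinates in the public interface are 1-based inclusive, matching the
CAID per-residue file dialect. Identifiers join across files by exact
string equality on the header token. Proteins without a prediction from
some method are tolerated everywhere and surface as a coverage fraction,
never as an error.

## AF2-derived disorder scores

`plddt_to_disorder` maps confidence to propensity as `1 − pLDDT/100`;
it is exactly invertible and strictly order-reversing. pLDDT is read
from the alpha-carbon temperature factor of each residue in the PDB
model, falling back to the residue's first atom (logged) when no CA
exists.

`asa_to_rsa` divides each residue's accessible surface area (Å²) by the
residue's maximum accessibility in an extended Gly-X-Gly tripeptide and
caps the ratio at 1. The packaged table holds the Tien et al. (2013)
theoretical values; any table with the 20 standard letters can be
swapped in via `load_max_asa(path)`. The unknown letter `X` is
normalized by the mean of the 20 values (logged); other letters are
errors.

`smooth_rsa` applies a centred moving average of odd width (default 25
residues). At the termini the window truncates to its in-range part —
no padding — so the output never leaves [min, max] of the input and a
constant series is a fixed point.

`select_best_model` implements the optimized-rank scenario over AF2's
up-to-five ranked models: the model whose derived profile has the
highest per-protein ROC AUC against the reference wins, with ties broken
toward the native rank order. Per-protein AUC was chosen as the
selection criterion because it is the headline residue-level metric of
the evaluation; the criterion is isolated in one function so an
alternative (e.g. per-protein AUPRC) is a one-line swap. Proteins whose
labels are single-class are rejected — the same exclusion applied
wherever per-protein AUC is needed.

## Calibration and metrics

The binarization threshold for a method is calibrated on the pooled
residues of the whole benchmark: among candidate cut-offs (the observed
scores plus 0), the one minimizing |#{scores > t} − native_count| is
chosen; objective ties are broken toward fewer predicted disordered
residues, then toward the smallest cut-off. With all-distinct scores and
an attainable target the match is exact. Binarization and the
fully-disordered cut-offs use strict `>` throughout ("above the
cut-off"; "content > 0.99"), so a score equal to the threshold is
ordered and a content equal to a cut-off is not fully disordered.

Residue-level metrics are micro-averages over the pooled residues of a
dataset, matching the single-threshold calibration. ROC AUC is the
Mann–Whitney probability with ties counted 1/2 (delegated to
scikit-learn; the test suite pins it against brute-force pair
enumeration); AUPRC is the average-precision formulation without
interpolation. MCC/F1/sensitivity with a zero denominator return 0 with
a `degenerate` flag rather than raising, so dataset aggregation never
aborts. Disorder content is the mean of a 0/1 series; content accuracy
uses mean absolute error and Spearman correlation (average ranks for
ties, which reduces to the classic 1 − 6Σd²/(n(n²−1)) on tie-free
input). Fully-disordered detection declares a protein predicted-FDP by
applying the same content cut-off to the predicted content — the
simplest declaration rule consistent with the calibrated binary calls.

## Resampling significance

Robustness across test sets is assessed on 20 subsets: disjoint 5%
slices of a single shuffle for residue-level and content comparisons,
and 20 independently drawn 20% samples for the fully-disordered
evaluation, whose positive class (45–56 proteins at CAID scale) is too
small for 5% slices. Twenty 20% subsets cannot be disjoint; independent
draws give the intended small overlap in expectation.

The normality gate is applied to the *paired differences* — the
quantity the paired t-test actually assumes normal — using the
Anderson–Darling test at p = 0.05; non-rejected differences go to a
two-sided paired t-test, others to a two-sided Wilcoxon signed-rank
test. All-zero differences short-circuit to `=` with p = 1; constant
nonzero differences (zero variance, t undefined) route to Wilcoxon.
Subsets where a metric is undefined become NaN and are dropped pairwise;
fewer than 5 surviving pairs makes the comparison untestable, rendered
as `.` in report cells. No multiple-testing correction is applied:
each comparison is tested at its own nominal α = 0.05, which is a
deliberate fidelity choice and means the family-wise error across a
full verdict grid is larger.

## Markers and the competitive split

Putative IDRs are runs of at least 4 consecutive predicted-disordered
residues. The composite score sums min(i−1, L−i) over *all* predicted
disordered residues (short runs included — the ≥4 rule applies only
where IDRs are counted) and divides by L; terminal residues contribute
0, so low values mean little disorder and/or terminal disorder. Marker 7
(distance of putative IDRs to the closest terminus) is the minimum over
putative-IDR residues, with sentinel L+1 when no putative IDR exists.

A protein is *competitive* for the AF2-derived predictor when its
per-protein AUC (i) strictly exceeds a floor — by convention the
dataset-level AUC of the best comparator — and (ii) is at or above the
lower bound of a 95% normal-approximation interval, mean − 1.96·sd/√k,
of its k comparator AUCs. The interval construction is isolated in
`competitive_split` so alternative readings are swappable. Marker
distributions between the competitive group and the rest are compared
with a two-sided Mann–Whitney rank-sum test (chosen for the markers'
skewed, partly discrete distributions); the below-median rule then
selects proteins whose significant markers all fall strictly below the
competitive group's medians.

## Synthetic generator

`synthgen` emulates the benchmark's statistical structure:

* **Labels** — alternating ordered/disordered runs with geometric
  lengths (defaults: mean IDR run 65, mean ordered run 340, i.e.
  prevalence ≈ 0.16 and ≈ 1.3 IDRs per protein), chain lengths
  log-normal (log-mean 6.0, log-sd 0.7; mean ≈ 520), terminal-IDR
  probability 0.3 per chain end, binding painted on whole disordered
  runs with probability 0.31, plus a fully-disordered mixture component
  (probability 0.07, log-normal lengths with median ≈ 134) reflecting
  the benchmark's 45–56 short fully disordered chains among 646.
* **Scores** — a binormal model: latent class-conditional normals
  (means mu0/mu1, common sigma) squashed to [0,1] by a logistic. ROC
  AUC is invariant under the monotone squash, so the expected pooled
  AUC is exactly Φ((mu1−mu0)/(σ√2)), giving tests a closed-form target.
* **AF2 series** — pLDDT anti-correlated with disorder and RSA elevated
  in disordered runs, with moving-average-autocorrelated noise; the
  `quality` parameter scales class separation.
* **Seeding** — one master seed; each protein/stream derives its RNG by
  stable CRC32 hashing of (seed, id, stream tag), so output is
  independent of iteration order.

Terminus handling: the terminal-IDR probability is drawn independently
for each chain end; when the end draw is "ordered" but the run process
ends mid-IDR, the trailing disordered run is re-typed ordered. This
makes the zero-probability case exact but removes a little disordered
mass at the chain end, so empirical prevalence sits slightly below the
run-length-law value at CAID-scale lengths; the law-of-large-numbers
check is therefore run at long chain lengths where the boundary effect
vanishes.

What the generator does **not** emulate: amino-acid composition biases
of real IDRs (sequences are uniform over the 20 letters); spatial score
saturation — real top predictors output near-1 propensities across
entire long IDRs, whereas iid binormal scores at moderate separation
essentially never push a protein's predicted content above the 0.9
fully-disordered cut-off, so FDP detection rates on synthetic data are
far below what saturating predictors achieve on real data (a
high-separation emulation is used where a non-degenerate FDP regime is
needed); and annotation noise. Passing tests therefore validate the
evaluation machinery, not any claim about real predictors.

## Problem sizes

The default generator emits 646 proteins (~320k residues), the scale the
pipeline targets; closed-form AUC recovery is checked at ≥ 10⁵ pooled
residues, stratification invariants at 10⁴ proteins, and the verdict
type-I error over 200 replicates of the 20×5% scheme — sizes chosen so
Monte-Carlo slack is small relative to the asserted tolerances.

## Known limitations

* The marker analysis needs at least two comparator methods per protein
  to form the confidence interval; with fewer it is skipped with a
  warning.
* The reference dialect is strictly 0/1; masked annotations (`-`) are
  rejected by design.
* mmCIF models are not parsed; AF2 models must be in PDB format.
* Verdicts inherit the per-comparison α with no family-wise control.
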