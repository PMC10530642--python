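# Methods

`hfadyn` implements a complete analysis chain for the question of how
visual content is represented in intracranial recordings while a stimulus
stays on screen: single-electrode activation, multivariate state-space
dynamics, time-resolved category decoding with temporal generalization,
and exemplar-level representational reliability. Because raw clinical
iEEG cannot ship with a package, every stage is exercised against a
synthetic-data generator with planted, recoverable structure. This note
records the models, the defaults and why, the numerical choices, and the
known limitations.

## High-frequency activity (HFA)

HFA (70–150 Hz amplitude) is treated as a proxy for aggregate local
firing. Estimation splits the band into eight 10-Hz sub-bands; each is
band-pass filtered (zero-phase FIR, Hamming design, order from the
standard transition-width heuristic `N ≈ 3.3·fs/Δf` with a 2.5 Hz
transition), Hilbert-transformed for instantaneous amplitude, and divided
by its own mean amplitude over the recording before averaging across
sub-bands. Per-band normalization counteracts the 1/f spectrum, which
would otherwise let the lowest sub-bands dominate the average. The
normalization mean excludes the filter's edge-transient region; with that
convention the estimate is exactly invariant to rescaling the recording,
and each band's interior mean is 1. A silent band (numerically zero
amplitude throughout — possible only in fully synthetic input) is passed
through unnormalized rather than dividing by zero.

Epochs span −300 to 1600 ms around stimulus onset. Baseline correction
subtracts the mean of the 300 ms before onset per trial and electrode
(idempotent by construction). Trials with excessive noise are dropped by
a rule the analysis chain needs but the underlying procedure leaves open:
a trial is excluded when any electrode's peak absolute amplitude exceeds
K = 5 robust SDs (1.4826·MAD) of that electrode's distribution of trial
peaks; K is configurable. Smoothing is a 50-ms centered boxcar whose
window shrinks at the epoch edges (no padding); this preserves constant
traces exactly and trace means to within edge effects. Decoding and RSA
run on data decimated to 200 Hz after smoothing (the boxcar acts as the
anti-alias filter for envelope data); window-based electrode statistics
run on unsmoothed data so information cannot leak across window borders.

## Synthetic data generator

The generator emulates a multi-duration visual experiment: four stimulus
categories (face, watch, non-watch object, animal; default exemplar
counts 18/19/13/10, the composition of a 60-image set shared across
patients), two repetitions per exemplar, presentation durations drawn
uniformly from {300, 900, 1500} ms, ISIs from {600…1200} ms. All
patients share the stimulus sequence, so the dataset is one
`trials × electrodes × time` tensor whose electrode axis concatenates
patients; per-patient analyses select electrode blocks. This mirrors the
merged-electrode convention used downstream (trajectories merged across
patients; decoders fed all electrodes of a region) without ragged
containers.

Each region follows a coding profile: zero response until an onset
latency, a squared-sine rise over ~80 ms to a transient peak, exponential
relaxation (τ ≈ 150 ms) toward `sustained_fraction × peak` while the
stimulus is on, and exponential return to baseline after offset. A
sustained fraction near 0.2 reproduces the roughly five-fold (~80%)
attenuation of sensory responses by 800–900 ms; frontoparietal-like
profiles use sustained fractions near 0. Defaults per region (peak
amplitude in noise-SD units / latency / sustained fraction): Occ 5.0/80/
0.25, VT 4.0/120/0.2, Par 2.0/150/0.05, PFC 1.8/180/0.0.

Category structure is a per-electrode gain pattern: gain = 1 +
`tuning_strength`·z per category (default SD 0.5). Exemplar identity adds
an isotropic perturbation around the category centroid
(`exemplar_gain_sd`, default 0.2). A `stable` profile keeps one pattern
throughout; a `dynamic` profile carries its category contrast on disjoint
electrode halves before and after a switch time (default 500 ms), making
the early and late discriminating directions orthogonal — the regime
that produces diagonal temporal-generalization matrices. About 15% of
responsive electrodes are sign-flipped (negative responders) and about
10% of electrodes carry no signal at all, so selection
sensitivity/specificity can be scored against ground truth.

Noise is additive Gaussian on the HFA amplitude (default SD 1.0, i.e.
peak signal-to-noise ≈ 4 for a strongly responsive electrode) with
optional trial-level multiplicative gain jitter. No quantitative
single-electrode SNR is published for this kind of data; the default was
chosen once to land in the qualitative regime the analyses assume —
clearly decodable category structure at the peak, attenuated but present
sustained coding — and is documented rather than fitted. The generator
does not emulate 1/f spectra, epileptiform artifacts, or eye-movement
artifacts; passing tests therefore demonstrate correctness of the
analysis chain and recoverability of planted structure, not robustness
to every pathology of clinical recordings.

A companion raw-trace mode synthesizes continuous voltage (eight
sub-band carriers amplitude-modulated by the planted envelope plus
broadband noise) to validate the HFA extraction stage end to end; the
extracted envelope correlates > 0.95 with the planted one.

## Electrode statistics

Visual responsiveness: per category and per 200-ms window (100–300,
300–500, 500–700, 700–900 ms; trials ≥ 900 ms only), a two-tailed paired
t test of the unsmoothed window mean against the 200-ms prestimulus mean.
Bonferroni across the four windows, Benjamini-Hochberg across electrodes
within each category × window family (the family grouping is the one
natural reading of "FDR across electrodes"); an electrode is responsive
when any test survives q < 0.05/4, and its sign is the sign of the sum of
t statistics over all tests — all tests, not only significant ones, so a
rare mixed electrode is classified by its dominant direction. Category
selectivity uses the same scheme with a one-way ANOVA across the four
categories, plus a point-by-point selectivity time course 100·η² =
100·SS_between/SS_total (0 where total variance is 0), reported on
smoothed traces to match plotted dynamics.

Response summaries: peak of the mean response in 0–900 ms, its latency,
the 800–900 ms mean, and attenuation = 100·(peak − end)/peak, which
exceeds 100% when the late response dips below baseline. Group contrasts
use one-way ANOVA with Tukey–Kramer post hocs and pairwise Cohen's d.

## State-space trajectories

The neural state is the vector of responses across a region's
electrodes. Because trials are baseline-corrected, the distance from the
prestimulus state is the plain L2 norm ‖s_t‖. Transition speed is
‖s_t − s_{t−1}‖ rescaled per ms when the axis is decimated. Duration
dependence is tested on the distance between duration-condition
trajectories with duration labels shuffled across trials and
max-statistic correction, restricted by default to the window where only
the longer stimulus remains on screen ([short, long] ms). The category
selectivity index is √(mean_C ‖s_Ct − mean_C s_Ct‖²), invariant to any
common offset. Confidence intervals use a jackknife: per iteration, each
patient drops one random trial per condition cell and the merged
trajectory statistic is recomputed; 1000 of the combinatorially many
leave-one-per-patient sets are sampled uniformly with a fixed seed. PCA
appears only in a plotting helper (3 components); no inference uses it.

## Decoding

Pairwise category decoding per time point with a regularized linear
discriminant: w = Σ̂⁻¹(μ₁ − μ₂), Σ̂ = (1−λ)Σ + λ(tr Σ/p)I, with the
pooled class-count-weighted covariance and the Ledoit-Wolf λ estimated on
the training fold only (never on test data). The identity target is
scaled so tr Σ̂ = tr Σ for every λ. If the pooled covariance is exactly
zero (noise-free baseline samples), the means-only discriminant
w = μ₁ − μ₂ is used; with λ = 0 and p ≥ n−1 fitting raises instead,
instructing regularization.

Performance is the AUC computed as the tie-corrected rank statistic,
equal to the ROC integral and to the probability that a random trial of
class 1 outscores one of class 2; it is invariant to monotone transforms
of the decision values and flips to 1−AUC under label exchange.
Repetitions of an image are averaged into one trial so no exemplar
straddles the train/test split; the larger class is undersampled to the
smaller, redrawn at each of 5 repeats of 5-fold stratified CV, and fold
AUCs are averaged across folds then repeats (averaging precedes
significance testing). Temporal generalization trains at every time
point and tests at all time points with shared splits; the TGM diagonal
equals the time-resolved AUC under the same folds. Permutation nulls
shuffle category labels once per permutation (shared across time points)
and rerun the identical CV with the observed fold-assignment seed, which
stabilizes the null.

Cross-validated AUC on information-free data sits at 0.5 with a
dataset-level spread of roughly ±0.015 (mean over time, 120 trials, 50
electrodes); small systematic deviations from 0.5 in single datasets are
the familiar finite-sample anti-correlation between training means and
held-out trials, not a bug.

## Permutation inference

One engine serves all analyses. A null is N_perm evaluations of the
statistic under label shuffles, one shuffled assignment per permutation
applied to every time point (preserving temporal structure).
Max-statistic correction z-scores the observed and permuted statistics
with the same column means/SDs (zero-SD columns give z = 0) and
thresholds the observed z at the 95th percentile of the per-permutation
maximal z. Cluster correction thresholds the statistic in its native
units (defaults: AUC 0.60, AUC-difference 0.10, reliability z 1.5 — or
0.75 for 100-ms-smoothed single-category analyses — and the analytic ρ
threshold below), clusters by temporal adjacency (4-connectivity over
train × test for TGMs; the minimal, most conservative 2-D neighborhood),
sums member values as the cluster mass, and compares against the null's
maximal cluster mass. Tests are one-sided except between-region
difference clusters, which use a two-sided flag. p values count the
observed statistic as a member of its own null, so p ≥ 1/(N_perm+1).
BH-FDR handles point-by-point inference.

## Exemplar reliability (RSA)

RDMs use correlation dissimilarity 1−r (range [0, 2]) or Euclidean
distance, per time point on the 200-Hz axis, over exemplars seen in both
of their first two qualifying (≥ 900 ms) repetitions.

**Item Reliability (IR).** For each presentation, Spearman-correlate its
dissimilarity vector to all other images within its own repetition with
its dissimilarity vector to all other images of the other repetition;
average over images and both repetitions. The null shuffles the stimulus
identities of the *other* repetition only — the anchor is never permuted
(asserted structurally in tests) — and the same 1000 shuffles are reused
at every time point; z-scoring is per time point.

**Geometry Reliability (GR).** From the 2N×2N cross-repetition RDM, the
within-repetition-1 triangle is averaged elementwise with the upper
between-repetition triangle, and within-repetition-2 with the lower
(transposed) one; the two geometry vectors (length N(N−1)/2) are Spearman
correlated. The same-exemplar between-repetition diagonal is excluded:
those N cells are identical in both pairings and would mechanically
inflate the correlation; cross-repetition state-space displacement still
enters through every between-triangle term. A flag switches to
correlating each set pair separately and averaging. The null shuffles
exemplar identities of repetition 2 throughout the matrix.

Both statistics mix within- and between-repetition dissimilarities, so
they test preservation of the geometry *and* of its location; and because
their nulls shuffle identities, exemplars that occupy interchangeable
positions reduce the z even when the geometry is preserved — verified in
tests as a reduction relative to distinct-exemplar geometries.

**Temporal stability.** The T×T stability matrix computes the IR (or GR)
comparison with the within-repetition structure taken at t₁ and the
other-repetition structure at t₂, so at least one side of every
comparison crosses repetitions and temporally autocorrelated spontaneous
activity cannot masquerade as stability. The diagonal reproduces the
reliability time course exactly.

**Category models and partial correlation.** Four model RDMs (0 within
category, 0.5 across categories sharing a higher-order group, 1
otherwise): single-category; low-level ({face, watch} vs {object,
animal}); semantic ({face, animal} vs {watch, object}); face-vs-rest.
Model fit time courses use Spearman ρ with a cluster-forming threshold
from the one-sided normal approximation z(1−α)/√(n_pairs) — 0.0391 at
the 60-image geometry's 1770 pairs — recomputed for other geometry
sizes. Category structure is removed from IR/GR by Spearman partial
correlation (ranks residualized on the model's ranks; one model row per
anchor for IR, the unfolded triangle for GR; average-rank ties), with the
identical shuffles applied to the partialed statistic. One property of
the statistics is worth knowing: the anchor presentation (IR) and the
shared between-repetition block (GR) couple the two compared vectors
through the same single-presentation patterns, so a purely categorical
geometry retains a small positive partialed z (a state-space location
component the flat model cannot absorb). Partialing therefore suppresses
category-driven reliability strongly but not to exactly zero, while
leaving model-orthogonal exemplar structure untouched.

## Pipeline and reproducibility

Stages run in dependency order (simulate → select → state-space → decode
→ RSA); every stochastic stage receives a sub-seed derived from the
master seed via `numpy.random.SeedSequence` and recorded in a provenance
JSON together with package and numpy versions and scalar parameters.
Epochs travel as HDF5 (`hfa`, `times_ms`) with TSV metadata sidecars;
round trips are bit-exact. Defaults mirror the analysis settings above
(1000 permutations, 5×5 CV, 200 Hz); a `fast` profile (200 permutations,
3×3 CV) exists for smoke testing. The bundled verification suite runs at
reduced problem sizes chosen to keep the full run within minutes on one
CPU: e.g. 24–50 electrodes, 40–120 trials, 100–300 permutations, and 300
simulated null datasets for the family-wise-error check; the sizes are
stated in each test.

## Known limitations

- The generator's noise is white across electrodes and time (after the
  planted envelope); real HFA has spatially and temporally correlated
  noise, which would widen permutation nulls but not bias them.
- Negative responders are modeled as exact sign flips; real suppression
  is rarely a mirror image of activation.
- The exact family grouping of the FDR step, the trial-rejection rule,
  and the GR set pairing are choices among defensible readings; all are
  configurable and recorded here.
- IR/GR retain an anchor-driven location component after category
  partialing (see above); comparisons of partialed scores across regions
  remain valid because the component is shared by construction.
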