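# Methods

## The estimand

A hypnogram is a whole-night sequence of sleep stages, one label per 30 s
epoch, over the consumer alphabet W/L/D/R (wake, light = N1+N2, deep = N3,
REM). Its first-order transition structure is summarised by the 4×4
row-stochastic matrix `s_{X→Y} = n_{X→Y} / Σ_B n_{X→B}`, where `n_{X→Y}`
counts adjacent epoch pairs, self-transitions included, so a night of
`n` epochs contributes exactly `n − 1` transitions. Every epoch inside the
aligned record participates, including pre-onset and mid-sleep wake.

A stage that never occurs yields a zero-support row. Such rows are
propagated as *missing*, never imputed as zero or uniform: imputation
would bias cohort averages of rare transitions (deep→REM and REM→deep are
structurally absent in healthy sleep). Cohort summaries average each cell
over the subjects for whom it is defined (pairwise deletion) and attach
Student-t 95 % confidence intervals, `mean ± t_{0.975,n−1}·SD/√n`; a cell
defined for a single subject reports its mean with an undefined CI.

## Device comparison

Per subject-night, tracker (F) and reference (M) matrices are estimated on
the aligned overlap of the two records (start snapped to the later start,
rounded to the nearest epoch boundary). Error and agreement statistics:

* **Absolute percent error** `e_{X→Y} = |s^F − s^M| / s^M × 100`,
  undefined where the reference cell is 0 or either cell is missing.
* **Paired t tests**, two-sided, per cell across subjects; cells with
  fewer than 3 complete pairs are untestable. All-zero differences (the
  exact null) report t undefined and p = 1; a *constant nonzero*
  difference reports p = 0, since a deterministic offset is the strongest
  possible evidence against the null, not the weakest. Raw p-values are
  reported by default, mirroring common practice in device-validation
  reports; Bonferroni and Benjamini–Hochberg corrections are available but
  off by default.
* **Bland–Altman**: bias = mean(tracker − reference), limits of agreement
  = bias ± 1.96·SD of the differences (the conventional normal quantile,
  not a small-sample t multiplier). The scatter's x-axis is the
  *reference* value by default — device discrepancy as a function of the
  medically measured quantity — with the classical pair-mean x-axis
  available as an option. |bias| ≤ 5 percentage points is classed as free
  of systematic bias.

## Factor stratification

The cohort is split at conventional cut-offs (age 25 y; PSQI 5; TST
360 min; WASO 30 min; SOL 30 min; SE 90 %; light 65 %; SWS 20 %; REM 20 %;
T_avg 90 min; sex by category). Values equal to the cut-off join the upper
group except for SE, which is reported as SE>90 vs SE≤90. Because the two
subsets are *different participants*, location differences in their error
distributions are tested with the two-sided Wilcoxon **rank-sum** test
(midranks for ties; exact permutation distribution enumerated for combined
n ≤ 20, normal approximation with continuity and tie correction above),
and sex/age comparisons of sleep patterns use the unequal-variance Welch
t test. Paired tests are inapplicable to disjoint groups, so none are
offered for stratified comparisons. The exact rank-sum path is implemented
here by direct enumeration because library implementations provide exact
distributions only for tie-free data; the asymptotic path is cross-checked
against an independent implementation in the tests.

## Sleep metrics

Derived from the reference hypnogram over the recorded in-bed interval:
sleep onset is the first epoch of any sleep stage (the simplest rule;
multi-epoch clinical onset rules exist and the choice is configurable in
principle, but onset differences of one epoch move SOL by 0.5 min);
SOL = minutes from record start to onset; the final awakening is the last
sleep epoch; TST = sleep minutes in [onset, final]; WASO = wake minutes
strictly inside that interval (TST + WASO spans it exactly); SE = TST /
record duration × 100, taking the recorded interval as the time-in-bed
proxy; stage ratios are stage minutes / TST. The average sleep cycle T_avg
is the mean interval between the *end epochs* of successive REM episodes
(maximal runs of R), the standard NREM→REM cycle delimiter; it needs at
least two episodes. All-wake records yield undefined metrics rather than
zeros.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: 23
participants, one analysis night each, 960 thirty-second epochs (8 h).

* **Reference nights** are first-order Markov chains started in W. The
  default generator matrix is the published cohort-mean transition matrix
  for the EEG-based reference device in healthy young adults; printed
  rows carry rounding (sums 95.7–100.1 %) and are renormalised to sum
  exactly to 1, preserving structural zeros.
* **Between-subject variation**: each subject's row is a Dirichlet draw
  with parameter `κ·p` over the row's nonzero cells, so the expectation is
  the cohort row and κ → ∞ recovers it. The default κ = 100 per row was
  set so that jitter variance plus within-night multinomial estimation
  variance gives simulated cohort CI widths of the same order as the
  published ones; for a mid-range cell (p = 0.5) it implies a
  between-subject SD of ≈ 5 percentage points.
* **Tracker nights** come either from an independent chain driven by the
  tracker-side cohort matrix (device-level emulation) or from an
  **epoch-wise confusion channel** applied to the reference night
  (mechanism-level emulation). The default channel relabels 30 % of true
  wake and true deep epochs as light sleep — the order of magnitude of
  epoch-level misclassification reported for wrist trackers — and passes
  light and REM through.
* **Covariates**: age discrete uniform 21–30, sex Bernoulli at the study's
  14:9 men:women ratio, PSQI uniform 0–10; sleep metrics are computed from
  the simulated reference night. Per-subject random streams derive from
  (master seed, subject index), so enlarging the cohort never reshuffles
  existing subjects and equal seeds give byte-identical output files.

### What the generator does and does not emulate

It reproduces the first-order transition structure, cohort-level means,
between-subject spread, and a plausible instantaneous misclassification
mechanism. It has **no** stage-duration (semi-Markov) structure, no
ultradian/circadian modulation, no coupling between covariates and sleep
architecture, and no temporally correlated tracker error. Consequences
worth stating plainly:

* Simulated nights are more "efficient" than real ones (little wake, TST
  near the full record), because the chain's stationary wake occupancy is
  low; stratification splits on TST/WASO/SE can be degenerate and are then
  skipped as untestable.
* An epoch-iid confusion channel **provably cannot** overestimate the
  persistence of a misclassified stage. If a fraction q of true-X epochs
  is relabelled and no other stage maps to X, then a tracker epoch
  labelled X is a true X, and P(next label X | this label X) =
  s_{XX}·(1−q) < s_{XX}: wake- and deep-persistence biases are strictly
  negative under the channel. The persistence *over*estimation seen in
  real tracker data (e.g. wake staying ≈ 90 % vs ≈ 54 % on the reference)
  requires temporally correlated output — the device smooths its labels
  into long runs — which the independent-chain mode captures
  descriptively but the confusion channel cannot mechanistically. The
  directionality test in the acceptance suite asserts the
  persistence-overestimation pattern under the channel and is therefore
  expected to fail; it is kept as an executable record of this limit.
* Parameter recovery of the generator matrix from 23 simulated nights is
  imperfect in a way real cohorts share: the per-subject MLE of a sticky
  row visited in a few long runs is biased downward (roughly
  `p̂ ≈ 1 − runs/support`), and subjects whose jittered chain rarely
  enters a stage contribute wild low-support estimates to the unweighted
  cohort mean. Diagonal cells are typically recovered within 1–2
  percentage points, but single cells can deviate by ≈ 5 on unlucky
  seeds; published cohort means, being unweighted means of per-subject
  MLEs themselves, carry the same small-sample character.

## Numerical and I/O conventions

Internal probabilities live on [0, 1]; every table written to disk is on
the percent scale. Epoch indices are 0-based internally and 1-based in
epoch CSVs. Night validity for analysis-night selection (second night
preferred, then third, then first) requires both devices present,
stage-level tracker data and ≥ 240 epochs (2 h); classic-level exports
(awake/restless/asleep at 60 s) are parsed but never analysed, as they
carry no stage information. Sleep-JSON records must tile the night
contiguously with durations divisible by the epoch length. Intermediate
CSVs are re-read with round-trip float parsing so that staged CLI runs are
bit-identical to monolithic runs. Problem sizes in the test and acceptance
suites (23 × 960-epoch cohorts, 50-seed null replications, 10⁶-epoch
consistency checks) were chosen as the smallest that exercise the
cohort-level statistics at realistic support.
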