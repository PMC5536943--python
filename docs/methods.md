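# Methods

## The experimental design being modeled

A daily session consists of six blocks of trace eyeblink conditioning in a
fixed order: in each of three condition combinations — auditory CS in box 1,
auditory CS in box 2, visual CS in box 1 — the animal first receives 20
CS-alone trials, then 50 CS–US paired trials. The CS lasts 100 ms; the US
(or its virtual equivalent on CS-alone trials) arrives 600 ms after CS
onset, leaving a 500 ms stimulus-free trace interval. Inter-trial intervals
(ITIs) are drawn uniformly from 20–40 s, measured from US offset to the next
CS onset. All event times are seconds from session start; analysis windows
are half-open `[start, end)`; trial indices are 1-based.

Three task variables define the selectivity contrasts:

* **R** (relationship): CS-alone vs CS-US blocks of the same modality/box —
  three such pairs; a cell is R-selective if any pair is significant.
* **M** (modality): auditory vs visual CS in box 1, CS-alone and CS-US
  trials pooled.
* **E** (environment): auditory CS in box 1 vs box 2, pooled likewise.

Pooling for M and E is the default; a strictly unpooled reading is not
exposed because every statistic in scope consumes pooled trials.

## Analysis epochs

* **Trial window**: CS onset → US onset, 600 ms — the phasic epoch. Using
  this window means no US-artifact handling is ever needed.
* **Pre-CS window**: 1 s before CS onset — the responsiveness baseline.
* **ITI window**: 9 s before CS onset — the tonic epoch. With ITIs ≥ 20 s it
  always begins ≥ 11 s after the previous US offset, avoiding lingering
  post-US rate transients. This bound is enforced structurally: a schedule
  whose minimum ITI cannot contain the 9 s window plus the trial is rejected
  at construction.

The window ahead of the very first trial has no preceding US; the first ITI
is drawn like every other so the window always exists.

## Permutation machinery

**CS-responsiveness** — statistic |mean trial-window rate − mean pre-CS
rate| per block; the null re-assigns, per trial, the two epoch rates to the
two epoch labels (equivalently, flips the sign of that trial's rate
difference); a unit is CS-responding if significant in ≥ 1 of 6 blocks. The
any-of-six rule is deliberately uncorrected — its family-wise false-positive
rate on non-responsive cells (~1 − 0.95⁶ ≈ 0.26) is part of the procedure
and is asserted, not hidden, in the tests.

**Shuffle-corrected differential index** — DI = |Fr₁ − Fr₂| / (Fr₁ + Fr₂) on
condition-mean rates; the null permutes condition labels over the pooled
trials (1000 draws by default). The correction subtracts the upper
`1 − α` null quantile, defined as the `ceil((1 − α)·n)`-th order statistic
of the null sample — a fixed convention that makes corrected values
reproducible. Selective ⇔ corrected DI > 0. When every rate in both
conditions is zero the DI is undefined; the cell is excluded from that
contrast (flagged NaN) rather than silently counted.

For ≤ 20 trials per condition both nulls can be enumerated exhaustively
(`exact=True`): all C(n, n₁) label assignments, or all 2ⁿ epoch swaps. The
enumeration is the oracle against which the sampled quantiles are tested;
at 20 000 draws the sampled threshold lands exactly on the enumerated
quantile in ≥ 90% of seeded fixtures and always on the enumerated support.

Empirical type-I error of both tests is calibrated on 500 simulated null
cells: within the 99% binomial CI of α = 0.05 (typical values 0.048–0.058).
The slight variation reflects the discreteness of low-count Poisson rates.

## Firing stability (KLD)

Per block, ITI rates are binned into fifteen 600 ms bins and trial-averaged;
the profile normalized to sum 1 is compared to uniform-15 by
D(P‖Q) = Σ P(i) log₂ P(i)/Q(i) (bits; 0·log 0 ≡ 0, Q must be positive).
Within-block KLD = median over the six blocks; between-block KLD = median
over the fifteen bins of the across-block rate vector against uniform-6.
All-zero profiles are undefined and excluded from the medians with a log
notice. A tonic block code yields between ≫ within; on the default synthetic
population 98.4% of cells show a positive difference.

## Ensemble analyses

State vectors are per-cell rates at one trial (600 ms window) or one ITI
(9 s mean, or one random 600 ms bin inside it). Cells recorded in different
sessions are aligned by within-session trial index (pseudo-population);
inter-cell correlations are ignored by construction. Normalization is
per-cell division by the cell's max over the declared scope; all-zero cells
are dropped and logged. Normalization is idempotent.

* **Block-pair comparison**: per repeat, 10 random trials per block are
  averaged into one vector per block; cells normalized across the six
  vectors; Pearson r computed for 2 block pairs per category × 20 repeats =
  40 r values per category. Categories: Modality, Environment, Relationship,
  None (odd- vs even-numbered trials of the two box-1 CS-US blocks; the
  upper bound) and All (the two pairs sharing no variable; the lower bound).
  ITI-period vectors redraw the random 600 ms bin each repeat.
* **ITI correlation matrix**: 100-cell subsample, 9 s mean-rate vectors,
  210 × 210 Pearson matrix (symmetric, unit diagonal).
* **Similarity Scores**: template = last ITI of each block; between-block
  score = mean r with the first 19 ITIs of the next block; within-block
  score = mean r with the 19 ITIs immediately preceding the template (the
  1st–19th trials of a 20-trial block, the 31st–49th of a 50-trial block).
  20 repeats with fresh 100-cell subsamples. Transitions are typed by what
  changes: R (contingency only), E (environment), E+M (environment +
  modality).
* **Sliding trend**: cells sorted by session; windows of 49 cells advanced
  by 10; per window the mean (within − between) per transition type;
  ordinary least squares of that series on window index (slope, R²,
  t-distribution p on the slope).

## Decoding

Per run: 200 randomly subsampled cells; hyperparameters (cost, gamma) of an
RBF-kernel SVM chosen by 5-fold stratified CV on *all* available trials
(normalized per cell over all trials); then 20 resamples in which 20 trials
per block are drawn without replacement, renormalized per cell over the 120
drawn trials, split 10 train / 10 test per block — 1200 predictions per
evaluation. Multiclass handling is one-vs-one voting (the LIBSVM
convention), which shapes the confusion matrices. Binary collapses relabel
blocks before training: modality (auditory vs visual), environment (box 1
vs 2), relationship (alone vs paired). Only the relationship collapse is
balanced (3 vs 3 blocks); modality and environment are 4 vs 2, so their
shuffled-label baseline is the 2/3 majority share rather than 1/2 — chance
controls use the relationship collapse.

Grid defaults: cost 2⁻⁵…2¹⁵ and gamma 2⁻¹⁵…2³ in powers of 4. Ties in CV
accuracy are broken toward the smallest gamma and then the **largest** cost.
The asymmetry is deliberate: hyperparameters are selected at ~210 training
trials but applied at 60, and among equally accurate grid points the
hard-margin (large-cost) solution transfers to the smaller training set,
whereas the most-regularized one can degenerate to the majority class there
(we observed exactly that failure with a smallest-cost rule: binary
collapses pinned at the 2/3 majority rate while 6-way decoding was
perfect).

## Synthetic data generator

The generator is the package's test bed; its defaults are the study
conditions above.

* **Spiking**: piecewise-homogeneous Poisson. Rate = per-block baseline
  during ITIs, baseline × phasic gain inside the 600 ms trial window. This
  ignores refractoriness, bursting and latency-resolved PSTH shape — a
  deliberate simplification, since every statistic in scope consumes
  window-averaged rates, and it buys closed-form oracles (count mean = rate
  × duration in any window).
* **Baselines**: log-normal with median 1 Hz (σ = 0.6 log-units), the
  low-rate regime typical of these recordings. Selectivity multiplies the
  baseline by (1 + effect_size) in the blocks on the cell's preferred side
  of each labeled contrast; effect_size = 1.0 (a 2× rate difference) by
  default. The preferred side is drawn at random per cell per contrast —
  with a fixed direction a selective population would re-scale rather than
  re-pattern across blocks, and block transitions would not decorrelate the
  ensemble. By construction, the contrasts with unequal generating rates are
  exactly those implied by the category label.
* **Category mix**: defaults reproduce a regime where nearly every cell
  carries tonic block information and the triple conjunction dominates
  (48.8% R+M+E on the default draw); 45.2% of cells are phasic responders
  with a 3× gain.
* **EMG**: Gaussian noise band-passed 250–5000 Hz (capped at 0.45 × the
  sampling rate) mirroring the acquisition filter; a CR is a
  5× amplitude scaling of the noise in the 200 ms before (virtual) US
  onset, drawn Bernoulli per trial with probability 0.7 on paired and 0.1 on
  CS-alone blocks. The detector reads only the envelope, so a scaled-noise
  burst is the appropriate minimal CR model. CS-alone trials are scored at a
  virtual US time of CS onset + 600 ms.
* **Optional knobs** used by specific analyses: linear within-block rate
  drift (exercises within-block decorrelation), a per-session effect-size
  gradient (exercises the sliding trend), and CR-locked trial-window gain
  (exercises the CR-correlation analysis).

What passing tests on this generator do **not** show about real data: real
spike trains are non-Poisson and non-stationary, real effect sizes are
heterogeneous and often far weaker than 2×, real EMG contains movement
artifacts, and real populations violate the independence the
pseudo-population construction assumes. The generator validates the
*machinery* — calibration, structure, recovery under known ground truth —
not the biological effect sizes. In particular, at the default effect size
the bin-size sweep saturates (the selective fraction barely drops at 1/8
bins) and decoding sits at ceiling; the decrease with shorter bins and
sub-ceiling accuracies appear only at weaker effects or lower rates.

## Numerical and interface choices

* One master seed; each stage derives a named substream (CRC-32 of the
  stage name XOR seed), so stages are reproducible independently and
  identical seeds give byte-identical output tables.
* CR-threshold SD uses the population convention (ddof = 0); the threshold
  scope is the whole session, with a per-block option.
* The EMG envelope of long traces is computed in 4M-sample chunks with 0.5 s
  guards; the analytic signal is edge-contaminated only within a filter
  transient of segment boundaries.
* Pearson r on a constant vector is undefined: returned as NaN with a
  warning and excluded from averages.
* Invalid session rows (unsorted spikes, events outside the recorded span,
  US times on unpaired blocks) are rejected loudly at load; alignment errors
  would silently corrupt every downstream statistic.
* Session duration is derived from the schedule and the drawn ITIs (it is
  not an independent parameter).

## Problem sizes

Test and script problem sizes are chosen for quick iteration while keeping
every structural count at its defining value (210 trials, 40 r values per
category, 1200 predictions per decoding evaluation, 19-trial similarity
windows): unit tests use 6-block sessions with 10–25 trials per block and
10–12 s ITIs plus 12–60 cells; calibration uses 500 null cells × 1000
shuffles; the analysis drivers run the full 210-trial, 250-cell session and
10 decoding runs per configuration.

## Known limitations

* The generator's phasic gain is uniform across blocks, so a cell's
  trial-epoch category coincides with its tonic category; phasic-only
  selectivity patterns require custom `CellParams`.
* The CR-correlation analysis inherits the generator's Bernoulli CR model;
  it does not model CR-amplitude gradation.
* The sliding-trend analysis approximates "a block of five sessions" by a
  49-cell window over session-sorted cells, as in the source procedure; with
  few cells per session the mapping is coarse.
* EMG at 10 kHz for a full session is ~260 MB in memory; scripts cache it
  under `scratch/` and tests use shorter sessions or lower sampling rates.
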