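# Methods note

This note records the model behind each analysis, the default parameters and
why they were chosen, the assumptions baked into the synthetic generators,
and the numerical decisions a reader should know before trusting or
extending the results.

## Scientific setting

Food-deprived female mice either remain parental towards pups or switch to
pup-directed aggression; the switch probability depends on oestrous stage,
and MPOA population activity enters a persistent "aggressive state" at the
first attack. The package implements the desk-scale statistical machinery of
that study: ethogram analysis, cohort switching statistics, photometry
conditioning, single-neuron tuning/selectivity, and population-state
segmentation and decoding — each validated against synthetic data with
planted ground truth.

## Behaviour

An ethogram is a list of labelled bouts `(behaviour, onset_s, offset_s)`
from a fixed vocabulary. A session is classified **aggressive** if it
contains at least one aggressive-contact bout; otherwise **parental** if it
contains retrieval, crouching or in-nest time; otherwise **ignoring**.
Total parenting time sums grooming, retrieval and in-nest durations.
Transition matrices count ordered pairs of consecutive bout labels
(self-transitions included) and are row-normalized over realized rows.
Cumulative incidence of attack is a right-continuous step function of first
attack latencies, with non-attackers censored at the assay end.

## Switching statistics

Stage-wise switching probabilities are `P(M) = 0.70` and `P(O) = 0.32`; the
prooestrus/diestrus value is not published separately, so the package
defaults to 0.62 for both, chosen so that the frequency-weighted mean over
the default stage composition (30, 19, 40, 37 of 126 animals for P, O, M, D)
reproduces a ≈60% overall switching rate. Both values are parameters of
`StageModel` and can be overridden.

The number of switchers in a cohort of heterogeneous animals is
Poisson-binomial; its PMF is computed exactly with the O(n²) convolution
recurrence (validated against exhaustive 2ⁿ enumeration). The observed count
is tested against an equal-tail interval on the count scale: the interval
is `[smallest k with CDF(k) ≥ α/2, smallest k with CDF(k) ≥ 1 − α/2]` at
level `1 − α` (default 0.99). Note that at extreme levels an outcome whose
point probability is below α/2 is legitimately outside the interval. Exact
two-sided binomial tests use the minimum-likelihood method. Logistic fits of
switching against covariates report McFadden pseudo-R² and flag perfect
separation instead of silently returning unstable coefficients.

## Photometry

The 415 nm (isosbestic) and 470 nm (activity) channels arrive as one
strictly alternating sample stream at twice the per-channel rate (20 Hz per
channel by default). Processing chain:

1. **Demux** — split by channel, pairing nearest samples; validated strict
   alternation.
2. **Isosbestic correction** — whole-session affine least-squares fit of the
   isosbestic onto the activity channel, subtracted; removes shared motion
   and bleaching.
3. **Moving-minimum detrend** — subtract a sliding 20 s window minimum
   (centred by default; a trailing variant is available). Implemented with
   `scipy.ndimage.minimum_filter1d`; edge windows shrink to the available
   samples.
4. **ΔF/F** — `(F − F_mean)/F_mean` followed by min–max scaling to [0, 1].
   Because the regression in step 2 zeroes the residual mean, the full chain
   uses the raw 470 nm session mean as the denominator (a brightness scale),
   while the numerator subtracts the detrended trace's own mean. A pure
   bleach-only recording therefore yields |ΔF/F| ≈ 0 rather than amplified
   numerical noise; this is tested.

## Single-neuron metrics

Peri-event windows are behaviour-specific: ±2 s for pup sniffing and
attacks, ±4 s for grooming, ±5 s for male-intruder and ±3 s for
female-intruder investigation. For chemoinvestigation behaviours the
analysed bout is the first with an uncontaminated pre-onset baseline;
grooming and aggression take the first bout regardless, since they occur
inside behavioural sequences.

- **Z-scores** are computed against the pre-onset baseline mean and s.d.
  per neuron; zero-s.d. neurons are flagged and excluded.
- **Tuning index** = |t| of a Welch unpaired t-test between per-frame ΔF/F
  in the activity and baseline windows; neurons are classed
  increased/decreased at p < 0.05, else unchanged. *Caveat:* frames are
  treated as independent observations, as in the source analysis; calcium
  autocorrelation inflates the nominal |t|, so the index should be read as
  a relative ranking, not a calibrated test statistic. The planted-effect
  benchmark only relies on monotonicity, which holds.
- **Selectivity index** = 1 − AUC = Mann-Whitney U / (n₁·n₂) with midrank
  tie handling, oriented so complete preference for the first behaviour
  scores 1, identical distributions 0.5, complete aversion 0.
- **Distribution diagnostic**: a population of selectivity indices centred
  at 0.5 (one-sample t, p ≥ 0.05) with low skew indicates persistent state
  encoding shared across the population; a skewed distribution (|skew| >
  0.5) indicates transient responses carried by a discrete tuned subset.

## Population state

- **PCA** standardizes each neuron and eigendecomposes the covariance
  matrix; a session is "usable" when the first two PCs explain ≥ 70% of
  variance. Episode distance is the Euclidean norm of the difference of two
  equal-shape episodes after projection onto the smallest k components
  reaching 90% cumulative variance (k = 2 available as a preset; a summed
  per-timepoint variant is provided because the source describes both).
- **HMM**: Gaussian emissions with diagonal covariance, k-means
  initialization, EM for up to 50 iterations (tol 1e-6). The state count K*
  is the knee of the final per-frame log-likelihood over a candidate range:
  the interior K with the most negative discrete second difference. The
  default range starts at K = 1 — the candidate range must bracket the true
  count from below, otherwise a knee at the true K is invisible and EM
  splits genuine states into alternating sub-states.
- **Alignment and detection**: each behaviour maps to the hidden state with
  the largest joint frame count (ties to the lower index); an episode is
  detected when ≥ 50% of its frames carry the aligned state.
- **Decoding**: episodes (> 2 s) are split at the episode level
  (stratified, 25% test) so no episode contributes frames to both sides;
  minority classes are oversampled on the training side with SMOTE-style
  k-NN interpolation (k = min(5, n − 1); implemented in-package); the
  classifier is a linear-kernel SVM. Confusion counts are summed over 50
  split iterations and row-normalized to percentages.

## Synthetic generators

Ethograms are homogeneous Poisson bout processes per behaviour with
exponential durations (floored at 0.2 s) and greedy overlap removal; the
aggressive phenotype plants its first attack at a configurable latency
(point mass 120 s by default) exactly. The published 2.1 s mean sniffing
bout is used; other rates/durations are package choices. Calcium traces are
baseline + exponential-decay kernels (τ = 1.5 s) at bout onsets scaled by
per-neuron effects + an optional persistent state shift from the first
aggression onset + i.i.d. Gaussian noise. Photometry is a shared
exponential bleach and AR(1) motion on both channels with calcium
transients on the 470 nm channel only. All generators are pure functions of
their parameters and seed and return ground-truth sidecars.

Limits: no bout-duration autocorrelation, no within-session drift of bout
rates, i.i.d. trace noise (no shared low-rank noise beyond the planted
state), and Markovian state structure by construction. These are adequate
for validating the analysis chain, not for simulating realistic biology.

## Benchmarks

`pupstate.benchmarks.aggression_state_benchmark` generates five sessions
(50 neurons, 20 Hz, 10 min, noise s.d. 1) with a planted −5 persistent
shift (5× noise) from the first attack, requires ≥ 5 aggression episodes of
≥ 2 s per session (ethograms are deterministically rejection-sampled on
this precondition only, before any model is fitted), selects K* over
K ∈ {1,…,6}, and scores episode detection. The reference seeds 1–5 give a
mean detection of 100%, and `scripts/acceptance.py` recomputes this plus
the three analytic selectivity anchors for any seed.

## Known limitations

- Per-frame t-tests ignore temporal autocorrelation (see above).
- The equal-tail Poisson-binomial interval is discrete; its realized
  coverage exceeds the nominal level.
- EM is a local optimizer: on planted 3-state data the knee rule recovers
  K* = 3 in 8/10 seeds with single-start fits; no restarts are performed.
- The P/D stage switching probability (0.62) is a package default, not a
  published value.
- HMM fits occasionally degenerate (a state losing support); a single
  reseeded retry is attempted and warned about.
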