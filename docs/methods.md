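# Methods

## Model and assumptions

The decoder treats each stimulus epoch as a feature vector x ∈ ℝᴰ drawn
from one of two class-conditional distributions (target / non-target) with
means μ₊, μ₋ and a shared covariance. Two assumptions carry the method:

* **IID within groups** — epochs of a proportion group are exchangeable
  draws; the group mean μ̂_g is then asymptotically normal with variance
  σ²/N_g per coordinate, so reconstructed class means converge at rate
  1/N (checked by the CLT-rate test).
* **Homogeneity** — the class-conditional distributions are identical
  across the two stimulus sequences. The paradigm works toward this by
  equalizing stimulus brightness (12 highlights per event, blanks as
  filler) and interleaving the two sequence types within each trial; the
  leave-one-out bootstrap (below) tests it on data.

Given the G×2 mixing matrix Π of per-group class proportions, class means
are the least-squares solution of Π[μ₊; μ₋] = [μ̂₁ … μ̂_G], computed
through an SVD pseudoinverse (identical to (ΠᵀΠ)⁻¹Πᵀ, better conditioned).
Π must have rank 2; the rank test compares the singular-value ratio
against 1e-10. The projection is w = Σ⁻¹(μ₊ − μ₋), solved with a
symmetric positive-definite solver rather than explicit inversion. Scores
carry no bias term: every selectable symbol is highlighted equally often
per trial (16×), so a bias cancels out of the per-symbol score sums.

The noise amplification factor NAF = G·Σ_c,k ν²_ck compares the summed
per-coordinate variance of the two reconstructed class means against the
variance σ²/N of a plain N-sample average — the normalization used in the
variance-calibration test, which reproduces NAF within a few percent under
IID Gaussian features.

## Covariance estimation

Both decoders use the analytic Ledoit–Wolf shrinkage estimator
(1−γ)S + γνI with ν the mean diagonal of S (sklearn's implementation).
The LLP decoder pools over *all* epochs regardless of class (it has no
labels); the supervised baseline pools within-class residuals, weighted by
class counts by default (`pooling="unweighted"` averages the two class
covariances instead). Degenerate case: with fewer than two effective
samples after centering (N = 2), the analytic intensity estimator is
identically zero and would return a singular rank-1 matrix; the estimator
then falls back to the scaled-identity target (γ = 1). Note that γ → 1 is
also the *correct* large-sample behaviour for isotropic data, where the
shrinkage target coincides with the truth.

## Stimulus scheduling

Blocks are generated by randomized constructive assignment: events take
the required number of symbols among those with remaining quota that did
not appear in the previous event, preferring the highest remaining quota
(random tie-break), with restarts on dead ends (capped at 10 000).
Sequence-2 events are padded to 12 highlights with blanks whose total
quota (152 slots) is spread as evenly as possible.

Double-flash avoidance applies to **selectable symbols only**, within
blocks and across block boundaries. It cannot apply to blanks: 152 blank
slots shared by 10 blanks across 18 events force consecutive repeats
(no-consecutive would cap each blank at 9 appearances, 90 in total).
Since blanks are never attended, a repeated blank cannot produce the
attention-related error the rule prevents. A user-supplied pairwise
conflict predicate can add adjacency-style constraints; no spatial
adjacency rule is built in.

Trials interleave 4 sequence-1 and 2 sequence-2 blocks in random
whole-block order by default. `interleave="event"` instead merges the six
block streams event-by-event under the same double-flash constraint,
preserving within-block order — genuinely uniform event shuffles are
infeasible because two sequence-1 events from different blocks almost
surely share a symbol.

Symbol indices are 0-based and row-major; blanks occupy the last 10 grid
positions. The study sentence preset appends a trailing "." to the
62-character pangram to give 63 trials per sentence.

## Signal processing

* Band pass 0.5–8 Hz, Chebyshev type II of order 3, 40 dB stopband
  attenuation. Chebyshev II designs are specified by stopband edges;
  these are placed one octave outside the nominal band (0.25 and 16 Hz)
  so that the printed band is an actual passband (gain ≈ 0.98 at 4 Hz;
  an order-3 design with stopband edges *at* the band would attenuate
  most of it). Filtering is causal (online-compatible) by default;
  `zero_phase=True` applies forward–backward filtering.
* Decimation 1000 → 100 Hz by integer subsampling after filtering; the
  8 Hz band edge makes the band pass the anti-alias stage.
* Epochs span [−200, 700) ms (half-open in samples, 90 samples at
  100 Hz); baseline correction subtracts each channel's mean over
  [−200, 0) ms and is idempotent.
* Interval means over [50,120], [121,200], [201,280], [281,380],
  [381,530], [531,700] ms. Millisecond bounds map to samples through one
  shared truncation-toward-zero utility; interval membership is inclusive
  and clipped to the window, so the six intervals tile [50, 700) without
  overlap at 100 Hz. Feature order is channel-major; the default montage
  (31 channels minus Fp1/Fp2) gives 29 × 6 = 174 features.
* Peak statistics take the extremum of a class-averaged waveform in a
  search interval; latency ties break earliest.

## Synthetic data

The generator emulates the structure of the visual-speller study at two
levels.

**Continuous level.** Target epochs evoke a two-component template:
occipital trough −8 µV at 150 ms (Gaussian, σ = 25 ms; weights 1.0 on
O1/O2, 0.6 on PO channels) and central bump +2 µV at 400 ms (σ = 60 ms;
1.0 on Cz, 0.5–0.7 on neighbours). Non-targets evoke nothing. Background
noise is AR(1) with ρ = 0.95 at 1 kHz and unit marginal variance (white
noise optional). `snr` is the template peak amplitude in units of the
noise standard deviation; onsets follow the 250 ms SOA with an 8 s
inter-trial gap (4 s cue + 4 s feedback).

**Feature level.** Epochs are Gaussian with identity covariance;
`feature_space_model` rescales the template-derived feature difference to
a Mahalanobis separation `snr`, so the Bayes-optimal AUC is Φ(snr/2). The
default separation is 2·Φ⁻¹(0.975) ≈ 3.92, calibrated so the synthetic
Bayes ceiling equals the 97.5% supervised AUC measured on the data the
generator emulates. Exact-count sampling (16 targets per 68-event trial,
3/2 per block) mirrors the paradigm; Bernoulli sampling serves the IID
theory tests.

**What this does not emulate:** volume conduction and realistic spatial
covariance across the 174 features (identity is used), non-stationarity
across a session, eye artifacts, and ERP modulation by target-to-target
interval. Synthetic decoding is therefore easier than real EEG — passing
tests demonstrate the *algorithms'* properties (convergence, variance
law, orderings, calibration), not real-world spelling accuracy.

## Evaluation procedures

* **Online simulation** retrains the LLP decoder after every character on
  all epochs observed so far (including the current trial's, matching
  end-of-trial retraining; a flag defers them) and selects the symbol
  with the largest score sum, blanks excluded, ties to the lowest index.
  Post-hoc re-analysis re-decides every trial with the sentence-final
  model. The AUC trajectory is computed on the training epochs seen so
  far, using labels for evaluation only.
* **Learning curves** take chronological prefixes, distribute epochs into
  proportion groups per mixing matrix — group sizes are solved from the
  data's class totals by non-negative least squares (with a weak ridge
  toward equal sizes when G > 2), since a mixing is only realizable if
  its aggregate target fraction brackets the data's — and evaluate by
  5-fold chronological cross-validation with contiguous folds. The
  supervised baseline trains on 4/5 folds; the unsupervised LLP model
  trains on all assigned epochs and is scored per fold.
* **Homogeneity bootstrap**: for each epoch of one class in group 1,
  the squared L2 distance to the leave-one-out class average of group 1
  and to the class average of group 2; a two-sided paired t-test on the
  distance differences, per class (paired because each epoch yields both
  distances; a Welch two-sample variant is available). On preprocessed
  epochs the distance uses all channels over [0, 700] ms; the test
  operates on any flattened representation. Callers apply Bonferroni
  correction (the study divided α by its 13 subjects).
* **Mixing presets** PI1–PI4 stand in for the four matrices of the
  ranking experiment, which are not fully specified; they honour the
  printed row [2/10, 8/10], the relation "dropping that row from PI3
  gives PI2", and ascending NAF (14.1, 38.3, 55.9, 252). PI4's window of
  realizable aggregate target fractions [0.2, 0.3] brackets the
  paradigm's 16/68.

## Problem sizes and numerical conventions

The statistical test suite runs at desk scale, chosen once: CLT rate with
200 replicates × N ∈ {250 … 4000} (D = 4); NAF calibration with 2000
replicates at N = 400 for three presets (tolerance 15%); NAF ordering
with 20 seeds × 4 sizes up to 4860 epochs at the full D = 174; paradigm
invariants over 1000 seeded trials; homogeneity calibration with 1000
null datasets of 500 epochs/class/group at D = 174 and power with 200
datasets at 200 epochs/class/group; online ramp-up with 20 seeds × 63
characters. Random streams derive from per-component child seeds
(CRC32-tagged SeedSequence) so one seed controls a whole run.

## Known limitations

* The mean-map variant with manifold regularization (more robust under
  homogeneity violations) is not implemented; `homogeneity_violation`
  exists to study the failure mode instead.
* The EM-based unsupervised comparison decoder is out of scope; any
  object with a `decision_function` can be slotted into the harness.
* The paired t-test of the bootstrap ignores the weak dependence induced
  by the shared group-2 average; at study-scale dimensionality its size
  is nominal (the calibration test), but in very low dimensions (D ≲ 10)
  it becomes mildly anticonservative.
* Group aggregation is the plain arithmetic mean; no robust or weighted
  variants.
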