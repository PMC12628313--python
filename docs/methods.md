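# Methods

`rpsdecode` implements a complete analysis chain for dyadic
Rock–Paper–Scissors (RPS) sessions with simultaneous EEG: behavioral
description of each player's strategy, time-resolved multivariate decoding
of game information from the neural signal, and group-level Bayesian
inference. Because the package ships no human recordings, a first-class
synthetic generator produces behavior and EEG with controllable structure;
every stage is specified and tested against that generator.

## Game and session model

A session is 480 games in 12 blocks of 40. Each game runs through three
screens: *Decision* (2 s), *Response* (2 s) and *Feedback* (1 s), and the
analysis treats each screen as a separate epoch locked to its onset.
Outcomes follow the cyclic dominance rule (rock > scissors > paper > rock);
identical responses draw. A player who times out loses to one who responds;
two simultaneous timeouts are scored as a draw — the rule set does not
cover this case, and a draw is the only symmetric choice. The *overall
match winner* is the player with strictly more wins across the session; a
session with an exact win-count tie has no winner/loser roles and is
excluded from group splits (no tie-break is defined).

Sessions serialize to UTF-8 tab-separated `events.tsv` tables (columns
`pair_id, block, trial, response_p1, response_p2, outcome`) with responses
written as `rock|paper|scissors|none`. The reader re-derives each outcome
from the responses and rejects contradictory rows by row number.

## Behavior generator

Each simulated player draws its response from a two-component mixture:

* with probability `1 − memory_mix`, an independent draw from `base_rates`
  (a probability triple over rock/paper/scissors);
* with probability `memory_mix`, an outcome-contingent rule: repeat the
  previous response with probability `stay_prob_by_outcome[o]` where `o` is
  the previous game's outcome for this player, otherwise shift along the
  dominance cycle, choosing up vs. down by `shift_direction_bias`
  (renormalized over its two shift components; its `stay` slot exists for
  configuration symmetry and is inert once the stay decision has been
  made).

The first game of a session is always a base-rate draw, and a timeout
occurs independently per game with probability `no_response_prob`. This
small family spans the strategies human players actually exhibit —
over-selection of one option (typically rock), win-stay/lose-shift, and
cycling — while remaining exactly recoverable from simulated output
(stay probabilities and marginal rates are checked by parameter-recovery
tests).

Defaults describe a mildly biased, moderately sequential player:
`base_rates = (0.40, 0.33, 0.27)` (rock bias of the size reported in
behavioral RPS studies), stay probabilities `{win: 0.30, lose: 0.22,
draw: 0.27}` — all below the 1/3 chance rate, matching the empirical bias
toward switching — `memory_mix = 0.5`, and `no_response_prob = 0.005`
(timeouts are rare in practice but their handling must be exercised; no
empirical rate is available). `PlayerPolicy.uniform()` gives the i.i.d.
uniform (optimal) player used for chance calibration.

## EEG generator

Per participant, phase and game, the generator emits an epoch of
`n_channels × samples` covering −200 ms to the phase end at `fs_hz`
(defaults: 64 channels laid out on the standard BioSemi/10-20 montage,
256 Hz). Each epoch is zero-mean Gaussian noise with unit channel variance
and exponential spatial correlation (`corr = noise_spatial_corr` at 0.2
normalized inter-electrode units; Matérn-1/2 kernel, so any correlation
level in [0, 1) yields a valid covariance). Noise is white in time: the
analysis applies no temporal filter, so temporal color would not change
what the tests can show.

Class-dependent signal is injected per *label stream* — own response,
opponent's response, and both players' previous-game responses. For each
stream, three fixed unit-norm channel patterns (one per class) are drawn
once per seed; the 12 vectors are orthonormalized so concurrently
scheduled streams are separably decodable and never alias into each other.
A `signal_schedule` maps (stream, phase) to an amplitude; the injected
signal is `amplitude · snr · pattern`, zero before phase onset and ramped
in with a 100 ms raised-cosine (any smooth envelope would do; this one is
fixed and differentiable at the boundaries). `snr` is therefore the
channel-space norm of a unit-amplitude class signal relative to the noise
SD. Trials whose stream label is undefined (first game for previous-trial
streams; timeouts) receive no contribution from that stream.

What the generator does **not** emulate: volume-conducted ERP morphology,
eye/muscle artifacts, temporally autocorrelated background rhythms,
inter-subject pattern variability, or any motor confound (the simulated
signal encodes the response class, never a button position — mirroring the
design's button-remapping control). Passing tests therefore demonstrate
that the analysis recovers exactly the information structure it assumes,
at realistic SNR — not that it is robust to real-world artifacts.

`make_group` assigns one EEG configuration to each pair's match winner and
another to the loser, which is how the winner/loser dissociation (e.g.
previous-trial information present only in losers) is instantiated. It
yields pairs lazily: a full-scale participant is ~0.4 GB of epochs, so
cohorts are reduced to binned features one participant at a time.

## Behavioral statistics

* **Outcome distribution** — proportions of (winner wins, winner loses,
  draw); 1/3 each for random play.
* **Response bias** — frequencies of the most/mid/least chosen responses
  (timeouts excluded); rank ties are broken rock < paper < scissors and
  flagged.
* **Switch rates** — probability that consecutive responses differ, split
  by the previous game's outcome; pairs containing a timeout are excluded;
  an empty stratum reports NaN rather than 0. Chance for a uniform player
  is 2/3.
* **Markov predictability** — for each window size w in 5..100: estimate
  first-order transition counts from the previous w games, predict the
  next response as the argmax of the row conditioned on the last response,
  score against the actual response, and average over all eligible games
  (every game t > w; block boundaries are ignored — nothing in the design
  resets strategy between blocks). Timeout games are removed from the
  sequence before analysis. Argmax ties fall back to the higher
  within-window marginal frequency, then to the fixed symbol order; an
  unseen context (all-zero transition row) degrades to the window-marginal
  argmax through the same rule. The implementation is a vectorized
  sliding-count computation and is regression-tested against a naive
  per-game transition-table oracle.

## Preprocessing

Epochs pass through: common-average reference → bad-channel interpolation
(unweighted mean of good channels within 0.5 normalized units; an
unrepairable channel is an error, and spline weighting is deliberately not
reproduced) → integer-factor downsampling → baseline correction (−200..0
ms) → 250 ms binning. Binning uses half-open `[start, start+250)` windows
from phase onset, so the onset sample belongs to bin 1 and baseline
samples contribute to no bin; the three phases concatenate to
8 + 8 + 4 = 20 bins covering the 0–5000 ms game time-course.

Downsampling defaults to block-mean decimation: no temporal filtering is
applied anywhere in the chain (filtering can smear information across time
bins), and a block mean is the same kind of averaging the 250 ms binning
performs while slightly suppressing aliasing. Naive take-every-kth
decimation is available as `method="naive"`; the choice cannot affect any
binned quantity at the tested rates. Numerical equality in the tests is
asserted at 1e-10 relative.

## Decoding

For each label stream: timeout trials (and the first game, for
previous-trial streams) are removed; trials are split into 10
class-stratified folds (seeded); within each fold and class, 20
pseudo-trials are formed, each the average of 4 distinct trials drawn
uniformly without replacement *within* a pseudo-trial and with replacement
*across* pseudo-trials. The stated counts (20 × 4 = 80 per fold-class)
exceed the ~16 trials a 480-game session yields per fold-class, so
disjoint groups are impossible and resampling is the only consistent
reading; pools smaller than 4 resample with replacement and warn.

Classification uses linear discriminant analysis with trace-normalized
shrinkage: `Σ_reg = (1 − λ)Σ + λ(tr Σ/p)I`, λ = 0.01, equal class priors,
assignment by maximal linear discriminant score. Both training (9 folds)
and testing (left-out fold) use pseudo-trials. Accuracy per time bin is
balanced accuracy — the mean of per-class recalls, which equals plain
accuracy here because pseudo-trial counts are balanced by construction —
with chance at 1/3. The in-house LDA is verified against explicit matrix
formulas at 1e-8 and against scikit-learn's `lsqr + shrinkage` LDA, which
implements the identical covariance model.

The channel searchlight repeats the full analysis on each channel plus its
k = 5 nearest neighbors (the 5th dropped beyond 0.5 normalized units, so
clusters hold 4–5 neighbors), then collapses the 20 bins into five 1-s
windows by averaging — one topography per window.

## Group statistics

Per time bin, one-sample evidence against chance uses a directional
interval-null Bayes factor: a Cauchy(0, r = √2/2) prior on Cohen's d,
truncated to the alternative region d > 0.5 versus the null region
0 ≤ d ≤ 0.5. Excluding (0, 0.5) from the alternative means small effects
count as evidence *for* the null; negative effects are excluded by the
directional truncation at 0. The Bayes factor is the ratio of the
noncentral-t likelihood of the observed t statistic averaged over each
truncated prior, computed by adaptive quadrature (tolerance 1e-8) and
validated against seeded Monte-Carlo integration with 10⁶ truncated-prior
draws (5% relative on a grid of t and n values). r = √2/2 is the
convention of the standard Bayes-factor t-test implementations.

The winner–loser comparison is a two-tailed JZS test (untruncated Cauchy
prior vs. the point null) on the paired within-dyad differences — pairing
respects the dyadic design, in which each pair contributes exactly one
winner and one loser; an independent-samples reading is also defensible
but discards that structure. The implementation agrees with pingouin's
JZS Bayes factor to ~1e-3 relative.

Evidence labels (anecdotal / moderate / strong at BF 3 and 10) are
reporting sugar only.

## Problem sizes and determinism

Cohort-level checks run at desk scale, chosen to keep sampling error well
inside the asserted tolerances: chance calibration uses 20 signal-free
participants at the full design (480 games, 64 channels, 256 Hz);
behavioral chance rates use 100 sessions (200 players); signal-recovery
checks use 8 participants at snr 0.5; the winner/loser dissociation uses a
16-pair cohort (vs. 31 pairs in a full study). All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
seeds reproduce sessions, epochs, fold assignments and pseudo-trials
bit-identically.

## Known limitations

* The synthetic EEG validates information recovery, not artifact
  robustness (see the generator's non-goals above).
* Epoching from continuous recordings, artifact rejection and ICA are out
  of scope; the generator emits phase-locked epochs directly.
* The Markov predictor is first-order by design; higher-order sequence
  structure in the simulated players (none is generated) would be
  invisible to it.
* The interval-null Bayes factor follows the truncated-Cauchy JZS
  construction; it is validated against its own Monte-Carlo oracle, not
  against an external implementation of the interval-null method.
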