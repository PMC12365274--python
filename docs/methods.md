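# Methods

This note documents the models, parameter choices and numerical decisions
behind `gazeshift`, in the order data flow through the pipeline.

## Coordinate and timing conventions

Pixel space uses the display convention (origin top-left, y down); degree
space is centred on the screen with **y up**, so "upward saccade" means a
positive vertical component. Conversion is per-axis `atan(offset_cm /
viewing_distance_cm)` with separate cm/px scales for x and y (the two
study monitors have different pixel pitches; square pixels are not
assumed). The inverse mapping round-trips to <1e-6 px, and below 5° the
arctangent differs from the small-angle linear form by <1 %. All
timestamps are milliseconds relative to stimulus onset, because every
analysis window (baseline [−300, 0), blink window [−300, 150], first-saccade
window [150, 1000]) is onset-relative.

## Trial scheduler

Designs are balanced factorials: emotion × orientation × presentation time
× initial fixation, `trials_per_cell` each. Stimulus identifiers are
synthetic, unique within participant, and sex-balanced within each cell
(half female, half male), mirroring how face images were assigned in the
studies. Sequencing draws uniform shuffles and rejects any with more than
`max_run_length = 3` consecutive same-emotion trials (up to 10 000 draws,
then a greedy constrained-insertion fallback); a closed-form feasibility
check (`max_count ≤ cap × (others + 1)`) rejects impossible specs up
front. The run cap is enforced on the whole within-participant sequence,
which implies it within every block cut from it. Everything is
deterministic per `(spec, seed)`.

## Synthetic gaze generator

The generator is first-class, tested code: its role is to produce sessions
whose *ground truth is known exactly*, so the detector, validation rules
and statistics can be checked by parameter recovery.

* **Fixational noise** is white Gaussian noise filtered with a Gaussian
  kernel (σ = 50 ms) and rescaled analytically to a stationary SD of
  0.3° (default). Filtering matters: fixational drift is slow, and white
  noise of the same amplitude would produce sample-to-sample velocities in
  the hundreds of °/s, swamping any velocity-threshold detector. With the
  smooth model, velocity noise stays well below the 30°/s criterion.
* **Saccades**: at most one injected "first saccade" per trial (the
  analysis only ever uses first saccades). The cell's probability of a
  toward-saccade comes from the truth table; opposite-direction saccades
  occur at 0.65 % by default, matching how rare they were in the recorded
  data. The position profile is a normalized logistic ramp (z spanning ±4
  over the duration), giving a smooth, unimodal velocity peak and exactly
  zero displacement outside [onset, onset+duration]. Durations follow a
  main-sequence-like rule, 21 ms + 2.2 ms/° plus up to 4 ms jitter,
  clipped to 30–60 ms: coupling duration to amplitude is the standard
  kinematic regularity and keeps threshold-crossing latency small for all
  amplitudes. Amplitudes are Gaussian (mean 4°, SD 1°) truncated at 1.5°,
  with the vertical component floored at 1.2° so an injected saccade always
  clears the 1° classification criterion; latencies are lognormal (median
  280 ms, σ = 0.35) truncated to (160, 920) ms so every injected onset lies
  strictly inside the analysis window and after face offset.
* **Blinks** (5 % of trials) are ≥50 ms runs of invalid samples placed to
  overlap the exclusion window; **baseline drift outliers** (3 %) add a
  whole-trial offset of 5–12 × the fixational SD in a random direction.
  Together with occasional false flags of the recursion these defaults
  yield ≈ 8–10 % excluded trials, the range reported for the recorded
  sessions.
* **Responses** are drawn from a row-stochastic 3×3 confusion matrix
  (default diagonal 0.94), response times from a lognormal (median 600 ms).

What the generator does **not** emulate: pursuit, microsaccades,
glissades/PSOs, calibration drift within blocks, head movement, and any
dependence of saccade kinematics or confusion structure on condition beyond
the truth table. Passing recovery tests therefore shows the pipeline is
correct *given* threshold-detectable saccades and honest labels; it cannot
certify behaviour on pathologies the generator does not produce.

## Event detection

Velocity is a Savitzky–Golay first derivative (order-2 polynomial over 5
samples) applied per contiguous run of valid samples, in degree space;
acceleration is the forward difference of speed. Half-window edges and
invalid runs are NaN. A sample is saccadic when speed > 30°/s **or**
|acceleration| ≥ 8 000°/s²; maximal saccadic runs closer than 20 ms are
merged, runs shorter than 4 ms dropped, and runs overlapping a blink
(invalid run padded by 50 ms each side) discarded. The two thresholds are
the published criteria; the differentiator, window, merge gap and minimum
duration are this package's declared choices, pinned by tests (no claim of
equivalence with any vendor parser). On default simulator settings the
detector reaches ≥99 % recall with ≤6 ms onset error and ≤1 % false alarms.

## Validation rules

The recursive outlier rule is implemented exactly as specified for the
baseline coordinates of each block, separately for x and y: one instance
each of the current min and max is set aside, mean and sample SD (n−1) are
computed from the rest, and an extreme is permanently flagged (with all
tied duplicates) when it deviates by more than 3 SD. Iteration stops when
nothing new is flagged, fewer than 3 values remain unflagged, or fewer than
2 values would remain to compute an SD. Two subtle choices are pinned by an
independently coded brute-force oracle: min and max are evaluated *jointly*
within an iteration, and ties are flagged together. Trials whose baseline
window contains no valid sample are treated as blink-contaminated. The 70 %
participant cutoff is strict (<0.70) and computed over all of a
participant's trials, not per block.

## Classification and aggregation

Direction uses the endpoint-to-endpoint vertical displacement of the
detected event (not peak excursion), consistent with endpoint-based
analysis; saccades that land short still count by direction, because in the
recorded data most toward-saccades undershot the peripheral feature. A
pre-window saccade (onset <150 ms) neither qualifies nor blocks a later
qualifying one; a configurable window makes the 50–150 ms sensitivity
variant available. Cells with zero valid trials propagate as missing (never
as 0) and abort the ANOVA with an explicit cell list — silently imputing
would fabricate data. The six-location design collapses to
left/middle/right via {left_eye, left_cheek}, {glabella, mouth_center},
{right_eye, right_cheek} for posthoc families.

## Statistics

The ANOVA operates on the n × K subject-by-cell matrix. Each effect is the
Kronecker product of orthonormal Helmert contrasts (involved factors) and
normalized mean vectors (uninvolved factors); SS_effect = n‖mean‖²,
SS_error the residual sum of squares of the projected scores, df₁ = ∏(kᶠ−1),
df₂ = (n−1)df₁. Greenhouse–Geisser ε̂ = tr(Σ)²/(df₁·tr(Σ²)) from the sample
covariance of the projected scores, clipped to [1/df₁, 1]; the corrected p
uses an F distribution with both dfs scaled by ε̂. Because the contrasts
are orthonormal, the between-subject stratum plus all effect/error pairs
tile the total SS exactly (tested to 1e-9 relative). Only the GG correction
is offered (no Huynh–Feldt). A caveat worth knowing: for F < 1 the
GG-corrected p can be *smaller* than the uncorrected p — df shrinkage
raises p only above F ≈ 1; reference implementations behave identically.

Cohen's d for paired posthocs uses the SD of the differences (the paired-t
denominator). All-zero difference vectors report t = 0, d = 0, p = 1;
zero-variance nonzero differences are flagged degenerate rather than given
an infinite t. Holm adjustment is the standard step-down maximum, applied
within one declared comparison family at a time.

Power is estimated by Monte Carlo: multivariate-normal sessions from
per-cell means/SDs and a compound or explicit correlation matrix, the
GG-corrected test applied to each, and the rejection fraction reported with
a binomial CI. Under a null spec the estimate sits at α (a built-in type-I
calibration check).

Calibration of the whole proportion analysis uses null sessions generated
at the behavioural level: each simulated participant gets a Beta(3, 17)
switching propensity (mean 0.15, about the observed toward rate) applied
identically to all cells, binomial counts over 12 trials per cell, 20
participants, 1 000 replicates. The type-I rate of the GG-corrected emotion
effect falls in [0.035, 0.065]. Sample-level gaze simulation is reserved for
the recovery checks (60 participants, 3 × 2 cells, 8 trials/cell), where
per-cell mean proportions recover injected probabilities of 0.05/0.15/0.30
within 3 binomial SEs.

## Known limitations

* The detector is not a replica of any commercial parser; only the two
  thresholds are shared, so event-level agreement with vendor output on
  real recordings is not claimed.
* Degree conversion treats the screen as locally flat per axis
  (arctangent of each offset independently); for the <20° extents involved
  the error is negligible.
* The behavioural layer drops unanswered trials (counted in the log) and,
  by default, applies the same validity mask as the gaze analysis; a switch
  (`respect_validity=False`) computes hit rates over all responded trials.
* Between-subject factors, mixed models and Bayesian variants are out of
  scope; the ANOVA requires complete balanced data by design.
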