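# Methods notes

This note documents the models, conventions, and design choices behind
`graspsupp`, in the spirit of a package's statistical documentation: what is
computed, under which assumptions, with which defaults, and what the synthetic
data do and do not establish.

## Trial-sequence construction

**Probe grid.** Six vibrotactile intensities, peak-to-peak displacement 9.4 µm to
56.7 µm, equally spaced, plus a 0-µm catch level.  The grid is defined by its two
endpoints and the number of levels; the step (≈ 9.46 µm) is derived.  (A fixed
9.4-µm step from 9.4 µm would end at 56.4 µm, which contradicts the printed upper
endpoint; defining by endpoints honors both printed values.)

**Experiment 1 grasping block.**  The mass-distribution (MD) sequence must make
every ordered pair of consecutive MDs — LL, RL, LR, RR — occur exactly 45 times
over 180 classified trials, each combination receiving 30 stimulated trials
(5 per intensity) and 15 catch trials, with 90 trials per object position.  180
trials yield only 179 pairs, so the generator prepends one flagged *lead-in*
trial, excluded from all analyses but serving as the first predecessor; this
makes exactly 180 classifiable pairs.  The MD sequence is built from alternating
runs: with the first and last runs the same letter there are 46 runs of one
letter (91 trials) and 45 of the other (90), giving exactly 45 within-letter
repeats each and 45 transitions each way.  Run lengths are randomized by a
multinomial split of the surplus trials and rejected until no MD run exceeds 5.
"No apparent regularity" is operationalized as bounded runs: probe intensities
are rejection-sampled until no intensity (catch included) repeats more than 3
times in a row, with a 10 000-try cap that raises a `GenerationError` rather than
returning a constraint-violating sequence.

**Experiment 2.**  216 trials alternating six 9-trial mixed parts and six
27-trial constant parts, always starting mixed; constant parts alternate MD
starting with the `first_constant_md` argument (three left, three right).
Counterbalancing is an explicit argument (as is the practice block's 5/4 position
split), never hidden randomness.  Object position varies within constant parts.

**Rest (baseline) blocks.**  45 trials: each intensity five times plus 15 catch,
pseudorandom under the same run cap.  Two blocks bracket the grasping block.

Same seed ⇒ byte-identical sequence; all randomness flows through one
`numpy.random.Generator`.

## Synthetic data generator

The generator produces what the analysis consumes: five marker trajectories
(thumb, index, three object markers; x lateral +right, y anterior, z vertical
+up, cm, 100 Hz) and yes/no responses.  It is a *phenomenological* emulation of
the recording conditions, not a biomechanical simulation:

* **Transport** — minimum-jerk path of the digit-pair centroid over 34 cm
  (default duration 0.8 s).  Minimum jerk is smooth, standard, and analytically
  differentiable, which lets ground-truth event times be defined exactly.
* **Loading dwell** — the hand speed stays below the 10 cm/s event threshold for
  the policy's condition-specific loading time (defaults: 300 ms after a repeated
  MD, 250 ms after a change, matching the observed direction that loading is
  longer for repeats; optional Gaussian jitter, default 40 ms SD in the pipeline
  configuration).  Ground-truth contact/lift times are the *analytic threshold
  crossings* of the noise-free speed profiles — exactly the quantities the event
  detector estimates — so the ±1-sample round-trip guarantee is well defined.
* **Grasp policy** — vertical thumb−index separation at contact is +s when the
  policy anticipates a left mass (thumb higher) and −s for a right mass, plus
  Gaussian noise (defaults s = 0.8 cm, noise 0.08 cm in the pipeline).  Rules:
  `predictive` (anticipate the previous MD), `anti_predictive`, `random`.
* **Lift and roll** — the object (and digits) rise 10 cm with a minimum-jerk
  profile (0.4 s); the object-marker edge rolls in the frontal plane with a
  smoothstep ramp (200 ms) to `roll_gain × |lateral mass-offset mismatch|`
  degrees (0 when the anticipated and actual MD agree; 9° for a full L↔R
  mismatch at the default 1 °/cm gain and ±4.5 cm tube offsets), plus optional
  half-normal trial-to-trial noise.  Roll is a ramp, not rigid-body dynamics,
  because only the maximal absolute tilt within 250 ms is analyzed.
* **Observer** — yes/no responses are Bernoulli draws from the same
  guess/lapse-scaled logistic that the fitting stage assumes, with a
  condition-specific threshold shift (default +10 µm in every movement
  condition, i.e. genuine suppression with no same/different difference).

What the generator does **not** emulate: tremor spectra, marker dropout and
occlusion, grip/load forces, drift in tactile sensitivity over a session, lapses
of attention correlated over time, or learning curves.  Passing round-trip and
recovery tests therefore certifies the *pipeline's* correctness under the
model's assumptions, not robustness to every pathology of real recordings.

## Kinematic analysis

* **Filtering.**  Speeds are computed by central differences of the marker
  centroid (one-sided at the endpoints), then dual-pass filtered (`filtfilt`,
  2nd-order low-pass Butterworth).  The protocol's cutoff is quoted as
  "0.3 Hz"; at 100 Hz an absolute 0.3 Hz cutoff would smear events over
  seconds, so the default interprets 0.3 as the normalized fraction of Nyquist
  (the MATLAB `butter` convention, 15 Hz effective).  An absolute-Hz mode is one
  config switch away.
* **Events.**  Lift onset: first sample with object speed strictly above
  10 cm/s.  Contact: the last *downward crossing* of the hand speed below
  10 cm/s before lift onset — i.e. the start of the final sub-threshold dwell.
  A literal "latest slow sample before lift" reading would collapse loading time
  to one sample whenever the hand is slow throughout loading; the crossing
  reading is the one consistent with a loading-time analysis, and the package
  falls back to the latest slow sample only when the hand never reached the
  threshold.  Ties exactly at 10 cm/s trigger neither event (strict
  comparisons).  Missing events are encoded as invalid results with reasons, not
  exceptions.
* **Measures.**  Digit separation: mean of z_thumb − z_index over the 100 ms
  from contact (window mean is the default; `window_ms=0` gives the
  instantaneous value).  Loading time: (lift − contact) in ms.  Object roll: the
  object-marker long edge's angle in the x–z plane, referenced to its own mean
  pre-lift orientation, maximal absolute value within 250 ms of lift; edges
  shorter than 1 cm in the frontal projection are rejected as degenerate.
* **Gaps.**  NaN runs up to 100 ms are linearly interpolated; longer gaps (or
  gaps touching the series ends) raise.  This is a placeholder policy; real
  recordings may need a stricter occlusion treatment.

## Pair classification and aggregates

Every grasping trial with a predecessor is labeled prev+curr; the lead-in trial
only serves as a predecessor.  Per participant, the separation indices are
mean(RR) − mean(LL) and mean(LR) − mean(RL); loading time and roll are averaged
per configuration.  Invalid trials are dropped listwise per variable with cell
counts retained.  In Experiment 2, part-boundary trials inherit their
predecessor across the boundary (no exception is stated for them); the
constant-part cell index uses the RR−LL contrast only (non-boundary constant
trials are all repeats), while the mixed-part cell averages the RR−LL and LR−RL
contrasts with equal weight — an interpretive choice, flagged as such, matching
the expectation that the mixed cell sits near zero under trial-by-trial
prediction.

## Psychometric fitting

Binomial ML over (γ, λ, m, w) with box constraints γ ∈ [0, 0.3], λ ∈ [0, 0.05]
(the lapse cap is standard practice to stabilize sparse fits and is
configurable), m ∈ (0, 2·x_max], w ∈ [span/50, 5·span]; five L-BFGS-B starts
from quantile heuristics; the convergence flag reports optimizer success
honestly.  All-yes, all-no, and perfectly separable step data raise a
`DegenerateFitError` instead of returning a silent extreme.  Constrained-ML psychometric toolboxes
(psignifit and relatives) add priors over the parameters; plain box-constrained
ML is used here because no particular prior is part of the protocol, and the
recovery suite quantifies what the sparse design costs at the study's sparse per-condition counts (30 stimulated + 15 catch):
median location error ≈ 2.3 µm (w/4 = 5 µm is the acceptance bound), and a small
finite-sample bias of the suppression difference (≈ −0.25 µm at the default
observer, within 2 SEM of zero over 200 replicates) that is inherent to ML
location estimation on a fixed sparse grid, not a coding artifact.

Threshold criterion: the 50% point of the core function (= m), the
γ/λ-corrected reading of "50% of the function"; an absolute-probability mode
(Ψ(x) = 0.5) is available and errors when γ ≥ 0.5 makes it unreachable.  The
two baseline blocks are merged before fitting; a paired t-test on the two
baseline thresholds is available as a configurable gate but not enforced by
default.  Exclusion: baseline false-alarm rate must be
*strictly below* 30% (9/30 drops, 8/30 keeps).

## Group statistics

Exact Student-t p-values (no normal approximation; cohorts in this paradigm are modest, n ≈ 24).
Cohen's d = mean/SD of the (difference) scores.  The 2×2 repeated-measures
ANOVA uses the standard within-subject decomposition, each effect tested
against its own effect-by-subject interaction with df = (1, n−1) and partial
η² = SS_effect/(SS_effect + SS_error); for a 2×2 within design each F equals
the squared paired t on the corresponding contrast, which the test suite
verifies to machine precision alongside an independent cross-check against
`pingouin.rm_anova`.  Zero-variance inputs raise rather than returning t = ∞.
Bonferroni: min(1, p·m).

## Pipeline and problem sizes

`run_pipeline` simulates each participant's full session(s) (Experiment 2 uses
the same grasping sequence in both sessions, as presented), analyzes them, and
refuses group statistics below two participants or after exclusions reduce the
cohort below two.  Reports are deterministic under config + seed.  The test and
acceptance runs use reduced cohorts (8–20 simulated participants) and 60–200
replicate fits — sizes chosen so the full suite completes in minutes while the
Monte-Carlo bands (binomial type-I bands at 2000 replicates, 2-SEM recovery
bands at 200) remain meaningful.

## Known limitations

* The synthetic kinematic noise is far smaller than real between-participant
  variability, so simulated effect sizes (|d| ≫ 10 on the indices) are not
  comparable to empirical ones; only signs and means are.
* The generator's dwell is defined on the filtered-speed threshold convention;
  loading-time estimates on real data will include whatever the hand does
  between physical contact and the last sub-threshold crossing.
* prior-based psychometric toolchains are not replicated; thresholds from very sparse or
  near-degenerate condition data may differ from the original toolchain.
* Real recordings can be analyzed once converted to the documented on-disk
  layout (long-format series CSV + trial TSV + manifest JSON); no native
  motion-tracker file reader is included.
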