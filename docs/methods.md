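# Methods

## Setting

Two interlocutors sit roughly 65 cm apart, eyes level, and play a
referential word game: one describes a word, the other guesses, in
4 rounds of 90 s with roles alternating and the experimenter describing
first (so the participant's condition sequence is GUESS, DESCRIBE,
GUESS, DESCRIBE). A table-top dual-camera system records both faces at
60 Hz and yields, per person and frame, 3D facial landmarks (left eye,
right eye, mouth, optionally nose) and a binocular pair of 3D gaze rays
in a common world frame (centimetres; origin at the camera rig, y up).
Calibration blocks at the start and end have both people fixate the
partner's left eye, right eye, nose and mouth for 5 s each, twice.

## Measurement chain

**Facial plane.** The partner's plane is the plane through their three
defining landmarks, refit at every frame so the areas of interest move
with the head. The normal is oriented toward the observer and the
in-plane basis is fixed (u along the owner's left→right eye direction,
v = n × u), making plane coordinates comparable across frames.
Collinear landmark triples (triangle area ≤ 1e−8 cm²) raise a
degenerate-geometry error in the scalar API and are masked per-frame in
the vectorised path.

**Intersection and binocular averaging.** Each gaze ray is solved
against the plane; a hit is valid when |n·d| > 1e−8 (non-parallel) and
the ray parameter t > 0 (in front of the eye). Valid left/right hits
are averaged; if exactly one is valid it is used alone
(`require_both_eyes` disables this fallback). Valid points satisfy the
on-plane residual tolerance of 1e−6 cm.

**AOI classification.** The eye area is the union of two discs of
radius 6.3 cm centred on the eye landmarks, tested by minimum 3D
Euclidean distance with an inclusive boundary; the mouth uses the same
rule (radius 6.3 cm by default) and the eye test takes precedence where
discs overlap. The 6.3 cm metric rule is the implemented definition; no
angular-threshold variant is used. Frames with no gaze estimate, no
temporally matching partner landmarks, or no valid intersection are
MISSING.

**Pairing and mutual contact.** The two classified series are paired
nearest-in-time with a window of half the nominal frame interval
(8.33 ms at 60 Hz), ties resolved toward the earlier partner frame;
unmatched frames are counted, never silently dropped. A pair is mutual
eye contact when both labels are EYE. Pairs with either label MISSING
leave both numerator and denominator. The default mutual percentage is
per valid paired interaction time; `mutuality="of_eye_gaze"` instead
divides by the participant's own EYE pairs. Both readings are plausible
for published mutual-contact figures; the interaction-time reading is
the default because it is numerically consistent with mutual percentages
being below the individual eye percentages.

**Aggregation.** Percentages are computed per trial and then averaged,
unweighted, per condition. The default denominator is valid
(non-missing) frames, with `denominator="total"` as a switch; the two
differ per trial by exactly the factor valid/(valid+missing).
Missingness is reported separately and enters a control contrast.
Frames are equal-weighted (percentage of samples ≈ percentage of time
at a fixed rate); no fixation filtering is applied. Trial exclusions
are manifest-level annotations.

**Calibration error.** For each scheduled fixation, the binocular mean
gaze direction of every valid frame is compared with the direction from
the eye midpoint to the partner's fixated landmark; the per-landmark and
overall medians (degrees) summarise accuracy.

## Statistics

Per condition × outcome (eye %, mutual %), two OLS models on raw units:
`y ~ aq + age + sex` and `y ~ discomfort + age + sex` (a combined model
is behind a flag), with heteroscedasticity-consistent covariance —
HC3 by default, i.e. Ω = diag(e²/(1−h)²), selectable down to HC0 —
via statsmodels, verified in the test suite against an explicit
(X′X)⁻¹X′ΩX(X′X)⁻¹ computation. Inference uses t on df = n − p;
because small-sample reports often print t(n−1) regardless of model
size, the report also echoes n − 1 as `df_echo`, clearly labelled.
Effect sizes are partial η² = t²/(t²+df_resid); this formula, not any
particular printed value, is normative. p-values are two-sided with no
multiplicity correction. Sex is coded 0 = female, 1 = male; AQ uses
4-point item scoring on one scale for both the adult and adolescent
instruments. Condition contrasts (eye %, mutual %, and the missing-data
control) are classical paired t-tests; zero-variance differences raise a
degenerate-test error rather than returning ±∞. Added-variable
(partial-regression) data are provided and the Frisch–Waugh–Lovell slope
identity is asserted to 1e−8 on every call.

## Synthetic dyads

The generator emulates the study design so the pipeline can be
validated by parameter recovery; it does not aspire to realistic
saccade kinematics.

*Cohort.* AQ ~ truncated normal, mean 19.5, SD 4.3 on (7, 32) — the
truncation is symmetric about the mean so the configured mean is the
distributional mean; the implied n = 20 sample range matches the
reported 12.8–29.0. Age ~ truncated normal 28.4 ± 6.0 y on
(12.8, 36.4); participants under 18 carry the adolescent instrument
label. Sex is an exact-count 40 % male assignment, and eye-contact
discomfort defaults to an exact-count 30 % subset (mirroring a fixed
6-of-20 composition); a logistic AQ-linked Bernoulli model is available
via `aq_discomfort_association`. Participant-level draws (AQ, age,
residual heterogeneity) use shuffled inverse-CDF (Latin-hypercube)
sampling: the marginal distribution is exactly the configured one while
finite-cohort sample moments match the configured values closely, so
cohort-level validation reflects the configured effects rather than
cohort-sampling luck.

*Behaviour targets.* Per participant and condition, eye % =
base + slope_AQ·(AQ − 19.5) + shift_disc·(discomfort − 0.30) + residual,
and likewise for mutual %. Effects are centred at the cohort references
so the configured bases are the cohort means. Residuals are bivariate
(eye, mutual) with correlation 0.85 — mutual contact is largely a subset
of own eye gaze — and SDs chosen so the *total* between-participant SDs
reproduce the reported 17.6/16.9/12.2/11.7 after adding the variance the
injected effects explain (eye: 14.2/13.8; mutual: 10.0/9.6). Eye
percentages clip to [1, 99]; mutual percentages project into the
Fréchet-feasible band max(0, p+q−100) ≤ m ≤ min(p, q) given the realised
eye marginal p and the experimenter marginal q, with clip counts
recorded. A deterministically infeasible overlap raises, naming the
participant. The experimenter's marginals are not reported in the
available text; the preset fixes them at 55.8 % while guessing and 52 %
while describing — attenuated role modulation, chosen inside the
feasibility envelope across the whole AQ range so clipping never
triggers for the deterministic preset.

*Label streams.* The participant's per-trial EYE process is a two-state
Markov chain with stationary probability p and mean EYE dwell 30 frames
(0.5 s, a plausible fixation-episode scale); both dwell distributions
are geometric, so a Bernoulli(p) start is stationary. The
experimenter's state is drawn frame-wise conditional on the
participant's with P(other|self) = m/p and
P(other|¬self) = (q−m)/(1−p), which controls both marginals and the
joint fraction exactly in expectation; persistence applies to the
participant chain only (controlled time-averages, not realistic
micro-dynamics, are what validation needs). An `exact_fractions` mode
places labels by exact frame counts for noiseless round-trip tests.

*Emission.* EYE frames aim at a Gaussian scatter (SD 1.5 cm) around a
randomly chosen eye landmark; with the default 0.3 cm in-plane noise the
combined scatter keeps ≥ 99 % of mass more than 1 cm inside the 6.3 cm
boundary, so emitted EYE frames classify EYE with probability ≥ 0.999.
Non-EYE frames are rejection-sampled at least 1 cm outside every AOI
within a face-sized box (`--boundary-stress` style testing is done by
setting the margin to zero). Rays run from the emitter's eye landmarks
through the (noisy) target; timestamps jitter by N(0, 1 ms) clipped at
±3 ms; frames go missing independently at 10.3 % per person (blinks and
head turns have no temporal model in the available description).
Heads are static; landmark motion enters only through the per-frame
plane refit, which real head motion would exercise further.

*Seeds.* One master seed; per-participant substreams derive from
(master, CRC32(participant id)), so any session is reproducible
independently of generation order.

What passing recovery shows — and does not: the pipeline correctly
inverts the generator's geometry, coupling, noise and missingness at the
study's sample sizes. It cannot certify behaviour under structured
missingness, correlated estimator error, head motion, or fixation
dynamics, none of which the generator models.

## Validation sizes and numerical choices

Cohort-level recovery uses 200 synthetic participants (full 4 × 90 s
sessions, ~28 000 frames per stream); effect recovery uses 50 replicate
cohorts of n = 20; both finish in a few minutes on one CPU. Tolerances:
parallelism 1e−8, on-plane 1e−6 cm, FWL identity 1e−8; pairing ties go
to the earlier frame; undefined ratios (no valid frames/pairs) are
NaN with an explicit `defined` flag, never silent zeros. CSV floats are
written at 17 significant digits and parsed in round-trip mode so
write∘read is bit-exact and stage-wise runs equal end-to-end runs.

## Known limitations

- The generator's missingness is iid per frame; real missingness is
  bursty (blinks) and state-dependent (aversion), which would bias
  valid-time percentages in ways the recovery study cannot detect.
- The experimenter's behavioural parameters are a design choice, not a
  reported quantity.
- Between-participant SDs are treated as pure heterogeneity; any share
  that is really measurement noise would tighten the reported SDs.
- Regression recovery assumes the linear-effects generative model; it
  says nothing about model adequacy on real data.
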