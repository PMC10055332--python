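# Methods

This note documents the quantitative model behind `gaitspace`: what each
statistic is, the assumptions it rests on, the numerical conventions used,
what the synthetic generator does and does not emulate, and the design
choices made where more than one reasonable construction existed.

## Data model and step-cycle parameterization

The raw input is a table of stance intervals: per paw contact, the limb
(LH/RH/LF/RF), stance onset and offset (s), and the contact position on the
runway (cm), grouped into bouts (one uninterrupted pass).

A step cycle is delimited by the midstance times (the halfway point between
stance onset and offset) of two consecutive stances of the reference limb,
the left hindlimb by default. Per cycle and limb we compute:

- period `T` (s) and frequency `1/T` (Hz);
- stance duration (onset to offset) and swing duration (offset to the next
  onset of the same limb);
- duty factor = stance duration / `T` (the reference period, for every
  limb);
- stride length = Euclidean distance between the limb's consecutive
  contact points (cm);
- instantaneous speed = mean over the four limbs of stride length / `T`;
- the normalized phase of the limb's midstance relative to the reference
  midstance, `((t_mid - t_ref)/T) mod 1`.

The phase vector `Phi = (phi_LR, phi_HL, phi_DIAG)` collects the phases of
RH, LF and RF relative to LH. The fourth pairwise phase difference is
determined by these three: `phi_FLR = (phi_DIAG - phi_HL) mod 1`. When a
reference limb other than LH is requested, phases are re-expressed relative
to LH before classification so template semantics are preserved.

**Window and drop rules.** Cycle windows are half-open, `[t_start, t_end)`.
A cycle is kept only if every limb contributes exactly one midstance to the
window, has a previous contact (stride length is undefined for a bout's
first contact), and a following stance (for the swing duration); otherwise
it is dropped and counted by reason in a diagnostics record. For gaits in
which a limb is synchronous with the reference (phase near 0), noisy
midstances straddle the window boundary and roughly half of those cycles
are dropped; this is the honest consequence of the exact-one-midstance
rule, and the kept cycles are unbiased on the circle. Single transition
steps can likewise yield hybrid windows whose limbs carry neighbouring
cycles' timing; they are genuinely ambiguous steps, not extraction errors.

Maximal speed is the 95th percentile of the instantaneous speeds, with
linear interpolation between order statistics (the common default; no
particular method is canonical here).

## Gait classification

Steps are classified against the dictionary of idealized one- to four-beat
gaits with equal phase shifts between beats: 23 templates (1 one-beat, 4
two-beat — including the extra `(0, 2/3, 2/3)` hop/bound row that accounts
for the fore-hind asymmetry common in bound — 12 three-beat, 6 four-beat).
The 12 three-beat rows are the complete set of distinct equal-shift
three-beat gaits, and the dictionary is closed under left-right mirroring.

The distance between a step `Phi` and a template `Psi` is Euclidean in the
wrapped phase differences, in radians:

    d(Phi, Psi) = sqrt( sum_j arg[exp(i 2 pi (phi_j - psi_j))]^2 ),
    j in {LR, HL, DIAG}

The nearest template wins; near-ties (within 1e-12 rad) are broken by table
row order and flagged. The walking name is used when the mean duty factor
over the four limbs is >= 0.5, the running name below — equality goes to
the walking branch as the conservative default, and the mean over limbs is
used because limb-specific parameters are otherwise averaged over limbs
throughout.

**Lead limbs.** For each fore/hind pair, the pair's two touchdowns split
the cycle circle into two arcs; the trailing limb strikes first and the
lead limb second within the shorter arc. Touchdowns within 1e-6 s are
simultaneous (no lead). One exception: the canter forelimb lead follows the
gait's definition — the leading forelimb is the one not in the synchronous
diagonal pair — because canter's fore pair is nearly alternating and
touchdown order degenerates to a coin flip on transition steps; the
touchdown-order value is retained in a cross-check field.

**Transitions.** Within each bout, consecutive ordered category pairs are
tallied into a matrix `A`; conditional probabilities normalize each row by
its sum, frequencies normalize by the total transition count. Transitions
never span bouts. The transition graph (DOT export) sizes nodes by gait
prevalence and edges by transition frequency.

## Variability: circular EMA and madev

Per bout and per limb pair, the sequence of phase differences (radians) is
smoothed by the circular exponential moving average

    S_0 = phi_0,   S_n = S_{n-1} + alpha * arg(exp(i(phi_n - S_{n-1})))

with `alpha = 2 pi f_c / (2 pi f_c + 1)` and cutoff `f_c = 0.125` per step
cycle by default (`alpha ~= 0.4399`). Only the innovation is wrapped; `S`
itself is unwrapped so it can track sustained drift. The variability
statistic is the mean deviation from the moving average normalized by pi:

- `abs-inside` (default): `madev = (1/(pi N)) sum_n |arg(exp(i(phi_n - S_n)))|`
- `as-written`: `madev = (1/(pi N)) |sum_n arg(exp(i(phi_n - S_n)))|`

The second form places the absolute value around the sum; because the EMA
tracks the phases, signed deviations largely cancel and that form hovers
near zero regardless of noise. A variability measure needs the magnitude,
so `abs-inside` is the default, but both are implemented and selectable.
Either way `madev` is bounded by 1 (each wrapped deviation is at most pi),
is invariant to a constant rotation of all phases, and — the property that
motivates it — penalizes persistent or stochastic phase change more than a
single ordered transition of equal net displacement, because the average
converges after a step change.

The six limb pairs reported are hind left-right, fore left-right, the two
homolateral pairs, and the two diagonals; all derive from the per-cycle
phase vector. Bouts with fewer than two cycles are skipped with a
diagnostic.

## Phase-space continuum models

Steps live on the 3-torus of normalized phase differences. A continuum
model is a segment between two gaits, `Psi_A` to `Psi_B`, with unit
direction `u` from the plain difference of the endpoint representatives
(scaled to radians). Each step gets the scalar projection `lambda` that
minimizes the circular distance `d(Phi, Psi_A + lambda u)` over
`lambda in [-2 pi, 2 pi]`.

Because phases wrap, the squared distance is piecewise quadratic in
`lambda`, one branch per combination of per-component 2-pi shifts.
`project_phases` minimizes exactly: it evaluates the stationary points of
all 27 wrap branches (these include the plain dot-product projection and
the projections from reference positions shifted by +-2 pi u), the
branch-crossing kinks, and the interval bounds, each clamped into
`[-2 pi, 2 pi]` before comparison, and keeps the candidate with the
smallest true distance. Ties (duplicate torus points on symmetric lines)
are broken toward the smaller |lambda|, then the positive sign. This
construction agrees with a dense grid search everywhere, which a fixed
three-candidate shortlist does not on points far from the line.

**Built-in models.**

- *trot to half-bound gallop*: from the average trot `(0.49, 0.47, 0.98)`
  to the average left-lead half-bound gallop `(0.94, 0.60, 0.36)`, with its
  right-lead mirrored counterpart.
- *trot to pace*: idealized trot to idealized pace `(0.5, 0, 0.5)`. Trot's
  diagonal phase is 0 == 1 on the circle; the representative
  `(0.5, 0.5, 1.0)` is used so the segment follows the family
  `phi_DIAG = phi_HL + 0.5` — the single degree of freedom left when both
  girdles alternate — and passes through the lateral- and
  diagonal-sequence walks and ambles. The 0.0 representative would give a
  chord containing none of those gaits and is contradicted by the gaits
  the continuum must span.

**Mirroring.** Left-right relabelling
`M(Phi) = ((1 - phi_LR), (phi_DIAG - phi_LR), (phi_HL - phi_LR)) mod 1`
is an involution on the torus but not a Euclidean isometry of the three
LH-referenced coordinates, so mirroring the endpoints and re-chording does
not reproduce mirrored data. The mirror branch instead relabels the *step*
and projects it onto the primary line; for a perfectly mirrored step this
is exact, and `lambda` of a mirrored step equals `lambda` of the original.
Each step keeps the branch (primary or mirror) with the smaller residual;
residuals from both branches pool into one fit.

**Goodness of fit.** `R^2 = 1 - sum_i d_i^2 / sum_i d(Phi_i, mu_Phi)^2`
with `mu_Phi` the componentwise circular mean (undefined, and reported as
an error, when a component's resultant vanishes). With animal identities,
R^2 is also computed per animal against that animal's own circular mean.
Model comparison uses `AIC = 2k + n log(mean_i d_i)` — the mean of
*unsquared* residual distances, kept exactly as defined even though a
log-of-mean-squared form would be more conventional — and Akaike weights
`w_m = exp(-Delta_m/2) / sum exp(-Delta/2)`. Both built-in models have
their endpoints fixed a priori, so `k = 0`; since compared models share
`k`, the weights are unaffected by this choice. All-zero residuals yield
`-inf` with a warning rather than an exception.

## Speed regressions

Stride length, the fore/hind duty factors and fore/hind swing durations are
modelled as linear in speed, `f(beta, v) = beta0 + beta1 v`; the cycle
period and fore/hind stance durations as inverse,
`f(beta, v) = beta0 + beta1 / v`. The inverse form is fitted by ordinary
least squares on the reciprocal regressor, which shares its optimum with a
nonlinear fit of the same model under additive error. Fits are per animal
(pooling the animal's cycles within a condition; at least three points,
non-degenerate speeds). The per-animal coefficient covariance is the
standard OLS estimator `sigma_hat^2 (X'X)^{-1}`. Group estimates average
the per-animal coefficient vectors and covariance matrices elementwise, and
the 95% band at speed `v` is the delta method,
`1.96 sqrt(grad f' Cov grad f)` with `grad f = (1, v)` or `(1, 1/v)`.
Statistical comparison across conditions (mixed models, post hocs) is out
of scope; the report emits per-condition estimates and bands only.

## Synthetic footfall generator

The generator emits bouts of stance intervals with known ground truth so
every pipeline stage can be validated end to end.

**Construction.** Per cycle, speed follows a ramp (default) or explicit
profile plus Gaussian jitter (SD 3 cm/s); stride length is linear in speed,
the period is stride/speed, and reference midstances accumulate periods.
Every other limb's midstance sits at `reference + phase * period`; stance
intervals are centered on midstances with width `duty * period` (duty
linear in speed, optional left-minus-right hindlimb offset), which makes
midstance-based extraction exact by construction. Contacts advance by the
per-cycle stride along the runway. Non-reference limbs track their phase
target through an unwrapped running phase (each step moves by the wrapped
innovation toward the new target), so consecutive stances always stay about
one period apart even across gait transitions. Two extra cycles (lead-in
and trailing) are generated so each configured cycle is complete for the
extractor. Noise is von Mises on each limb's phase independently
(concentration `kappa`, default 100, roughly SD 0.016 cycles); a noiseless
switch gives exact round-trips (every extracted parameter equals its
setting to well below 1e-9).

**Laws and templates.** The default stride law `18.8..30 cm over
77..174 cm/s` (`10.64 + 0.1088 v`) and duty law (`0.663 - 0.00186 v`,
anchored at walk 0.52 and bound 0.34) are least-squares / endpoint fits
through the per-gait means reported for intact overground locomotion of
adult rats; gait selection under a speed ramp uses thresholds at midpoints
between the per-gait mean speeds (77.1, 100.5, 106.3, 122.4, 141, 173.9
cm/s), the minimal-assumption rule given means but no boundaries. Intended
gaits use the idealized left-lead templates (lateral-sequence walk for
"walk", transverse gallop for "gallop"); asymmetric gaits (canter, gallop,
half-bound) are mirrored to the right lead with probability
`1 - lead_bias`. The lead is drawn once per bout — lead persists within
real gallop runs, and independent per-cycle flips would jump limb targets
by half a cycle between consecutive steps — so the across-cycle left-lead
fraction converges to `lead_bias` with bout-level variance.

**Presets.**

- `intact`: full repertoire, ramp 60-180 cm/s, `lead_bias = 0.374`.
- `hemisection`: repertoire capped at gallop (no half-bound/bound), ramp
  50-130 cm/s, `lead_bias = 0.965`, trot left-right phases biased to
  (hind 0.549, fore 0.546), left-minus-right hindlimb duty offset +0.03,
  steeper duty law (`0.70 - 0.00232 v`).
- `contusion`: ramp 40-100 cm/s, flatter stride law; both left-right
  phases von Mises around 0.5 while the homolateral phase performs an
  unwrapped Gaussian random walk (step SD 0.05 cycles) with the diagonal
  phase following half a cycle away — steps drift along the trot-pace
  continuum with weakened fore-hind coupling. In expectation the cohort
  satisfies alternation of both girdles and
  `phi_DIAG = phi_HL + 0.5` to within 0.02 cycles.

**What the generator does not emulate.** Kinematics beyond footfall timing
(no joint angles, forces or body dynamics), missed or dorsal steps,
paw-placement error in the contact positions (stride laws are exact in
speed), within-animal idiosyncrasies (animals differ only by noise stream),
gait-transition hysteresis, and the recovery time course after injury.
Passing tests therefore certify the analysis pipeline — extraction,
classification, variability, projection, regression — on data with the
assumed statistical structure, not the biological variability of real
recordings.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at desk scale: cohorts of
3-10 animals with 5-10 bouts of 8-20 cycles (a few hundred to ~1200 steps),
500-step cohorts for the model-selection and variance-explained checks,
10,000 random points for the classifier oracle and 1,000 for the projection
grid oracle (grid step 1e-4). Key tolerances: noiseless round-trips to
1e-9; template near-tie window 1e-12 rad; touchdown simultaneity 1e-6 s;
circular-mean resultant threshold 1e-9; projection grid agreement within
one grid step. Randomness is always drawn from seeded
`numpy.random.Generator` streams, with per-animal and per-bout substreams
spawned from the master seed.

## Known limitations

- The drop rule discards roughly half of the cycles of gaits with a limb
  synchronous to the reference under noise, and single transition steps
  can survive as hybrid windows; both are properties of midstance-window
  bookkeeping, not of the classifier.
- The AIC uses the unsquared mean residual as defined; its absolute values
  are not comparable to likelihood-based AICs, only the weights between
  models fitted to the same steps are meaningful.
- The per-animal R^2 uses each animal's own circular mean, so animals whose
  steps cluster tightly can show small or negative values even when the
  pooled fit is good.
- Lead limbs at exact alternation (phase difference 0.5) are reported from
  sub-tolerance timing noise and are not meaningful for symmetric gaits.
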