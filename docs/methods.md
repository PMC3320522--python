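# Methods

## Data model

A *course* is an ordered series of one real-valued rating per session,
sessions numbered 1..n consecutively (length ≥ 3; a V-shape needs three
points). Gaps are an input error by default because every criterion here
reasons about session-to-session differences; an opt-in linear
interpolation fills internal gaps and flags the filled sessions in the
output. Ratings are unitless (an affiliation-index-like scale); all
detection logic is shift-invariant, and magnitudes scale linearly with the
data.

Variability is summarised per course by the **intraindividual SD** (sample
SD of the course's values, n−1 denominator; a `ddof` switch selects the
population formula) and per sample by the **interindividual SD** (the
arithmetic mean of per-course SDs). Detection thresholds are
`multiplier × SD` with `multiplier ∈ {1, 2}` and the SD source chosen by
mode: `inter_only` (the original step-rule convention), `intra_only` (the
convention for a stand-alone long course, where pooling with courses of
different lengths would distort the scale), or `stricter` — the larger of
the two — which guards simultaneously against over-reading minor
fluctuations in stable courses and intraindividually insignificant dips in
volatile ones. All threshold comparisons are inclusive (`≥`), matching the
"at least"-style wording of the rules implemented.

## Quadratic-trend residual rule

The per-course fit regresses the rating on the centred session index
`s − (n+1)/2` and its square, by ordinary least squares; the midpoint may be
half-integer for even n. RMSE uses residual degrees of freedom n−3 by
default (three estimated parameters; a switch selects the plain-n
denominator — the choice is a documented convention, not derivable from the
rule's description). Exact polynomial courses produce RMSE exactly 0 (a
relative-tolerance snap suppresses numerical dust, so the "RMSE = 0 iff the
data lie on the fitted parabola" invariant holds).

A session is a rupture when its value falls at least `rmse_multiplier`
(default 2) times the RMSE below the fitted value. The original preset adds:
first/last sessions never count; the value must be below the previous
session's; the value must fall below an absolute floor. The floor has no
defensible universal value — it is instrument-specific — so it is a
required, explicit parameter of the original preset and absent from the
modified preset. The modified preset drops the course-level exclusions (the
negative-slope exclusion and the floor) but keeps the per-session
specifications, which address what counts as a rupture rather than which
courses enter the analysis. Courses that are highly fluctuating simply
yield a large RMSE and hence few or no ruptures; no special casing is
needed.

This rule marks rupture *sessions* and defines no repair point, so its
output is a session list plus a per-course exclusion verdict, not episode
records.

## Step rule

Ruptures and repairs are single session-to-session differences reaching the
threshold. Gradual declines whose steps stay individually sub-threshold are
deliberately invisible here — that gap is the motivation for the cumulative
criterion. Consecutive sub-threshold decreases never combine into a rupture
even under aggregation; aggregation (a modification) only extends a rupture
whose first step already qualified, into a maximal run of consecutive
qualifying decreases counted as one rupture with the summed magnitude.

Repair search: the first qualifying increase after the rupture and no later
than the next detected rupture's start session; each repair step serves one
rupture, processed left to right. With repair-matching active, a rupture of
magnitude ≥ 2 SD is only repaired when the net recovery from its trough
(`v(t) − v(trough)`) reaches the rupture magnitude; "cumulative increase"
is read as net recovery because intervening dips that are given back should
not count toward the repair.

Under the original preset, a course whose final rupture stays unrepaired is
excluded entirely (all its episodes discarded, the verdict carries the
reason); the modified preset reports all episodes and flags unrepaired ones.

## Crisis-repair criterion

Steps are segmented into maximal runs: strictly positive steps form incline
runs, non-positive steps form decline runs — **constant values are not a
direction change** and attach to the current or upcoming decline, which
matters for length accounting. A decline run whose cumulative drop reaches
the threshold flags a rupture. The episode's start session is the last
session before the run's first strictly downward step (leading constants
are skipped and the episode is flagged when they occur, since the printed
length conventions do not illustrate that case); the trough is the last
session attaining the episode's minimum (so trailing constants extend the
decline).

Repair requires two things at a session t: at least one strictly upward step
since the (current) trough, and recovery to within the threshold of the
start value, `v(t) ≥ v_start − multiplier·SD` (reaching or exceeding
`v_start` always repairs; equality with the band counts, consistent with
the global `≥` convention). The upward-step requirement prevents a decline
of exactly threshold depth from being "repaired" at its own trough. The
recovery band scales with the multiplier: a 2-SD detection run uses a 2-SD
band. This reading of the repair definition — full recovery *or* recovery
into the SD band, after an actual upturn — is one of two grammatically
possible readings of the rule; it is the one consistent with the principle
that deep ruptures need commensurate repairs, and it is documented here
rather than asserted as the only possible intent.

If a further qualifying decline begins before repair, the episode extends
and the trough updates to the global minimum; such merged episodes are the
complex pattern. Episodes never overlap (a repair session may serve as the
next episode's start). An episode still open at the final session is
emitted unrepaired; no course is ever excluded. First-session declines are
allowed — the first/last-session rule belongs to the residual criterion,
not to this one.

## Pattern taxonomy

Labels are assigned from episode geometry: pattern 5 when the episode span
contains ≥ 2 threshold-reaching decline runs (re-segmented from the course,
so the classifier works for externally supplied episodes too); otherwise
decline length 1 vs ≥ 2 crosses repair length 1 vs ≥ 2 to give patterns
1–4. A "jump" inside a slide (subtypes 3b/4b) is a single step whose drop
reaches the detection threshold — the threshold is reused rather than
inventing a second parameter, and is overridable. Repairs are not
subdivided by shape beyond one-vs-many sessions. Unrepaired episodes keep
the label their decline shape implies (1/3a/3b) with `repaired = False`
carried separately, rather than a class of their own.

Summaries report counts and percentages per label and per group
(percentages to one decimal, halves rounded away from zero), counts of
courses with ≥ 1 episode, and length statistics. Complex episodes are
excluded from the length histograms and means; the means are computed over
repaired, non-complex episodes so that mean episode length = mean decline
length + mean repair length exactly.

## Synthetic data

The generator carves planted episode geometry into a flat baseline *before*
adding noise, so ground truth is geometric: each planted episode knows its
exact start/trough/repair sessions and pattern. Noise is independent
additive Gaussian per session (optionally AR(1), since post-session ratings
are plausibly autocorrelated; the marginal SD is held fixed). Defaults
emulate the targeted study conditions: ten courses of 29–35 sessions and one
200-session course, baseline 100, noise SD 18, episode depths 80–130 rating
units and 3–4 episodes per short course — together these put per-course SDs
at the documented order of 38–41, with most of the variability generated by
the episodes themselves, as in real series. The schematic pattern fixtures
are five minimal noise-free courses realising patterns 1–5 at a stated
threshold (each contains exactly one detectable episode).

A subsampling utility restricts a course to a sparse measurement schedule
(e.g. sessions 2, 5, 10, 20, 30) to demonstrate how sparse designs distort
detection: a gradual slide collapses into a single jump and changes its
pattern label.

What passing tests on generated data do **not** show: real session ratings
are bounded, discretised, autocorrelated and missing-prone; the generator's
Gaussian, unbounded, independent noise is a deliberate simplification. An
optional clamp emulates bounded scales but distorts planted geometry and is
off by default.

### Noise sensitivity of episode starts

The cumulative criterion defines a decline run by step signs, so with
continuous noise the step immediately before a planted onset is negative
with probability one half — the detected run then starts inside the
preceding noise wiggle, moving the episode start earlier and lengthening
the decline. The trough and repair sessions, by contrast, are robust
whenever the geometry keeps a few noise SDs of margin around each decision
boundary. Consequently, on noisy data the distribution of decline lengths
(and the 1-vs-many split that separates pattern 1 from pattern 3) is
intrinsically sensitive to measurement noise; this is a property of the
criterion itself, not of the implementation, and it is why the recovery
tests assert exact trough/repair positions and episode counts under noise
but exact starts and labels only in the noise-free case.

## Numerical and testing choices

Detection is exact arithmetic over the input floats; no smoothing or
detrending is applied. Scans are cross-checked against independently coded
brute-force oracles that apply the definitions literally — exhaustively
over all courses of length ≤ 8 on a 5-point value grid and over seeded
random courses up to length 35; the quadratic fit is checked against an
independent regression implementation to 1e-8. Property tests cover
threshold nesting (2-SD episodes nest within 1-SD episodes),
anti-monotonicity of the residual rule in its multiplier, shift invariance,
and run-partition well-formedness. All stochastic tests use fixed seeds.

## Known limitations

* The exact published affiliation-index weights are not distributed with
  the package; weight profiles must be supplied (the shipped `unit` profile
  is an example, selected explicitly, never a silent default).
* The absolute floor of the original residual rule has no published value
  and must be chosen per instrument.
* Within-session (moment-by-moment) rupture processes are out of scope; the
  unit of analysis is the session.
* The step rule's original sparse sampling schedule is not reproduced;
  every-session data are assumed, with the subsampler available to mimic
  sparse designs.
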