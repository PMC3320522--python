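# crisisrepair

Detection, classification and summary of **rupture-repair (crisis-repair)
episodes** in session-by-session ratings of the therapeutic relationship.

Psychotherapy process research rates the patient–therapist relationship after
every session (for example with a weighted SASB/Intrex affiliation index,
where higher = a more affectionate interaction). A *rupture* is a temporary
deterioration of that series; a *repair* is its return to (or near) the
pre-rupture level. Whether an episode "counts" depends heavily on the formal
criterion used, and published criteria disagree. This package implements the
competing criteria side by side, for methodologists and process researchers
who need to choose one — or demonstrate how much the choice matters.

## The criteria

Let `v(s)` be the rating at session `s = 1..n` of one course, `SD_intra` the
course's own standard deviation, and `SD_inter` the mean of the per-course
SDs over a sample of courses.

**Quadratic-trend residual rule (Stiles-type).** Fit
`v(s) ≈ β₀ + β₁(s − m) + β₂(s − m)²` with `m = (n+1)/2` (so `β₀` is the
midtreatment intercept, `β₁` the slope, `β₂` the curve) and let RMSE be the
residual root-mean-square error. Session `s` is a rupture when
`v(s) ≤ fitted(s) − 2·RMSE`, subject to four specifications: never the first
or last session; `v(s) < v(s−1)`; `v(s)` below a pre-specified absolute
floor; and courses with `β₁ < 0` are excluded outright. The *modified*
preset drops the course-exclusion parts (negative-trend exclusion and
floor).

**Step rule (Strauss-type).** A rupture is a single session-to-session
decrease `≥ 1·SD_inter`, repaired by a subsequent one-step increase of the
same size; a course whose final rupture stays unrepaired is removed
entirely. The *modified* preset applies the proposed adjustments: the
stricter of `SD_intra`/`SD_inter`, optional 2-SD threshold, no course
exclusion, repairs matched to the rupture magnitude for ≥ 2-SD ruptures, and
aggregation of consecutive threshold-reaching decreases into one rupture.

**Crisis-repair criterion.** Session-to-session differences are summed
within maximal same-direction *runs* (constant values are not a direction
change — they belong to the rupture). A rupture is flagged when a decline
run's cumulative drop reaches `k·SD` (`k ∈ {1, 2}`, SD = the stricter of
intra/inter, or intra alone for a stand-alone long course); this catches
gradual slides that the step rule misses. The episode is repaired at the
first session that follows an upward step and has recovered to within
`k·SD` of the pre-decline start value. Unrepaired episodes at course end are
reported, never excluded.

Episodes are then classified into five patterns: **1** jump-in/jump-out (the
simple V), **2** jump-in/slide-out, **3** slide-in/jump-out, **4**
slide-in/slide-out (3/4 split into **a** without and **b** with a
threshold-sized jump inside the slide), and **5** complex (two or more
qualifying declines separated by a direction change before repair).

## Worked example

Simulate a study-scale batch (ten courses of 29–35 sessions with planted
episodes on a realistic rating scale), detect crisis-repair episodes and
compare criteria:

```bash
$ crisisrepair simulate --seed 7 --n-courses 10 --out-dir demo
wrote 10 course(s) to demo/courses.csv

$ crisisrepair detect --input demo/courses.csv --criterion crisis_repair --out-dir demo/det
crisis_repair: 48 episode(s)/rupture(s) in 10 course(s); 0 course(s) excluded

$ head -3 demo/det/episodes.csv
course_id,criterion,multiplier,start_session,trough_session,repair_session,rupture_magnitude,repair_magnitude,decline_length,repair_length,repaired,pattern
course01,crisis_repair,1,3,7,9.0,149.20663159830505,127.41277524383288,4,2.0,True,4b
course01,crisis_repair,1,9,11,12.0,133.23610182828267,130.98268614318852,2,1.0,True,3b
```

Each row is one episode: it started at session 3 (the last pre-decline
session), bottomed out at session 7 after a 4-session decline of 149 rating
units (≥ the course's 1-SD threshold), and was repaired two sessions later —
a slide-in/slide-out shape containing a jump, pattern 4b.

```bash
$ crisisrepair compare --input demo/courses.csv --criteria strauss --criteria crisis_repair --out-dir demo/cmp
                                   strauss  crisis_repair_1sd  crisis_repair_2sd
Total CREs/RREs                         35                 48                 32
Courses with at least one CRE/RRE        7                 10                 10
Courses with no CRE/RRE                  0                  0                  0
Excluded courses                         3                  0                  0
```

The cumulative criterion finds more episodes than the step rule (48 vs 35 at
the same 1-SD scale) because it also captures gradual multi-session slides,
and it excludes no courses; the 2-SD episode set is nested inside the 1-SD
set. `demo/det/summary.json` carries the pattern distribution (here 20.8 %
pattern 1, 56.3 % pattern 3) and the mean decline/repair/episode lengths
(2.29 / 1.19 / 3.48 sessions).

The same operations are available as a library:

```python
from crisisrepair import Course, VariabilityProfile, detect_crisis_repair, classify_episodes

course = Course.from_values("demo", [60, 55, 50, 45, 40, 60])
profile = VariabilityProfile(15.0, 0.0, multiplier=1, mode="intra_only")
episodes = classify_episodes(detect_crisis_repair(course, profile), course, 15.0)
# one episode: start 1, trough 5, repair 6, magnitude 20, pattern "3a"
```

## Layout

| module | contents |
| --- | --- |
| `crisisrepair.core` | `Course`/`CourseSet` containers, intra-/interindividual SD, effective thresholds |
| `crisisrepair.stiles` | quadratic-trend fit and the residual-outlier rule |
| `crisisrepair.strauss` | step-level decrease/increase rule, original and modified |
| `crisisrepair.crisis_repair` | run segmentation and the cumulative crisis-repair criterion |
| `crisisrepair.patterns` | five-pattern taxonomy, summary tables |
| `crisisrepair.synthetic` | seeded generator with planted episodes, schematic pattern fixtures, sparse-schedule subsampling |
| `crisisrepair.io` / `crisisrepair.cli` | CSV readers/writers, affiliation index, run configuration, `crisisrepair` command |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
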