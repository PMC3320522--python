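"""The crisis-repair criterion: cumulative-run rupture detection.

The series of session-to-session differences is segmented into maximal
*runs*: a decline run collects consecutive non-positive steps (constant
steps are not a direction change — they belong to the rupture, not the
repair), an incline run collects consecutive strictly positive steps.  A
rupture is flagged whenever the cumulative drop of a decline run reaches the
effective variability threshold (1 or 2 SD units).  Because the drop is
cumulated over the whole run, gradual multi-session slides are detected as
well as single-session jumps — the gap left open by step-level rules.

The episode is *repaired* at the first subsequent session that (a) follows
at least one strictly upward step since the trough and (b) has recovered to
within the threshold of the pre-decline start value (reaching or exceeding
the start value always repairs).  If, before that happens, a further
qualifying decline begins, the episode extends and the trough updates — such
merged episodes are later labelled as the complex pattern.  An episode still
open at the final session is emitted unrepaired; no course is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .core import (
    ConfigurationError,
    Course,
    Episode,
    VariabilityProfile,
)

__all__ = ["Run", "segment_runs", "detect_crisis_repair"]


@dataclass(frozen=True)
class Run:
    """A maximal same-direction run of session-to-session steps.

    ``start_session`` .. ``end_session`` are 1-based and inclusive; the run
    owns the steps between them.  ``cumulative_change`` is the signed sum of
    those steps, i.e. value(end) − value(start).
    """

    kind: str  # "decline" | "incline"
    start_session: int
    end_session: int
    cumulative_change: float


def _segment(values: Sequence[float]) -> List[tuple]:
    """0-based run segmentation: list of (kind, start_idx, end_idx, cum)."""
    n = len(values)
    runs: List[tuple] = []
    if n < 2:
        return runs
    cur_kind = None
    cur_start = 0
    for i in range(1, n):
        step = values[i] - values[i - 1]
        # constant steps are not a direction change: they attach to the
        # current decline or open a new one after an incline
        kind = "incline" if step > 0 else "decline"
        if kind != cur_kind:
            if cur_kind is not None:
                runs.append(
                    (cur_kind, cur_start, i - 1, values[i - 1] - values[cur_start])
                )
            cur_kind = kind
            cur_start = i - 1
    runs.append((cur_kind, cur_start, n - 1, values[n - 1] - values[cur_start]))
    return runs


def segment_runs(course: Course) -> List[Run]:
    """Partition a course's steps into alternating maximal decline/incline runs."""
    return [
        Run(kind, start + 1, end + 1, cum)
        for kind, start, end, cum in _segment(course.values)
    ]


def _scan_episodes(values: Sequence[float], threshold: float) -> List[tuple]:
    """Low-level detection on a plain value sequence.

    Returns tuples ``(start_idx, trough_idx, repair_idx_or_None,
    qualifying_run_start_idxs, has_leading_constants)`` with 0-based indices.
    """
    n = len(values)
    runs = _segment(values)
    # run lookup by the index of the session the run starts at
    run_by_start = {r[1]: r for r in runs}

    episodes: List[tuple] = []
    open_ep = None  # [start_idx, v_start, trough_idx, v_trough, up_since_trough,
    #                 qual_starts, leading_consts]
    pending_open_at = None  # step index at which an episode opens (first down-step)
    pending_run_start = None
    pending_leading = False

    for i in range(1, n):
        d = values[i] - values[i - 1]
        run = run_by_start.get(i - 1)

        if open_ep is None:
            if pending_open_at is None and run is not None and run[0] == "decline":
                drop = -run[3]
                if drop >= threshold and drop > 0:
                    # first strictly-down step inside the run fixes v_start
                    j = run[1]
                    while values[j + 1] >= values[j]:
                        j += 1
                    pending_open_at = j
                    pending_run_start = run[1]
                    pending_leading = j > run[1]
            if pending_open_at is not None and i - 1 == pending_open_at:
                open_ep = [
                    pending_open_at,
                    values[pending_open_at],
                    i,
                    values[i],
                    False,
                    [pending_run_start],
                    pending_leading,
                ]
                pending_open_at = None
                pending_run_start = None
            continue

        # --- episode open ---
        if run is not None and run[0] == "decline":
            drop = -run[3]
            if drop >= threshold and drop > 0:
                open_ep[5].append(run[1])

        if values[i] <= open_ep[3]:
            # new (or equal, via a non-positive step) minimum: trough moves,
            # constants after the trough belong to the decline
            open_ep[2] = i
            open_ep[3] = values[i]
            open_ep[4] = False
            continue
        if d > 0:
            open_ep[4] = True
        if open_ep[4] and values[i] >= open_ep[1] - threshold:
            episodes.append(
                (open_ep[0], open_ep[2], i, tuple(open_ep[5]), open_ep[6])
            )
            open_ep = None

    if open_ep is not None:
        episodes.append((open_ep[0], open_ep[2], None, tuple(open_ep[5]), open_ep[6]))
    return episodes


def detect_crisis_repair(
    course: Course,
    profile: VariabilityProfile,
    multiplier: Optional[int] = None,
) -> List[Episode]:
    """Detect crisis-repair episodes in one course.

    ``multiplier`` (1 or 2) overrides the profile's multiplier; the
    threshold is ``multiplier × base SD`` of the profile, and the repair
    band scales with the same multiplier.
    """
    mult = profile.multiplier if multiplier is None else multiplier
    if mult not in (1, 2):
        raise ConfigurationError(f"multiplier must be 1 or 2, got {mult!r}")
    threshold = mult * profile.base_sd
    out: List[Episode] = []
    for start, trough, repair, quals, leading in _scan_episodes(
        course.values, threshold
    ):
        v_start = course.values[start]
        v_trough = course.values[trough]
        repaired = repair is not None
        out.append(
            Episode(
                course_id=course.course_id,
                criterion="crisis_repair",
                start_session=start + 1,
                trough_session=trough + 1,
                repair_session=None if repair is None else repair + 1,
                rupture_magnitude=v_start - v_trough,
                repaired=repaired,
                threshold_multiplier=mult,
                repair_magnitude=(
                    None if repair is None else course.values[repair] - v_trough
                ),
                qualifying_decline_starts=tuple(q + 1 for q in quals),
                has_leading_constants=leading,
            )
        )
    return out
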