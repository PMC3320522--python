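"""Five-pattern taxonomy of crisis-repair episodes and frequency summaries.

Episodes are labelled by the shape of their decline and repair segments:

* ``1`` — jump in / jump out (the simple V): one-session decline, one-session repair
* ``2`` — jump in / slide out: one-session decline, repair over ≥ 2 sessions
* ``3a``/``3b`` — slide in / jump out: decline over ≥ 2 sessions, one-session
  repair; subtype ``b`` if the slide contains at least one single step
  reaching the detection threshold (a jump), ``a`` otherwise
* ``4a``/``4b`` — slide in / slide out: both segments over ≥ 2 sessions
* ``5`` — complex: two or more threshold-reaching declines separated by a
  direction change before the episode repairs

Repairs are not subdivided by shape beyond one-vs-many sessions.  An episode
left unrepaired at the end of the course keeps the label its decline shape
implies (with ``repaired=False`` carried on the episode) rather than getting
a class of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .core import Course, CourseSet, Episode, InvalidInputError
from .crisis_repair import _segment

__all__ = [
    "PATTERN_LABELS",
    "PATTERN_GROUPS",
    "classify_episode",
    "classify_episodes",
    "round_percentage",
    "Summary",
    "summarize",
]

PATTERN_LABELS = ("1", "2", "3a", "3b", "4a", "4b", "5")
PATTERN_GROUPS = ("1", "2", "3", "4", "5")


def pattern_group(label: str) -> str:
    return label[0]


def _count_qualifying_declines(
    values: Sequence[float], threshold: float
) -> int:
    runs = _segment(values)
    return sum(
        1 for kind, _s, _e, cum in runs if kind == "decline" and -cum >= threshold > 0
    ) + (
        # threshold == 0: strict declines qualify, mirroring detection
        sum(1 for kind, _s, _e, cum in runs if kind == "decline" and -cum > 0)
        if threshold == 0
        else 0
    )


def classify_episode(
    episode: Episode, course: Course, threshold: float
) -> str:
    """Assign one of the seven labels to a detected episode.

    ``threshold`` must be the effective threshold the detection used; it is
    reused as the jump size for the ``a``/``b`` subtypes, so that a "jump"
    inside a slide means a single step that would have qualified as a
    rupture on its own.
    """
    if course.course_id != episode.course_id:
        raise InvalidInputError(
            f"episode belongs to course {episode.course_id!r}, "
            f"got course {course.course_id!r}"
        )
    last = episode.repair_session if episode.repair_session is not None else course.n_sessions
    if not (1 <= episode.start_session < episode.trough_session <= last <= course.n_sessions):
        raise InvalidInputError(
            f"episode sessions ({episode.start_session}, {episode.trough_session}, "
            f"{episode.repair_session}) inconsistent with course of "
            f"{course.n_sessions} sessions"
        )
    span = course.values[episode.start_session - 1 : last]
    if _count_qualifying_declines(span, threshold) >= 2:
        return "5"
    decline_length = episode.decline_length
    repair_length = episode.repair_length  # None when unrepaired
    if decline_length == 1:
        return "1" if repair_length in (1, None) else "2"
    decline = course.values[episode.start_session - 1 : episode.trough_session]
    has_jump = any(
        decline[i] - decline[i + 1] >= threshold and decline[i] - decline[i + 1] > 0
        for i in range(len(decline) - 1)
    )
    sub = "b" if has_jump else "a"
    return ("3" if repair_length in (1, None) else "4") + sub


def classify_episodes(
    episodes: Iterable[Episode], course: Course, threshold: float
) -> List[Episode]:
    """Label a course's episodes, returning relabelled copies."""
    return [e.relabelled(classify_episode(e, course, threshold)) for e in episodes]


def round_percentage(count: int, total: int) -> float:
    """Percentage to one decimal, rounding halves away from zero."""
    if total == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Summary:
    """Frequency table of the labelled episodes of one analysis run.

    Length statistics (histograms and means) exclude complex (pattern-5)
    episodes; the means are over repaired, non-complex episodes so that
    mean episode length = mean decline + mean repair length.
    """

    n_episodes: int
    counts: Dict[str, int]
    percentages: Dict[str, float]
    group_counts: Dict[str, int]
    group_percentages: Dict[str, float]
    courses_with_episode: Dict[str, int]
    n_courses_with_episode: int
    n_courses_without_episode: int
    decline_length_hist: Dict[int, int]
    repair_length_hist: Dict[int, int]
    mean_decline_length: Optional[float]
    mean_repair_length: Optional[float]
    mean_episode_length: Optional[float]
    empty: bool = False

    def to_table(self) -> pd.DataFrame:
        """Table-shaped frame: totals, percentages and course counts per pattern."""
        cols = ["1", "2", "3 (3a, 3b)", "4 (4a, 4b)", "complex"]
        d2 = self.counts
        total_row = [
            self.group_counts["1"],
            self.group_counts["2"],
            f"{self.group_counts['3']} ({d2['3a']}, {d2['3b']})",
            f"{self.group_counts['4']} ({d2['4a']}, {d2['4b']})",
            self.group_counts["5"],
        ]
        d2 = self.percentages
        pct_row = [
            self.group_percentages["1"],
            self.group_percentages["2"],
            f"{self.group_percentages['3']} ({d2['3a']}, {d2['3b']})",
            f"{self.group_percentages['4']} ({d2['4a']}, {d2['4b']})",
            self.group_percentages["5"],
        ]
        d2 = self.courses_with_episode
        course_row = [
            d2["1"],
            d2["2"],
            f"{d2['3']} ({d2['3a']}, {d2['3b']})",
            f"{d2['4']} ({d2['4a']}, {d2['4b']})",
            d2["5"],
        ]
        return pd.DataFrame(
            [total_row, pct_row, course_row],
            index=["Total CREs", "%", "Courses with at least one CRE"],
            columns=cols,
        )

    def to_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "group_counts": dict(self.group_counts),
            "group_percentages": dict(self.group_percentages),
            "courses_with_episode": dict(self.courses_with_episode),
            "n_courses_with_episode": self.n_courses_with_episode,
            "n_courses_without_episode": self.n_courses_without_episode,
            "decline_length_hist": {str(k): v for k, v in self.decline_length_hist.items()},
            "repair_length_hist": {str(k): v for k, v in self.repair_length_hist.items()},
            "mean_decline_length": self.mean_decline_length,
            "mean_repair_length": self.mean_repair_length,
            "mean_episode_length": self.mean_episode_length,
            "empty": self.empty,
        }


def summarize(
    episodes: Iterable[Episode],
    course_set: Optional[CourseSet] = None,
) -> Summary:
    """Tabulate labelled episodes: counts, percentages, lengths.

    Every episode must carry a ``pattern`` label.  ``course_set``, when
    given, supplies the denominator for courses without any episode.
    """
    eps = list(episodes)
    for e in eps:
        if e.pattern not in PATTERN_LABELS:
            raise InvalidInputError(
                f"episode at session {e.start_session} of course "
                f"{e.course_id!r} has no valid pattern label (got {e.pattern!r})"
            )
    n = len(eps)
    counts = {lab: 0 for lab in PATTERN_LABELS}
    for e in eps:
        counts[e.pattern] += 1
    group_counts = {
        g: sum(v for k, v in counts.items() if k[0] == g) for g in PATTERN_GROUPS
    }
    percentages = {lab: round_percentage(c, n) for lab, c in counts.items()}
    group_percentages = {g: round_percentage(c, n) for g, c in group_counts.items()}

    courses_with = {}
    for key in list(PATTERN_LABELS) + list(PATTERN_GROUPS):
        group = len(key) == 1
        ids = {
            e.course_id
            for e in eps
            if (e.pattern[0] == key if group else e.pattern == key)
        }
        courses_with[key] = len(ids)
    any_ids = {e.course_id for e in eps}
    n_with = len(any_ids)
    n_without = (len(course_set) - n_with) if course_set is not None else 0

    simple = [e for e in eps if e.pattern != "5"]
    decline_hist: Dict[int, int] = {}
    for e in simple:
        decline_hist[e.decline_length] = decline_hist.get(e.decline_length, 0) + 1
    repaired_simple = [e for e in simple if e.repaired]
    repair_hist: Dict[int, int] = {}
    for e in repaired_simple:
        repair_hist[e.repair_length] = repair_hist.get(e.repair_length, 0) + 1

    if repaired_simple:
        mean_decline = sum(e.decline_length for e in repaired_simple) / len(repaired_simple)
        mean_repair = sum(e.repair_length for e in repaired_simple) / len(repaired_simple)
        mean_episode = sum(e.episode_length for e in repaired_simple) / len(repaired_simple)
    else:
        mean_decline = mean_repair = mean_episode = None

    return Summary(
        n_episodes=n,
        counts=counts,
        percentages=percentages,
        group_counts=group_counts,
        group_percentages=group_percentages,
        courses_with_episode=courses_with,
        n_courses_with_episode=n_with,
        n_courses_without_episode=n_without,
        decline_length_hist=dict(sorted(decline_hist.items())),
        repair_length_hist=dict(sorted(repair_hist.items())),
        mean_decline_length=mean_decline,
        mean_repair_length=mean_repair,
        mean_episode_length=mean_episode,
        empty=(n == 0),
    )
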