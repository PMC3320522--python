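"""Core domain types for session-rating time series.

A *course* is one course of psychotherapy represented as an ordered series of
one numeric rating per session (e.g. a weighted affiliation index completed
after every session).  Rupture/repair criteria compare declines in this series
against a variability threshold expressed in standard-deviation units; this
module holds the course container and the intra-/interindividual SD machinery
shared by all criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

__all__ = [
    "InvalidInputError",
    "ConfigurationError",
    "Course",
    "CourseSet",
    "VariabilityProfile",
    "Episode",
    "ThresholdMode",
    "intraindividual_sd",
    "interindividual_sd",
    "effective_threshold",
]


class InvalidInputError(ValueError):
    """Raised when input data violate a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when a run configuration is internally inconsistent."""


ThresholdMode = Literal["intra_only", "inter_only", "stricter"]

_VALID_MODES = ("intra_only", "inter_only", "stricter")


@dataclass(frozen=True)
class Course:
    """One course of therapy: strictly consecutive 1-based sessions, one value each.

    ``original_sessions`` is set by the sparse-schedule subsampler to record
    which sessions of the parent course the (renumbered) values came from.
    """

    course_id: str
    sessions: tuple[int, ...]
    values: tuple[float, ...]
    original_sessions: Optional[tuple[int, ...]] = None
    interpolated: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sessions", tuple(int(s) for s in self.sessions))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.sessions) != len(self.values):
            raise InvalidInputError(
                f"course {self.course_id!r}: {len(self.sessions)} sessions "
                f"but {len(self.values)} values"
            )
        if len(self.values) < 3:
            raise InvalidInputError(
                f"course {self.course_id!r}: needs at least 3 sessions "
                f"(a V-shape), got {len(self.values)}"
            )
        expected = tuple(range(1, len(self.sessions) + 1))
        if self.sessions != expected:
            raise InvalidInputError(
                f"course {self.course_id!r}: sessions must be consecutive "
                f"integers starting at 1; got {self.sessions[:8]}..."
            )
        for s, v in zip(self.sessions, self.values):
            if not math.isfinite(v):
                raise InvalidInputError(
                    f"course {self.course_id!r}: non-finite value {v!r} at session {s}"
                )

    @classmethod
    def from_values(cls, course_id: str, values: Sequence[float], **kw) -> "Course":
        return cls(course_id, tuple(range(1, len(values) + 1)), tuple(values), **kw)

    @property
    def n_sessions(self) -> int:
        return len(self.values)

    def value_at(self, session: int) -> float:
        return self.values[session - 1]


@dataclass(frozen=True)
class CourseSet:
    """A non-empty collection of courses with distinct ids."""

    courses: tuple[Course, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "courses", tuple(self.courses))
        if not self.courses:
            raise InvalidInputError("CourseSet must contain at least one course")
        ids = [c.course_id for c in self.courses]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate course ids: {dupes}")

    def __iter__(self):
        return iter(self.courses)

    def __len__(self) -> int:
        return len(self.courses)

    def get(self, course_id: str) -> Course:
        for c in self.courses:
            if c.course_id == course_id:
                return c
        raise KeyError(course_id)


def intraindividual_sd(course: Course | Sequence[float], ddof: int = 1) -> float:
    """Standard deviation of one course's session values.

    The sample SD (``ddof=1``) is the default; ``ddof=0`` selects the
    population formula for comparability with sources that used n in the
    denominator.
    """
    values = course.values if isinstance(course, Course) else tuple(course)
    n = len(values)
    if n < 2:
        raise InvalidInputError("intraindividual SD needs at least 2 sessions")
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    return math.sqrt(ss / (n - ddof))


def interindividual_sd(course_set: CourseSet, ddof: int = 1) -> float:
    """Arithmetic mean of the per-course intraindividual SDs."""
    if not isinstance(course_set, CourseSet):
        course_set = CourseSet(tuple(course_set))
    sds = [intraindividual_sd(c, ddof=ddof) for c in course_set]
    return sum(sds) / len(sds)


def effective_threshold(
    intra: float,
    inter: float,
    multiplier: int,
    mode: ThresholdMode = "stricter",
) -> float:
    """Detection threshold in rating units.

    ``mode`` selects the variability source: the interindividual SD alone
    (the original Strauss convention), the intraindividual SD alone (the
    stand-alone long-course convention), or the stricter — larger — of the
    two (the combined rule).  ``multiplier`` expresses the 1-SD vs 2-SD
    threshold choice.
    """
    if intra < 0 or inter < 0:
        raise InvalidInputError(
            f"standard deviations must be non-negative (got intra={intra}, inter={inter})"
        )
    if multiplier not in (1, 2):
        raise ConfigurationError(f"multiplier must be 1 or 2, got {multiplier!r}")
    if mode not in _VALID_MODES:
        raise ConfigurationError(f"mode must be one of {_VALID_MODES}, got {mode!r}")
    if mode == "intra_only":
        base = intra
    elif mode == "inter_only":
        base = inter
    else:
        base = max(intra, inter)
    return multiplier * base


@dataclass(frozen=True)
class VariabilityProfile:
    """Variability context for one course: intra/inter SD and the active threshold."""

    intraindividual_sd: float
    interindividual_sd: float
    multiplier: int = 1
    mode: ThresholdMode = "stricter"
    effective_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        thr = effective_threshold(
            self.intraindividual_sd,
            self.interindividual_sd,
            self.multiplier,
            self.mode,
        )
        object.__setattr__(self, "effective_threshold", thr)

    @property
    def base_sd(self) -> float:
        """The 1-SD unit the active mode selects (threshold / multiplier)."""
        return self.effective_threshold / self.multiplier

    def with_multiplier(self, multiplier: int) -> "VariabilityProfile":
        return VariabilityProfile(
            self.intraindividual_sd, self.interindividual_sd, multiplier, self.mode
        )

    @classmethod
    def for_course(
        cls,
        course: Course,
        course_set: Optional[CourseSet] = None,
        multiplier: int = 1,
        mode: ThresholdMode = "stricter",
        ddof: int = 1,
    ) -> "VariabilityProfile":
        """Build the profile for ``course`` in the context of ``course_set``.

        Without a course set (a stand-alone course, e.g. a single long-term
        therapy) the intraindividual SD is used solely and the mode is forced
        to ``intra_only``.
        """
        intra = intraindividual_sd(course, ddof=ddof)
        if course_set is None:
            return cls(intra, 0.0, multiplier, "intra_only")
        inter = interindividual_sd(course_set, ddof=ddof)
        return cls(intra, inter, multiplier, mode)


@dataclass(frozen=True)
class Episode:
    """One detected rupture/crisis-repair episode.

    ``start_session`` is the last pre-decline session (it carries the start
    value), ``trough_session`` the session of minimum value within the
    episode, ``repair_session`` the first session satisfying the criterion's
    repair rule (``None`` while unrepaired).  Lengths are in sessions:
    decline from start+1 through the trough, repair from trough+1 through the
    repair session.
    """

    course_id: str
    criterion: str
    start_session: int
    trough_session: int
    repair_session: Optional[int]
    rupture_magnitude: float
    repaired: bool
    threshold_multiplier: int = 1
    repair_magnitude: Optional[float] = None
    qualifying_decline_starts: tuple[int, ...] = ()
    has_leading_constants: bool = False
    pattern: Optional[str] = None

    @property
    def decline_length(self) -> int:
        return self.trough_session - self.start_session

    @property
    def repair_length(self) -> Optional[int]:
        if self.repair_session is None:
            return None
        return self.repair_session - self.trough_session

    @property
    def episode_length(self) -> Optional[int]:
        """Total length in sessions (decline + repair) for repaired episodes."""
        if self.repair_session is None:
            return None
        return self.repair_session - self.start_session

    def relabelled(self, pattern: str) -> "Episode":
        return Episode(
            **{**self.__dict__, "pattern": pattern}
        )
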