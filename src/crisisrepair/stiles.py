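"""Quadratic-trend regression rule for rupture sessions (Stiles-type criterion).

Each course is summarised by a quadratic regression of the rating on the
centred session number: the fitted value at midtreatment (intercept), the
linear trend (slope), the quadratic trend (curve) and the residual
root-mean-square error (RMSE).  A session is a rupture when its observed
value falls at least ``rmse_multiplier`` × RMSE below the fitted curve,
subject to the original rule's specifications: first/last sessions never
count, the value must be below the previous session's, the value must fall
below a pre-specified absolute floor, and courses with a negative linear
trend are excluded outright.  The modified preset drops the course-exclusion
parts (the negative-trend exclusion and the floor) while keeping the
per-session specifications.

This rule marks rupture *sessions* only — it defines no repair point, so the
result is a session list plus a per-course exclusion verdict, not episode
records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import ConfigurationError, Course, InvalidInputError

__all__ = [
    "StilesFit",
    "StilesConfig",
    "StilesResult",
    "fit_quadratic_course",
    "detect_stiles",
]


@dataclass(frozen=True)
class StilesFit:
    """Per-course quadratic regression parameters."""

    midtreatment_intercept: float
    slope: float
    curve: float
    rmse: float

    def predict(self, session: int, n_sessions: int) -> float:
        x = session - (n_sessions + 1) / 2.0
        return self.midtreatment_intercept + self.slope * x + self.curve * x * x


@dataclass(frozen=True)
class StilesConfig:
    """Detection flags; ``original()`` and ``modified()`` build the presets."""

    rmse_multiplier: float = 2.0
    absolute_floor: Optional[float] = None
    require_floor: bool = False
    exclude_first_last: bool = True
    exclude_negative_slope: bool = True
    require_below_previous: bool = True

    def __post_init__(self) -> None:
        if self.rmse_multiplier <= 0:
            raise ConfigurationError("rmse_multiplier must be > 0")

    @classmethod
    def original(cls, absolute_floor: float, rmse_multiplier: float = 2.0) -> "StilesConfig":
        """All four specifications active; the absolute floor is required
        because the published rule used one (its value is instrument-specific
        and must be supplied)."""
        return cls(
            rmse_multiplier=rmse_multiplier,
            absolute_floor=absolute_floor,
            require_floor=True,
        )

    @classmethod
    def modified(cls, rmse_multiplier: float = 2.0) -> "StilesConfig":
        """Course-exclusion parts disabled: no negative-trend exclusion, no floor."""
        return cls(
            rmse_multiplier=rmse_multiplier,
            absolute_floor=None,
            require_floor=False,
            exclude_negative_slope=False,
        )


@dataclass(frozen=True)
class StilesResult:
    course_id: str
    fit: StilesFit
    rupture_sessions: tuple[int, ...]
    excluded: bool = False
    exclusion_reason: Optional[str] = None


def fit_quadratic_course(course: Course, residual_df: str = "n-3") -> StilesFit:
    """Least-squares quadratic fit of value on the centred session index.

    The session index is centred at midtreatment, (n+1)/2, so the intercept
    is the fitted value at the course's temporal midpoint.  ``residual_df``
    chooses the RMSE denominator: ``"n-3"`` (residual degrees of freedom,
    default) or ``"n"``.
    """
    n = course.n_sessions
    if n < 4:
        raise InvalidInputError(
            f"course {course.course_id!r}: quadratic fit needs at least 4 sessions"
        )
    if residual_df not in ("n-3", "n"):
        raise ConfigurationError(f"residual_df must be 'n-3' or 'n', got {residual_df!r}")
    x = np.arange(1, n + 1, dtype=float) - (n + 1) / 2.0
    X = np.column_stack([np.ones(n), x, x * x])
    y = np.asarray(course.values, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    denom = n - 3 if residual_df == "n-3" else n
    rmse = float(np.sqrt(max(ssr, 0.0) / denom))
    # exact fits: clear numerical dust so rmse == 0 holds for polynomial data
    if ssr < 1e-18 * max(1.0, float(y @ y)):
        rmse = 0.0
    return StilesFit(float(beta[0]), float(beta[1]), float(beta[2]), rmse)


def _scan_ruptures(
    values,
    fitted,
    rmse: float,
    rmse_multiplier: float,
    absolute_floor: Optional[float],
    exclude_first_last: bool,
    require_below_previous: bool,
) -> List[int]:
    """Session scan shared by the public API; sessions are 1-based."""
    n = len(values)
    out: List[int] = []
    for i in range(n):
        if values[i] > fitted[i] - rmse_multiplier * rmse:
            continue
        s = i + 1
        if exclude_first_last and (s == 1 or s == n):
            continue
        if require_below_previous and (i == 0 or not values[i] < values[i - 1]):
            continue
        if absolute_floor is not None and not values[i] < absolute_floor:
            continue
        out.append(s)
    return out


def detect_stiles(
    course: Course, fit: StilesFit, config: StilesConfig
) -> StilesResult:
    """Apply the rupture rule to one fitted course."""
    if config.require_floor and config.absolute_floor is None:
        raise ConfigurationError(
            "this configuration requires an absolute_floor but none was supplied"
        )
    if config.exclude_negative_slope and fit.slope < 0:
        return StilesResult(
            course.course_id,
            fit,
            (),
            excluded=True,
            exclusion_reason="negative linear trend",
        )
    n = course.n_sessions
    fitted = [fit.predict(s, n) for s in course.sessions]
    ruptures = _scan_ruptures(
        course.values,
        fitted,
        fit.rmse,
        config.rmse_multiplier,
        config.absolute_floor,
        config.exclude_first_last,
        config.require_below_previous,
    )
    return StilesResult(course.course_id, fit, tuple(ruptures))
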