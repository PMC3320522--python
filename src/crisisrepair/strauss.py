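"""Step-level decrease/increase rule (Strauss-type criterion).

The original rule reads single session-to-session differences: a rupture is
a one-step decrease of at least the averaged (interindividual) standard
deviation, repaired by a subsequent one-step increase of the same threshold.
A course whose final rupture stays unrepaired is removed from analysis
entirely.  The modified presets apply the proposed adjustments: the stricter
of intra-/interindividual SD, an optional 2-SD threshold, no course
exclusion (unrepaired ruptures are flagged instead), repairs matched to the
rupture magnitude for deep (≥ 2 SD) ruptures, and aggregation of
consecutive threshold-reaching decreases into one rupture.

Gradual multi-step declines whose individual steps stay below the threshold
are deliberately invisible to this rule — that gap is what the cumulative
crisis-repair criterion addresses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .core import (
    ConfigurationError,
    Course,
    Episode,
    VariabilityProfile,
)

__all__ = ["StraussConfig", "StraussResult", "detect_strauss"]


@dataclass(frozen=True)
class StraussConfig:
    threshold_source: str = "inter_only"  # "inter_only" (original) | "stricter"
    multiplier: int = 1
    drop_exclusion: bool = False
    match_repair_to_rupture: bool = False
    aggregate_consecutive: bool = False

    def __post_init__(self) -> None:
        if self.threshold_source not in ("inter_only", "stricter", "intra_only"):
            raise ConfigurationError(
                f"unknown threshold_source {self.threshold_source!r}"
            )
        if self.multiplier not in (1, 2):
            raise ConfigurationError(f"multiplier must be 1 or 2, got {self.multiplier!r}")

    @classmethod
    def original(cls) -> "StraussConfig":
        return cls()

    @classmethod
    def modified(cls, multiplier: int = 1) -> "StraussConfig":
        return cls(
            threshold_source="stricter",
            multiplier=multiplier,
            drop_exclusion=True,
            match_repair_to_rupture=True,
            aggregate_consecutive=True,
        )


@dataclass(frozen=True)
class StraussResult:
    course_id: str
    episodes: tuple[Episode, ...]
    excluded: bool = False
    exclusion_reason: Optional[str] = None


def _rupture_units(diffs, threshold: float, aggregate: bool) -> List[tuple]:
    """(first_step_idx, last_step_idx, magnitude) per rupture, 0-based steps.

    Step ``i`` is the transition session i+1 → i+2.  With ``aggregate`` a
    maximal run of consecutive threshold-reaching decreases is one rupture
    whose magnitude is the summed drop; consecutive sub-threshold decreases
    never combine into a rupture.
    """
    units: List[tuple] = []
    i = 0
    m = len(diffs)
    while i < m:
        if -diffs[i] >= threshold and -diffs[i] > 0:
            j = i
            if aggregate:
                while j + 1 < m and -diffs[j + 1] >= threshold:
                    j += 1
            units.append((i, j, -sum(diffs[i : j + 1])))
            i = j + 1
        else:
            i += 1
    return units


def _scan_strauss(
    values,
    threshold: float,
    base_sd: float,
    aggregate: bool,
    match_repair: bool,
) -> List[tuple]:
    """Low-level scan on a plain value sequence.

    Returns ``(start_session, trough_session, repair_session_or_None,
    magnitude, repair_magnitude_or_None)`` with 1-based sessions.
    """
    v = values
    diffs = [v[i + 1] - v[i] for i in range(len(v) - 1)]
    units = _rupture_units(diffs, threshold, aggregate)
    out: List[tuple] = []
    for k, (i, j, magnitude) in enumerate(units):
        start_session = i + 1
        trough_session = j + 2
        # repair window: after this rupture, up to the next rupture's start
        window_end_step = units[k + 1][0] if k + 1 < len(units) else len(diffs)
        repair_session: Optional[int] = None
        repair_magnitude: Optional[float] = None
        deep = magnitude >= 2 * base_sd
        if match_repair and deep:
            # cumulative recovery from the trough must reach the rupture magnitude
            for t in range(trough_session + 1, window_end_step + 2):
                gain = v[t - 1] - v[trough_session - 1]
                if gain >= magnitude:
                    repair_session = t
                    repair_magnitude = gain
                    break
        else:
            for step in range(j + 1, window_end_step):
                if diffs[step] >= threshold and diffs[step] > 0:
                    repair_session = step + 2
                    repair_magnitude = diffs[step]
                    break
        out.append(
            (start_session, trough_session, repair_session, magnitude, repair_magnitude)
        )
    return out


def detect_strauss(
    course: Course,
    profile: VariabilityProfile,
    config: StraussConfig,
) -> StraussResult:
    """Apply the step-level rule to one course.

    The profile must have been built with the mode and multiplier the config
    names, so that the logged threshold is the one actually used.
    """
    if profile.mode != config.threshold_source:
        raise ConfigurationError(
            f"profile mode {profile.mode!r} does not match config "
            f"threshold_source {config.threshold_source!r}"
        )
    if profile.multiplier != config.multiplier:
        raise ConfigurationError(
            f"profile multiplier {profile.multiplier} does not match config "
            f"multiplier {config.multiplier}"
        )
    threshold = profile.effective_threshold
    episodes: List[Episode] = []
    for start_session, trough_session, repair_session, magnitude, repair_magnitude in _scan_strauss(
        course.values,
        threshold,
        profile.base_sd,
        config.aggregate_consecutive,
        config.match_repair_to_rupture,
    ):
        episodes.append(
            Episode(
                course_id=course.course_id,
                criterion="strauss",
                start_session=start_session,
                trough_session=trough_session,
                repair_session=repair_session,
                rupture_magnitude=magnitude,
                repaired=repair_session is not None,
                threshold_multiplier=config.multiplier,
                repair_magnitude=repair_magnitude,
            )
        )

    if not config.drop_exclusion and episodes and not episodes[-1].repaired:
        return StraussResult(
            course.course_id,
            (),
            excluded=True,
            exclusion_reason="unrepaired rupture at end of treatment",
        )
    return StraussResult(course.course_id, tuple(episodes))
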