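"""Readers/writers, the affiliation-index pre-processor, and run orchestration.

Course data travel as long-format CSV with a header row and columns
``course_id, session, value`` — one row per session, sessions 1-based and
consecutive.  The weighted affiliation index condenses per-session SASB
Intrex cluster scores (clusters 2-4, affiliative; 6-8, hostile; over two
rating directions and the transitive/intransitive foci) into the single
warmth value the criteria operate on.  Because published weighting
conventions vary, no weight set is applied silently: a named profile or an
explicit weight mapping must be selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    Course,
    CourseSet,
    Episode,
    InvalidInputError,
    VariabilityProfile,
    interindividual_sd,
    intraindividual_sd,
)
from .crisis_repair import detect_crisis_repair
from .patterns import Summary, classify_episodes, summarize
from .stiles import StilesConfig, StilesResult, detect_stiles, fit_quadratic_course
from .strauss import StraussConfig, StraussResult, detect_strauss

__all__ = [
    "read_courses",
    "write_courses",
    "episodes_to_frame",
    "IntrexRecord",
    "affiliation_index",
    "read_intrex",
    "WEIGHT_PROFILES",
    "RunConfig",
    "RunResult",
    "run_detection",
    "compare_criteria",
    "load_run_config",
]

logger = logging.getLogger("crisisrepair")

CRITERIA = (
    "stiles",
    "stiles_modified",
    "strauss",
    "strauss_modified",
    "crisis_repair",
)

REQUIRED_CLUSTERS = (2, 3, 4, 6, 7, 8)

# Example profile: unit affiliation weights (+1 affiliative, -1 hostile
# clusters).  It must be selected explicitly; instrument-specific weight
# sets can be supplied as a mapping or a YAML file.
WEIGHT_PROFILES: Dict[str, Dict[int, float]] = {
    "unit": {2: 1.0, 3: 1.0, 4: 1.0, 6: -1.0, 7: -1.0, 8: -1.0},
}


# ---------------------------------------------------------------------------
# course CSV I/O
# ---------------------------------------------------------------------------

def read_courses(path, on_gaps: str = "error") -> CourseSet:
    """Read a long-format course CSV into a validated CourseSet.

    ``on_gaps`` is ``"error"`` (default: non-consecutive sessions are an
    input error) or ``"interpolate"`` (internal gaps are filled linearly and
    flagged on the course).
    """
    if on_gaps not in ("error", "interpolate"):
        raise ConfigurationError(f"on_gaps must be 'error' or 'interpolate', got {on_gaps!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"course_id", "session", "value"} - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"input file lacks required column(s): {sorted(missing)}"
        )
    if df.empty:
        raise InvalidInputError("input file contains no data rows")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna()]
    if len(bad):
        raise InvalidInputError(
            f"non-numeric value at line {bad[0] + 2} (course "
            f"{df.loc[bad[0], 'course_id']!r}, session {df.loc[bad[0], 'session']})"
        )
    df = df.assign(value=values)
    dup = df.duplicated(subset=["course_id", "session"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise InvalidInputError(
            f"duplicated session row: course {row['course_id']!r}, "
            f"session {int(row['session'])}"
        )
    courses = []
    for cid, grp in df.groupby("course_id", sort=False):
        grp = grp.sort_values("session")
        sessions = grp["session"].astype(int).tolist()
        vals = grp["value"].astype(float).tolist()
        expected = list(range(1, max(sessions) + 1))
        if sessions != expected:
            if on_gaps == "error" or sessions[0] != 1:
                raise InvalidInputError(
                    f"course {cid!r}: sessions are not consecutive from 1 "
                    f"(got {sessions[:8]}...); pass on_gaps='interpolate' to fill "
                    "internal gaps"
                )
            filled = np.interp(expected, sessions, vals)
            gap_sessions = tuple(s for s in expected if s not in set(sessions))
            courses.append(
                Course(
                    str(cid), tuple(expected), tuple(filled.tolist()),
                    interpolated=gap_sessions,
                )
            )
            logger.warning(
                "course %s: interpolated %d missing session(s): %s",
                cid, len(gap_sessions), gap_sessions,
            )
        else:
            courses.append(Course(str(cid), tuple(sessions), tuple(vals)))
    return CourseSet(tuple(courses))


def write_courses(course_set: CourseSet | Course, path) -> None:
    """Write courses as long-format CSV (full float precision, round-trips)."""
    if isinstance(course_set, Course):
        course_set = CourseSet((course_set,))
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["course_id", "session", "value"])
        for c in course_set:
            for s, v in zip(c.sessions, c.values):
                # repr() is the shortest exact decimal: values round-trip
                writer.writerow([c.course_id, s, repr(v)])


_EPISODE_COLUMNS = [
    "course_id",
    "criterion",
    "multiplier",
    "start_session",
    "trough_session",
    "repair_session",
    "rupture_magnitude",
    "repair_magnitude",
    "decline_length",
    "repair_length",
    "repaired",
    "pattern",
]


def episodes_to_frame(episodes: Iterable[Episode]) -> pd.DataFrame:
    rows = [
        {
            "course_id": e.course_id,
            "criterion": e.criterion,
            "multiplier": e.threshold_multiplier,
            "start_session": e.start_session,
            "trough_session": e.trough_session,
            "repair_session": e.repair_session,
            "rupture_magnitude": e.rupture_magnitude,
            "repair_magnitude": e.repair_magnitude,
            "decline_length": e.decline_length,
            "repair_length": e.repair_length,
            "repaired": e.repaired,
            "pattern": e.pattern,
        }
        for e in episodes
    ]
    return pd.DataFrame(rows, columns=_EPISODE_COLUMNS)


# ---------------------------------------------------------------------------
# affiliation index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntrexRecord:
    """One rated surface of one session: direction × focus cluster scores."""

    course_id: str
    session: int
    direction: str  # "patient_to_therapist" | "therapist_to_patient"
    focus: str  # "transitive" | "intransitive"
    cluster_scores: Mapping[int, float]


def affiliation_index(
    record: IntrexRecord, weights: Mapping[int, float]
) -> float:
    """Weighted sum of the affiliation-relevant cluster scores (2-4, 6-8).

    Higher values signify an experience of affectionate interaction.
    """
    for c in REQUIRED_CLUSTERS:
        if c not in weights:
            raise InvalidInputError(f"missing weight for cluster {c}")
        if c not in record.cluster_scores:
            raise InvalidInputError(
                f"course {record.course_id!r} session {record.session}: "
                f"missing score for cluster {c}"
            )
    return float(
        sum(weights[c] * record.cluster_scores[c] for c in REQUIRED_CLUSTERS)
    )


def resolve_weights(weights: str | Mapping[int, float]) -> Dict[int, float]:
    """Accept a named profile, a YAML file path, or an explicit mapping."""
    if isinstance(weights, Mapping):
        return {int(k): float(v) for k, v in weights.items()}
    if weights in WEIGHT_PROFILES:
        return dict(WEIGHT_PROFILES[weights])
    p = Path(weights)
    if p.exists():
        import yaml

        with open(p) as fh:
            loaded = yaml.safe_load(fh)
        return {int(k): float(v) for k, v in loaded.items()}
    raise ConfigurationError(
        f"unknown weight profile {weights!r}; available: {sorted(WEIGHT_PROFILES)} "
        "or a YAML file mapping cluster -> weight"
    )


def read_intrex(path, weights: str | Mapping[int, float]) -> CourseSet:
    """Convert an Intrex cluster-score CSV into one course value per session.

    Expected columns: course_id, session, direction, focus, cluster_2..4 and
    cluster_6..8.  The per-session index is the sum of the weighted
    affiliation indices of the rated surfaces (directions × foci).
    """
    w = resolve_weights(weights)
    df = pd.read_csv(path)
    needed = {"course_id", "session", "direction", "focus"} | {
        f"cluster_{c}" for c in REQUIRED_CLUSTERS
    }
    missing = needed - set(df.columns)
    if missing:
        raise InvalidInputError(f"Intrex file lacks column(s): {sorted(missing)}")
    indices = []
    for _, row in df.iterrows():
        rec = IntrexRecord(
            str(row["course_id"]),
            int(row["session"]),
            str(row["direction"]),
            str(row["focus"]),
            {c: float(row[f"cluster_{c}"]) for c in REQUIRED_CLUSTERS},
        )
        indices.append(affiliation_index(rec, w))
    df = df.assign(_index=indices)
    agg = (
        df.groupby(["course_id", "session"], sort=False)["_index"]
        .sum()
        .reset_index()
        .rename(columns={"_index": "value"})
    )
    courses = []
    for cid, grp in agg.groupby("course_id", sort=False):
        grp = grp.sort_values("session")
        courses.append(
            Course(str(cid), tuple(grp["session"].astype(int)), tuple(grp["value"]))
        )
    return CourseSet(tuple(courses))


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one detection run.

    Criterion presets lock incompatible fields: the original Strauss preset
    forces the interindividual threshold at multiplier 1; original Stiles
    requires an absolute floor.  ``threshold_source`` defaults to the
    preset's convention when left unset.
    """

    criterion: str
    multiplier: int = 1
    threshold_source: Optional[str] = None
    rmse_multiplier: float = 2.0
    absolute_floor: Optional[float] = None
    sd_ddof: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ConfigurationError(
                f"unknown criterion {self.criterion!r}; choose from {CRITERIA}"
            )
        if self.multiplier not in (1, 2):
            raise ConfigurationError("multiplier must be 1 or 2")
        if self.criterion == "strauss":
            if self.threshold_source not in (None, "inter_only"):
                raise ConfigurationError(
                    "original Strauss preset locks threshold_source to 'inter_only'"
                )
            if self.multiplier != 1:
                raise ConfigurationError(
                    "original Strauss preset locks the multiplier to 1"
                )
        if self.criterion == "stiles" and self.absolute_floor is None:
            raise ConfigurationError(
                "original Stiles preset requires an absolute_floor"
            )
        if self.sd_ddof not in (0, 1):
            raise ConfigurationError("sd_ddof must be 0 or 1")

    @property
    def resolved_threshold_source(self) -> str:
        if self.threshold_source is not None:
            return self.threshold_source
        return "inter_only" if self.criterion == "strauss" else "stricter"


def load_run_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win over file keys."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(f"bad config key: {exc}") from exc


@dataclass
class RunResult:
    criterion: str
    counts: Dict[str, int]
    episode_table: pd.DataFrame
    summary: Optional[Summary]
    course_logs: List[dict] = field(default_factory=list)
    course_table: Optional[pd.DataFrame] = None  # per-course fits (Stiles)


def _log_course(logs: List[dict], course: Course, intra: float, inter: float,
                threshold: float, source: str, multiplier: int,
                excluded: bool = False, reason: Optional[str] = None) -> None:
    rec = {
        "course_id": course.course_id,
        "intraindividual_sd": intra,
        "interindividual_sd": inter,
        "stricter_source": "intra" if intra >= inter else "inter",
        "threshold_source": source,
        "multiplier": multiplier,
        "effective_threshold": threshold,
        "excluded": excluded,
        "exclusion_reason": reason,
    }
    logs.append(rec)
    logger.info(
        "course %s: intra SD %.4f, inter SD %.4f, source %s, threshold %.4f%s",
        course.course_id, intra, inter, source, threshold,
        f" (excluded: {reason})" if excluded else "",
    )


def run_detection(config: RunConfig, course_set: CourseSet) -> RunResult:
    """Dispatch one criterion over a course set.

    Emits the episode table, a pattern summary (crisis-repair runs), the
    per-criterion count block (total episodes/ruptures, courses with and
    without any, excluded courses) and an audit log with the thresholds
    actually used per course.
    """
    if not isinstance(course_set, CourseSet) or len(course_set) == 0:
        raise InvalidInputError("run_detection needs a non-empty CourseSet")
    logs: List[dict] = []
    inter = interindividual_sd(course_set, ddof=config.sd_ddof)

    if config.criterion in ("stiles", "stiles_modified"):
        if config.criterion == "stiles":
            scfg = StilesConfig.original(
                absolute_floor=config.absolute_floor,
                rmse_multiplier=config.rmse_multiplier,
            )
        else:
            scfg = StilesConfig.modified(rmse_multiplier=config.rmse_multiplier)
        rows, total = [], 0
        with_r = without_r = excluded_n = 0
        for course in course_set:
            intra = intraindividual_sd(course, ddof=config.sd_ddof)
            fit = fit_quadratic_course(course)
            res = detect_stiles(course, fit, scfg)
            _log_course(
                logs, course, intra, inter,
                config.rmse_multiplier * fit.rmse, "rmse", 1,
                res.excluded, res.exclusion_reason,
            )
            rows.append(
                {
                    "course_id": course.course_id,
                    "midtreatment_intercept": fit.midtreatment_intercept,
                    "slope": fit.slope,
                    "curve": fit.curve,
                    "rmse": fit.rmse,
                    "rupture_sessions": ";".join(map(str, res.rupture_sessions)),
                    "n_ruptures": len(res.rupture_sessions),
                    "excluded": res.excluded,
                    "exclusion_reason": res.exclusion_reason,
                }
            )
            if res.excluded:
                excluded_n += 1
            elif res.rupture_sessions:
                with_r += 1
                total += len(res.rupture_sessions)
            else:
                without_r += 1
        counts = {
            "total": total,
            "courses_with": with_r,
            "courses_without": without_r,
            "excluded": excluded_n,
        }
        return RunResult(
            config.criterion, counts, episodes_to_frame([]), None, logs,
            course_table=pd.DataFrame(rows),
        )

    episodes: List[Episode] = []
    with_e = without_e = excluded_n = 0
    if config.criterion in ("strauss", "strauss_modified"):
        if config.criterion == "strauss":
            cfg = StraussConfig.original()
        else:
            cfg = StraussConfig.modified(multiplier=config.multiplier)
        source = config.resolved_threshold_source if config.criterion == "strauss_modified" else "inter_only"
        cfg = StraussConfig(
            threshold_source=source,
            multiplier=cfg.multiplier,
            drop_exclusion=cfg.drop_exclusion,
            match_repair_to_rupture=cfg.match_repair_to_rupture,
            aggregate_consecutive=cfg.aggregate_consecutive,
        )
        for course in course_set:
            intra = intraindividual_sd(course, ddof=config.sd_ddof)
            profile = VariabilityProfile(intra, inter, cfg.multiplier, source)
            res = detect_strauss(course, profile, cfg)
            _log_course(
                logs, course, intra, inter, profile.effective_threshold,
                source, cfg.multiplier, res.excluded, res.exclusion_reason,
            )
            if res.excluded:
                excluded_n += 1
            elif res.episodes:
                with_e += 1
                episodes.extend(res.episodes)
            else:
                without_e += 1
        summary = None
    else:  # crisis_repair
        source = config.resolved_threshold_source
        for course in course_set:
            intra = intraindividual_sd(course, ddof=config.sd_ddof)
            profile = VariabilityProfile(intra, inter, config.multiplier, source)
            eps = detect_crisis_repair(course, profile)
            eps = classify_episodes(eps, course, profile.effective_threshold)
            _log_course(
                logs, course, intra, inter, profile.effective_threshold,
                source, config.multiplier,
            )
            if eps:
                with_e += 1
                episodes.extend(eps)
            else:
                without_e += 1
        summary = summarize(episodes, course_set)

    counts = {
        "total": len(episodes),
        "courses_with": with_e,
        "courses_without": without_e,
        "excluded": excluded_n,
    }
    return RunResult(
        config.criterion, counts, episodes_to_frame(episodes), summary, logs
    )


_COUNT_ROWS = [
    ("total", "Total CREs/RREs"),
    ("courses_with", "Courses with at least one CRE/RRE"),
    ("courses_without", "Courses with no CRE/RRE"),
    ("excluded", "Excluded courses"),
]


def compare_criteria(
    configs: Sequence[RunConfig], course_set: CourseSet
) -> tuple[pd.DataFrame, Dict[str, RunResult]]:
    """Run several criteria on one dataset; comparison table + per-run results."""
    results: Dict[str, RunResult] = {}
    for cfg in configs:
        label = cfg.criterion
        if cfg.criterion == "crisis_repair":
            label = f"crisis_repair_{cfg.multiplier}sd"
        results[label] = run_detection(cfg, course_set)
    table = pd.DataFrame(
        {
            label: [res.counts[key] for key, _ in _COUNT_ROWS]
            for label, res in results.items()
        },
        index=[name for _, name in _COUNT_ROWS],
    )
    return table, results
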