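"""Seeded generator of courses with planted crisis-repair episodes.

The study conditions this generator emulates are short psychodynamic
courses of roughly 29-35 sessions (plus one 200-session long-term course)
rated on an affiliation-index-like scale whose per-course standard
deviations are of order 38-41.  Episodes are carved into a flat baseline
*before* noise is added, so the ground truth is geometric: each planted
episode knows its exact (start, trough, repair) sessions and pattern.

Noise is independent additive Gaussian per session by default, with an
optional AR(1) coefficient because post-session ratings are plausibly
autocorrelated.  ``target_course_sd`` anchors the noise scale so that the
empirical course SD converges to the study's printed order of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import Course, InvalidInputError
from .patterns import PATTERN_LABELS

__all__ = [
    "PlantedEpisode",
    "GeneratorSpec",
    "generate_course",
    "generate_course_set",
    "figure2_fixtures",
    "study_batch",
    "subsample_schedule",
]


@dataclass(frozen=True)
class PlantedEpisode:
    """Geometry of one planted episode.

    ``start_session`` is the last pre-decline session; the decline occupies
    the next ``decline_length`` sessions and the repair the
    ``repair_length`` after that.  ``depth`` is the trough depth below
    baseline in rating units.  For the b-subtypes, ``jump_positions``
    (1-based step positions within the decline) mark steps that drop by
    ``jump_size`` each; the remaining depth is spread equally over the other
    steps.  ``steps`` overrides the derived geometry with explicit signed
    session-to-session offsets (required form for irregular shapes; the
    complex pattern has a canonical shape used when ``steps`` is omitted).
    """

    pattern: str
    start_session: int
    depth: float
    decline_length: int = 1
    repair_length: int = 1
    jump_positions: Tuple[int, ...] = ()
    jump_size: Optional[float] = None
    steps: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_LABELS:
            raise InvalidInputError(f"unknown pattern {self.pattern!r}")
        if self.depth <= 0:
            raise InvalidInputError("depth must be positive")
        if self.start_session < 1:
            raise InvalidInputError("start_session must be >= 1")
        if self.steps is not None:
            object.__setattr__(self, "steps", tuple(float(s) for s in self.steps))
            return
        dl, rl = self.decline_length, self.repair_length
        wants_jump = self.pattern in ("3b", "4b")
        checks = {
            "1": dl == 1 and rl == 1,
            "2": dl == 1 and rl >= 2,
            "3a": dl >= 2 and rl == 1,
            "3b": dl >= 2 and rl == 1,
            "4a": dl >= 2 and rl >= 2,
            "4b": dl >= 2 and rl >= 2,
            "5": True,
        }
        if not checks[self.pattern]:
            raise InvalidInputError(
                f"pattern {self.pattern}: decline_length={dl}, repair_length={rl} "
                "inconsistent with the pattern definition"
            )
        if wants_jump and not self.jump_positions:
            raise InvalidInputError(
                f"pattern {self.pattern} requires at least one jump position"
            )
        if not wants_jump and self.pattern != "5" and self.jump_positions:
            raise InvalidInputError(
                f"pattern {self.pattern} admits no jump positions"
            )
        if any(not (1 <= p <= dl) for p in self.jump_positions):
            raise InvalidInputError("jump positions must lie within the decline")

    def offsets(self) -> Tuple[float, ...]:
        """Signed step offsets from ``start_session`` onwards (sum ≈ 0 for
        repaired shapes)."""
        if self.steps is not None:
            return self.steps
        d = self.depth
        if self.pattern == "5":
            # canonical complex shape: qualifying drop, partial recovery,
            # second qualifying drop, full repair
            return (-d, 0.25 * d, -0.75 * d, 1.5 * d)
        dl, rl = self.decline_length, self.repair_length
        njump = len(self.jump_positions)
        if njump:
            jump = self.jump_size if self.jump_size is not None else 0.6 * d / njump
            rest = d - njump * jump
            n_small = dl - njump
            if rest < 0 or (n_small == 0 and rest > 1e-12):
                raise InvalidInputError("jump sizes exceed or underfill the depth")
            small = rest / n_small if n_small else 0.0
            if n_small and small <= 0:
                raise InvalidInputError(
                    "non-jump decline steps would not be strictly downward"
                )
            down = [
                -(jump if (i + 1) in self.jump_positions else small)
                for i in range(dl)
            ]
        else:
            down = [-d / dl] * dl
        if rl == 1:
            up = [d]
        else:
            lead = 0.2 * d / (rl - 1)
            up = [lead] * (rl - 1) + [0.8 * d]
        return tuple(down + up)

    @property
    def end_session(self) -> int:
        return self.start_session + len(self.offsets())

    def ground_truth(self, baseline: float) -> dict:
        offs = self.offsets()
        levels = np.concatenate([[0.0], np.cumsum(offs)])
        trough_rel = int(np.flatnonzero(levels == levels.min())[-1])
        return {
            "pattern": self.pattern,
            "start": self.start_session,
            "trough": self.start_session + trough_rel,
            "repair": self.end_session,
            "magnitude": float(-levels.min()),
        }


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic course."""

    n_sessions: int
    baseline: float = 100.0
    noise_sd: float = 0.0
    target_course_sd: Optional[float] = None
    planted: Tuple[PlantedEpisode, ...] = ()
    seed: int = 0
    ar_coefficient: float = 0.0
    clamp: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.n_sessions < 3:
            raise InvalidInputError("n_sessions must be >= 3")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not (0 <= abs(self.ar_coefficient) < 1):
            raise InvalidInputError("ar_coefficient must have modulus < 1")
        planted = tuple(
            sorted(self.planted, key=lambda e: e.start_session)
        )
        object.__setattr__(self, "planted", planted)
        prev_end = 0
        for ep in planted:
            if ep.start_session <= prev_end:
                raise InvalidInputError(
                    f"planted episodes overlap near session {ep.start_session}"
                )
            if ep.end_session > self.n_sessions:
                raise InvalidInputError(
                    f"planted episode ending at session {ep.end_session} exceeds "
                    f"the course length {self.n_sessions}"
                )
            prev_end = ep.end_session

    @property
    def effective_noise_sd(self) -> float:
        return self.target_course_sd if self.target_course_sd is not None else self.noise_sd


def _noise(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    sd = spec.effective_noise_sd
    n = spec.n_sessions
    if sd == 0:
        return np.zeros(n)
    z = rng.normal(0.0, sd, n)
    phi = spec.ar_coefficient
    if phi == 0:
        return z
    e = np.empty(n)
    e[0] = z[0]
    innov_scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov_scale * z[t]
    return e


def generate_course(
    spec: GeneratorSpec, course_id: str = "synthetic"
) -> Tuple[Course, List[dict]]:
    """Build one course and its planted ground truth.

    Reproducible: the same spec (including seed) always yields the same
    course.  With ``noise_sd = 0`` the values pass through the planted
    geometry exactly.
    """
    values = np.full(spec.n_sessions, float(spec.baseline))
    truth: List[dict] = []
    for ep in spec.planted:
        offs = np.cumsum(ep.offsets())
        sl = slice(ep.start_session, ep.start_session + len(offs))
        values[sl] += offs
        truth.append(ep.ground_truth(spec.baseline))
    rng = np.random.default_rng(spec.seed)
    values = values + _noise(spec, rng)
    if spec.clamp is not None:
        values = np.clip(values, spec.clamp[0], spec.clamp[1])
    return Course.from_values(course_id, values.tolist()), truth


def generate_course_set(
    specs: Sequence[GeneratorSpec], prefix: str = "course"
) -> Tuple["CourseSet", dict]:
    """Generate several courses; returns the set and per-course ground truth."""
    from .core import CourseSet

    courses, truths = [], {}
    for k, spec in enumerate(specs, start=1):
        cid = f"{prefix}{k:02d}"
        course, truth = generate_course(spec, cid)
        courses.append(course)
        truths[cid] = truth
    return CourseSet(tuple(courses)), truths


def figure2_fixtures(
    baseline: float = 50.0, threshold: float = 10.0
) -> List[Course]:
    """Five minimal noise-free courses realising patterns 1-5 at ``threshold``.

    Each fixture contains exactly one episode when detected at the stated
    threshold; the complex fixture's two qualifying declines merge into one
    episode.
    """
    t = threshold
    shapes = {
        "pattern1": [0, 0, 0, 0, -2.0, 0, 0, 0, 0],
        "pattern2": [0, 0, 0, -2.6, -1.2, 0, 0, 0, 0],
        "pattern3": [0, 0, -0.8, -1.6, -2.4, 0, 0, 0, 0],
        "pattern4": [0, -0.8, -1.6, -2.4, -1.7, -1.1, 0, 0, 0],
        "pattern5": [0, 0, -2.0, -1.2, -3.0, 0, 0, 0, 0],
    }
    return [
        Course.from_values(name, [baseline + off * t for off in offsets])
        for name, offsets in shapes.items()
    ]


_STUDY_PATTERN_POOL = (
    # weighted towards the V-shape and the slide-in-with-jump shapes, the
    # mixture observed in session-rating series of this kind
    ("1",) * 8 + ("3b",) * 6 + ("3a",) * 2 + ("2",) + ("4a",) + ("4b",) + ("5",)
)


def _random_planted(pattern: str, start: int, depth: float, rng: np.random.Generator) -> PlantedEpisode:
    if pattern == "1":
        return PlantedEpisode("1", start, depth)
    if pattern == "2":
        return PlantedEpisode("2", start, depth, repair_length=2)
    if pattern in ("3a", "3b", "4a", "4b"):
        dl = int(rng.integers(2, 4))
        rl = 1 if pattern[0] == "3" else 2
        jumps = (int(rng.integers(1, dl + 1)),) if pattern[1] == "b" else ()
        return PlantedEpisode(
            pattern, start, depth, decline_length=dl, repair_length=rl,
            jump_positions=jumps,
        )
    return PlantedEpisode("5", start, depth)


def study_batch(
    seed: int,
    n_courses: int = 10,
    session_range: Tuple[int, int] = (29, 35),
    include_long_course: bool = False,
    long_sessions: int = 200,
    baseline: float = 100.0,
    noise_sd: float = 18.0,
    episode_depth_range: Tuple[float, float] = (80.0, 130.0),
    episodes_per_course: Tuple[int, int] = (3, 4),
    long_course_episodes: int = 18,
):
    """Generate a study-scale batch of courses with planted episodes.

    Defaults emulate the study conditions this package targets: ten courses of 29-35
    sessions whose per-course SDs land around 38-41 (episode depths of
    80-130 rating units over a noise floor of SD 18 supply most of that
    variability, as crises do in real series), roughly 3-4 episodes per
    short course, and optionally one 200-session long course analysed
    stand-alone.  Returns ``(course_set, truths)`` plus the long course as a
    separate ``(course, truth)`` pair when requested.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_courses):
        n = int(rng.integers(session_range[0], session_range[1] + 1))
        k = int(rng.integers(episodes_per_course[0], episodes_per_course[1] + 1))
        planted = []
        pos = int(rng.integers(2, 5))
        for _ in range(k):
            pattern = _STUDY_PATTERN_POOL[rng.integers(len(_STUDY_PATTERN_POOL))]
            depth = float(rng.uniform(*episode_depth_range))
            ep = _random_planted(pattern, pos, depth, rng)
            if ep.end_session > n - 1:
                break
            planted.append(ep)
            pos = ep.end_session + int(rng.integers(1, 5))
        specs.append(
            GeneratorSpec(
                n_sessions=n,
                baseline=baseline,
                noise_sd=noise_sd,
                planted=tuple(planted),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    course_set, truths = generate_course_set(specs)
    if not include_long_course:
        return course_set, truths
    planted = []
    pos = int(rng.integers(2, 6))
    for _ in range(long_course_episodes):
        pattern = _STUDY_PATTERN_POOL[rng.integers(len(_STUDY_PATTERN_POOL))]
        depth = float(rng.uniform(*episode_depth_range))
        ep = _random_planted(pattern, pos, depth, rng)
        if ep.end_session > long_sessions - 1:
            break
        planted.append(ep)
        pos = ep.end_session + int(rng.integers(2, 9))
    long_spec = GeneratorSpec(
        n_sessions=long_sessions,
        baseline=baseline,
        noise_sd=noise_sd,
        planted=tuple(planted),
        seed=int(rng.integers(2**31 - 1)),
    )
    long_course, long_truth = generate_course(long_spec, "long01")
    return course_set, truths, long_course, long_truth


def subsample_schedule(course: Course, schedule: Sequence[int]) -> Course:
    """Restrict a course to a sparse measurement schedule.

    The result is renumbered 1..k with the original session numbers kept in
    ``original_sessions``; it demonstrates how sparse schedules distort
    detection (a gradual slide collapses into a single jump).
    """
    sched = tuple(int(s) for s in schedule)
    if len(sched) < 3:
        raise InvalidInputError("schedule must keep at least 3 sessions")
    if list(sched) != sorted(set(sched)):
        raise InvalidInputError("schedule must be strictly increasing")
    if sched[0] < 1 or sched[-1] > course.n_sessions:
        raise InvalidInputError(
            f"schedule {sched} outside course sessions 1..{course.n_sessions}"
        )
    values = [course.value_at(s) for s in sched]
    return Course(
        course_id=f"{course.course_id}[subsampled]",
        sessions=tuple(range(1, len(sched) + 1)),
        values=tuple(values),
        original_sessions=sched,
    )
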