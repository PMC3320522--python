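"""Independent brute-force oracles used to cross-check the detection scans.

Each oracle applies the criterion definitions literally and from scratch
(quantifiers evaluated by enumeration, per-position segment recomputation),
deliberately sharing no code with the package's incremental scan
implementations.
"""

from __future__ import annotations

import itertools
import statistics
from typing import List, Optional, Sequence, Tuple


def sample_sd(values: Sequence[float]) -> float:
    """Textbook sample SD (n-1 denominator)."""
    return statistics.stdev(values)


def runs_by_groupby(values: Sequence[float]) -> List[Tuple[str, int, int, float]]:
    """Run segmentation via itertools.groupby on the step direction.

    Constant steps are grouped with declines (not a direction change).
    Returns (kind, start_idx, end_idx, cumulative) with 0-based indices.
    """
    diffs = [b - a for a, b in zip(values, values[1:])]
    runs = []
    idx = 0
    for up, grp in itertools.groupby(diffs, key=lambda d: d > 0):
        size = len(list(grp))
        start, end = idx, idx + size
        runs.append(
            ("incline" if up else "decline", start, end, values[end] - values[start])
        )
        idx = end
    return runs


def crisis_repair_oracle(
    values: Sequence[float], threshold: float
) -> List[Tuple[int, int, Optional[int]]]:
    """Literal crisis-repair detection: (start, trough, repair) index triples.

    For every candidate repair session t the definition is re-evaluated from
    scratch: the trough is the last minimum of the values after the start up
    to t, there must exist a strictly upward step after that trough, and
    value(t) must lie within the threshold of the start value.
    """
    n = len(values)
    runs = runs_by_groupby(values)
    qualifying = [
        r for r in runs if r[0] == "decline" and -r[3] >= threshold and r[3] < 0
    ]
    episodes: List[Tuple[int, int, Optional[int]]] = []
    next_free = 0
    for _kind, s, _e, _cum in qualifying:
        if s < next_free:
            continue  # merged into the previous (complex or unrepaired) episode
        j = s
        while values[j + 1] >= values[j]:
            j += 1
        start = j
        repair: Optional[int] = None
        for t in range(start + 1, n):
            segment = values[start + 1 : t + 1]
            low = min(segment)
            trough = start + 1 + max(i for i, v in enumerate(segment) if v == low)
            has_up = any(
                values[u] > values[u - 1] for u in range(trough + 1, t + 1)
            )
            if has_up and values[t] >= values[start] - threshold:
                repair = t
                break
        end = repair if repair is not None else n - 1
        segment = values[start + 1 : end + 1]
        low = min(segment)
        trough = start + 1 + max(i for i, v in enumerate(segment) if v == low)
        episodes.append((start, trough, repair))
        next_free = end if repair is not None else n
    return episodes


def strauss_oracle(
    values: Sequence[float],
    threshold: float,
    base_sd: Optional[float] = None,
    aggregate: bool = False,
    match_repair: bool = False,
    drop_exclusion: bool = False,
):
    """Literal step-level rule.

    Returns ``(episodes, excluded)`` where each episode is
    ``(start, trough, repair, magnitude)`` with 1-based sessions.
    """
    if base_sd is None:
        base_sd = threshold
    diffs = [b - a for a, b in zip(values, values[1:])]
    marks = [i for i, d in enumerate(diffs) if -d >= threshold and -d > 0]
    # group consecutive marked steps into one rupture when aggregating
    units = []
    for mark in marks:
        if aggregate and units and mark == units[-1][-1] + 1:
            units[-1].append(mark)
        else:
            units.append([mark])
    episodes = []
    for k, unit in enumerate(units):
        first, last = unit[0], unit[-1]
        magnitude = -sum(diffs[i] for i in unit)
        limit = units[k + 1][0] if k + 1 < len(units) else len(diffs)
        repair = None
        if match_repair and magnitude >= 2 * base_sd:
            # repair window runs to the next rupture's start session inclusive
            candidates = [
                t
                for t in range(last + 2, limit + 1)
                if values[t] - values[last + 1] >= magnitude
            ]
            if candidates:
                repair = min(candidates) + 1  # to 1-based session
        else:
            candidates = [
                r for r in range(last + 1, limit) if diffs[r] >= threshold and diffs[r] > 0
            ]
            if candidates:
                repair = min(candidates) + 2
        episodes.append((first + 1, last + 2, repair, magnitude))
    excluded = bool(episodes) and episodes[-1][2] is None and not drop_exclusion
    if excluded:
        return [], True
    return episodes, False


def stiles_condition_oracle(
    values: Sequence[float],
    fitted: Sequence[float],
    rmse: float,
    slope: float,
    rmse_multiplier: float = 2.0,
    absolute_floor: Optional[float] = None,
    exclude_first_last: bool = True,
    exclude_negative_slope: bool = True,
    require_below_previous: bool = True,
):
    """Check every session against the four specifications independently.

    Returns ``(rupture_sessions, excluded)``.
    """
    if exclude_negative_slope and slope < 0:
        return [], True
    n = len(values)
    ruptures = []
    for s in range(1, n + 1):
        v = values[s - 1]
        conditions = [v <= fitted[s - 1] - rmse_multiplier * rmse]
        if exclude_first_last:
            conditions.append(s != 1 and s != n)
        if require_below_previous:
            conditions.append(s > 1 and v < values[s - 2])
        if absolute_floor is not None:
            conditions.append(v < absolute_floor)
        if all(conditions):
            ruptures.append(s)
    return ruptures, False
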