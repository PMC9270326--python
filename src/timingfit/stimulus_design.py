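"""Stimulus schedules for sub-second visual event timing experiments.

An experiment presents brief visual events whose *duration* (onset to
offset) and *period* (onset to next onset) vary in 50 ms steps between
50 and 1000 ms.  Four condition blocks disambiguate duration, period and
luminance responses:

``constant_luminance``
    duration and period are equal and sweep together, so mean luminance
    is constant while timing changes.
``constant_duration``
    duration fixed at 50 ms, period sweeps.
``constant_period``
    period fixed at 1000 ms, duration sweeps.
``gaps``
    four short progressions that sample duration/period combinations the
    other conditions miss.

Each timing step nominally occupies one fMRI volume (TR = 2100 ms), a
block lasts 56 TRs (117.6 s) and a run concatenates the four blocks in
one of the 24 possible orders (224 TRs, 470.4 s).  Events tile the block
contiguously, so the number of repeats per step is chosen greedily to
keep the cumulative schedule close to the nominal TR grid (see
:func:`build_condition_schedule`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import pandas as pd

TR_MS = 2100
BLOCK_MS = 117_600
BLOCK_TRS = BLOCK_MS // TR_MS  # 56
RUN_TRS = 4 * BLOCK_TRS  # 224

CONDITIONS = ("constant_luminance", "constant_duration", "constant_period", "gaps")

#: short aliases accepted by the CLI
CONDITION_ALIASES = {
    "CL": "constant_luminance",
    "CD": "constant_duration",
    "CP": "constant_period",
    "G": "gaps",
}

_SWEEP_STEPS_MS = range(50, 1001, 50)  # 20 steps


@dataclass(frozen=True, order=True)
class EventTiming:
    """Duration and period of one repeating visual event, in ms."""

    duration_ms: int
    period_ms: int

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.period_ms <= 0:
            raise ValueError("duration and period must be positive")
        if self.duration_ms > self.period_ms:
            raise ValueError(
                f"duration {self.duration_ms} ms exceeds period {self.period_ms} ms"
            )

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    @property
    def period_s(self) -> float:
        return self.period_ms / 1000.0

    @property
    def frequency_hz(self) -> float:
        return 1000.0 / self.period_ms


@dataclass(frozen=True)
class ScheduledEvent:
    """One event placed on the block timeline (times in ms from block start)."""

    onset_ms: int
    timing: EventTiming

    @property
    def offset_ms(self) -> int:
        return self.onset_ms + self.timing.duration_ms


@dataclass(frozen=True)
class ConditionSchedule:
    condition: str
    events: tuple[ScheduledEvent, ...]
    tr_ms: int = TR_MS
    n_tr: int = BLOCK_TRS
    per_tr_timing: tuple[EventTiming, ...] = field(default=())

    @property
    def total_ms(self) -> int:
        return self.n_tr * self.tr_ms


@dataclass(frozen=True)
class RunSchedule:
    order: tuple[str, ...]
    blocks: tuple[ConditionSchedule, ...]

    @property
    def n_tr(self) -> int:
        return sum(b.n_tr for b in self.blocks)

    @property
    def total_ms(self) -> int:
        return sum(b.total_ms for b in self.blocks)


def _interval_timing(condition: str) -> EventTiming:
    # 16.8 s intervals: 50 ms events for constant_duration, 2000 ms otherwise
    dur = 50 if condition == "constant_duration" else 2000
    return EventTiming(dur, TR_MS)


def sweep_timings(condition: str, direction) -> list[EventTiming]:
    """Ordered timing steps of one sweep (20 steps) or gaps progression (10).

    ``direction`` is ``"ascending"``/``"descending"`` for the three standard
    conditions, or a segment index 1-4 for the gaps condition.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "gaps":
        if direction not in (1, 2, 3, 4):
            raise ValueError("gaps segment index must be 1, 2, 3 or 4")
        inc = list(range(50, 501, 50))
        dec = inc[::-1]
        if direction == 1:
            durs, pers = inc, list(range(950, 499, -50))
        elif direction == 2:
            durs, pers = inc, list(range(550, 1001, 50))
        elif direction == 3:
            durs, pers = dec, list(range(500, 951, 50))
        else:
            durs, pers = dec, list(range(1000, 549, -50))
        return [EventTiming(d, p) for d, p in zip(durs, pers)]

    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    steps = list(_SWEEP_STEPS_MS)
    if direction == "descending":
        steps = steps[::-1]
    if condition == "constant_luminance":
        timings = [EventTiming(s, s) for s in steps]
    elif condition == "constant_duration":
        timings = [EventTiming(50, s) for s in steps]
    else:  # constant_period
        timings = [EventTiming(s, 1000) for s in steps]
    return timings


def _segments(condition: str) -> list[tuple[EventTiming, int]]:
    """Block plan as (timing step, nominal step duration in ms) pairs."""
    if condition == "gaps":
        sep = EventTiming(50, TR_MS)
        plan: list[tuple[EventTiming, int]] = []
        for seg in (1, 2, 3, 4):
            plan += [(t, TR_MS) for t in sweep_timings("gaps", seg)]
            plan.append((sep, 14_700 if seg == 4 else 6_300))
        return plan
    iv = _interval_timing(condition)
    plan = [(t, TR_MS) for t in sweep_timings(condition, "ascending")]
    plan.append((iv, 16_800))
    plan += [(t, TR_MS) for t in sweep_timings(condition, "descending")]
    plan.append((iv, 16_800))
    return plan


def build_condition_schedule(condition: str) -> ConditionSchedule:
    """Tile one 56-TR condition block with events.

    Events tile contiguously.  For each timing step the repeat count is
    chosen from {floor, ceil} of (nominal step duration / period) to
    minimize the absolute drift of the cumulative schedule time from the
    nominal step boundary (ties broken toward the smaller count).  Trailing
    events that would not finish before the block end are dropped.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    events: list[ScheduledEvent] = []
    t = 0  # actual cumulative time
    nominal = 0
    for timing, step_ms in _segments(condition):
        nominal += step_ms
        p = timing.period_ms
        lo = max((nominal - t) // p, 0)
        best_n, best_err = lo, abs(t + lo * p - nominal)
        err_hi = abs(t + (lo + 1) * p - nominal)
        if err_hi < best_err:
            best_n = lo + 1
        for _ in range(best_n):
            if t + timing.duration_ms <= BLOCK_MS:
                events.append(ScheduledEvent(t, timing))
            t += p
    ev = tuple(events)
    per_tr = tuple(_per_tr_timing(ev))
    return ConditionSchedule(condition=condition, events=ev, per_tr_timing=per_tr)


def _per_tr_timing(events: tuple[ScheduledEvent, ...]) -> list[EventTiming]:
    """Majority-occupancy timing label per TR; ties go to the later step."""
    # order of first appearance = timing step order within the block
    order: dict[EventTiming, int] = {}
    for e in events:
        if e.timing not in order:
            order[e.timing] = len(order)
    labels = []
    for k in range(BLOCK_TRS):
        w0, w1 = k * TR_MS, (k + 1) * TR_MS
        occ: dict[EventTiming, int] = {}
        for e in events:
            span0, span1 = e.onset_ms, min(e.onset_ms + e.timing.period_ms, BLOCK_MS)
            ov = min(span1, w1) - max(span0, w0)
            if ov > 0:
                occ[e.timing] = occ.get(e.timing, 0) + ov
        if not occ:
            labels.append(labels[-1])  # silent tail of the block keeps last label
            continue
        best = max(occ.items(), key=lambda kv: (kv[1], order[kv[0]]))
        labels.append(best[0])
    return labels


def per_tr_timing(schedule: ConditionSchedule) -> list[EventTiming]:
    return list(schedule.per_tr_timing)


def build_run_schedule(order) -> RunSchedule:
    """Concatenate the four condition blocks in the given order."""
    order = tuple(CONDITION_ALIASES.get(o, o) for o in order)
    if sorted(order) != sorted(CONDITIONS):
        raise ValueError(f"order must be a permutation of {CONDITIONS}, got {order}")
    return RunSchedule(order=order, blocks=tuple(build_condition_schedule(c) for c in order))


def all_run_orders() -> list[tuple[str, ...]]:
    return [tuple(p) for p in itertools.permutations(CONDITIONS)]


def event_offsets(schedule) -> list[tuple[int, EventTiming]]:
    """(offset time, timing) per event; run blocks shifted to global time."""
    if isinstance(schedule, ConditionSchedule):
        return [(e.offset_ms, e.timing) for e in schedule.events]
    out = []
    shift = 0
    for block in schedule.blocks:
        out += [(e.offset_ms + shift, e.timing) for e in block.events]
        shift += block.total_ms
    return out


def max_onset_drift_ms(schedule: ConditionSchedule) -> int:
    """Largest deviation of any timing-step change from the nominal TR grid.

    Reported (not asserted) as a soft check on the greedy tiling rule.
    """
    drift = 0
    # boundaries: onset of the first event of each step vs the nominal grid
    step_starts = []
    prev = None
    for e in schedule.events:
        if e.timing != prev:
            step_starts.append(e.onset_ms)
            prev = e.timing
    for onset in step_starts:
        nearest = round(onset / TR_MS) * TR_MS
        drift = max(drift, abs(onset - nearest))
    return drift


# ---------------------------------------------------------------------------
# serialization


def schedule_to_frame(schedule) -> pd.DataFrame:
    """Tidy event table (one row per event) for a condition block or a run."""
    rows = []
    blocks = schedule.blocks if isinstance(schedule, RunSchedule) else (schedule,)
    shift = 0
    for bi, block in enumerate(blocks):
        for ei, e in enumerate(block.events):
            rows.append(
                dict(
                    block=bi,
                    condition=block.condition,
                    event_index=ei,
                    onset_ms=e.onset_ms + shift,
                    offset_ms=e.offset_ms + shift,
                    duration_ms=e.timing.duration_ms,
                    period_ms=e.timing.period_ms,
                )
            )
        shift += block.total_ms
    return pd.DataFrame(rows)


def design_summary(schedule) -> str:
    """JSON design summary with the per-TR timing table."""
    blocks = schedule.blocks if isinstance(schedule, RunSchedule) else (schedule,)
    out = {
        "tr_ms": TR_MS,
        "n_tr": sum(b.n_tr for b in blocks),
        "blocks": [
            {
                "condition": b.condition,
                "n_events": len(b.events),
                "per_tr_timing": [
                    {"duration_ms": t.duration_ms, "period_ms": t.period_ms}
                    for t in b.per_tr_timing
                ],
            }
            for b in blocks
        ],
    }
    return json.dumps(out, indent=1)
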