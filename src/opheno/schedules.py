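"""Deterministic schedule-of-reinforcement state machines.

Each operant session is represented as a timed stream of lever presses
(:class:`PressStream`) that is transformed into an :class:`EventLog` by a
deterministic walk implementing one schedule of reinforcement:

* fixed ratio (FR) — every ``fixed_ratio``-th countable active press during a
  pellet period delivers a pellet, followed by a 10-s time-out in which presses
  are recorded but do not count toward the ratio;
* progressive ratio (PR) — the response requirement per pellet escalates along
  a fixed 35-step series; the last completed requirement is the breaking point;
* shock test — FR5 blocks in which the 4th countable press delivers a footshock
  without a pellet and the 5th delivers a footshock plus a pellet; the block
  resets if the 5th response does not follow the 4th within 60 s.

FR sessions are structured as two pellet periods separated by a pellet-free
period during which no pellet is available; active presses in that window are
the persistence-of-food-seeking measure.

Time is continuous, in seconds from session start.  Time-out intervals are
half-open ``[t_pellet, t_pellet + timeout_s)``: a press exactly at time-out end
counts.  Presses with equal timestamps are processed in input order.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "SessionConfig",
    "PressStream",
    "Event",
    "EventLog",
    "PR_SERIES",
    "build_pr_series",
    "run_fr_session",
    "run_pr_session",
    "run_shock_session",
    "breaking_point",
    "count_reinforcers",
    "count_shocks",
    "count_pellet_free_active",
    "count_active_presses",
    "count_inactive_presses",
]

SessionKind = Literal["fr", "pr", "shock"]

#: Escalating response requirement per pellet under the progressive-ratio
#: schedule (35 steps, 1 .. 5500).
PR_SERIES: tuple[int, ...] = (
    1, 5, 12, 21, 33, 51, 75, 90, 120, 155,
    180, 225, 260, 300, 350, 410, 465, 540, 630, 730,
    850, 1000, 1200, 1500, 1800, 2100, 2400, 2700, 3000, 3400,
    3800, 4200, 4600, 5000, 5500,
)


def build_pr_series() -> tuple[int, ...]:
    """Return the 35-step progressive-ratio escalation series (1 .. 5500)."""
    return PR_SERIES


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one operant session.

    The default FR structure is the long protocol: a 25-min pellet period, a
    10-min pellet-free period and a second 25-min pellet period (1 h total).
    The short protocol (55/10/55 min, 2 h) is obtained by overriding the
    period durations.  ``pellet_free_s`` and ``pellet_period_2_s`` may be 0 to
    model a single continuous pellet period.
    """

    session_kind: SessionKind = "fr"
    fixed_ratio: int = 5
    pellet_period_1_s: float = 25 * 60.0
    pellet_free_s: float = 10 * 60.0
    pellet_period_2_s: float = 25 * 60.0
    timeout_s: float = 10.0
    shock_block_rules_enabled: bool = True
    pr_max_duration_s: float = 5 * 3600.0
    pr_inactivity_limit_s: float = 3600.0
    shock_session_duration_s: float = 50 * 60.0
    shock_fifth_response_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.session_kind not in ("fr", "pr", "shock"):
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.fixed_ratio < 1:
            raise ValueError("fixed_ratio must be >= 1")
        if self.timeout_s < 0:
            raise ValueError("timeout_s must be >= 0")
        if self.session_kind == "fr":
            if self.pellet_period_1_s <= 0:
                raise ValueError("pellet_period_1_s must be > 0")
            if self.pellet_free_s < 0 or self.pellet_period_2_s < 0:
                raise ValueError("period durations must be >= 0")
        for name in ("pr_max_duration_s", "pr_inactivity_limit_s",
                     "shock_session_duration_s", "shock_fifth_response_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # -- derived session geometry -------------------------------------------------

    @property
    def fr_session_duration_s(self) -> float:
        return self.pellet_period_1_s + self.pellet_free_s + self.pellet_period_2_s

    @property
    def pellet_free_interval(self) -> tuple[float, float]:
        """Half-open [start, end) of the pellet-free period (empty if 0-length)."""
        start = self.pellet_period_1_s
        return (start, start + self.pellet_free_s)

    def in_pellet_free(self, t: float) -> bool:
        lo, hi = self.pellet_free_interval
        return lo <= t < hi

    def config_hash(self) -> str:
        payload = repr(tuple(sorted(self.__dict__.items()))).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def with_kind(self, kind: SessionKind) -> "SessionConfig":
        return replace(self, session_kind=kind)


@dataclass(frozen=True)
class PressStream:
    """Ordered lever presses: times in seconds from session start, per-press lever."""

    times: np.ndarray
    active: np.ndarray  # bool; True = active lever

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        active = np.asarray(self.active, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "active", active)
        if times.shape != active.shape or times.ndim != 1:
            raise ValueError("times and active must be 1-D arrays of equal length")
        if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
            raise ValueError("press times must be nonnegative and nondecreasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_events(cls, events: Iterable[tuple[float, str]]) -> "PressStream":
        """Build from ``(time_s, lever)`` pairs with lever 'active'/'inactive'."""
        ev = list(events)
        times = np.array([t for t, _ in ev], dtype=float)
        active = np.array([lv == "active" for _, lv in ev], dtype=bool)
        return cls(times, active)

    @classmethod
    def merge(cls, a: "PressStream", b: "PressStream") -> "PressStream":
        times = np.concatenate([a.times, b.times])
        active = np.concatenate([a.active, b.active])
        order = np.argsort(times, kind="stable")
        return cls(times[order], active[order])


class Event(NamedTuple):
    time_s: float
    event_type: str  # active_press | inactive_press | pellet | shock |
    #                  period_start | period_end | timeout_start | timeout_end |
    #                  session_end
    countable: bool | None = None  # set only on presses


@dataclass
class EventLog:
    """Chronological record of one session; the source of all criterion scores."""

    mouse_id: str
    session_index: int
    session_kind: SessionKind
    config_hash: str
    events: list[Event] = field(default_factory=list)
    config: SessionConfig | None = None

    def of_type(self, *event_types: str) -> list[Event]:
        return [e for e in self.events if e.event_type in event_types]

    @property
    def n_pellets(self) -> int:
        return len(self.of_type("pellet"))

    @property
    def n_shocks(self) -> int:
        return len(self.of_type("shock"))

    def to_records(self) -> list[dict]:
        return [
            {
                "mouse_id": self.mouse_id,
                "session_index": self.session_index,
                "session_kind": self.session_kind,
                "time_s": e.time_s,
                "event_type": e.event_type,
                "countable": e.countable,
            }
            for e in self.events
        ]


class SessionOverrunWarning(UserWarning):
    """Presses beyond the session end were dropped."""


def _clip_stream(stream: PressStream, duration: float) -> PressStream:
    if len(stream) and stream.times[-1] >= duration:
        n_drop = int(np.sum(stream.times >= duration))
        warnings.warn(
            f"{n_drop} press(es) at or beyond session end ({duration} s) dropped",
            SessionOverrunWarning,
            stacklevel=3,
        )
        keep = stream.times < duration
        return PressStream(stream.times[keep], stream.active[keep])
    return stream


def run_fr_session(
    stream: PressStream,
    config: SessionConfig,
    *,
    mouse_id: str = "mouse",
    session_index: int = 0,
) -> EventLog:
    """Walk a press stream through a fixed-ratio session.

    Pellets are delivered on every ``fixed_ratio``-th countable active press
    during a pellet period; each pellet opens a ``timeout_s`` time-out in which
    presses are recorded with ``countable=False``.  No pellet is delivered in
    the pellet-free period; active presses there are recorded non-countable.
    The press counter persists across the pellet-free period.
    """
    if config.session_kind != "fr":
        raise ValueError("config.session_kind must be 'fr'")
    duration = config.fr_session_duration_s
    stream = _clip_stream(stream, duration)

    log = EventLog(mouse_id, session_index, "fr", config.config_hash(), config=config)
    ev = log.events
    free_lo, free_hi = config.pellet_free_interval

    # Period boundary markers, in chronological order relative to presses: we
    # emit them lazily as the walk crosses each boundary.
    boundaries: list[tuple[float, str]] = [(0.0, "period_start")]
    if config.pellet_free_s > 0:
        boundaries += [(free_lo, "period_end"), (free_lo, "period_start"),
                       (free_hi, "period_end"), (free_hi, "period_start")]
    boundaries.append((duration, "period_end"))
    b_idx = 0

    def emit_boundaries(upto: float) -> None:
        nonlocal b_idx
        while b_idx < len(boundaries) and boundaries[b_idx][0] <= upto:
            t, kind = boundaries[b_idx]
            ev.append(Event(t, kind))
            b_idx += 1

    counter = 0
    timeout_until = -np.inf  # half-open [t_pellet, timeout_until)
    for t, is_active in zip(stream.times, stream.active):
        emit_boundaries(t)
        if not is_active:
            ev.append(Event(float(t), "inactive_press", False))
            continue
        in_timeout = t < timeout_until
        in_free = free_lo <= t < free_hi
        countable = not in_timeout and not in_free
        ev.append(Event(float(t), "active_press", countable))
        if countable:
            counter += 1
            if counter == config.fixed_ratio:
                ev.append(Event(float(t), "pellet"))
                counter = 0
                ev.append(Event(float(t), "timeout_start"))
                timeout_until = t + config.timeout_s
                ev.append(Event(min(timeout_until, duration), "timeout_end"))
    emit_boundaries(duration)
    ev.append(Event(duration, "session_end"))
    _sort_events(log)
    return log


def _sort_events(log: EventLog) -> None:
    # Stable sort by time only: simultaneous events keep emission order,
    # except timeout_end markers scheduled in the future, which must move
    # after intervening presses.
    log.events.sort(key=lambda e: e.time_s)


PRPolicy = Callable[[int, int], Sequence[float]]
"""Policy callback: ``policy(requirement, ratio_index)`` returns the
inter-press intervals (s) the animal emits while working on that requirement.
Returning fewer than ``requirement`` intervals means the animal quits and
stops responding for the rest of the session."""


def run_pr_session(
    policy: PRPolicy,
    series: Sequence[int] = PR_SERIES,
    config: SessionConfig | None = None,
    *,
    mouse_id: str = "mouse",
    session_index: int = 0,
) -> EventLog:
    """Run a progressive-ratio session driven by a response-emitting policy.

    The session is one continuous period.  After each pellet a ``timeout_s``
    time-out elapses before the next requirement is attempted.  The session
    ends at ``pr_max_duration_s``, or ``pr_inactivity_limit_s`` after the last
    lever response if the animal goes silent, or when the series is exhausted.
    """
    config = config or SessionConfig(session_kind="pr")
    if config.session_kind != "pr":
        raise ValueError("config.session_kind must be 'pr'")
    log = EventLog(mouse_id, session_index, "pr", config.config_hash(), config=config)
    ev = log.events
    ev.append(Event(0.0, "period_start"))

    t = 0.0
    last_response = 0.0
    end_time: float | None = None
    cap = config.pr_max_duration_s
    for idx, requirement in enumerate(series):
        intervals = list(policy(int(requirement), idx))
        quit_now = len(intervals) < requirement
        presses_done = 0
        for dt in intervals[:requirement]:
            t_next = t + max(float(dt), 0.0)
            if t_next - last_response >= config.pr_inactivity_limit_s:
                end_time = last_response + config.pr_inactivity_limit_s
                break
            if t_next >= cap:
                end_time = cap
                break
            t = t_next
            last_response = t
            ev.append(Event(t, "active_press", True))
            presses_done += 1
        if end_time is not None:
            break
        if presses_done == requirement:
            ev.append(Event(t, "pellet"))
            ev.append(Event(t, "timeout_start"))
            t_to = min(t + config.timeout_s, cap)
            ev.append(Event(t_to, "timeout_end"))
            t = t + config.timeout_s
            if t >= cap:
                end_time = cap
                break
        if quit_now:
            end_time = min(last_response + config.pr_inactivity_limit_s, cap)
            break
    if end_time is None:  # series exhausted
        end_time = min(t, cap)
    ev.append(Event(end_time, "period_end"))
    ev.append(Event(end_time, "session_end"))
    _sort_events(log)
    return log


def breaking_point(
    source: EventLog | int,
    series: Sequence[int] = PR_SERIES,
) -> int:
    """Last completed response requirement of a PR session (0 if none).

    Accepts either a PR :class:`EventLog` (completed ratios = pellets earned)
    or the number of completed ratios directly.
    """
    if isinstance(source, EventLog):
        n_completed = source.n_pellets
    else:
        n_completed = int(source)
    if n_completed < 0:
        raise ValueError("n_completed must be >= 0")
    if n_completed > len(series):
        raise ValueError(
            f"n_completed={n_completed} exceeds series length {len(series)}"
        )
    if n_completed == 0:
        return 0
    return int(series[n_completed - 1])


def run_shock_session(
    stream: PressStream,
    config: SessionConfig,
    *,
    mouse_id: str = "mouse",
    session_index: int = 0,
) -> EventLog:
    """Walk a press stream through the punished (shock) FR5 session.

    Within each FR5 block the 4th countable active press delivers a footshock
    without a pellet and the 5th delivers a footshock plus a pellet followed by
    a time-out.  If the 5th response does not occur within
    ``shock_fifth_response_window_s`` of the 4th, the block resets: the press
    counter returns to 0 and the 4th press of the new block again delivers a
    shock.  The session is a single 50-min period.
    """
    if config.session_kind != "shock":
        raise ValueError("config.session_kind must be 'shock'")
    duration = config.shock_session_duration_s
    stream = _clip_stream(stream, duration)
    log = EventLog(mouse_id, session_index, "shock", config.config_hash(), config=config)
    ev = log.events
    ev.append(Event(0.0, "period_start"))

    ratio = config.fixed_ratio
    counter = 0
    timeout_until = -np.inf
    fourth_deadline: float | None = None  # block resets at/after this time
    for t, is_active in zip(stream.times, stream.active):
        if not is_active:
            ev.append(Event(float(t), "inactive_press", False))
            continue
        if (
            config.shock_block_rules_enabled
            and fourth_deadline is not None
            and t >= fourth_deadline
        ):
            counter = 0
            fourth_deadline = None
        countable = not (t < timeout_until)
        ev.append(Event(float(t), "active_press", countable))
        if not countable:
            continue
        counter += 1
        if config.shock_block_rules_enabled and counter == ratio - 1:
            ev.append(Event(float(t), "shock"))
            fourth_deadline = t + config.shock_fifth_response_window_s
        elif counter == ratio:
            if config.shock_block_rules_enabled:
                ev.append(Event(float(t), "shock"))
            ev.append(Event(float(t), "pellet"))
            ev.append(Event(float(t), "timeout_start"))
            timeout_until = t + config.timeout_s
            ev.append(Event(min(timeout_until, duration), "timeout_end"))
            counter = 0
            fourth_deadline = None
    ev.append(Event(duration, "period_end"))
    ev.append(Event(duration, "session_end"))
    _sort_events(log)
    return log


# -- score extraction ------------------------------------------------------------


def count_reinforcers(log: EventLog) -> int:
    """Number of pellets delivered in the session."""
    return log.n_pellets


def count_shocks(log: EventLog) -> int:
    """Number of footshocks delivered in the session."""
    return log.n_shocks


def count_active_presses(log: EventLog, countable_only: bool = False) -> int:
    presses = log.of_type("active_press")
    if countable_only:
        presses = [e for e in presses if e.countable]
    return len(presses)


def count_inactive_presses(log: EventLog) -> int:
    return len(log.of_type("inactive_press"))


def count_pellet_free_active(log: EventLog) -> int:
    """Non-reinforced active presses during the pellet-free period.

    Requires the session config (FR structure) attached to the log, or infers
    the pellet-free interval as the second period of an FR log's markers.
    """
    if log.config is not None:
        lo, hi = log.config.pellet_free_interval
    else:
        starts = [e.time_s for e in log.events if e.event_type == "period_start"]
        ends = [e.time_s for e in log.events if e.event_type == "period_end"]
        if len(starts) < 3:
            return 0
        lo, hi = starts[1], sorted(ends)[1]
    if hi <= lo:
        return 0
    return sum(
        1
        for e in log.events
        if e.event_type == "active_press" and lo <= e.time_s < hi
    )
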