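"""Independent brute-force oracles used to cross-check the schedule machines.

Deliberately written as slow chronological walks with interval bookkeeping,
structurally unlike the production state machines: countability is decided by
membership tests against accumulated time-out interval lists, and ratios are
re-derived from press prefixes rather than running counters.
"""

from __future__ import annotations

import numpy as np


def oracle_fr_walk(times, active, *, ratio, timeout_s, p1, free, p2):
    """Brute-force FR session walk.

    Returns dict with press records (time, lever, countable), pellet times.
    Presses at or after session end are ignored.
    """
    duration = p1 + free + p2
    timeouts: list[tuple[float, float]] = []
    pellets: list[float] = []
    presses: list[tuple[float, str, bool]] = []
    countable_times: list[float] = []
    for t, is_active in zip(times, active):
        if t >= duration:
            continue
        if not is_active:
            presses.append((t, "inactive", False))
            continue
        in_free = (free > 0) and (p1 <= t < p1 + free)
        in_timeout = any(lo <= t < hi for lo, hi in timeouts)
        countable = (not in_free) and (not in_timeout)
        presses.append((t, "active", countable))
        if countable:
            countable_times.append(t)
            # pellet whenever the count of countable presses since the last
            # pellet reaches the ratio, re-derived from the full prefix
            n_since = len(countable_times) - len(pellets) * ratio
            if n_since == ratio:
                pellets.append(t)
                timeouts.append((t, t + timeout_s))
    return {"presses": presses, "pellets": pellets}


def oracle_shock_walk(times, active, *, ratio, timeout_s, duration, window_s):
    """Brute-force shock-session walk (FR blocks with punished 4th/5th press)."""
    timeouts: list[tuple[float, float]] = []
    pellets: list[float] = []
    shocks: list[float] = []
    presses: list[tuple[float, str, bool]] = []
    block: list[float] = []  # countable presses of the current block
    fourth_at: float | None = None
    for t, is_active in zip(times, active):
        if t >= duration:
            continue
        if not is_active:
            presses.append((t, "inactive", False))
            continue
        if fourth_at is not None and t >= fourth_at + window_s:
            block = []
            fourth_at = None
        countable = not any(lo <= t < hi for lo, hi in timeouts)
        presses.append((t, "active", countable))
        if not countable:
            continue
        block.append(t)
        if len(block) == ratio - 1:
            shocks.append(t)
            fourth_at = t
        elif len(block) == ratio:
            shocks.append(t)
            pellets.append(t)
            timeouts.append((t, t + timeout_s))
            block = []
            fourth_at = None
    return {"presses": presses, "pellets": pellets, "shocks": shocks}


def oracle_pr_completions(n_presses, series):
    """Number of completed PR ratios for a policy emitting ``n_presses``
    presses total (cumulative-sum rule)."""
    csum = np.cumsum(series)
    return int(np.searchsorted(csum, n_presses, side="right"))


def random_stream(rng, n_events, duration):
    """Random press stream: sorted uniform times, ~80 % active presses."""
    times = np.sort(rng.uniform(0, duration, size=n_events))
    active = rng.random(n_events) < 0.8
    return times, active
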