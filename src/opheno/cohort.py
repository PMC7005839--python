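"""Synthetic cohorts of virtual mice for the operant food-addiction protocol.

Each mouse carries a latent :class:`TraitProfile` that drives a stochastic
press-stream generator; the deterministic schedule machines in
:mod:`opheno.schedules` turn those streams into event logs.  Group structure
(e.g. resilient vs vulnerable) is expressed purely as shifts of the trait
distributions between :class:`GroupSpec` s — no mechanistic neural modelling.

Press emission model
--------------------
Active presses arrive as a Poisson process at ``active_rate`` presses/min
during pellet periods, scaled by ``persistence_factor`` during the pellet-free
period.  Inactive presses are an independent Poisson process at
``inactive_rate``.  During FR1 acquisition the active rate ramps up
geometrically by ``acquisition_gain`` per session toward its asymptote.  In
the progressive-ratio session the animal works at its active rate and quits
when the current response requirement exceeds ``motivation_cap``.  In the
shock session each footshock is survived with probability
``shock_continue_prob``; the first failure suppresses pressing for the rest of
the session (absorbing stop).

The module also provides :func:`simulate_null_scores`, an idealized control
score population with continuous, independent criteria.  It exists because the
expected addicted fraction under the 2-of-3 percentile rule has a closed form
(3·0.25²·0.75 + 0.25³ = 15.625 %) only when the three scores are continuous
and independent; the mechanistic generator produces discrete motivation and
shock scores for which that constant is only approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schedules import (
    PR_SERIES,
    EventLog,
    PressStream,
    SessionConfig,
    run_fr_session,
    run_pr_session,
    run_shock_session,
)

__all__ = [
    "TraitProfile",
    "GroupSpec",
    "ProtocolConfig",
    "ProtocolDataset",
    "default_group_specs",
    "sample_cohort",
    "generate_press_stream",
    "generate_shock_press_stream",
    "make_pr_policy",
    "run_protocol",
    "simulate_null_scores",
]


@dataclass(frozen=True)
class TraitProfile:
    """Latent behavioural parameters of one virtual mouse.

    active_rate / inactive_rate are presses per minute; persistence_factor
    multiplies the active rate in the pellet-free period; motivation_cap is
    the largest response requirement the mouse will complete in the PR
    session; shock_continue_prob is the per-shock probability of continuing to
    respond; acquisition_gain is the per-session learning factor during FR1.
    """

    active_rate: float = 6.0
    inactive_rate: float = 0.6
    persistence_factor: float = 0.35
    motivation_cap: int = 60
    shock_continue_prob: float = 0.35
    acquisition_gain: float = 1.3

    def __post_init__(self) -> None:
        if self.active_rate < 0 or self.inactive_rate < 0:
            raise ValueError("press rates must be >= 0")
        if self.persistence_factor < 0:
            raise ValueError("persistence_factor must be >= 0")
        if self.motivation_cap < 1:
            raise ValueError("motivation_cap must be a positive integer")
        if not 0.0 <= self.shock_continue_prob <= 1.0:
            raise ValueError("shock_continue_prob must lie in [0, 1]")
        if self.acquisition_gain < 1.0:
            raise ValueError("acquisition_gain must be >= 1")


# (location, scale) per trait; sampling distributions are fixed per trait:
# lognormal for rates/factors/caps (location = mean), logistic-normal for the
# continue probability (location = the probability itself at scale 0).
_TRAIT_NAMES = (
    "active_rate",
    "inactive_rate",
    "persistence_factor",
    "motivation_cap",
    "shock_continue_prob",
    "acquisition_gain",
)


@dataclass(frozen=True)
class GroupSpec:
    """Distribution of trait profiles within one experimental group."""

    label: str
    n: int
    traits: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        for name, (loc, scale) in self.traits.items():
            if name not in _TRAIT_NAMES:
                raise ValueError(f"unknown trait {name!r}")
            if scale < 0:
                raise ValueError(f"scale for {name!r} must be >= 0")
            if name == "shock_continue_prob" and not 0.0 < loc < 1.0:
                if not 0.0 <= loc <= 1.0:
                    raise ValueError("shock_continue_prob location must be in [0, 1]")


def default_group_specs(
    n_control: int = 25, n_vulnerable: int = 25
) -> tuple[GroupSpec, GroupSpec]:
    """Control (resilient-leaning) and vulnerable group specifications.

    Press-rate distributions are not reported in the source behavioural data,
    so locations are chosen to give realistic FR5 performance (tens of pellets
    per 1-h session) and the vulnerable group shifts the three
    criterion-linked traits upward.
    """
    control = GroupSpec(
        "control",
        n_control,
        {
            "active_rate": (6.0, 0.4),
            "inactive_rate": (0.6, 0.4),
            "persistence_factor": (0.35, 0.5),
            "motivation_cap": (60.0, 0.7),
            "shock_continue_prob": (0.35, 1.0),
            "acquisition_gain": (1.3, 0.1),
        },
    )
    vulnerable = GroupSpec(
        "vulnerable",
        n_vulnerable,
        {
            "active_rate": (7.0, 0.4),
            "inactive_rate": (0.6, 0.4),
            "persistence_factor": (1.1, 0.5),
            "motivation_cap": (400.0, 0.7),
            "shock_continue_prob": (0.80, 1.0),
            "acquisition_gain": (1.3, 0.1),
        },
    )
    return control, vulnerable


def _sample_lognormal(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    """Lognormal with exact mean ``mean``; sigma is the log-scale spread."""
    if mean == 0 or sigma == 0:
        return np.full(n, float(mean))
    return mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def _sample_logistic_normal(rng: np.random.Generator, p: float, scale: float, n: int) -> np.ndarray:
    if scale == 0 or p in (0.0, 1.0):
        return np.full(n, float(p))
    logit = np.log(p / (1.0 - p))
    z = rng.normal(logit, scale, size=n)
    return 1.0 / (1.0 + np.exp(-z))


def sample_cohort(spec: GroupSpec, rng_seed: int | np.random.Generator) -> list[TraitProfile]:
    """Draw ``spec.n`` trait profiles; reproducible under a fixed seed."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    defaults = TraitProfile()
    cols: dict[str, np.ndarray] = {}
    for name in _TRAIT_NAMES:
        loc, scale = spec.traits.get(name, (getattr(defaults, name), 0.0))
        if name == "shock_continue_prob":
            cols[name] = _sample_logistic_normal(rng, loc, scale, spec.n)
        else:
            cols[name] = _sample_lognormal(rng, loc, scale, spec.n)
    caps = np.maximum(1, np.rint(cols["motivation_cap"])).astype(int)
    gains = np.maximum(1.0, cols["acquisition_gain"])
    return [
        TraitProfile(
            active_rate=float(cols["active_rate"][i]),
            inactive_rate=float(cols["inactive_rate"][i]),
            persistence_factor=float(cols["persistence_factor"][i]),
            motivation_cap=int(caps[i]),
            shock_continue_prob=float(cols["shock_continue_prob"][i]),
            acquisition_gain=float(gains[i]),
        )
        for i in range(spec.n)
    ]


def _poisson_times(rng: np.random.Generator, rate_per_min: float, t0: float, t1: float) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [t0, t1)."""
    if rate_per_min <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_per_min / 60.0 * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def generate_press_stream(
    traits: TraitProfile,
    config: SessionConfig,
    rng: np.random.Generator,
    *,
    rate_scale: float = 1.0,
) -> PressStream:
    """Open-loop press stream for an FR session under the trait model.

    Active presses are piecewise-Poisson: ``active_rate * rate_scale`` in the
    pellet periods and additionally scaled by ``persistence_factor`` in the
    pellet-free period.  Inactive presses are an independent Poisson process
    over the whole session.
    """
    duration = config.fr_session_duration_s
    lo, hi = config.pellet_free_interval
    rate = traits.active_rate * rate_scale
    active_times = np.concatenate(
        [
            _poisson_times(rng, rate, 0.0, lo),
            _poisson_times(rng, rate * traits.persistence_factor, lo, hi),
            _poisson_times(rng, rate, hi, duration),
        ]
    )
    inactive_times = _poisson_times(rng, traits.inactive_rate, 0.0, duration)
    active = PressStream(active_times, np.ones(active_times.size, dtype=bool))
    inactive = PressStream(inactive_times, np.zeros(inactive_times.size, dtype=bool))
    return PressStream.merge(active, inactive)


def generate_shock_press_stream(
    traits: TraitProfile,
    config: SessionConfig,
    rng: np.random.Generator,
) -> PressStream:
    """Closed-loop press stream for the punished session.

    Active presses arrive at ``active_rate`` until the first footshock the
    mouse does not tolerate (per-shock continuation probability
    ``shock_continue_prob``); suppression is absorbing for the rest of the
    session.  The generator tracks the same block rules the schedule machine
    applies, so shock timing is consistent with :func:`run_shock_session`.
    """
    duration = config.shock_session_duration_s
    ratio = config.fixed_ratio
    rate_s = traits.active_rate / 60.0
    times: list[float] = []
    t = 0.0
    counter = 0
    timeout_until = -np.inf
    fourth_deadline: float | None = None
    pressing = rate_s > 0
    while pressing:
        t += rng.exponential(1.0 / rate_s)
        if t >= duration:
            break
        times.append(t)
        if fourth_deadline is not None and t >= fourth_deadline:
            counter = 0
            fourth_deadline = None
        if t < timeout_until:
            continue
        counter += 1
        shocked = False
        if counter == ratio - 1:
            shocked = True
            fourth_deadline = t + config.shock_fifth_response_window_s
        elif counter == ratio:
            shocked = True
            timeout_until = t + config.timeout_s
            counter = 0
            fourth_deadline = None
        if shocked and rng.random() > traits.shock_continue_prob:
            pressing = False
    inactive_times = _poisson_times(rng, traits.inactive_rate, 0.0, duration)
    active_arr = np.asarray(times, dtype=float)
    return PressStream.merge(
        PressStream(active_arr, np.ones(active_arr.size, dtype=bool)),
        PressStream(inactive_times, np.zeros(inactive_times.size, dtype=bool)),
    )


def make_pr_policy(traits: TraitProfile, rng: np.random.Generator):
    """PR policy: press at ``active_rate``; quit when the requirement exceeds
    ``motivation_cap``."""

    rate_s = traits.active_rate / 60.0

    def policy(requirement: int, idx: int) -> np.ndarray:
        if requirement > traits.motivation_cap or rate_s <= 0:
            return np.empty(0)
        return rng.exponential(1.0 / rate_s, size=requirement)

    return policy


@dataclass(frozen=True)
class ProtocolConfig:
    """Session counts and criterion-evaluation window of the full protocol."""

    n_fr1_sessions: int = 6
    n_fr5_sessions: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fr1_sessions < 0:
            raise ValueError("n_fr1_sessions must be >= 0")
        if self.n_fr5_sessions < 3:
            raise ValueError("n_fr5_sessions must be >= 3 (persistence scoring)")


@dataclass
class ProtocolDataset:
    """All event logs of a simulated cohort, with traits and group labels."""

    mice: pd.DataFrame  # index mouse_id; columns: group + trait values
    logs: dict[str, list[EventLog]]
    protocol: ProtocolConfig
    session_config: SessionConfig

    @property
    def mouse_ids(self) -> list[str]:
        return list(self.mice.index)

    def logs_of_kind(self, mouse_id: str, kind: str) -> list[EventLog]:
        return [lg for lg in self.logs[mouse_id] if lg.session_kind == kind]

    def fr5_logs(self, mouse_id: str) -> list[EventLog]:
        cfg_ratio = self.session_config.fixed_ratio
        return [
            lg
            for lg in self.logs_of_kind(mouse_id, "fr")
            if lg.config is not None and lg.config.fixed_ratio == cfg_ratio
        ]

    def fr1_logs(self, mouse_id: str) -> list[EventLog]:
        return [
            lg
            for lg in self.logs_of_kind(mouse_id, "fr")
            if lg.config is not None and lg.config.fixed_ratio == 1
        ]


def run_protocol(
    groups: Sequence[GroupSpec],
    protocol: ProtocolConfig | None = None,
    session_config: SessionConfig | None = None,
) -> ProtocolDataset:
    """Simulate the full protocol for every mouse of every group.

    Per mouse: ``n_fr1_sessions`` FR1 sessions with geometric acquisition of
    the active press rate, ``n_fr5_sessions`` FR5 sessions, one
    progressive-ratio session and one shock session.  The master seed is
    expanded into independent per-mouse substreams so cohorts are reproducible
    independent of iteration order.
    """
    protocol = protocol or ProtocolConfig()
    base = session_config or SessionConfig(session_kind="fr")
    fr5_cfg = base
    fr1_cfg = SessionConfig(
        **{**base.__dict__, "fixed_ratio": 1, "session_kind": "fr"}
    )
    pr_cfg = SessionConfig(**{**base.__dict__, "session_kind": "pr"})
    shock_cfg = SessionConfig(**{**base.__dict__, "session_kind": "shock"})

    root = np.random.SeedSequence(protocol.seed)
    n_total = sum(g.n for g in groups)
    seeds = root.spawn(len(groups) + n_total)
    group_seeds, mouse_seeds = seeds[: len(groups)], seeds[len(groups):]

    rows = []
    logs: dict[str, list[EventLog]] = {}
    m = 0
    for g_idx, spec in enumerate(groups):
        cohort = sample_cohort(spec, np.random.default_rng(group_seeds[g_idx]))
        for traits in cohort:
            mouse_id = f"{spec.label}_{m:04d}"
            rng = np.random.default_rng(mouse_seeds[m])
            m += 1
            mouse_logs: list[EventLog] = []
            session_index = 0
            n1 = protocol.n_fr1_sessions
            for i in range(n1):
                # rate ramps geometrically up to the asymptotic active_rate
                scale = traits.acquisition_gain ** (i + 1 - n1)
                stream = generate_press_stream(traits, fr1_cfg, rng, rate_scale=scale)
                mouse_logs.append(
                    run_fr_session(stream, fr1_cfg, mouse_id=mouse_id,
                                   session_index=session_index)
                )
                session_index += 1
            for _ in range(protocol.n_fr5_sessions):
                stream = generate_press_stream(traits, fr5_cfg, rng)
                mouse_logs.append(
                    run_fr_session(stream, fr5_cfg, mouse_id=mouse_id,
                                   session_index=session_index)
                )
                session_index += 1
            mouse_logs.append(
                run_pr_session(
                    make_pr_policy(traits, rng), PR_SERIES, pr_cfg,
                    mouse_id=mouse_id, session_index=session_index,
                )
            )
            session_index += 1
            stream = generate_shock_press_stream(traits, shock_cfg, rng)
            mouse_logs.append(
                run_shock_session(stream, shock_cfg, mouse_id=mouse_id,
                                  session_index=session_index)
            )
            logs[mouse_id] = mouse_logs
            rows.append({"mouse_id": mouse_id, "group": spec.label,
                         **traits.__dict__})
    mice = pd.DataFrame(rows).set_index("mouse_id")
    return ProtocolDataset(mice=mice, logs=logs, protocol=protocol,
                           session_config=fr5_cfg)


def simulate_null_scores(
    n: int,
    rng: int | np.random.Generator = 0,
    *,
    persistence_mean: float = 35.0,
    persistence_sigma: float = 0.6,
    motivation_mean: float = 120.0,
    motivation_sigma: float = 0.8,
    compulsivity_shape: float = 2.0,
    compulsivity_scale: float = 3.0,
    correlation: float = 0.0,
) -> pd.DataFrame:
    """Idealized control criterion scores: continuous and (by default) independent.

    Persistence and motivation are lognormal, compulsivity is gamma; a single
    ``correlation`` knob induces a shared Gaussian factor across the three
    criteria (real criteria correlate; independence is the analytic default).
    Returns a DataFrame with columns persistence / motivation / compulsivity.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    z = rng.standard_normal((n, 3))
    if correlation > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(1 - correlation) * z + np.sqrt(correlation) * shared
    from scipy import stats as sps

    persistence = persistence_mean * np.exp(
        persistence_sigma * z[:, 0] - 0.5 * persistence_sigma**2
    )
    motivation = motivation_mean * np.exp(
        motivation_sigma * z[:, 1] - 0.5 * motivation_sigma**2
    )
    u = sps.norm.cdf(z[:, 2])
    compulsivity = sps.gamma.ppf(u, a=compulsivity_shape, scale=compulsivity_scale)
    return pd.DataFrame(
        {
            "persistence": persistence,
            "motivation": motivation,
            "compulsivity": compulsivity,
        }
    )
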