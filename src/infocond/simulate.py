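"""Seeded simulation of conditioning-session event streams.

Sessions are an alternating ITI/tone cycle.  ITIs (and, where specified,
tone durations) are drawn from exponential distributions.  Rewards are
scheduled either response-independently (Pavlovian: a Poisson pellet
process that runs only during ITIs under a negative contingency, or
session-wide under a zero contingency) or by a random-interval (RI)
operant schedule: an exponential arming interval elapses on the eligible
clock, after which the next response in an eligible state is rewarded
(single arming — at most one reward is held, and the arming clock pauses
while a reward is pending).

The responding agent emits head pokes / lever presses from a
piecewise-constant Poisson process.  Before its learning change point
(expressed as a cumulative pellet count) it responds at a single baseline
rate in both states; afterwards it switches to separate ITI and tone
rates, optionally shaping the within-tone rate with the Weber-scaled
response-profile model.

All event times are recorded at 0.1-s resolution, mimicking behavioral
hardware logs; internally the timeline is kept in integer deciseconds so
state boundaries are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .protocols import Contingency, ExposureSummary, Paradigm, ProtocolSpec, ToneKind

__all__ = [
    "Event",
    "EventLog",
    "EventLogError",
    "AgentParams",
    "simulate_session",
    "simulate_cohort",
    "empirical_exposures",
    "validate_log",
]

#: recording resolution, seconds
TIME_RESOLUTION_S = 0.1

EVENT_KINDS = ("session_start", "tone_on", "tone_off", "reward", "response", "session_end")

# tie-break order for events sharing a 0.1-s timestamp: a reward generated
# late in an ITI sorts before the tone onset that ends the ITI, and an
# operant response sorts before the reward it triggers.
_KIND_ORDER = {
    "session_start": 0,
    "tone_off": 1,
    "response": 2,
    "reward": 3,
    "tone_on": 4,
    "session_end": 5,
}


class Event(NamedTuple):
    time_s: float
    kind: str


class EventLogError(ValueError):
    """Raised when an event log violates its structural invariants."""


@dataclass
class EventLog:
    """One session's ordered, timestamped behavioral events."""

    session_id: str
    events: list[Event] = field(default_factory=list)

    def times(self, kind: str) -> np.ndarray:
        return np.array([e.time_s for e in self.events if e.kind == kind], dtype=float)

    @property
    def tone_on_times(self) -> np.ndarray:
        return self.times("tone_on")

    @property
    def tone_off_times(self) -> np.ndarray:
        return self.times("tone_off")

    @property
    def reward_times(self) -> np.ndarray:
        return self.times("reward")

    @property
    def response_times(self) -> np.ndarray:
        return self.times("response")

    @property
    def start_time(self) -> float:
        return self.events[0].time_s

    @property
    def end_time(self) -> float:
        return self.events[-1].time_s

    @property
    def duration_s(self) -> float:
        return self.end_time - self.start_time


def validate_log(log: EventLog, contingency: Contingency | None = None) -> None:
    """Check structural invariants, raising :class:`EventLogError` on failure.

    Checks ordering, session_start/session_end bracketing, strict
    tone_on/tone_off alternation, and (when ``contingency`` is negative)
    that no reward falls inside a ``[tone_on, tone_off)`` interval.
    """
    if not log.events:
        raise EventLogError(f"{log.session_id}: empty event log")
    if log.events[0].kind != "session_start":
        raise EventLogError(f"{log.session_id}: first event must be session_start")
    if log.events[-1].kind != "session_end":
        raise EventLogError(f"{log.session_id}: last event must be session_end")
    prev_t = -math.inf
    expect_on = True
    for t, kind in log.events:
        if kind not in _KIND_ORDER:
            raise EventLogError(f"{log.session_id}: unknown event kind {kind!r} at t={t}")
        if t < prev_t:
            raise EventLogError(f"{log.session_id}: non-monotone timestamp at t={t}")
        prev_t = t
        if kind == "tone_on":
            if not expect_on:
                raise EventLogError(f"{log.session_id}: tone_on without tone_off at t={t}")
            expect_on = False
        elif kind == "tone_off":
            if expect_on:
                raise EventLogError(f"{log.session_id}: tone_off without tone_on at t={t}")
            expect_on = True
    if not expect_on:
        raise EventLogError(f"{log.session_id}: unterminated tone at session end")
    if contingency is Contingency.NEGATIVE:
        on, off = log.tone_on_times, log.tone_off_times
        for r in log.reward_times:
            i = np.searchsorted(on, r, side="right")
            if i > 0 and r < off[i - 1]:
                raise EventLogError(
                    f"{log.session_id}: reward inside tone at t={r} under negative contingency"
                )


@dataclass(frozen=True)
class AgentParams:
    """Responding-agent parameters.

    The agent responds at ``baseline_rate_per_min`` in both states until
    ``changepoint_pellets`` cumulative rewards have been delivered, then
    switches to ``post_iti_rate_per_min`` during ITIs and
    ``post_tone_rate_per_min`` during tones.  ``changepoint_pellets=None``
    means the agent never learns.  ``within_tone_profile``, if set, shapes
    the post-acquisition within-tone rate with the Weber-scaled profile
    model (``post_iti - amplitude * normalized occupancy``), which requires
    fixed-duration tones.
    """

    baseline_rate_per_min: float = 5.0
    post_iti_rate_per_min: float = 5.0
    post_tone_rate_per_min: float = 5.0
    changepoint_pellets: int | None = None
    within_tone_profile: "object | None" = None  # ProfileParams, optional
    collection_window_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("baseline_rate_per_min", "post_iti_rate_per_min", "post_tone_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.changepoint_pellets is not None and self.changepoint_pellets < 0:
            raise ValueError("changepoint_pellets must be non-negative")


# ---------------------------------------------------------------------------
# internal helpers (integer-decisecond timeline)


def _dur_to_ds(x: float) -> int:
    """Duration to integer deciseconds, minimum one tick."""
    return max(1, int(round(x * 10.0)))


def _floor_ds(t_s: float) -> int:
    return int(math.floor(t_s * 10.0))


def _sample_tone_ds(spec: ProtocolSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.tones_per_session
    if spec.tone_duration_kind is ToneKind.FIXED:
        durs = np.full(n, spec.tone_duration_s)
    elif spec.tone_duration_kind is ToneKind.EXPONENTIAL:
        durs = rng.exponential(spec.tone_duration_s, n)
    else:  # mixed: uniform choice among the listed fixed values
        durs = rng.choice(np.asarray(spec.tone_duration_values), size=n)
    return np.array([_dur_to_ds(d) for d in durs], dtype=np.int64)


def _poisson_times_on_clock(
    rng: np.random.Generator, rate_per_s: float, segments_ds: list[tuple[int, int]]
) -> list[int]:
    """Homogeneous Poisson arrivals restricted to ``segments_ds``.

    The process runs on the concatenated eligible clock (segment gaps do
    not count), so the inter-arrival distribution over eligible time is
    exponential with mean ``1/rate_per_s``.  Returns decisecond times,
    each strictly inside its segment.
    """
    if rate_per_s <= 0 or not segments_ds:
        return []
    lengths = np.array([(e - s) / 10.0 for s, e in segments_ds])
    total = float(lengths.sum())
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    times: list[int] = []
    u = rng.exponential(1.0 / rate_per_s)
    while u < total:
        seg = int(np.searchsorted(cum, u, side="right")) - 1
        t_s = segments_ds[seg][0] / 10.0 + (u - cum[seg])
        ds = min(max(_floor_ds(t_s), segments_ds[seg][0]), segments_ds[seg][1] - 1)
        times.append(ds)
        u += rng.exponential(1.0 / rate_per_s)
    return times


def _profile_rate_fn(agent: AgentParams, tone_ds: int):
    """Within-tone post-acquisition rate (per min) as a function of seconds in tone."""
    from . import profiles  # local import to avoid a cycle

    params = agent.within_tone_profile
    T = tone_ds / 10.0
    grid = np.linspace(0.0, T, 2001)
    p = profiles.p_low(profiles.subjective_time(grid, params), params.tau_subjective)
    peak = float(p.max())

    def rate(t_in_tone: float) -> float:
        if peak <= 0:
            return agent.post_iti_rate_per_min
        s = profiles.subjective_time(t_in_tone, params)
        val = profiles.p_low(s, params.tau_subjective) / peak
        return max(0.0, agent.post_iti_rate_per_min - params.amplitude * float(val))

    return rate


# ---------------------------------------------------------------------------
# session simulation


def simulate_session(
    spec: ProtocolSpec,
    agent: AgentParams,
    seed: int | np.random.SeedSequence,
    session_id: str = "session",
    pellets_before: int = 0,
) -> EventLog:
    """Simulate one conditioning session.

    ``seed`` fixes all randomness; it is split into independent scheduler
    and agent sub-streams (``SeedSequence(seed).spawn(2)``), so the reward
    schedule of a given seed is identical whatever the agent does — except
    in operant mode, where delivery (not arming) depends on responding.
    ``pellets_before`` carries the cumulative pellet count across sessions
    so that a multi-session change point lands correctly.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, (int, np.integer)):
        ss = np.random.SeedSequence(int(seed))
    else:
        raise TypeError(f"seed must be an integer or SeedSequence, got {type(seed)!r}")
    sched_ss, agent_ss = ss.spawn(2)
    sched = np.random.default_rng(sched_ss)
    agent_rng = np.random.default_rng(agent_ss)

    n = spec.tones_per_session
    iti_ds = np.array([_dur_to_ds(d) for d in sched.exponential(spec.iti_mean_s, n)], dtype=np.int64)
    tone_ds = _sample_tone_ds(spec, sched)

    # cycle i: ITI then tone; session ends at the last tone offset
    tone_on = np.zeros(n, dtype=np.int64)
    tone_off = np.zeros(n, dtype=np.int64)
    t = 0
    for i in range(n):
        t += iti_ds[i]
        tone_on[i] = t
        t += tone_ds[i]
        tone_off[i] = t
    end_ds = t

    iti_segments = [(int(tone_off[i - 1]) if i else 0, int(tone_on[i])) for i in range(n)]
    negative = spec.contingency is Contingency.NEGATIVE
    eligible_segments = iti_segments if negative else [(0, int(end_ds))]

    # --- reward scheduling -------------------------------------------------
    pavlovian_rewards: list[int] = []
    arming_interval_s = None
    if spec.paradigm is Paradigm.PAVLOVIAN:
        if negative:
            rate = 1.0 / spec.iri_mean_s
        else:
            # zero contingency: pellet budget yoked to the ITI-only schedule,
            # delivered at random times throughout the session
            mean_tone = spec.tone_duration_s
            rate = (spec.iti_mean_s / (spec.iti_mean_s + mean_tone)) / spec.iri_mean_s
        pavlovian_rewards = _poisson_times_on_clock(sched, rate, eligible_segments)
    else:
        arming_interval_s = spec.iri_mean_s

    # --- agent responses (thinning) + operant delivery ---------------------
    rate_max = max(
        agent.baseline_rate_per_min, agent.post_iti_rate_per_min, agent.post_tone_rate_per_min
    )
    candidates: list[float] = []
    if rate_max > 0:
        lam = rate_max / 60.0
        tt = agent_rng.exponential(1.0 / lam)
        end_s = end_ds / 10.0
        while tt < end_s:
            candidates.append(tt)
            tt += agent_rng.exponential(1.0 / lam)

    profile_rate = None
    if agent.within_tone_profile is not None:
        if spec.tone_duration_kind is not ToneKind.FIXED:
            raise ValueError("within_tone_profile requires fixed-duration tones")
        profile_rate = _profile_rate_fn(agent, int(tone_ds[0]))

    # process chronologically; marker events at tone boundaries keep every
    # span within a single state for the operant eligible-time clock
    queue: list[tuple[float, int, int]] = []  # (time_s, priority, payload)
    CAND, PAV_REWARD, MARKER = 0, 1, 2
    for i, c in enumerate(candidates):
        queue.append((c, 1, CAND))
    for r in pavlovian_rewards:
        queue.append((r / 10.0, 0, PAV_REWARD))
    for b in np.concatenate([tone_on, tone_off]):
        queue.append((b / 10.0, 2, MARKER))
    queue.sort(key=lambda x: (x[0], x[1]))

    changepoint = agent.changepoint_pellets
    pellets = pellets_before
    responses_ds: list[int] = []
    operant_rewards: list[int] = []
    armed = False
    elig_timer = 0.0
    next_arm = sched.exponential(arming_interval_s) if arming_interval_s else math.inf
    prev_t = 0.0

    def in_tone(ts: float) -> tuple[bool, float]:
        i = int(np.searchsorted(tone_on, ts * 10.0, side="right"))
        if i > 0 and ts * 10.0 < tone_off[i - 1]:
            return True, ts - tone_on[i - 1] / 10.0
        return False, 0.0

    for ts, _, payload in queue:
        if arming_interval_s is not None and not armed:
            tone_state, _ = in_tone((prev_t + ts) / 2.0) if ts > prev_t else (False, 0.0)
            span_eligible = (not negative) or (not tone_state)
            if ts > prev_t and span_eligible:
                elig_timer += ts - prev_t
                if elig_timer >= next_arm:
                    armed = True
        prev_t = ts
        if payload == PAV_REWARD:
            pellets += 1
            continue
        if payload == MARKER:
            continue
        # response candidate
        tone_state, t_in_tone = in_tone(ts)
        learned = changepoint is not None and pellets >= changepoint
        if not learned:
            r = agent.baseline_rate_per_min
        elif tone_state:
            r = profile_rate(t_in_tone) if profile_rate is not None else agent.post_tone_rate_per_min
        else:
            r = agent.post_iti_rate_per_min
        if agent_rng.uniform() < r / rate_max:
            ds = min(_floor_ds(ts), end_ds - 1)
            responses_ds.append(ds)
            if arming_interval_s is not None and armed and ((not negative) or (not tone_state)):
                operant_rewards.append(ds)
                pellets += 1
                armed = False
                elig_timer = 0.0
                next_arm = sched.exponential(arming_interval_s)

    # --- assemble ----------------------------------------------------------
    events = [Event(0.0, "session_start")]
    events += [Event(b / 10.0, "tone_on") for b in tone_on]
    events += [Event(b / 10.0, "tone_off") for b in tone_off]
    events += [Event(r / 10.0, "reward") for r in pavlovian_rewards + operant_rewards]
    events += [Event(r / 10.0, "response") for r in responses_ds]
    events.append(Event(end_ds / 10.0, "session_end"))
    events.sort(key=lambda e: (e.time_s, _KIND_ORDER[e.kind]))
    log = EventLog(session_id=session_id, events=events)
    validate_log(log, contingency=spec.contingency)
    return log


def simulate_cohort(
    spec: ProtocolSpec,
    agent: AgentParams,
    n_subjects: int,
    base_seed: int,
    n_sessions: int = 1,
    changepoint_jitter_sigma: float = 0.0,
) -> list[list[EventLog]]:
    """Simulate ``n_subjects`` independent subjects, each for ``n_sessions``.

    Subject ``i`` uses seed ``base_seed + i``; from it a per-subject
    generator first draws the (optional) lognormal multiplicative jitter of
    the change point (``exp(N(0, sigma))``), then one 31-bit seed per
    session.  Pellet counts carry across a subject's sessions so the change
    point refers to cumulative deliveries.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    cohort: list[list[EventLog]] = []
    for i in range(n_subjects):
        srng = np.random.default_rng(base_seed + i)
        subj_agent = agent
        if changepoint_jitter_sigma > 0 and agent.changepoint_pellets is not None:
            factor = srng.lognormal(0.0, changepoint_jitter_sigma)
            cp = max(1, int(round(agent.changepoint_pellets * factor)))
            import dataclasses as _dc

            subj_agent = _dc.replace(agent, changepoint_pellets=cp)
        session_seeds = srng.integers(0, 2**31 - 1, size=n_sessions)
        logs: list[EventLog] = []
        pellets = 0
        for j, s in enumerate(session_seeds):
            log = simulate_session(
                spec,
                subj_agent,
                int(s),
                session_id=f"sub{i:03d}_ses{j:03d}",
                pellets_before=pellets,
            )
            pellets += len(log.reward_times)
            logs.append(log)
        cohort.append(logs)
    return cohort


def empirical_exposures(logs: Iterable[EventLog] | Sequence[EventLog]) -> ExposureSummary:
    """Accumulate state exposures and reward counts from event logs.

    A moment belongs to the tone state iff ``tone_on <= t < tone_off``;
    everything else inside the session is no-tone (ITI) time.  The result
    feeds :func:`infocond.protocols.informativeness` exactly as expected
    protocol exposures do.
    """
    logs = list(logs)
    if not logs:
        raise ValueError("empty log list")
    cum_tone = cum_context = 0.0
    n_tone = n_no_tone = 0
    for log in logs:
        validate_log(log)
        on, off = log.tone_on_times, log.tone_off_times
        cum_tone += float((off - on).sum())
        cum_context += log.duration_s
        for r in log.reward_times:
            i = np.searchsorted(on, r, side="right")
            if i > 0 and r < off[i - 1]:
                n_tone += 1
            else:
                n_no_tone += 1
    return ExposureSummary(
        cum_context_s=cum_context,
        cum_tone_s=cum_tone,
        cum_no_tone_s=cum_context - cum_tone,
        n_rewards_context=n_tone + n_no_tone,
        n_rewards_no_tone=n_no_tone,
        n_rewards_tone=n_tone,
    )
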