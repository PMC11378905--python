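"""Within-tone response-rate profiles: Weber-scaled timing model and empirics.

When a fixed-duration tone signals that rewards are unavailable, trained
subjects drop their response rate shortly after tone onset and, if the
tone is long enough in *subjective* time, resume responding in
anticipation of tone offset.  Subjective time is Weber-scaled: one
subjective unit equals ``w_d * mu_R|C`` seconds, where ``w_d`` is the
Weber fraction for duration (0.16 by default, from the timing literature)
and ``mu_R|C`` is the mean inter-reinforcement interval in the context.

Both the latency to drop and the latency to resume are modeled as
exponential with time constant ``tau`` subjective units (0.8 by default),
the resumption clock starting only after the drop.  The probability that
the rate is at its lower value at elapsed subjective time ``t`` is then
the self-convolution occupancy

    p_low(t) = (t / tau) * exp(-t / tau),

i.e. ``tau`` times the Gamma(shape 2, scale tau) density — unimodal with
mode at ``tau`` and peak value ``1/e``.  The model profile over a tone of
duration T is the ITI rate minus an amplitude times the (optionally
peak-normalized) occupancy, windowed to [0, T]: short tones (ending
before ``tau`` subjective units) give a monotone non-increasing profile,
long tones a U shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocols import ProtocolSpec, ToneKind, expected_exposures
from .simulate import EventLog, validate_log
from .acquisition import _cum_length_fn, _merge_intervals

__all__ = [
    "ProfileParams",
    "ProfileCurve",
    "subjective_time",
    "p_low",
    "model_rate",
    "model_profile",
    "empirical_profile",
    "profile_params_for",
]


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of the within-tone response-profile model.

    ``amplitude`` is the vertical scale of the drop, in responses/min: by
    convention the asymptotic difference between the ITI rate and the
    minimum within-tone rate.  ``mu_context_s`` is the mean
    inter-reinforcement interval in the context (1 / contextual rate).
    """

    mu_context_s: float
    amplitude: float = 0.0
    weber_fraction: float = 0.16
    tau_subjective: float = 0.8
    shape: int = 2  # fixed by the exponential self-convolution

    def __post_init__(self) -> None:
        if not 0 < self.weber_fraction < 1:
            raise ValueError("weber_fraction must lie in (0, 1)")
        if self.tau_subjective <= 0:
            raise ValueError("tau_subjective must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.mu_context_s <= 0:
            raise ValueError("mu_context_s must be positive")
        if self.shape != 2:
            raise ValueError("shape is fixed at 2 by the self-convolution")


@dataclass(frozen=True)
class ProfileCurve:
    """Response rate across elapsed-fraction bins of the tone."""

    bin_edges: np.ndarray  # fractions of tone duration, length n_bins + 1
    rates_per_min: np.ndarray
    source: str  # "model" or "empirical"

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.rates_per_min) + 1:
            raise ValueError("bin_edges must have one more entry than rates")
        if np.any(np.asarray(self.rates_per_min) < 0):
            raise ValueError("rates must be non-negative")


def subjective_time(t_s, params: ProfileParams):
    """Elapsed time in subjective units: ``t / (w_d * mu_R|C)``.

    Scale-free: multiplying both ``t`` and ``mu_context_s`` by the same
    factor leaves the result unchanged.
    """
    if params.mu_context_s <= 0:
        raise ValueError("mu_context_s must be positive")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = t / (params.weber_fraction * params.mu_context_s)
    return float(out) if out.ndim == 0 else out


def p_low(t_subjective, tau: float):
    """Occupancy probability of the low-rate state at subjective time ``t``.

    ``P(X <= t < X + Y)`` for i.i.d. exponential drop/resume latencies
    with mean ``tau``: ``(t/tau) exp(-t/tau)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t_subjective, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = (t / tau) * np.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


def model_rate(
    t_s,
    tone_duration_s: float,
    params: ProfileParams,
    iti_rate_per_min: float,
    normalized: bool = True,
):
    """Model response rate (per min) at time ``t_s`` within the tone.

    ``normalized=True`` (default) divides the occupancy by its maximum
    over the [0, T] window, so ``amplitude`` equals the full observed
    ITI-minus-tone rate difference; ``normalized=False`` uses the raw
    occupancy (whose global peak is 1/e).  Rates are floored at zero.
    """
    grid = np.linspace(0.0, tone_duration_s, 2001)
    occ_grid = p_low(subjective_time(grid, params), params.tau_subjective)
    denom = float(occ_grid.max()) if normalized else 1.0
    occ = p_low(subjective_time(t_s, params), params.tau_subjective)
    if denom > 0:
        occ = occ / denom
    out = np.maximum(0.0, iti_rate_per_min - params.amplitude * np.asarray(occ))
    return float(out) if out.ndim == 0 else out


def model_profile(
    spec: ProtocolSpec,
    params: ProfileParams,
    iti_rate_per_min: float,
    n_bins: int = 10,
    normalized: bool = True,
) -> ProfileCurve:
    """Model profile across ``n_bins`` equal elapsed-fraction bins of the tone.

    Evaluated at bin midpoints.  Only fixed-duration tones have a defined
    within-tone profile.
    """
    if spec.tone_duration_kind is not ToneKind.FIXED:
        raise ValueError("model profiles are defined only for fixed-duration tones")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0 * spec.tone_duration_s
    rates = model_rate(mids, spec.tone_duration_s, params, iti_rate_per_min, normalized)
    return ProfileCurve(bin_edges=edges, rates_per_min=np.asarray(rates), source="model")


def profile_params_for(
    spec: ProtocolSpec,
    amplitude: float = 0.0,
    weber_fraction: float = 0.16,
    tau_subjective: float = 0.8,
) -> ProfileParams:
    """Profile parameters with ``mu_R|C`` derived from the protocol.

    ``mu_R|C`` is the expected context time per reward, i.e. the
    reciprocal of the contextual reinforcement rate.
    """
    exp = expected_exposures(spec)
    mu = exp.cum_context_s / exp.n_rewards_context
    return ProfileParams(
        mu_context_s=mu,
        amplitude=amplitude,
        weber_fraction=weber_fraction,
        tau_subjective=tau_subjective,
    )


def empirical_profile(
    logs, n_bins: int = 10, collection_window_s: float = 2.0
) -> ProfileCurve:
    """Empirical within-tone response profile from event logs.

    Responses inside each tone are assigned to elapsed-fraction bins
    (half-open: a response exactly on a boundary goes to the later bin);
    the rate in a bin is its adjusted count over its cumulative adjusted
    exposure.  Requires a common fixed tone duration across logs.
    Responses and exposure inside post-reward collection windows are
    excluded.
    """
    if isinstance(logs, EventLog):
        logs = [logs]
    logs = list(logs)
    if not logs:
        raise ValueError("no event logs supplied")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    counts = np.zeros(n_bins)
    exposure = np.zeros(n_bins)
    T = None
    any_tone = False
    for log in logs:
        validate_log(log)
        on, off = log.tone_on_times, log.tone_off_times
        if len(on) == 0:
            continue
        any_tone = True
        durs = off - on
        if T is None:
            T = float(durs[0])
        if np.any(np.abs(durs - T) > 0.05):
            raise ValueError("empirical profiles require a common fixed tone duration")
        rewards = log.reward_times
        if collection_window_s > 0 and len(rewards):
            ws, we = _merge_intervals(
                rewards, np.minimum(rewards + collection_window_s, log.end_time)
            )
            excl_fn = _cum_length_fn(ws, we)
        else:
            ws = we = np.array([])
            excl_fn = None
        resp = log.response_times
        if len(ws):
            widx = np.searchsorted(ws, resp, side="left")
            keep = ~((widx > 0) & (resp <= we[np.maximum(widx - 1, 0)]))
        else:
            keep = np.ones(len(resp), dtype=bool)
        resp = resp[keep]
        for a, b in zip(on, off):
            inside = resp[(resp >= a) & (resp < b)]
            frac = (inside - a) / T
            idx = np.minimum((frac * n_bins).astype(int), n_bins - 1)
            np.add.at(counts, idx, 1)
            edges = a + np.linspace(0.0, T, n_bins + 1)
            seg = np.diff(edges)
            if excl_fn is not None:
                cut = np.diff(excl_fn(edges))
                seg = seg - cut
            exposure += seg
    if not any_tone:
        raise ValueError("no tones in the supplied logs")
    if np.any(exposure <= 0):
        raise ValueError("zero adjusted exposure in at least one bin")
    rates = 60.0 * counts / exposure
    return ProfileCurve(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        rates_per_min=rates,
        source="empirical",
    )
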