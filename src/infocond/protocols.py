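"""Temporal structure of conditioning protocols and the quantities derived from it.

A conditioning protocol is described entirely by its metric temporal
structure: the tone (CS) duration, the mean intertrial interval (ITI), the
mean inter-reward interval (IRI) of the pellet/reward scheduling process,
and the number of tones per session.  From these one obtains the cumulative
exposure to each reward-availability state, the reinforcement rate in each
state, and the *informativeness* of the cue

    iota = lambda_high / lambda_context,

the ratio of the reinforcement rate in the higher-rate state (the ITI, when
the cue signals reward *un*availability) to the contextual rate computed
over the whole session.  Its natural logarithm is the mutual information
(in nats) conveyed by the informative cue transition.

This module also provides rate-based credit assignment (solving the 2x2
conditional-probability system for the rates attributable to the tone and
to the context alone) and the one-parameter learning-rate law

    n_R = k / (iota - 1),

the number of reinforcements preceding the appearance of differential
responding.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Paradigm",
    "Contingency",
    "ToneKind",
    "ProtocolSpec",
    "ExposureSummary",
    "InformativenessReport",
    "CreditAssignment",
    "LearningRateFit",
    "expected_exposures",
    "informativeness",
    "delta_H",
    "assign_credit",
    "predicted_acquisition",
    "fit_k",
    "NOT_ACQUIRED",
]

#: Sentinel returned by :func:`predicted_acquisition` when the cue conveys no
#: information (iota <= 1): the predicted learning rate is zero, so the
#: number of reinforcements to acquisition is unbounded.
NOT_ACQUIRED = math.inf


class Paradigm(str, enum.Enum):
    PAVLOVIAN = "pavlovian"
    OPERANT = "operant"


class Contingency(str, enum.Enum):
    #: rewards are scheduled only in the cue's absence (cue offset informative)
    NEGATIVE = "negative"
    #: rewards are scheduled irrespective of the cue (iota = 1)
    ZERO = "zero"


class ToneKind(str, enum.Enum):
    FIXED = "fixed"
    #: tone durations drawn from an exponential with the stated mean
    EXPONENTIAL = "exponential_mean"
    #: tone durations drawn uniformly from an explicit list of fixed values
    MIXED = "mixed"


@dataclass(frozen=True)
class ProtocolSpec:
    """The metric temporal structure of one conditioning protocol.

    Parameters
    ----------
    paradigm
        ``pavlovian`` (response-independent pellet delivery) or ``operant``
        (random-interval schedule: a reward is armed after an exponential
        interval and delivered on the next response).
    contingency
        ``negative`` (rewards only outside tones) or ``zero`` (rewards
        random with respect to tones).
    tone_duration_s
        Tone duration in seconds; the mean when ``tone_duration_kind`` is
        not ``fixed``.
    iti_mean_s
        Mean of the exponential intertrial-interval distribution, seconds.
    iri_mean_s
        Mean inter-reward interval of the scheduling process, seconds.
    tones_per_session
        Number of tone presentations per session.
    collection_window_s
        Post-reward window excluded from response analyses (reward
        collection, not anticipatory responding).
    tone_duration_values
        Explicit duration values for ``mixed`` tone kind.
    """

    paradigm: Paradigm = Paradigm.PAVLOVIAN
    contingency: Contingency = Contingency.NEGATIVE
    tone_duration_s: float = 10.0
    tone_duration_kind: ToneKind = ToneKind.FIXED
    iti_mean_s: float = 20.0
    iri_mean_s: float = 20.0
    tones_per_session: int = 32
    collection_window_s: float = 2.0
    tone_duration_values: tuple[float, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "paradigm", Paradigm(self.paradigm))
        object.__setattr__(self, "contingency", Contingency(self.contingency))
        object.__setattr__(self, "tone_duration_kind", ToneKind(self.tone_duration_kind))
        for name in ("tone_duration_s", "iti_mean_s", "iri_mean_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if int(self.tones_per_session) != self.tones_per_session or self.tones_per_session < 1:
            raise ValueError("tones_per_session must be a positive integer")
        if self.collection_window_s < 0:
            raise ValueError("collection_window_s must be non-negative")
        if self.tone_duration_kind is ToneKind.MIXED:
            vals = self.tone_duration_values
            if not vals or any(v <= 0 for v in vals):
                raise ValueError("mixed tone kind requires positive tone_duration_values")
            object.__setattr__(self, "tone_duration_values", tuple(float(v) for v in vals))
            mean = sum(vals) / len(vals)
            if not math.isclose(mean, self.tone_duration_s, rel_tol=1e-9):
                raise ValueError(
                    "tone_duration_s must equal the mean of tone_duration_values "
                    f"({mean} != {self.tone_duration_s})"
                )

    def scaled(self, c: float) -> "ProtocolSpec":
        """Return a copy with every duration multiplied by ``c`` > 0.

        Informativeness and mutual information are invariant under this
        transformation (timescale invariance).
        """
        if not c > 0:
            raise ValueError("scale factor must be positive")
        vals = self.tone_duration_values
        return dataclasses.replace(
            self,
            tone_duration_s=self.tone_duration_s * c,
            iti_mean_s=self.iti_mean_s * c,
            iri_mean_s=self.iri_mean_s * c,
            collection_window_s=self.collection_window_s * c,
            tone_duration_values=None if vals is None else tuple(v * c for v in vals),
        )


@dataclass(frozen=True)
class ExposureSummary:
    """Cumulative state exposures and reward counts, expected or empirical.

    ``cum_context_s`` is total time in the chamber (C); it splits exactly
    into tone time (T) and no-tone/ITI time (~T).  Counts may be
    non-integral when they are expectations.
    """

    cum_context_s: float
    cum_tone_s: float
    cum_no_tone_s: float
    n_rewards_context: float
    n_rewards_no_tone: float
    n_rewards_tone: float

    def __post_init__(self) -> None:
        if min(self.cum_context_s, self.cum_tone_s, self.cum_no_tone_s) < 0:
            raise ValueError("exposure durations must be non-negative")
        if min(self.n_rewards_context, self.n_rewards_no_tone, self.n_rewards_tone) < 0:
            raise ValueError("reward counts must be non-negative")


@dataclass(frozen=True)
class InformativenessReport:
    """Reinforcement rates (per minute), informativeness and mutual information."""

    rate_context_per_min: float
    rate_no_tone_per_min: float
    rate_tone_per_min: float
    iota: float
    delta_H_nats: float
    delta_H_bits: float


@dataclass(frozen=True)
class CreditAssignment:
    """Rates attributed to the tone and to the context alone.

    The conditional-probability matrix ``P = [[1, p(~T|C)], [1, 1]]`` maps
    the attributed rates onto the observed (contextual, no-tone) rates;
    credit assignment inverts it.  When the tone is never on,
    ``p(~T|C) = 1`` and the system is singular; both attributed rates then
    equal the contextual rate.
    """

    p_no_tone_given_context: float
    matrix: np.ndarray
    attributed_rate_tone_per_min: float
    attributed_rate_no_tone_per_min: float
    singular: bool


@dataclass(frozen=True)
class LearningRateFit:
    """One-parameter fit of reinforcements-to-acquisition against informativeness."""

    points: tuple[tuple[float, float], ...]
    k: float
    fit_space: str  # "log" or "linear"

    def predict(self, iota: float) -> float:
        return predicted_acquisition(iota, self.k)


# ---------------------------------------------------------------------------
# exposures and informativeness


def expected_exposures(spec: ProtocolSpec) -> ExposureSummary:
    """Expected per-session cumulative exposures and reward counts.

    Tone exposure is ``tones_per_session x mean tone duration`` (variable
    tones enter through their mean), ITI exposure is
    ``tones_per_session x mean ITI``.  Expected rewards:

    * negative contingency: the scheduling process runs only during ITIs,
      so rewards = cumulative ITI time / IRI.
    * zero contingency, operant: the random-interval schedule runs
      session-wide, so rewards = cumulative context time / IRI.
    * zero contingency, Pavlovian: the pellet budget is yoked to the
      ITI-only schedule (cumulative ITI time / IRI) but pellets fall at
      random times throughout the session, so the expected counts split in
      proportion to state exposure.
    """
    n = spec.tones_per_session
    cum_tone = n * spec.tone_duration_s
    cum_no_tone = n * spec.iti_mean_s
    cum_context = cum_tone + cum_no_tone
    if spec.contingency is Contingency.NEGATIVE:
        n_rewards = cum_no_tone / spec.iri_mean_s
        n_tone = 0.0
        n_no_tone = n_rewards
    else:  # zero contingency
        if spec.paradigm is Paradigm.OPERANT:
            n_rewards = cum_context / spec.iri_mean_s
        else:
            n_rewards = cum_no_tone / spec.iri_mean_s
        n_tone = n_rewards * cum_tone / cum_context
        n_no_tone = n_rewards * cum_no_tone / cum_context
    return ExposureSummary(
        cum_context_s=cum_context,
        cum_tone_s=cum_tone,
        cum_no_tone_s=cum_no_tone,
        n_rewards_context=n_rewards,
        n_rewards_no_tone=n_no_tone,
        n_rewards_tone=n_tone,
    )


def informativeness(exposures: ExposureSummary, signal: str = "offset") -> InformativenessReport:
    """Reinforcement rates, informativeness and mutual information.

    Parameters
    ----------
    exposures
        Expected (protocol-level) or empirical (event-log) exposures.
    signal
        Which cue transition is informative: ``"offset"`` (negative
        contingency; iota = lambda_ITI / lambda_C) or ``"onset"``
        (positive contingency; iota = lambda_tone / lambda_C).
    """
    if exposures.cum_context_s <= 0:
        raise ValueError("cum_context_s must be positive")
    if exposures.n_rewards_context <= 0:
        raise ValueError("reinforcement rates undefined with zero rewards")
    if exposures.cum_no_tone_s <= 0:
        raise ValueError("no-tone exposure must be positive")
    rate_c = 60.0 * exposures.n_rewards_context / exposures.cum_context_s
    rate_no_tone = 60.0 * exposures.n_rewards_no_tone / exposures.cum_no_tone_s
    rate_tone = (
        60.0 * exposures.n_rewards_tone / exposures.cum_tone_s
        if exposures.cum_tone_s > 0
        else 0.0
    )
    if signal == "offset":
        iota = rate_no_tone / rate_c
    elif signal == "onset":
        iota = rate_tone / rate_c
    else:
        raise ValueError("signal must be 'offset' or 'onset'")
    nats, bits = delta_H(iota)
    return InformativenessReport(
        rate_context_per_min=rate_c,
        rate_no_tone_per_min=rate_no_tone,
        rate_tone_per_min=rate_tone,
        iota=iota,
        delta_H_nats=nats,
        delta_H_bits=bits,
    )


def delta_H(iota: float) -> tuple[float, float]:
    """Mutual information conveyed by the informative cue transition.

    Returns ``(ln iota, log2 iota)``: the difference between the
    differential entropies of the exponential wait distributions before and
    after the transition.  The subjective temporal unit cancels in the
    difference, so the result is timescale invariant.
    """
    if not iota > 0:
        raise ValueError(f"iota must be positive, got {iota!r}")
    return math.log(iota), math.log2(iota)


# ---------------------------------------------------------------------------
# credit assignment


def assign_credit(exposures: ExposureSummary, singular_tol: float = 1e-9) -> CreditAssignment:
    """Attribute reinforcement rates to the tone and to the context alone.

    Solves ``P @ [rate_tone_attr, rate_no_tone_attr] = [rate_C, rate_noT]``
    where ``P = [[1, p(~T|C)], [1, 1]]`` and ``p(~T|C)`` is the probability
    that the tone is off at a random moment (cumulative ITI time over
    cumulative context time).  When ``p(~T|C) = 1`` within ``singular_tol``
    the matrix is singular (the tone is never on) and both attributed rates
    are the contextual rate.
    """
    if exposures.cum_context_s <= 0 or exposures.cum_no_tone_s <= 0:
        raise ValueError("cumulative durations must be positive")
    p = exposures.cum_no_tone_s / exposures.cum_context_s
    rate_c = 60.0 * exposures.n_rewards_context / exposures.cum_context_s
    rate_no_tone = 60.0 * exposures.n_rewards_no_tone / exposures.cum_no_tone_s
    matrix = np.array([[1.0, p], [1.0, 1.0]])
    if abs(p - 1.0) < singular_tol:
        return CreditAssignment(
            p_no_tone_given_context=p,
            matrix=matrix,
            attributed_rate_tone_per_min=rate_c,
            attributed_rate_no_tone_per_min=rate_c,
            singular=True,
        )
    sol = np.linalg.solve(matrix, np.array([rate_c, rate_no_tone]))
    return CreditAssignment(
        p_no_tone_given_context=p,
        matrix=matrix,
        attributed_rate_tone_per_min=float(sol[0]),
        attributed_rate_no_tone_per_min=float(sol[1]),
        singular=False,
    )


# ---------------------------------------------------------------------------
# learning-rate law


def predicted_acquisition(iota: float, k: float = 255.0) -> float:
    """Predicted reinforcements to acquisition, ``n_R = k / (iota - 1)``.

    The learning rate ``alpha = 1/n_R = (iota - 1)/k`` is a one-parameter
    near-linear function of informativeness; ``k = 255`` is the constant
    obtained from rat inhibitory-conditioning cohorts.  For ``iota <= 1``
    the predicted learning rate is non-positive and :data:`NOT_ACQUIRED`
    is returned.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    if iota <= 1:
        return NOT_ACQUIRED
    return k / (iota - 1.0)


def fit_k(points: Sequence[tuple[float, float]], fit_space: str = "log") -> LearningRateFit:
    """Least-squares fit of ``n_R = k/(iota - 1)`` to (iota, n_R) points.

    ``fit_space="log"`` (default) minimises squared residuals of
    ``ln n_R`` — appropriate because acquisition scores are plotted and
    dispersed multiplicatively (log-log) — with the closed form
    ``ln k = mean(ln n_R + ln(iota - 1))``.  ``fit_space="linear"``
    minimises squared residuals of ``n_R`` itself:
    ``k = sum(x_i y_i)/sum(x_i^2)`` with ``x_i = 1/(iota_i - 1)``.
    """
    pts = [(float(i), float(n)) for i, n in points]
    if len(pts) < 2:
        raise ValueError("need at least two (iota, n_r) points")
    if any(i <= 1 for i, _ in pts):
        raise ValueError("all iota values must exceed 1")
    if any(n <= 0 for _, n in pts):
        raise ValueError("all n_r values must be positive")
    iotas = np.array([i for i, _ in pts])
    n_r = np.array([n for _, n in pts])
    if fit_space == "log":
        k = float(np.exp(np.mean(np.log(n_r) + np.log(iotas - 1.0))))
    elif fit_space == "linear":
        x = 1.0 / (iotas - 1.0)
        k = float(np.dot(x, n_r) / np.dot(x, x))
    else:
        raise ValueError("fit_space must be 'log' or 'linear'")
    return LearningRateFit(points=tuple(pts), k=k, fit_space=fit_space)
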