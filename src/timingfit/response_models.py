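"""Per-event forward models of neural responses to visual event timing.

Two models map an event's (duration, period) to a relative neural
response amplitude, evaluated at the event's offset:

*Monotonic model* — response amplitude grows sub-linearly with both
event duration and event frequency (1/period)::

    A = beta_dur * duration**exp_dur + beta_freq * frequency**(exp_freq - 1)

with compressive exponents ``exp_dur``, ``exp_freq`` in (0, 1].  Note the
per-event frequency term is ``f**exp_freq / f``: summed over the events
of one second it gives ``f**exp_freq``, which is non-decreasing in
frequency — responses accumulate monotonically per unit time even though
the per-event amplitude falls with frequency.

*Tuned model* — an anisotropic two-dimensional Gaussian over (duration,
period), peaking at a preferred timing, times the same compressive
frequency term::

    A = exp(-0.5 * ((Y/sigma_maj)**2 + (X/sigma_min)**2)) * frequency**(exp_freq - 1)

where (X, Y) are the (duration, period) offsets from the preferred
timing rotated by the major-axis orientation ``theta``.

Rotation convention: a printed form of this rotation circulates in the
literature with ``Y = dDur*sin(theta) - dPer*cos(theta)``, whose rows are
not orthogonal for general theta (so major and minor axes would not be
perpendicular).  The default ``rotation_mode="corrected"`` uses the
proper rotation ``Y = dDur*sin(theta) + dPer*cos(theta)``; pass
``rotation_mode="as_printed"`` for a literal reproduction of the
non-orthogonal form.

All internal computation is in seconds and Hz; interfaces report ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stimulus_design import EventTiming, event_offsets


@dataclass(frozen=True)
class MonotonicParams:
    """Monotonic model parameters (durations in seconds internally)."""

    exp_dur: float
    exp_freq: float
    beta_dur: float = 1.0
    beta_freq: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.exp_dur <= 1 and 0 < self.exp_freq <= 1):
            raise ValueError("compressive exponents must lie in (0, 1]")
        if self.beta_dur < 0 or self.beta_freq < 0:
            raise ValueError("component amplitudes must be non-negative")

    @property
    def amplitude_ratio(self) -> float:
        """beta_dur / beta_freq; inf when the frequency component is absent."""
        if self.beta_freq == 0:
            return math.inf
        return self.beta_dur / self.beta_freq


@dataclass(frozen=True)
class TunedParams:
    """Tuned model parameters; preferred timings and extents in seconds."""

    pref_duration_s: float
    pref_period_s: float
    sigma_major: float
    sigma_minor: float
    theta_rad: float
    exp_freq: float

    def __post_init__(self) -> None:
        if self.sigma_minor <= 0 or self.sigma_major < self.sigma_minor:
            raise ValueError("require sigma_major >= sigma_minor > 0")
        if not 0 < self.exp_freq <= 1:
            raise ValueError("exp_freq must lie in (0, 1]")
        object.__setattr__(self, "theta_rad", self.theta_rad % math.pi)


def monotonic_event_amplitude(timing: EventTiming, params: MonotonicParams) -> float:
    """Eq.-style weighted sum of compressive duration and frequency terms."""
    d = timing.duration_s
    f = timing.frequency_hz
    return params.beta_dur * d**params.exp_dur + params.beta_freq * f ** (params.exp_freq - 1.0)


def tuned_event_amplitude(
    timing: EventTiming, params: TunedParams, rotation_mode: str = "corrected"
) -> float:
    """Anisotropic Gaussian in (duration, period) times the frequency term."""
    g = _tuned_gauss(
        np.asarray(timing.duration_s), np.asarray(timing.period_s), params, rotation_mode
    )
    return float(g) * timing.frequency_hz ** (params.exp_freq - 1.0)


def _tuned_gauss(dur_s, per_s, params: TunedParams, rotation_mode: str = "corrected"):
    dd = dur_s - params.pref_duration_s
    dp = per_s - params.pref_period_s
    c, s = math.cos(params.theta_rad), math.sin(params.theta_rad)
    x = dd * c - dp * s
    if rotation_mode == "corrected":
        y = dd * s + dp * c
    elif rotation_mode == "as_printed":
        y = dd * s - dp * c
    else:
        raise ValueError("rotation_mode must be 'corrected' or 'as_printed'")
    return np.exp(-0.5 * ((y / params.sigma_major) ** 2 + (x / params.sigma_minor) ** 2))


def neural_impulse_train(schedule, model, rotation_mode: str = "corrected"):
    """One (time_ms, amplitude) impulse per event, at the event offset."""
    offs = event_offsets(schedule)
    if isinstance(model, MonotonicParams):
        return [(t, monotonic_event_amplitude(tim, model)) for t, tim in offs]
    return [(t, tuned_event_amplitude(tim, model, rotation_mode)) for t, tim in offs]


# ---------------------------------------------------------------------------
# vectorized evaluation over timing tables (used by the fitting grid search)


def monotonic_amplitudes(dur_s: np.ndarray, freq_hz: np.ndarray, exp_dur, exp_freq):
    """Duration and frequency component amplitudes (unit betas), vectorized.

    Broadcasts exponent arrays against timing arrays: with ``exp_*`` of
    shape (k, 1) and timings of shape (m,), returns two (k, m) arrays.
    """
    return dur_s**np.asarray(exp_dur), freq_hz ** (np.asarray(exp_freq) - 1.0)


def tuned_amplitudes(
    dur_s: np.ndarray,
    per_s: np.ndarray,
    pref_dur,
    pref_per,
    sigma_major,
    sigma_minor,
    theta,
    exp_freq,
    rotation_mode: str = "corrected",
):
    """Tuned amplitudes for parameter arrays broadcast against timing arrays."""
    dd = dur_s - np.asarray(pref_dur)
    dp = per_s - np.asarray(pref_per)
    c, s = np.cos(np.asarray(theta)), np.sin(np.asarray(theta))
    x = dd * c - dp * s
    if rotation_mode == "corrected":
        y = dd * s + dp * c
    elif rotation_mode == "as_printed":
        y = dd * s - dp * c
    else:
        raise ValueError("rotation_mode must be 'corrected' or 'as_printed'")
    g = np.exp(-0.5 * ((y / np.asarray(sigma_major)) ** 2 + (x / np.asarray(sigma_minor)) ** 2))
    return g * (1.0 / per_s) ** (np.asarray(exp_freq) - 1.0)


def params_to_frame(params_list):
    """Serialize a list of parameter objects to a tidy table (ms units)."""
    import pandas as pd

    rows = []
    for p in params_list:
        if isinstance(p, MonotonicParams):
            rows.append(
                dict(
                    model="monotonic",
                    exp_dur=p.exp_dur,
                    exp_freq=p.exp_freq,
                    beta_dur=p.beta_dur,
                    beta_freq=p.beta_freq,
                    amplitude_ratio=p.amplitude_ratio,
                )
            )
        else:
            rows.append(
                dict(
                    model="tuned",
                    pref_duration_ms=p.pref_duration_s * 1000,
                    pref_period_ms=p.pref_period_s * 1000,
                    sigma_major_ms=p.sigma_major * 1000,
                    sigma_minor_ms=p.sigma_minor * 1000,
                    theta_rad=p.theta_rad,
                    exp_freq=p.exp_freq,
                )
            )
    return pd.DataFrame(rows)
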