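"""Trace cleaning and exponential-moving-average (EMA) low-pass filtering.

The raw amperogram carries instrument noise and injection spikes. Before onset
detection the signal is smoothed with the recursive EMA filter

    A_n = alpha * M + (1 - alpha) * A_{n-1}

where M is the new measurement and alpha in (0, 1] trades smoothing against
lag: smaller alpha removes more noise but delays the signal. The sweep over
alpha uses the standard period parameterization alpha = 2 / (p + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .signal_model import DEFAULT_DT, AmperogramTrace

__all__ = [
    "FilterConfig",
    "TraceRejection",
    "ema_filter",
    "alpha_from_p",
    "clean_trace",
]


@dataclass(frozen=True)
class FilterConfig:
    """EMA filter settings.

    alpha = 0 would freeze the output at its seed forever, so it is excluded;
    alpha = 1 is the identity filter. When `initial_value` is None the
    recurrence is seeded with the first raw sample, which avoids a startup
    transient on constant signals.
    """

    alpha: float = 0.22
    initial_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class TraceRejection:
    """A trace discarded during cleaning, with the reason why.

    reason is one of: non_finite_values, non_uniform_sampling, too_short,
    signal_loss.
    """

    reason: str
    detail: str = ""


def ema_filter(raw: AmperogramTrace, cfg: FilterConfig) -> AmperogramTrace:
    """Apply the causal EMA recurrence to a trace.

    The output has the same times as the input and every filtered value lies
    within [min(raw), max(raw)] — the recurrence is a convex combination.
    """
    y = raw.currents
    out = np.empty_like(y)
    state = float(y[0]) if cfg.initial_value is None else float(cfg.initial_value)
    a = cfg.alpha
    out[0] = a * y[0] + (1.0 - a) * state
    for i in range(1, len(y)):
        out[i] = a * y[i] + (1.0 - a) * out[i - 1]
    return raw.with_currents(out, filter_alpha=a)


class EmaStream:
    """Sample-by-sample EMA, for the streaming pipeline.

    Feeding the whole trace through :meth:`update` reproduces
    :func:`ema_filter` exactly.
    """

    def __init__(self, cfg: FilterConfig):
        self._alpha = cfg.alpha
        self._state = cfg.initial_value
        self._seed_from_first = cfg.initial_value is None

    def update(self, m: float) -> float:
        if self._state is None:
            self._state = float(m)
        state = self._alpha * float(m) + (1.0 - self._alpha) * self._state
        self._state = state
        return state


def alpha_from_p(p: int) -> float:
    """EMA smoothing constant from the period index p: alpha = 2/(p+1).

    p = 1 gives alpha = 1 (identity filter); the sweep uses p = 2..20.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    return 2.0 / (p + 1)


def alpha_report_value(p: int, decimals: int = 4) -> float:
    """alpha_from_p rounded for reporting in sweep tables."""
    return round(alpha_from_p(p), decimals)


def clean_trace(
    times,
    currents,
    dt: float = DEFAULT_DT,
    min_len: int = 2,
    gap_max: int = 3,
) -> Union[AmperogramTrace, TraceRejection]:
    """Validate a raw (time, current) series; return a trace or a rejection.

    Rejection reasons:

    - ``too_short``: fewer than `min_len` samples.
    - ``non_finite_values``: any NaN/inf in either column.
    - ``non_uniform_sampling``: the time axis deviates from a uniform grid
      with spacing `dt`.
    - ``signal_loss``: a run of at least `gap_max` consecutive samples at
      exactly zero — the device reporting nothing, not a real current.

    Rejection is a value, not an exception: dirty field data is expected.
    """
    times = np.asarray(times, dtype=float)
    currents = np.asarray(currents, dtype=float)
    if len(times) != len(currents):
        return TraceRejection(
            "non_uniform_sampling",
            f"{len(times)} times vs {len(currents)} currents",
        )
    if len(times) < min_len:
        return TraceRejection("too_short", f"{len(times)} samples < {min_len}")
    if not (np.all(np.isfinite(times)) and np.all(np.isfinite(currents))):
        bad = np.flatnonzero(~(np.isfinite(times) & np.isfinite(currents)))
        return TraceRejection("non_finite_values", f"first at sample {bad[0]}")
    if np.any(np.abs(np.diff(times) - dt) > 1e-9):
        bad = np.flatnonzero(np.abs(np.diff(times) - dt) > 1e-9)
        return TraceRejection("non_uniform_sampling", f"first gap after sample {bad[0]}")
    run = _longest_zero_run(currents)
    if run >= gap_max:
        return TraceRejection("signal_loss", f"{run} consecutive zero samples")
    return AmperogramTrace(times=times, currents=currents, dt=dt)


def _longest_zero_run(y: np.ndarray) -> int:
    longest = current = 0
    for v in y:
        current = current + 1 if v == 0.0 else 0
        longest = max(longest, current)
    return longest
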