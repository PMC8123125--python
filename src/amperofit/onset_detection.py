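"""Causal detection of the enzymatic-decay onset (the inflection point).

After injection the signal homogenizes stochastically — spikes and wander —
before the exponential decay begins. For a decaying exponential the first
derivative is most negative right where the decay starts, so the onset is
declared at the minimum of the first derivative of the *filtered* signal.

Working in real time the global minimum is unknowable, so a candidate minimum
is only declared once the derivative has stayed at or above it for
`confirm_k` consecutive samples (the confirmation horizon). If the signal
rises again (derivative above +`rise_eps`) the candidate was an injection
spike, not the decay: it is discarded and the search re-arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signal_model import AmperogramTrace

__all__ = [
    "OnsetConfig",
    "OnsetResult",
    "OnsetDetector",
    "discrete_derivative",
    "find_onset",
]


@dataclass(frozen=True)
class OnsetConfig:
    """Thresholds for the causal onset search.

    confirm_k: samples the derivative must stay >= the running minimum before
    that minimum is confirmed as the onset. rise_eps: derivative above this
    (current units / s) counts as "signal increasing" and re-arms the search.

    min_drop: total signal drop (current units) from the trace start a
    candidate must exceed before it can be confirmed; 0 disables the check.

    deriv_snr: significance guard against noise dips on the baseline being
    confirmed as the decay onset. A sample can only become a candidate if its
    derivative is below −deriv_snr × (running SD of the derivative over the
    samples seen so far, robustly estimated). On the plateau that running SD
    is the derivative noise floor, which a genuine onset undercuts by an
    order of magnitude while noise dips stay within a few SD. Noiseless
    signals have a zero floor, so the guard is inert there; 0 disables it.

    drop_snr: guard against the falling edge of an injection spike anchoring
    the onset. At a spike fall the signal is still at (or above) the
    baseline, whereas at the true onset's derivative minimum it has already
    lost a visible part of the span; a candidate is therefore only confirmed
    once the drop from the trace start exceeds
    max(min_drop, drop_snr × noise floor × dt). With a zero noise floor
    (noiseless data) this degenerates to requiring a strictly positive drop.
    0 disables it (then only min_drop applies, if set).
    """

    confirm_k: int = 3
    rise_eps: float = 0.0
    min_drop: float = 0.0
    deriv_snr: float = 4.0
    drop_snr: float = 10.0

    def __post_init__(self) -> None:
        if self.confirm_k < 1:
            raise ValueError(f"confirm_k must be >= 1, got {self.confirm_k}")
        if self.rise_eps < 0:
            raise ValueError(f"rise_eps must be >= 0, got {self.rise_eps}")
        if self.min_drop < 0:
            raise ValueError(f"min_drop must be >= 0, got {self.min_drop}")
        if self.deriv_snr < 0:
            raise ValueError(f"deriv_snr must be >= 0, got {self.deriv_snr}")
        if self.drop_snr < 0:
            raise ValueError(f"drop_snr must be >= 0, got {self.drop_snr}")


@dataclass(frozen=True)
class OnsetResult:
    detected: bool
    onset_index: int = -1
    onset_time: float = float("nan")
    derivative_at_onset: float = float("nan")
    restarts: int = 0
    #: index of the sample at which the decision became available (causality
    #: bookkeeping: onset_index + confirm_k when detected)
    decided_at_index: int = -1


def discrete_derivative(trace: AmperogramTrace) -> np.ndarray:
    """First backward difference (y[i] − y[i−1]) / dt for i >= 1.

    Length is len(trace) − 1; entry j corresponds to trace sample j + 1.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples for a derivative")
    return np.diff(trace.currents) / trace.dt


class OnsetDetector:
    """Streaming onset detector; feed filtered samples one at a time.

    State machine per derivative sample d:

    - d > rise_eps: the signal is rising (a spike); any candidate is dropped
      and the search re-arms (restart counted only if a candidate existed).
    - d < current candidate minimum (and d < 0): new candidate, confirmation
      counter resets.
    - otherwise: the candidate survives one more sample; after `confirm_k`
      surviving samples it is confirmed, provided the cumulative drop from the
      first sample exceeds `min_drop`.

    The decision at sample i therefore uses samples [0, i] only.
    """

    def __init__(self, cfg: OnsetConfig, dt: float = 1.0):
        self.cfg = cfg
        self.dt = dt
        self._prev: Optional[float] = None
        self._first: Optional[float] = None
        self._index = -1
        self._cand_index: Optional[int] = None
        self._cand_deriv = 0.0
        self._cand_value = 0.0
        self._confirm = 0
        self._last_d: Optional[float] = None
        self.restarts = 0
        self.result: Optional[OnsetResult] = None
        # Welford accumulator for the derivative noise floor (causal)
        self._d_count = 0
        self._d_mean = 0.0
        self._d_m2 = 0.0

    def _noise_floor(self) -> float:
        """Running SD of all derivative samples seen so far."""
        if self._d_count < 2:
            return 0.0
        return (self._d_m2 / (self._d_count - 1)) ** 0.5

    def _significant(self, d: float) -> bool:
        if self.cfg.deriv_snr == 0.0:
            return d < 0.0
        if self._d_count < 3:
            return False  # no noise floor yet: withhold judgement
        return d < -self.cfg.deriv_snr * self._noise_floor()

    def update(self, y: float, t: Optional[float] = None) -> Optional[OnsetResult]:
        """Consume one filtered sample; return the OnsetResult once decided."""
        if self.result is not None:
            return self.result
        self._index += 1
        if self._prev is None:
            self._prev = y
            self._first = y
            return None
        d = (y - self._prev) / self.dt
        self._prev = y
        significant = self._significant(d)
        # Robust floor update: spikes and the decay itself are outliers
        # against the plateau noise and must not inflate the floor estimate.
        floor = self._noise_floor()
        if self._d_count < 3 or abs(d - self._d_mean) <= 4.0 * floor:
            self._d_count += 1
            delta = d - self._d_mean
            self._d_mean += delta / self._d_count
            self._d_m2 += delta * (d - self._d_mean)

        if d > self.cfg.rise_eps:
            # an increase re-arms the search; it counts as a restart whenever
            # it interrupts one (an active candidate, or a non-rising stretch)
            if self._cand_index is not None or self._last_d is not None and self._last_d <= self.cfg.rise_eps:
                self.restarts += 1
            self._cand_index = None
            self._confirm = 0
            self._last_d = d
            return None
        self._last_d = d

        new_candidate = (
            self._cand_index is None and significant
        ) or (self._cand_index is not None and d < self._cand_deriv)
        if new_candidate:
            self._cand_index = self._index
            self._cand_deriv = d
            self._cand_value = y
            self._confirm = 0
            return None

        if self._cand_index is not None:
            self._confirm += 1
            if self._confirm >= self.cfg.confirm_k:
                drop = self._first - self._cand_value
                required = max(
                    self.cfg.min_drop,
                    self.cfg.drop_snr * self._noise_floor() * self.dt,
                )
                disabled = self.cfg.min_drop == 0.0 and self.cfg.drop_snr == 0.0
                if disabled or drop > required:
                    onset_time = (
                        self._cand_index * self.dt if t is None
                        else t - (self._index - self._cand_index) * self.dt
                    )
                    self.result = OnsetResult(
                        detected=True,
                        onset_index=self._cand_index,
                        onset_time=onset_time,
                        derivative_at_onset=self._cand_deriv,
                        restarts=self.restarts,
                        decided_at_index=self._index,
                    )
                    return self.result
                # confirmed but the drop is too small: discard, keep searching
                self._cand_index = None
                self._confirm = 0
        return None

    def finish(self) -> OnsetResult:
        """Trace ended with no confirmed onset."""
        if self.result is None:
            self.result = OnsetResult(detected=False, restarts=self.restarts)
        return self.result


def find_onset(filtered: AmperogramTrace, cfg: OnsetConfig) -> OnsetResult:
    """Batch wrapper: run the causal detector over a whole filtered trace."""
    det = OnsetDetector(cfg, dt=filtered.dt)
    for t, y in zip(filtered.times, filtered.currents):
        res = det.update(float(y), t=float(t))
        if res is not None:
            return res
    return det.finish()
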