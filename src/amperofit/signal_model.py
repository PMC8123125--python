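"""One-phase exponential decay model of the biosensor response.

After sample injection the enzymatic RedOx reaction consumes the analyte and
the cell current relaxes from the baseline Io toward the equilibrium current
I_inf following

    I(t) = A * exp(-B * t) + C

where ``A`` is the span (Io - I_inf, proportional to analyte concentration),
``B`` the decay rate of the reaction and ``C`` the asymptotic current I_inf.
Model time ``t`` is measured from the detected reaction onset, so ``A`` is
directly the remaining span at onset and ``B`` does not depend on when the
sample was injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "AmperogramTrace",
    "ExpDecayParams",
    "FitWindow",
    "model_current",
    "jacobian_row",
]

#: default sampling interval, seconds (the device registers one sample per second)
DEFAULT_DT = 1.0

_SPACING_TOL = 1e-9


@dataclass(frozen=True)
class AmperogramTrace:
    """A uniformly sampled current-vs-time series.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing with uniform spacing `dt`.
    currents
        Measured (or filtered) currents, same length as `times`; units are the
        device's raw current units (typically nA).
    dt
        Sampling interval in seconds.
    meta
        Free-form provenance tags (source file, filter settings, ...).
    """

    times: np.ndarray
    currents: np.ndarray
    dt: float = DEFAULT_DT
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        currents = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "currents", currents)
        if times.ndim != 1 or currents.ndim != 1:
            raise ValueError("times and currents must be one-dimensional")
        if len(times) != len(currents):
            raise ValueError(
                f"length mismatch: {len(times)} times vs {len(currents)} currents"
            )
        if len(times) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(currents)):
            raise ValueError("trace contains non-finite values")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        steps = np.diff(times)
        if np.any(np.abs(steps - self.dt) > _SPACING_TOL):
            raise ValueError("times are not uniformly spaced at dt")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Elapsed time between first and last sample, seconds."""
        return float(self.times[-1] - self.times[0])

    def with_currents(self, currents: np.ndarray, **meta: Any) -> "AmperogramTrace":
        """Return a copy carrying new current values (e.g. after filtering)."""
        return AmperogramTrace(
            times=self.times,
            currents=np.asarray(currents, dtype=float),
            dt=self.dt,
            meta={**self.meta, **meta},
        )


@dataclass(frozen=True)
class ExpDecayParams:
    """The (A, B, C) triple of the one-phase decay model.

    A: span amplitude (current units); B: decay rate (1/s); C: asymptotic
    current (current units). An accepted fit requires B >= 0 — negative B is
    growth, which contradicts the decay model.
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.A, self.B, self.C)):
            raise ValueError(f"non-finite parameters: {(self.A, self.B, self.C)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C], dtype=float)

    @classmethod
    def from_array(cls, beta: np.ndarray) -> "ExpDecayParams":
        return cls(A=float(beta[0]), B=float(beta[1]), C=float(beta[2]))


@dataclass(frozen=True)
class FitWindow:
    """Post-onset buffer handed to the fitter: times relative to onset."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if len(t) != len(y):
            raise ValueError("t and y must have the same length")
        if len(t) == 0 or t[0] != 0.0:
            raise ValueError("window time axis must start at 0 (onset)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("window times must be strictly increasing")

    @property
    def length(self) -> int:
        return len(self.t)


def model_current(t, params: ExpDecayParams):
    """Evaluate the decay model A·exp(−B·t) + C.

    Accepts a scalar or array of times (seconds from onset) and returns the
    modeled current. Monotone non-increasing in ``t`` for A ≥ 0, B ≥ 0, with
    limit C as t → ∞.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time value")
    out = params.A * np.exp(-params.B * t) + params.C
    return float(out) if out.ndim == 0 else out


def jacobian_row(t, params: ExpDecayParams):
    """Partial derivatives of the model w.r.t. (A, B, C) at time(s) ``t``.

    Returns ``(∂f/∂A, ∂f/∂B, ∂f/∂C) = (e^{−Bt}, −A·t·e^{−Bt}, 1)``; each
    entry is a scalar for scalar ``t`` or an array matching ``t``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time value")
    e = np.exp(-params.B * t)
    dA = e
    dB = -params.A * t * e
    dC = np.ones_like(t)
    if t.ndim == 0:
        return float(dA), float(dB), float(dC)
    return dA, dB, dC
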