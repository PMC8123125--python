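"""Synthetic amperogram generator with attached ground truth.

Emulates the structure of real enzyme-biosensor analyses: a baseline plateau
at Io while the cell sits at its working potential, a stochastic
homogenization transient after sample injection (random spikes, optionally an
initial overshoot), an exponential decay A·e^{−B·(t−t_onset)} + C toward the
equilibrium current I_inf, additive Gaussian noise throughout, and an
automatic end of analysis once the (filtered) signal has stabilized.

Continuity ties the pieces together: the plateau current Io equals A + C, so
the decay takes over exactly where the plateau left off and the full span of
the decay is A — proportional, physically, to the analyte concentration.

The stabilization rule stands in for the device's proprietary end-of-analysis
logic: the analysis ends once the lightly filtered signal has changed by less
than ``stab_change`` over the trailing ``stab_window_s`` seconds, for
``stab_len`` consecutive samples after onset, capped at ``max_duration_s``.
A trailing-change rule (rather than an instantaneous-slope one) lets the
monitor terminate a near-instant reaction within seconds of its end while
remaining sensitive enough not to cut a slow decay far from its asymptote.

Known simplifications: noise is white Gaussian (real traces may carry mains
hum and autocorrelated drift), and the decay is a single exponential phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .preprocessing import FilterConfig, ema_filter
from .signal_model import AmperogramTrace

__all__ = ["TraceSpec", "DEFAULT_COHORT_RANGES", "generate_trace", "generate_cohort"]


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one synthetic analysis. Units: seconds, device current."""

    A: float = 20.0            # span (decay amplitude)
    B: float = 0.12            # decay rate, 1/s
    C: float = 15.0            # equilibrium current I_inf
    plateau_s: float = 12.0    # baseline duration before injection
    transient_s: float = 5.0   # homogenization duration
    spike_prob: float = 0.25   # per-sample spike probability in the transient
    spike_amp: float = 2.0     # spike magnitude scale (current units)
    overshoot_amp: float = 0.0  # optional decaying bump at injection
    overshoot_tau_s: float = 3.0
    noise_sigma: float = 0.2   # additive white-noise SD (current units)
    dt: float = 1.0
    seed: int = 0
    stab_window_s: float = 5.0  # trailing change window of the end monitor
    stab_change: Optional[float] = None  # default: max(1% of span, noise-calibrated)
    stab_len: int = 2
    stab_alpha: float = 0.4    # light EMA used by the stabilization monitor
    max_duration_s: float = 300.0

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError(f"decay rate B must be > 0, got {self.B}")
        if min(self.plateau_s, self.transient_s) < 0:
            raise ValueError("durations must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.spike_prob <= 1.0):
            raise ValueError(f"spike_prob must be in [0, 1], got {self.spike_prob}")

    @property
    def I0(self) -> float:
        """Baseline current; A + C by continuity at the injection hand-off."""
        return self.A + self.C

    @property
    def onset_time(self) -> float:
        return self.plateau_s + self.transient_s


def generate_trace(spec: TraceSpec) -> Tuple[AmperogramTrace, Dict[str, float]]:
    """Build one synthetic amperogram and its ground truth.

    Ground truth: ``onset_time`` (= plateau_s + transient_s by construction),
    ``I_inf`` (= C), ``span`` (= A), ``end_time`` (stabilization instant) and
    ``truncated`` (1.0 if the cap ended the trace before stabilization).
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.dt
    n_max = int(round(spec.max_duration_s / dt)) + 1
    t = np.arange(n_max) * dt

    n_plateau = int(round(spec.plateau_s / dt))
    n_transient = int(round(spec.transient_s / dt))
    i_onset = n_plateau + n_transient

    y = np.empty(n_max)
    y[:i_onset] = spec.I0
    # stochastic homogenization: spikes (and optional overshoot) on the hold
    if n_transient > 0:
        tr = slice(n_plateau, i_onset)
        spikes = rng.random(n_transient) < spec.spike_prob
        y[tr] += spikes * spec.spike_amp * rng.uniform(0.5, 1.5, n_transient)
        if spec.overshoot_amp > 0:
            tt = np.arange(n_transient) * dt
            y[tr] += spec.overshoot_amp * np.exp(-tt / spec.overshoot_tau_s)
    # enzymatic decay from onset
    y[i_onset:] = spec.A * np.exp(-spec.B * (t[i_onset:] - t[i_onset])) + spec.C
    if spec.noise_sigma > 0:
        y += rng.normal(0.0, spec.noise_sigma, n_max)

    end_idx, truncated = _stabilization_index(y, spec, i_onset)
    trace = AmperogramTrace(
        times=t[: end_idx + 1],
        currents=y[: end_idx + 1],
        dt=dt,
        meta={"synthetic": True, "seed": spec.seed},
    )
    truth = {
        "onset_time": float(i_onset * dt),
        "I_inf": spec.C,
        "span": spec.A,
        "B": spec.B,
        "end_time": float(end_idx * dt),
        "truncated": float(truncated),
    }
    return trace, truth


def _stabilization_index(y: np.ndarray, spec: TraceSpec, i_onset: int) -> Tuple[int, bool]:
    """First index where the trailing change stays small for stab_len samples.

    The change threshold defaults to 1% of the span, but never below 2x the
    noise SD of the trailing difference — a cutoff buried in the noise would
    postpone the end of the analysis indefinitely, which no instrument's
    termination logic would do.
    """
    a = spec.stab_alpha
    if spec.stab_change is not None:
        stab_change = spec.stab_change
    else:
        diff_noise_sd = spec.noise_sigma * np.sqrt(2.0 * a / (2.0 - a))
        stab_change = max(0.01 * spec.A, 2.0 * diff_noise_sd)
    times = np.arange(len(y)) * spec.dt
    filt = ema_filter(
        AmperogramTrace(times=times, currents=y, dt=spec.dt),
        FilterConfig(alpha=a),
    ).currents
    lag = max(1, int(round(spec.stab_window_s / spec.dt)))
    run = 0
    start = max(i_onset, lag)
    for j in range(start, len(filt)):
        change = abs(filt[j] - filt[j - lag])
        run = run + 1 if change < stab_change else 0
        if run >= spec.stab_len:
            return j, False
    return len(y) - 1, True


#: Cohort sampling ranges emulating routine food-safety analyses: spans and
#: residual currents of comparable magnitude (tens of nA), decay rates giving
#: stabilization within tens of seconds so analyses center near one minute,
#: short stochastic injection transients, ~1% of span measurement noise.
#: A small fraction of reactions (``fast_frac``) is drawn from the ``B_fast``
#: range instead of ``B``: near-instant conversions whose analysis ends
#: within 10–20 s of onset. Real cohorts contain such analyses (high enzyme
#: activity, low substrate) and they are what makes long buffers
#: inapplicable to part of the data.
DEFAULT_COHORT_RANGES: Dict[str, Tuple[float, float]] = {
    "A": (5.0, 40.0),
    "B": (0.072, 0.33),
    "B_fast": (0.9, 1.5),
    "fast_frac": (0.05, 0.05),
    "C": (5.0, 40.0),
    "plateau_s": (5.0, 20.0),
    "transient_s": (2.0, 8.0),
    "spike_prob": (0.1, 0.4),
    "spike_amp_rel": (0.05, 0.25),   # spike size as a fraction of the span
    "noise_rel": (0.01, 0.01),       # noise SD as a fraction of the span
    "overshoot_rel": (0.0, 0.0),
}


def generate_cohort(
    n: int,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
) -> List[Tuple[AmperogramTrace, Dict[str, float]]]:
    """Draw ``n`` independent traces with spec fields uniform over ``ranges``.

    ``ranges`` overlays :data:`DEFAULT_COHORT_RANGES`; ``spike_amp_rel``,
    ``noise_rel`` and ``overshoot_rel`` are resolved against the drawn span A.
    Reproducible: the same (n, ranges, seed) always yields the same cohort,
    with an independent per-trace sub-seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    eff = dict(DEFAULT_COHORT_RANGES)
    if ranges:
        unknown = set(ranges) - set(eff)
        if unknown:
            raise ValueError(f"unknown range keys: {sorted(unknown)}")
        eff.update(ranges)
    for key, (lo, hi) in eff.items():
        if hi < lo:
            raise ValueError(f"inverted range for {key}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    trace_seeds = rng.integers(0, 2**31 - 1, size=n)

    def draw(key: str) -> float:
        lo, hi = eff[key]
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    cohort = []
    for k in range(n):
        a = draw("A")
        fast = rng.random() < draw("fast_frac")
        if fast:
            b = draw("B_fast")
        else:
            # uniform in the time constant 1/B, not in B: analysis durations
            # then spread evenly instead of piling up at the fast end
            b_lo, b_hi = eff["B"]
            b = 1.0 / rng.uniform(1.0 / b_hi, 1.0 / b_lo) if b_hi > b_lo else b_lo
        spec = TraceSpec(
            A=a,
            B=b,
            C=draw("C"),
            plateau_s=round(draw("plateau_s")),
            transient_s=round(draw("transient_s")),
            spike_prob=draw("spike_prob"),
            spike_amp=draw("spike_amp_rel") * a,
            overshoot_amp=draw("overshoot_rel") * a,
            noise_sigma=draw("noise_rel") * a,
            seed=int(trace_seeds[k]),
        )
        cohort.append(generate_trace(spec))
    return cohort
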