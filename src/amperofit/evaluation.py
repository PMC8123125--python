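"""Cohort-level evaluation: percentage error, α sweep and window sweep.

The method's two tuning studies are reproduced as sweeps over a cohort of
traces: the EMA smoothing constant α (via its period index p, α = 2/(p+1))
with the buffer length fixed, and the buffer length with α fixed. Each sweep
row summarizes how often the algorithm could be applied, how accurate the
predicted endpoint was, and how much analysis time was saved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import nan
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .endpoint_estimator import EstimatorConfig, StreamOutcome, run_streaming
from .preprocessing import alpha_from_p
from .signal_model import AmperogramTrace

__all__ = [
    "SweepSummary",
    "percent_error",
    "signed_percent_error",
    "run_cohort",
    "sweep_alpha",
    "sweep_window",
    "duration_stats",
]


def signed_percent_error(i_real: float, i_estimated: float) -> float:
    """(I_real − I_estimated) / I_real × 100; sign shows the bias direction."""
    if i_real == 0:
        raise ValueError("percentage error undefined for I_real == 0")
    return (i_real - i_estimated) / i_real * 100.0


def percent_error(i_real: float, i_estimated: float) -> float:
    """Magnitude of the percentage relative error between real and estimated
    endpoint currents. Reported errors are magnitudes; use
    :func:`signed_percent_error` for bias diagnostics."""
    return abs(signed_percent_error(i_real, i_estimated))


@dataclass(frozen=True)
class SweepSummary:
    """One row of a sweep table.

    Error columns are over predicted cases only (the "No algorithm" count is
    its own column); a misestimation is a predicted case with |PE| > 20%.
    With no predicted cases the error columns are NaN.
    """

    key: float                # swept value: p (alpha sweep) or window size
    total: int
    no_algorithm: int
    misestimation_pct: float
    mean_error_pct: float
    std_error_pct: float
    pe_lt10_pct: float
    pe_lt20_pct: float
    pe_10to20_pct: float
    mean_saved_s: float
    std_saved_s: float

    @property
    def predicted(self) -> int:
        return self.total - self.no_algorithm

    @classmethod
    def from_outcomes(cls, key: float, outcomes: Sequence[StreamOutcome]) -> "SweepSummary":
        total = len(outcomes)
        pes = np.array([o.pe for o in outcomes if o.predicted])
        saved = np.array([o.saved_time_s for o in outcomes if o.predicted])
        n_pred = len(pes)
        if n_pred == 0:
            return cls(
                key=key, total=total, no_algorithm=total,
                misestimation_pct=nan, mean_error_pct=nan, std_error_pct=nan,
                pe_lt10_pct=nan, pe_lt20_pct=nan, pe_10to20_pct=nan,
                mean_saved_s=nan, std_saved_s=nan,
            )
        lt10 = float(np.mean(pes < 10.0) * 100.0)
        lt20 = float(np.mean(pes <= 20.0) * 100.0)
        return cls(
            key=key,
            total=total,
            no_algorithm=total - n_pred,
            misestimation_pct=100.0 - lt20,
            mean_error_pct=float(np.mean(pes)),
            std_error_pct=float(np.std(pes, ddof=1)) if n_pred > 1 else 0.0,
            pe_lt10_pct=lt10,
            pe_lt20_pct=lt20,
            pe_10to20_pct=lt20 - lt10,
            mean_saved_s=float(np.mean(saved)),
            std_saved_s=float(np.std(saved, ddof=1)) if n_pred > 1 else 0.0,
        )


Cohort = Sequence[Tuple[AmperogramTrace, Dict[str, float]]]


def run_cohort(cohort: Cohort, cfg: EstimatorConfig) -> List[StreamOutcome]:
    """Run the streaming estimator over every trace of a cohort."""
    return [run_streaming(trace, cfg) for trace, _ in cohort]


def sweep_alpha(
    cohort: Cohort,
    p_values: Iterable[int],
    cfg: EstimatorConfig,
) -> List[SweepSummary]:
    """One summary row per EMA period index p, buffer length held fixed."""
    if not len(cohort):
        raise ValueError("empty cohort")
    rows = []
    for p in p_values:
        run_cfg = replace(
            cfg, filter=replace(cfg.filter, alpha=alpha_from_p(p))
        )
        rows.append(SweepSummary.from_outcomes(p, run_cohort(cohort, run_cfg)))
    return rows


def sweep_window(
    cohort: Cohort,
    windows: Iterable[int],
    cfg: EstimatorConfig,
) -> List[SweepSummary]:
    """One summary row per buffer length, α held fixed."""
    if not len(cohort):
        raise ValueError("empty cohort")
    rows = []
    for w in windows:
        run_cfg = replace(cfg, window_size=int(w))
        rows.append(SweepSummary.from_outcomes(w, run_cohort(cohort, run_cfg)))
    return rows


def duration_stats(outcomes: Sequence[StreamOutcome]) -> Dict[str, float]:
    """Analysis-duration statistics with and without the early-stopping
    algorithm, over predicted cases.

    The "with algorithm" duration of a predicted trace is onset + buffer —
    the moment the prediction is emitted. Variance is the n−1 sample
    convention.
    """
    pred = [o for o in outcomes if o.predicted]
    if len(pred) < 2:
        raise ValueError("need at least 2 predicted outcomes")
    orig = np.array([o.trace_duration_s for o in pred])
    eff = np.array([o.trace_duration_s - o.saved_time_s for o in pred])
    return {
        "mean_s": float(np.mean(orig)),
        "variance_s2": float(np.var(orig, ddof=1)),
        "with_algorithm_mean_s": float(np.mean(eff)),
        "with_algorithm_variance_s2": float(np.var(eff, ddof=1)),
    }
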