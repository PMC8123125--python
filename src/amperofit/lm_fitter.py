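"""Levenberg–Marquardt fitting of the one-phase decay on a short buffer.

The solver is written out explicitly (normal equations, damping, the
accept/reject λ schedule) because fitting a 3-parameter model on a 10–25
sample buffer is the core of the real-time estimator and has to run with
predictable, tiny cost on embedded-class hardware.

Each iteration solves the damped normal equations

    (JᵗJ + λ·I) δ = Jᵗ E,      E = y − f(t; A, B, C)

and proposes β' = β + δ. If the sum of squared errors decreased the step is
accepted and λ shrinks by `lambda_factor`; otherwise the step is discarded
and λ grows by the same factor, sliding the method from Gauss–Newton (small
λ) toward gradient descent (large λ). Iterations stop when an accepted step
no longer reduces the SSE meaningfully.

The damping term is λ·I by default. Classic Marquardt scaling,
λ·diag(JᵗJ), is available via ``LMConfig.damping`` for comparison.

The starting point comes from a linearization: with the asymptote pinned
slightly below the window minimum, ln(y − Ĉ) is linear in t and ordinary
least squares yields ln Â and −B̂.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .signal_model import ExpDecayParams, FitWindow, jacobian_row, model_current

__all__ = [
    "LMConfig",
    "FitResult",
    "DegenerateWindowError",
    "initial_guess",
    "lm_step",
    "lm_fit",
    "sse",
]

_EPS_SPAN = 1e-12  # below this span a window is considered constant
_B_FLOOR = 1e-6    # 1/s; keeps the initial guess a decay, never exactly flat
_GRAD_TOL = 1e-12  # ‖JᵗE‖∞ below this is machine-scale: already at an optimum


class DegenerateWindowError(ValueError):
    """The buffer carries no usable decay signal (e.g. constant)."""


@dataclass(frozen=True)
class LMConfig:
    """Solver knobs. λ starts at 0.1 and moves by factors of 10.

    sse_rel_tol is the relative SSE decrease on an accepted step below which
    the iteration is declared converged; lambda_max aborts runaway damping.
    """

    lambda0: float = 0.1
    lambda_factor: float = 10.0
    max_iter: int = 200
    sse_rel_tol: float = 1e-8
    lambda_max: float = 1e10
    damping: str = "identity"  # "identity" (λ·I) or "diag" (λ·diag(JᵗJ))

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda0 <= 1.0):
            raise ValueError(f"lambda0 must be in (0, 1], got {self.lambda0}")
        if self.lambda_factor <= 1.0:
            raise ValueError(f"lambda_factor must be > 1, got {self.lambda_factor}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.damping not in ("identity", "diag"):
            raise ValueError(f"unknown damping mode {self.damping!r}")


@dataclass(frozen=True)
class IterationRecord:
    sse: float
    lam: float
    accepted: bool


@dataclass(frozen=True)
class FitResult:
    params: ExpDecayParams
    sse: float
    n_iter: int
    converged: bool
    lambda_final: float
    history: Tuple[IterationRecord, ...] = field(default_factory=tuple)


def sse(params: ExpDecayParams, window: FitWindow) -> float:
    """Sum of squared residuals of the model over the buffer."""
    r = window.y - model_current(window.t, params)
    return float(r @ r)


def initial_guess(window: FitWindow, eps: float = 0.01) -> ExpDecayParams:
    """Linearization-based starting point for the LM iteration.

    Pins Ĉ = min(y) − eps·span (so y − Ĉ > 0 everywhere), then regresses
    ln(y − Ĉ) on t: the intercept is ln Â and the slope −B̂. The eps shift
    biases Ĉ slightly low; LM corrects it in the nonlinear phase.
    """
    y = window.y
    span = float(np.max(y) - np.min(y))
    if span < _EPS_SPAN:
        raise DegenerateWindowError("constant window: no decay to linearize")
    c_hat = float(np.min(y)) - eps * span
    shifted = y - c_hat
    if np.any(shifted <= 0):
        raise DegenerateWindowError("shifted window not positive; cannot take log")
    slope, intercept = np.polyfit(window.t, np.log(shifted), 1)
    a_hat = float(np.exp(intercept))
    b_hat = max(float(-slope), _B_FLOOR)
    return ExpDecayParams(A=a_hat, B=b_hat, C=c_hat)


def _solve_damped(
    params: ExpDecayParams, lam: float, window: FitWindow, damping: str
) -> np.ndarray:
    dA, dB, dC = jacobian_row(window.t, params)
    J = np.column_stack([dA, dB, dC])
    E = window.y - model_current(window.t, params)
    H = J.T @ J
    g = J.T @ E
    if damping == "identity":
        D = np.eye(3)
    else:
        D = np.diag(np.diag(H))
    if not np.all(np.isfinite(H)) or not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite normal equations")
    return np.linalg.solve(H + lam * D, g)


def lm_step(
    params: ExpDecayParams,
    lam: float,
    window: FitWindow,
    cfg: LMConfig,
) -> Tuple[ExpDecayParams, float, bool, float]:
    """One damped Gauss–Newton trial step.

    Returns (params', λ', accepted, sse'). On acceptance λ' = λ/factor and
    params' is the updated triple; on rejection params' is unchanged and
    λ' = λ·factor.
    """
    current_sse = sse(params, window)
    delta = _solve_damped(params, lam, window, cfg.damping)
    candidate = ExpDecayParams.from_array(params.as_array() + delta)
    candidate_sse = sse(candidate, window)
    # ties accept: at an exact optimum δ = 0 and the SSE is unchanged, which
    # is a successful (if vacuous) step, not a failed one
    if np.isfinite(candidate_sse) and candidate_sse <= current_sse:
        return candidate, lam / cfg.lambda_factor, True, candidate_sse
    return params, lam * cfg.lambda_factor, False, current_sse


def lm_fit(
    window: FitWindow,
    cfg: Optional[LMConfig] = None,
    init: Optional[ExpDecayParams] = None,
) -> FitResult:
    """Fit (A, B, C) to the buffer; returns the best parameters seen.

    Convergence: an accepted step whose relative SSE decrease falls below
    ``cfg.sse_rel_tol``, or a gradient already at machine scale. Runaway
    damping (λ > lambda_max) or the iteration cap ends the fit with
    ``converged=False``. A final B < 0 (growth, not decay) is also flagged
    not converged — the model is then physically meaningless for this signal.
    """
    cfg = cfg or LMConfig()
    if window.length < 3:
        raise DegenerateWindowError("need at least 3 samples to fit 3 parameters")
    params = initial_guess(window) if init is None else init
    lam = cfg.lambda0
    best = params
    best_sse = sse(params, window)
    history: List[IterationRecord] = []
    converged = False

    for _ in range(cfg.max_iter):
        if _grad_inf_norm(params, window) < _GRAD_TOL:
            converged = True
            break
        try:
            params_new, lam_new, accepted, new_sse = lm_step(params, lam, window, cfg)
        except (np.linalg.LinAlgError, FloatingPointError):
            converged = False
            break
        history.append(IterationRecord(sse=new_sse, lam=lam, accepted=accepted))
        if accepted:
            prev_sse = best_sse
            params = params_new
            if new_sse < best_sse:
                best, best_sse = params_new, new_sse
            rel_drop = (prev_sse - new_sse) / max(prev_sse, np.finfo(float).tiny)
            lam = lam_new
            if rel_drop < cfg.sse_rel_tol:
                converged = True
                break
        else:
            lam = lam_new
            if lam > cfg.lambda_max:
                # damping exhausted: the error "does not decrease anymore".
                # That is convergence if any progress was ever made (SSE is
                # monotone over accepted steps, so the iterate cannot have
                # drifted); from a start that never produced a downhill step
                # it is a failed fit.
                converged = (
                    any(h.accepted for h in history)
                    or _grad_inf_norm(params, window) < _GRAD_TOL
                )
                break

    if best.B < 0:
        converged = False
    return FitResult(
        params=best,
        sse=best_sse,
        n_iter=len(history),
        converged=converged,
        lambda_final=lam,
        history=tuple(history),
    )


def _grad_inf_norm(params: ExpDecayParams, window: FitWindow) -> float:
    dA, dB, dC = jacobian_row(window.t, params)
    J = np.column_stack([dA, dB, dC])
    E = window.y - model_current(window.t, params)
    return float(np.max(np.abs(J.T @ E)))
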