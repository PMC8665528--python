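"""Survival prediction and IPCW Brier-score evaluation.

Predicted survival uses the proportional-hazards plug-in
S(t|x) = exp(-H0(t) exp(beta'x)) with the posterior-mean baseline increments
accumulated over the training time partition (linear interpolation within
intervals). The Brier score at time t is the mean squared difference between
the predicted survival probability and the observed survival status,
reweighted by the inverse Kaplan-Meier estimate of the censoring
distribution; the integrated Brier score is its time average over [0, t*].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "PredictionCurve",
    "BrierResult",
    "predict_survival",
    "censoring_km",
    "brier_score",
    "brier_curve",
    "integrated_brier",
    "evaluate_model",
]


@dataclass
class PredictionCurve:
    eval_times: np.ndarray  # increasing, within follow-up
    survival: np.ndarray  # (n_test, n_times) in [0, 1]


@dataclass
class BrierResult:
    eval_times: np.ndarray
    bs: np.ndarray
    ibs: float
    t_star: float


def predict_survival(
    coeffs: np.ndarray,
    boundaries: np.ndarray,
    mean_h: np.ndarray,
    X_test: np.ndarray,
    eval_times: np.ndarray,
) -> PredictionCurve:
    """PH plug-in survival curves on the training time partition.

    ``coeffs`` is one subgroup's coefficient vector (MPM or BMA); ``X_test``
    must be standardized with the training parameters. Times beyond the final
    partition boundary are rejected (no extrapolation).
    """
    eval_times = np.asarray(eval_times, dtype=float)
    if (eval_times < 0).any():
        raise ValueError("evaluation times must be non-negative")
    if (eval_times > boundaries[-1]).any():
        raise ValueError(
            f"evaluation time beyond the last partition boundary {boundaries[-1]:g}"
        )
    cum = np.concatenate([[0.0], np.cumsum(mean_h)])
    H0 = np.interp(eval_times, boundaries, cum)
    risk = np.exp(np.asarray(X_test, dtype=float) @ np.asarray(coeffs, dtype=float))
    surv = np.exp(-np.outer(risk, H0))
    return PredictionCurve(eval_times=eval_times, survival=surv)


def censoring_km(train_times: np.ndarray, train_events: np.ndarray):
    """Kaplan-Meier estimator of the censoring distribution C(t) (censoring
    treated as the event). Returns a right-continuous step function."""
    kmf = KaplanMeierFitter()
    kmf.fit(train_times, 1 - np.asarray(train_events, dtype=int))

    def C_hat(t):
        return np.atleast_1d(np.asarray(kmf.predict(np.atleast_1d(t)), dtype=float))

    return C_hat


def brier_score(
    surv_at_t: np.ndarray,
    test_times: np.ndarray,
    test_events: np.ndarray,
    C_hat,
    t: float,
) -> float:
    """IPCW Brier score at a single time t.

    BS(t) = (1/n) sum_m w_m(t) (1(t_m > t) - S(t|x_m))^2 with
    w_m(t) = 1(t_m <= t) delta_m / C(t_m) + 1(t_m > t) / C(t);
    subjects censored before t receive weight 0.
    """
    test_times = np.asarray(test_times, dtype=float)
    test_events = np.asarray(test_events, dtype=int)
    alive = test_times > t
    died = (~alive) & (test_events == 1)
    w = np.zeros(len(test_times))
    if died.any():
        c_at_tm = C_hat(test_times[died])
        if (c_at_tm <= 0).any():
            raise ZeroDivisionError("censoring KM is zero at an event time")
        w[died] = 1.0 / c_at_tm
    if alive.any():
        c_at_t = float(C_hat(t)[0])
        if c_at_t <= 0:
            raise ZeroDivisionError(f"censoring KM is zero at t={t:g}")
        w[alive] = 1.0 / c_at_t
    resid = alive.astype(float) - np.asarray(surv_at_t, dtype=float)
    return float(np.mean(w * resid**2))


def brier_curve(
    curve: PredictionCurve,
    test_times: np.ndarray,
    test_events: np.ndarray,
    C_hat,
) -> np.ndarray:
    return np.array([
        brier_score(curve.survival[:, k], test_times, test_events, C_hat, t)
        for k, t in enumerate(curve.eval_times)
    ])


def integrated_brier(eval_times: np.ndarray, bs: np.ndarray, t_star: float) -> float:
    """Trapezoidal time-average of BS over [0, t*].

    The curve is extended to 0 and t* by nearest-endpoint / linear
    interpolation of the supplied grid.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    eval_times = np.asarray(eval_times, dtype=float)
    bs = np.asarray(bs, dtype=float)
    keep = eval_times <= t_star
    t = eval_times[keep]
    y = bs[keep]
    if len(t) == 0 or t[0] > 0:
        y0 = bs[0] if len(t) == 0 else y[0]
        t = np.r_[0.0, t]
        y = np.r_[y0, y]
    if t[-1] < t_star:
        y_end = float(np.interp(t_star, eval_times, bs))
        t = np.r_[t, t_star]
        y = np.r_[y, y_end]
    return float(np.trapezoid(y, t) / t_star)


def evaluate_model(
    coeffs: np.ndarray,
    boundaries: np.ndarray,
    mean_h: np.ndarray,
    X_test: np.ndarray,
    test_times: np.ndarray,
    test_events: np.ndarray,
    train_times: np.ndarray,
    train_events: np.ndarray,
    t_star: float | None = None,
) -> BrierResult:
    """Prediction-error pipeline for one subgroup model.

    The censoring distribution is estimated on training data; the evaluation
    grid is the unique test event times up to t* (default: the 90th
    percentile of observed test times), clipped to the training follow-up.
    """
    test_times = np.asarray(test_times, dtype=float)
    if t_star is None:
        t_star = float(np.quantile(test_times, 0.9))
    t_star = min(t_star, float(boundaries[-1]))
    grid = np.unique(test_times[(np.asarray(test_events) == 1) & (test_times <= t_star)])
    grid = np.r_[0.0, grid, t_star] if len(grid) == 0 or grid[-1] < t_star else np.r_[0.0, grid]
    curve = predict_survival(coeffs, boundaries, mean_h, X_test, grid)
    C_hat = censoring_km(train_times, train_events)
    bs = brier_curve(curve, test_times, test_events, C_hat)
    ibs = integrated_brier(grid, bs, t_star)
    return BrierResult(eval_times=grid, bs=bs, ibs=ibs, t_star=t_star)
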