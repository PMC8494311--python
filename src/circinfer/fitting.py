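"""Per-participant model fitting by least squares in logit space.

Responses are assumed to carry Gaussian noise on the logit confidence,
so minimizing the mean squared error of logit residuals is maximum
likelihood.  Each model is scored with the Gaussian-error approximation
of the Bayesian information criterion,

    BIC = n ln(sigma^2) + k ln(n),

with ``sigma^2`` the residual MSE, ``n`` the fitted trial count and
``k`` the model's free-parameter count (0 / 2 / 4 / 4 for SB / WB /
CII / CINI; the noise SD is not counted).

Optimization runs in the rescaled [0, 1] parameter box with a
bound-constrained local search from a deterministic start grid plus
seeded random restarts; ties between equally scoring optima are broken
toward the least-reverberant solution, then lexicographically, so
refitting is bit-reproducible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import MODELS, N_FREE_PARAMS, PARAM_NAMES, ModelParams, _F

MSE_FLOOR = 1e-12
TIE_TOL = 1e-9

FIT_COLUMNS = ["participant_id", "model", *PARAM_NAMES, "mse", "n", "bic"]


def compute_bic(n: int, mse: float, k: int) -> float:
    """Gaussian-error BIC, ``n ln(mse) + k ln(n)``.

    A zero MSE (perfect fit, which occurs only on degenerate synthetic
    data) is floored at 1e-12 with a warning rather than rejected.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1; got {n}")
    if mse < 0:
        raise ValueError(f"mse must be nonnegative; got {mse}")
    if mse < MSE_FLOOR:
        warnings.warn(
            f"mse={mse} floored at {MSE_FLOOR} for BIC", RuntimeWarning, stacklevel=2
        )
        mse = MSE_FLOOR
    return n * np.log(mse) + k * np.log(n)


@dataclass
class FitOptions:
    """Multistart and observation-model settings.

    ``logit_bound`` is the response scale's edge in logit units: observed
    confidences are clipped to [eps, 1-eps] before the logit transform,
    so the forward model caps its predictions at the same level (ln 99
    for the default eps = 0.01) rather than penalizing a model for
    predicting beyond what the scale can express.  Set to ``None`` to
    compare raw predictions.
    """

    n_random_starts: int = 8
    seed: int = 0
    optimizer_tol: float = 1e-10
    logit_bound: float | None = float(np.log(99.0))
    n_polish: int = 3


@dataclass
class FitResult:
    """One (participant, model) least-squares fit."""

    participant_id: object
    model: str
    params: ModelParams
    mse: float
    n: int
    bic: float
    n_starts_converged: int

    def as_row(self) -> dict:
        row = {"participant_id": self.participant_id, "model": self.model}
        row.update(dict(zip(PARAM_NAMES, self.params.as_array())))
        row.update({"mse": self.mse, "n": self.n, "bic": self.bic})
        return row


def _predict_raw(model: str, L_p, L_s, theta):
    """Prediction from a rescaled parameter vector, no validation."""
    if model == "SB":
        return L_p + L_s
    w_p = 0.5 + 0.5 * theta[0]
    w_s = 0.5 + 0.5 * theta[1]
    if model == "WB":
        return _F(L_p, w_p) + _F(L_s, w_s)
    a_p = 60.0 * theta[2]
    a_s = 60.0 * theta[3]
    if model == "CII":
        I = _F(a_p * L_p, w_p) + _F(a_s * L_s, w_s)
        return _F(L_p + I, w_p) + _F(L_s + I, w_s)
    if model == "CINI":
        return _F(L_p + _F(a_p * L_p, w_p), w_p) + _F(L_s + _F(a_s * L_s, w_s), w_s)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _start_points(k: int, options: FitOptions) -> np.ndarray:
    grid = np.array(list(itertools.product((0.25, 0.75), repeat=k)))
    rng = np.random.default_rng(options.seed)
    rand = rng.uniform(0.0, 1.0, size=(options.n_random_starts, k))
    return np.vstack([grid, rand])


def _join(responses: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    unmatched = set(responses["trial_id"]) - set(trials["trial_id"])
    if unmatched:
        raise ValueError(f"responses reference unknown trial_ids: {sorted(unmatched)[:10]}")
    merged = responses.merge(trials[["trial_id", "L_p", "L_s"]], on="trial_id", how="inner")
    return merged.dropna(subset=["L_c", "L_p", "L_s"])


def fit_model(
    model: str,
    responses: pd.DataFrame,
    trials: pd.DataFrame,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one model to one participant's logit confidences.

    SB has no free parameters, so its residuals are computed directly.
    For the parametric models the rescaled-box MSE is minimized by
    L-BFGS-B from every start point; the best score wins, with ties
    (within 1e-9) resolved toward the smallest ``a_p + a_s`` and then
    the lexicographically smallest vector.
    """
    options = options or FitOptions()
    data = _join(responses, trials)
    n = len(data)
    if n < 10:
        raise ValueError(f"need at least 10 matched responses; got {n}")
    L_p = data["L_p"].to_numpy()
    L_s = data["L_s"].to_numpy()
    y = data["L_c"].to_numpy()
    pid = responses["participant_id"].iloc[0] if "participant_id" in responses else None
    k = N_FREE_PARAMS[model]
    bound = options.logit_bound

    def cap(pred):
        return pred if bound is None else np.clip(pred, -bound, bound)

    if model == "SB":
        # the cap never binds for SB on the 9-level grid (|L_p+L_s| <= 2 ln 9)
        mse = float(np.mean((y - cap(L_p + L_s)) ** 2))
        return FitResult(pid, model, ModelParams(), mse, n, compute_bic(n, mse, 0), 1)

    def objective(theta):
        r = y - cap(_predict_raw(model, L_p, L_s, theta))
        return np.mean(r * r)

    bounds = [(0.0, 1.0)] * k
    candidates = []
    n_converged = 0
    for x0 in _start_points(k, options):
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, tol=options.optimizer_tol
        )
        if res.success:
            n_converged += 1
        candidates.append((float(res.fun), np.clip(res.x, 0.0, 1.0)))
    if n_converged == 0:
        raise RuntimeError(
            f"no start converged for model {model} (participant {pid}); "
            f"best objective {min(c[0] for c in candidates):.3g}"
        )
    # Where the reverberated signal saturates, the objective is almost
    # flat along a and gradient-based steps stall; a derivative-free
    # polish of the leading candidates walks those directions by line
    # search instead.
    candidates.sort(key=lambda c: c[0])
    for _, x0 in list(candidates[: options.n_polish]):
        res = minimize(
            objective,
            x0,
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-10, "ftol": 1e-14},
        )
        candidates.append((float(res.fun), np.clip(res.x, 0.0, 1.0)))
    best_mse = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_mse + TIE_TOL]
    # least-reverberant explanation first, then lexicographic
    def tie_key(c):
        theta = c[1]
        a_sum = theta[2] + theta[3] if k == 4 else 0.0
        return (a_sum, tuple(theta))

    mse, theta = min(tied, key=tie_key)
    full = np.zeros(4)
    full[:k] = theta
    params = ModelParams(*full)
    return FitResult(pid, model, params, float(mse), n, compute_bic(n, mse, k), n_converged)


def fit_participants(
    responses: pd.DataFrame,
    trials: pd.DataFrame,
    models=MODELS,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Fit every requested model to every participant.

    Returns a long-format table with one row per (participant, model):
    rescaled parameter estimates, residual MSE, fitted trial count and
    BIC.
    """
    rows = []
    for pid, group in responses.groupby("participant_id"):
        for model in models:
            fit = fit_model(model, group, trials, options)
            row = fit.as_row()
            row["participant_id"] = pid
            rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
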