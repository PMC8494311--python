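"""Group-level model comparison.

Two complementary views of which observer model best describes a cohort:

* **Fixed effects** — summed per-participant BIC relative to a baseline
  model (``group_delta_bic``); assumes one model generated everyone.
* **Random effects** — Bayesian model selection treating the generating
  model as a random effect across participants
  (``random_effects_bms``): a variational scheme estimates a Dirichlet
  posterior over model frequencies from per-participant approximate log
  model evidences (taken as -BIC/2), yielding expected posterior model
  probabilities and exceedance probabilities (the chance that each model
  is the most frequent in the population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp


def group_delta_bic(fits: pd.DataFrame, baseline: str = "CII") -> pd.Series:
    """Summed BIC per model minus the summed BIC of ``baseline``.

    Requires a complete (participant x model) table; the baseline's
    Delta-BIC is 0 by construction and lower values indicate better fit.
    """
    table = fits.pivot(index="participant_id", columns="model", values="bic")
    if table.isna().any().any():
        missing = [
            (pid, m)
            for pid, row in table.iterrows()
            for m in table.columns
            if pd.isna(row[m])
        ]
        raise ValueError(f"missing (participant, model) fits: {missing[:10]}")
    if baseline not in table.columns:
        raise ValueError(f"baseline {baseline!r} not among fitted models {list(table.columns)}")
    sums = table.sum(axis=0)
    return sums - sums[baseline]


@dataclass
class BMSResult:
    """Posterior over model frequencies from random-effects selection.

    ``alpha`` parametrizes the Dirichlet posterior over population model
    frequencies; ``member_probabilities`` holds each participant's
    posterior attribution over models (rows of the variational u).
    """

    models: list
    alpha: np.ndarray
    exceedance: np.ndarray
    member_probabilities: np.ndarray
    iterations: int
    converged: bool

    @property
    def expected_probabilities(self) -> np.ndarray:
        """Expected posterior model probabilities r_k = alpha_k / sum(alpha)."""
        return self.alpha / self.alpha.sum()


def bic_to_log_evidence(fits: pd.DataFrame) -> pd.DataFrame:
    """Participant x model matrix of approximate log evidences (-BIC/2)."""
    table = fits.pivot(index="participant_id", columns="model", values="bic")
    if table.isna().any().any():
        raise ValueError("incomplete fits table; every participant needs every model")
    return -table / 2.0


def random_effects_bms(
    log_evidence,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_exceedance_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Variational Dirichlet estimate of population model frequencies.

    Starting from a symmetric Dirichlet(``alpha0``) prior, iterate

        u_nk  propto  exp(log_evidence_nk + psi(alpha_k) - psi(sum alpha)),

    normalized over models per participant, then
    ``alpha_k = alpha0 + sum_n u_nk``, until the largest change in alpha
    falls below ``tol``.  Exceedance probabilities are estimated by
    seeded Monte-Carlo sampling from the posterior Dirichlet.

    ``log_evidence`` is a participants x models array or DataFrame
    (columns are model names).  Non-convergence within ``max_iter``
    returns the current state flagged ``converged=False``.
    """
    if alpha0 <= 0:
        raise ValueError(f"alpha0 must be positive; got {alpha0}")
    if isinstance(log_evidence, pd.DataFrame):
        models = list(log_evidence.columns)
        lme = log_evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(log_evidence, dtype=float)
        models = list(range(lme.shape[1]))
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidence matrix must be finite")
    n, K = lme.shape

    alpha = np.full(K, float(alpha0))
    converged = False
    iterations = 0
    u = np.full((n, K), 1.0 / K)
    for iterations in range(1, max_iter + 1):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_exceedance_samples)
    exceedance = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_exceedance_samples
    return BMSResult(
        models=models,
        alpha=alpha,
        exceedance=exceedance,
        member_probabilities=u,
        iterations=iterations,
        converged=converged,
    )
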