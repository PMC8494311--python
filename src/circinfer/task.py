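"""Fisher-task trial design.

A trial presents two cues about which of two lakes a red fish came from:
the fisherman's lake preference (a prior, conveyed by basket sizes) and
the proportion of red fish in each lake (the likelihood).  Both cues take
one of nine probability levels, 0.1 through 0.9, and the two lakes are
complementary, so a trial is fully described by the left-lake prior and
likelihood probabilities.  All models operate on the log-odds (logits) of
these probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The nine probability levels used for both priors and likelihoods.
GRID_LEVELS = np.round(np.arange(1, 10) * 0.1, 10)

TRIAL_COLUMNS = ["trial_id", "prior_p", "like_p", "L_p", "L_s"]


def logit(p):
    """Natural-log odds ln(p / (1 - p)).

    Parameters
    ----------
    p : float or array-like
        Probability strictly inside (0, 1).

    Raises
    ------
    ValueError
        If any value lies outside the open interval (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)) or not np.all(np.isfinite(p)):
        bad = p[~((p > 0) & (p < 1))]
        raise ValueError(f"logit requires 0 < p < 1; got {bad!r}")
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inverse_logit(L):
    """Inverse of :func:`logit`: 1 / (1 + exp(-L))."""
    L = np.asarray(L, dtype=float)
    out = np.where(L >= 0, 1.0 / (1.0 + np.exp(-L)), np.exp(L) / (1.0 + np.exp(L)))
    return float(out) if out.ndim == 0 else out


def build_trial_set(n_trials: int = 130, seed: int = 0, full_coverage: bool = True) -> pd.DataFrame:
    """Construct a balanced fisher-task trial set over the 9x9 cue grid.

    Every one of the 81 (prior, likelihood) combinations appears at least
    once; the remaining ``n_trials - 81`` trials are spread as evenly as
    possible over the combinations, the surplus cells chosen and the final
    order shuffled by ``seed``.  The exact trial list used in the original
    online study is not public, so this balanced construction is a
    documented stand-in with the same grid and trial count.

    Parameters
    ----------
    n_trials : int
        Number of trials (default 130, the length of the online session).
    seed : int
        Seed controlling surplus-cell choice and trial order.
    full_coverage : bool
        Require every grid cell at least once (needs ``n_trials >= 81``).

    Returns
    -------
    pandas.DataFrame
        Columns ``trial_id, prior_p, like_p, L_p, L_s``.
    """
    n_cells = len(GRID_LEVELS) ** 2
    if full_coverage and n_trials < n_cells:
        raise ValueError(
            f"full-grid coverage needs n_trials >= {n_cells}; got {n_trials}"
        )
    rng = np.random.default_rng(seed)
    cells = np.array([(p, s) for p in GRID_LEVELS for s in GRID_LEVELS])
    base = n_trials // n_cells
    extra = n_trials - base * n_cells
    counts = np.full(n_cells, base)
    # surplus spread over a seeded choice of distinct cells
    counts[rng.choice(n_cells, size=extra, replace=False)] += 1
    rows = np.repeat(np.arange(n_cells), counts)
    rng.shuffle(rows)
    prior_p = cells[rows, 0]
    like_p = cells[rows, 1]
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "prior_p": prior_p,
            "like_p": like_p,
            "L_p": logit(prior_p),
            "L_s": logit(like_p),
        }
    )


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial set to CSV.  Logits are derived, never stored."""
    trials[["trial_id", "prior_p", "like_p"]].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV written by :func:`write_trials`, recomputing logits."""
    df = pd.read_csv(path)
    df["L_p"] = logit(df["prior_p"].to_numpy())
    df["L_s"] = logit(df["like_p"].to_numpy())
    return df[TRIAL_COLUMNS]
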