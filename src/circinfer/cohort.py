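"""Synthetic fisher-task cohorts.

The original participant data are not public, so every downstream stage
(fitting, model selection, recovery, trait statistics) is exercised on
synthetic cohorts that emulate the study's structure: 130 trials on the
9x9 cue grid, confidence responses generated from a chosen observer model
with Gaussian noise added in logit space, and AQ/PDI trait scores with
the cohort moments reported for this population (AQ mean 22.9, SD 6.5;
PDI mean 6.1, SD 3.1; ASD subgroup AQ mean 28.0, SD 8.0).

Trait--parameter couplings default to zero: the null cohort, in which
observer parameters carry no trait association, is the reference fixture
for type-I-error calibration of the association battery.  Nonzero
couplings inject a monotone trait effect for power checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import PARAM_NAMES, ModelParams, predict_trials
from .task import build_trial_set, inverse_logit, logit

logger = logging.getLogger(__name__)

#: Confidence clipping bound before the logit transform.  Edge clicks on
#: the response scale nominally mean probability 0 or 1; they are mapped
#: to [EPS, 1-EPS], i.e. |logit confidence| <= ln(99) ~ 4.595.
EPS = 0.01

RESPONSE_COLUMNS = ["participant_id", "trial_id", "confidence", "L_c", "rt"]


def simulate_responses(
    model: str,
    params: ModelParams | None,
    trials: pd.DataFrame,
    noise_sd: float,
    seed: int,
    participant_id=0,
    eps: float = EPS,
    rt_base: float = 2.0,
    rt_conf_slope: float = 0.1,
    rt_sigma: float = 0.4,
) -> pd.DataFrame:
    """Simulate one participant's responses on a trial set.

    The logit confidence is the model prediction plus Gaussian noise of
    SD ``noise_sd``; the reported confidence is its inverse logit clipped
    to ``[eps, 1-eps]`` (the response scale has finite resolution at the
    edges), and the stored ``L_c`` is the logit of that clipped value.

    Reaction times are log-normal with median ``rt_base`` seconds scaled
    down by ``exp(-rt_conf_slope * |prediction|)`` — confident trials are
    answered faster — with log-scale SD ``rt_sigma``.
    """
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be positive; got {noise_sd}")
    rng = np.random.default_rng(seed)
    pred = predict_trials(model, trials, params)
    L_noisy = pred + rng.normal(0.0, noise_sd, size=len(trials))
    confidence = np.clip(inverse_logit(L_noisy), eps, 1 - eps)
    rt = np.exp(
        np.log(rt_base)
        - rt_conf_slope * np.abs(pred)
        + rng.normal(0.0, rt_sigma, size=len(trials))
    )
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_id": trials["trial_id"].to_numpy(),
            "confidence": confidence,
            "L_c": logit(confidence),
            "rt": rt,
        }
    )


def _truncated_normal_scores(rng, mean, sd, lo, hi, size):
    """Integer trait scores from a truncated normal on [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.rint(draws), lo, hi).astype(int)


@dataclass
class CohortConfig:
    """Generating configuration for a synthetic cohort.

    Observer parameters are drawn (rescaled scale) from uniform ranges
    bracketing the values this task elicits: weights well inside (0, 1]
    and reverberations in the lower third of the range — fitted samples
    on this design stay far below the nominal ceiling (the largest
    reported non-rescaled reverberation is about 29 of 60).  Logit noise
    SDs span roughly the spread seen in online cohorts.

    ``couplings`` maps parameter name -> {trait name -> slope}; the drawn
    parameter is shifted by slope * standardized trait and clipped back
    into [0, 1] (clipping is logged).  All-zero couplings give the null
    cohort.
    """

    model: str = "CINI"
    w_range: tuple[float, float] = (0.3, 1.0)
    a_range: tuple[float, float] = (0.0, 0.3)
    noise_sd_range: tuple[float, float] = (0.5, 1.5)
    aq_mean: float = 22.9
    aq_sd: float = 6.5
    pdi_mean: float = 6.1
    pdi_sd: float = 3.1
    asd_fraction: float = 21 / 176
    asd_aq_mean: float = 28.0
    asd_aq_sd: float = 8.0
    nd_fraction: float = 61 / 176
    couplings: dict = field(default_factory=dict)
    n_trials: int = 130
    eps: float = EPS


@dataclass
class Cohort:
    """A simulated cohort: trial set, per-participant profiles, responses.

    ``profiles`` holds one row per participant (generating model and
    parameters, noise SD, AQ, PDI, diagnosis); ``responses`` one row per
    trial per participant.
    """

    trials: pd.DataFrame
    profiles: pd.DataFrame
    responses: pd.DataFrame


def simulate_cohort(n: int, config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate ``n`` participants under ``config``.

    All participants share one trial set (as in the original session).
    Diagnosis labels are assigned first (ASD / ND / other per the config
    fractions); ASD participants draw AQ from the ASD-subgroup moments.
    The whole cohort is a pure function of ``(n, config, seed)``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 participants; got {n}")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    trials = build_trial_set(cfg.n_trials, seed=int(rng.integers(2**31)))

    n_asd = int(round(cfg.asd_fraction * n))
    n_nd = int(round(cfg.nd_fraction * n))
    diagnosis = np.array(["ASD"] * n_asd + ["ND"] * n_nd + ["other"] * (n - n_asd - n_nd))
    rng.shuffle(diagnosis)

    aq = np.where(
        diagnosis == "ASD",
        _truncated_normal_scores(rng, cfg.asd_aq_mean, cfg.asd_aq_sd, 0, 50, n),
        _truncated_normal_scores(rng, cfg.aq_mean, cfg.aq_sd, 0, 50, n),
    )
    pdi = _truncated_normal_scores(rng, cfg.pdi_mean, cfg.pdi_sd, 0, 21, n)
    traits = {"AQ": aq, "PDI": pdi}

    params = {
        "w_p": rng.uniform(*cfg.w_range, size=n),
        "w_s": rng.uniform(*cfg.w_range, size=n),
        "a_p": rng.uniform(*cfg.a_range, size=n),
        "a_s": rng.uniform(*cfg.a_range, size=n),
    }
    for pname, trait_slopes in cfg.couplings.items():
        if pname not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {pname!r} in couplings")
        for tname, slope in trait_slopes.items():
            t = traits[tname].astype(float)
            z = (t - t.mean()) / t.std() if t.std() > 0 else np.zeros(n)
            params[pname] = params[pname] + slope * z
    for pname in PARAM_NAMES:
        clipped = (params[pname] < 0) | (params[pname] > 1)
        if clipped.any():
            logger.warning(
                "coupling pushed %s outside [0, 1] for %d participants; clipped",
                pname,
                int(clipped.sum()),
            )
            params[pname] = np.clip(params[pname], 0.0, 1.0)

    noise_sd = rng.uniform(*cfg.noise_sd_range, size=n)
    response_seeds = rng.integers(2**31, size=n)

    profiles = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "model": cfg.model,
            **{p: params[p] for p in PARAM_NAMES},
            "noise_sd": noise_sd,
            "AQ": aq,
            "PDI": pdi,
            "diagnosis": diagnosis,
        }
    )
    responses = pd.concat(
        [
            simulate_responses(
                cfg.model,
                ModelParams(*(params[p][i] for p in PARAM_NAMES)),
                trials,
                noise_sd[i],
                seed=int(response_seeds[i]),
                participant_id=i,
                eps=cfg.eps,
            )
            for i in range(n)
        ],
        ignore_index=True,
    )
    return Cohort(trials=trials, profiles=profiles, responses=responses)


def quality_flags(responses: pd.DataFrame, sd_floor: float = 0.05, mid_frac: float = 0.3, mid_width: float = 0.02) -> pd.Series:
    """Flag participants whose response pattern suggests disengagement.

    A participant is flagged when the SD of their confidence is below
    ``sd_floor`` (the cursor barely moved) or more than ``mid_frac`` of
    clicks fall within ``mid_width`` of the scale midpoint.  The original
    study's exclusion rules are not public; this is a documented
    stand-in, and exclusion is the caller's (logged) decision.
    """

    def _flag(g):
        near_mid = (g["confidence"] - 0.5).abs() <= mid_width
        return g["confidence"].std() < sd_floor or near_mid.mean() > mid_frac

    flags = responses.groupby("participant_id").apply(_flag, include_groups=False)
    n_flagged = int(flags.sum())
    if n_flagged:
        logger.info("quality_flags: %d participant(s) flagged", n_flagged)
    return flags
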