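"""Model-free regressors, mixed-effects variants and trait associations.

This module carries the statistical surface of the analysis:

* trial-level regressors for the model-free check that participants use
  both cues — absolute confidence ``|c - 0.5|`` as the response,
  absolute likelihood ``|likelihood - 0.5|`` and signed prior congruency
  ``|prior - 0.5| * sgn[(prior - 0.5)(likelihood - 0.5)]`` as predictors,
  with reaction time probing a speed-accuracy trade-off;
* five linear mixed-effects variants that add AQ/PDI main effects and
  interactions on top of the core regressors;
* nonparametric trait--parameter association tests (Kendall tau-b,
  Mann-Whitney U with the common-language effect size f) assembled into
  the battery run on the winning model's fitted parameters, with
  Benjamini-Hochberg adjustment;
* extreme-group definitions (top/bottom 15% by AQ; ASD vs ND) and the
  symmetric-trial averaging used to denoise per-cell confidence plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .models import PARAM_NAMES


def build_regressors(
    responses: pd.DataFrame, trials: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Trial-level regressor table for the mixed-effects analysis.

    One row per response: ``abs_confidence = |c - 0.5|`` (the response
    variable), ``abs_likelihood = |likelihood - 0.5|``,
    ``prior_congruency = |prior - 0.5| * sgn[(prior - 0.5)(likelihood - 0.5)]``
    (positive when the cues agree; a 0.5 prior contributes zero), plus
    reaction time and the participant's AQ and PDI.
    """
    merged = responses.merge(trials[["trial_id", "prior_p", "like_p"]], on="trial_id")
    if len(merged) != len(responses):
        raise ValueError("responses reference trial_ids missing from the trial set")
    merged = merged.merge(traits[["participant_id", "AQ", "PDI"]], on="participant_id")
    if len(merged) != len(responses):
        raise ValueError("responses reference participants missing from the trait table")
    dp = merged["prior_p"] - 0.5
    ds = merged["like_p"] - 0.5
    return pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "trial_id": merged["trial_id"],
            "abs_confidence": (merged["confidence"] - 0.5).abs(),
            "abs_likelihood": ds.abs(),
            "prior_congruency": dp.abs() * np.sign(dp * ds),
            "rt": merged["rt"],
            "AQ": merged["AQ"],
            "PDI": merged["PDI"],
        }
    )


#: Fixed-effects formulas of the five mixed-model variants.  All share
#: the core regressors and the likelihood x congruency interaction; the
#: trait variants add AQ and/or PDI main effects and their two- and
#: three-way interactions with the two cue regressors; LME_rtInteract
#: additionally interacts each trait with reaction time.
LME_VARIANTS = {
    "LME_core": "abs_confidence ~ abs_likelihood * prior_congruency + rt",
    "LME_AQ": (
        "abs_confidence ~ abs_likelihood * prior_congruency + rt"
        " + AQ + AQ:abs_likelihood + AQ:prior_congruency"
        " + AQ:abs_likelihood:prior_congruency"
    ),
    "LME_PDI": (
        "abs_confidence ~ abs_likelihood * prior_congruency + rt"
        " + PDI + PDI:abs_likelihood + PDI:prior_congruency"
        " + PDI:abs_likelihood:prior_congruency"
    ),
    "LME_full": (
        "abs_confidence ~ abs_likelihood * prior_congruency + rt"
        " + AQ + AQ:abs_likelihood + AQ:prior_congruency"
        " + AQ:abs_likelihood:prior_congruency"
        " + PDI + PDI:abs_likelihood + PDI:prior_congruency"
        " + PDI:abs_likelihood:prior_congruency"
    ),
    "LME_rtInteract": (
        "abs_confidence ~ abs_likelihood * prior_congruency + rt"
        " + AQ + AQ:abs_likelihood + AQ:prior_congruency"
        " + AQ:abs_likelihood:prior_congruency"
        " + PDI + PDI:abs_likelihood + PDI:prior_congruency"
        " + PDI:abs_likelihood:prior_congruency"
        " + AQ:rt + PDI:rt"
    ),
}

RANDOM_SLOPES = "~abs_likelihood + prior_congruency"


@dataclass
class LMEVariantResult:
    """Coefficients and fit statistics for one mixed-model variant."""

    variant: str
    coefficients: pd.DataFrame  # estimate, t, p per fixed effect
    bic: float
    converged: bool
    random_structure: str  # "slopes" or "intercept-only" fallback


def _mixedlm_bic(result) -> float:
    """BIC for an ML-fitted mixed model: -2 llf + df ln(N).

    df counts fixed effects, the unique random-effect (co)variances and
    the residual variance.
    """
    q = result.cov_re.shape[0]
    df = result.k_fe + q * (q + 1) // 2 + 1
    return -2.0 * result.llf + df * np.log(result.nobs)


def fit_lme_variants(
    regressors: pd.DataFrame, variants: dict | None = None
) -> dict[str, LMEVariantResult]:
    """Fit the mixed-effects variants with participant as random factor.

    The random structure is an intercept plus slopes for the two
    repeated-measures cue regressors; a variant whose slope model fails
    or is singular is refit with a random intercept only and flagged.
    Traits are mean-centred before entering interactions, and models are
    fitted by maximum likelihood so BICs are comparable across variants.
    """
    if regressors["participant_id"].nunique() < 2:
        raise ValueError("mixed models need at least 2 participants")
    data = regressors.copy()
    for trait in ("AQ", "PDI"):
        data[trait] = data[trait] - data[trait].mean()
    variants = variants or LME_VARIANTS
    out = {}
    for name, formula in variants.items():
        result, structure, ok = None, "slopes", True
        for re_formula in (RANDOM_SLOPES, "~1"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    model = smf.mixedlm(
                        formula, data, groups=data["participant_id"], re_formula=re_formula
                    )
                    result = model.fit(reml=False)
                singular = not np.all(np.isfinite(result.bse_fe)) or not np.all(
                    np.linalg.eigvalsh(result.cov_re) > 1e-10
                )
                ok = result.converged and not singular
            except (np.linalg.LinAlgError, ValueError):
                ok, result = False, None
            if ok:
                structure = "slopes" if re_formula == RANDOM_SLOPES else "intercept-only"
                break
            structure = "intercept-only"
        if result is None:
            raise RuntimeError(f"mixed model {name} failed under both random structures")
        fe = result.fe_params
        coef = pd.DataFrame(
            {
                "estimate": fe,
                "t": result.tvalues[fe.index],
                "p": result.pvalues[fe.index],
            }
        )
        out[name] = LMEVariantResult(
            variant=name,
            coefficients=coef,
            bic=_mixedlm_bic(result),
            converged=bool(result.converged),
            random_structure=structure,
        )
    return out


@dataclass
class TestOutcome:
    """One nonparametric test: statistic, effect size, raw/adjusted p."""

    name: str
    statistic: float
    p: float
    effect_size: float | None = None
    p_adjusted: float | None = None
    flags: list = field(default_factory=list)


def kendall_tau(x, y) -> TestOutcome:
    """Kendall tau-b rank correlation with a two-sided p-value.

    Tie-corrected (tau-b), appropriate for integer questionnaire totals;
    zero variance in either input leaves the outcome NaN and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("kendall_tau needs two equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance input; Kendall tau undefined", RuntimeWarning)
        return TestOutcome("kendall_tau", np.nan, np.nan, flags=["zero_variance"])
    res = stats.kendalltau(x, y)
    return TestOutcome("kendall_tau", float(res.statistic), float(res.pvalue))


def mann_whitney_f(x, y) -> TestOutcome:
    """Mann-Whitney U with the common-language effect size f.

    ``f = U_x / (n_x n_y)`` estimates the probability that a random
    member of ``x`` exceeds a random member of ``y`` (ties count half),
    so f = 0.5 means no group difference and f(x, y) + f(y, x) = 1.
    The p-value uses the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("mann_whitney_f needs two samples of size >= 2")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    f = float(res.statistic) / (len(x) * len(y))
    return TestOutcome("mann_whitney_u", float(res.statistic), float(res.pvalue), effect_size=f)


def define_groups(
    traits: pd.DataFrame, tail: float = 0.15, nd_low_quantile: float | None = None
) -> pd.DataFrame:
    """Extreme-trait and diagnosis groupings.

    ``aq_group`` marks the bottom/top ``tail`` fraction of the sample by
    AQ (ties at the threshold fall on the extreme side); the remainder
    is ``middle``.  ``diagnosis_group`` carries the stated label (ASD /
    ND / other).  ``nd_low`` additionally flags ND participants at or
    below the low-AQ threshold, the subgroup used to contrast diagnosed
    participants with trait-matched undiagnosed ones.
    """
    if traits["AQ"].isna().any():
        raise ValueError("AQ must be present for every participant")
    n = len(traits)
    if n * tail < 1:
        raise ValueError(f"sample of {n} too small for non-empty {tail:.0%} tails")
    aq = traits["AQ"].to_numpy(dtype=float)
    if np.all(aq == aq[0]):
        raise ValueError("all AQ scores identical; extreme groups undefined")
    lo_thr = np.quantile(aq, tail)
    hi_thr = np.quantile(aq, 1 - tail)
    aq_group = np.where(aq <= lo_thr, "low", np.where(aq >= hi_thr, "high", "middle"))
    out = pd.DataFrame(
        {
            "participant_id": traits["participant_id"],
            "aq_group": aq_group,
            "diagnosis_group": traits.get("diagnosis", pd.Series(["other"] * n)).to_numpy(),
        }
    )
    out["nd_low"] = (out["diagnosis_group"] == "ND") & (aq <= lo_thr)
    return out


def association_battery(
    fits: pd.DataFrame,
    traits: pd.DataFrame,
    groups: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Trait--parameter association tests for one model's fitted parameters.

    Runs Kendall tau-b of each of the four parameters against AQ and
    against PDI (the correlation table) and Mann-Whitney U with f for
    the ASD-vs-ND and low-vs-high-AQ contrasts (the group table), where
    f > 0.5 means larger parameters in the ASD / high-AQ group.
    Benjamini-Hochberg adjustment is applied separately within each
    8-test table; raw p-values are always reported alongside.
    """
    if fits["model"].nunique() != 1:
        raise ValueError("association_battery expects fits for exactly one model")
    merged = fits.merge(traits[["participant_id", "AQ", "PDI"]], on="participant_id")
    if len(merged) != len(fits):
        raise ValueError("traits missing for some fitted participants")
    if groups is None:
        groups = define_groups(traits)
    merged = merged.merge(groups, on="participant_id")

    rows = []
    for trait in ("AQ", "PDI"):
        for p in PARAM_NAMES:
            t = kendall_tau(merged[p], merged[trait])
            rows.append(
                {
                    "table": "correlations",
                    "contrast": trait,
                    "parameter": p,
                    "test": t.name,
                    "statistic": t.statistic,
                    "f": np.nan,
                    "p": t.p,
                    "flags": ";".join(t.flags),
                }
            )
    contrasts = {
        "ASD_vs_ND": (merged["diagnosis_group"] == "ASD", merged["diagnosis_group"] == "ND"),
        "highAQ_vs_lowAQ": (merged["aq_group"] == "high", merged["aq_group"] == "low"),
    }
    for cname, (mask_a, mask_b) in contrasts.items():
        for p in PARAM_NAMES:
            t = mann_whitney_f(merged.loc[mask_a, p], merged.loc[mask_b, p])
            rows.append(
                {
                    "table": "groups",
                    "contrast": cname,
                    "parameter": p,
                    "test": t.name,
                    "statistic": t.statistic,
                    "f": t.effect_size,
                    "p": t.p,
                    "flags": ";".join(t.flags),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for table in ("correlations", "groups"):
        mask = (out["table"] == table) & out["p"].notna()
        if mask.any():
            out.loc[mask, "p_adjusted"] = multipletests(
                out.loc[mask, "p"], alpha=alpha, method="fdr_bh"
            )[1]
    return out


def symmetric_trial_average(responses: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Average logit confidence between mirror-image trials.

    A trial and its mirror (both cue probabilities complemented) probe
    the same evidence strength with opposite sign, and every observer
    model predicts exactly opposite logit confidences for them, so
    ``(L_c(t) - L_c(t')) / 2`` halves the response-noise variance while
    leaving a model-consistent responder's values unchanged.  The output
    is indexed by the grid cells with non-negative summed logits (45 of
    the 81); a cell whose mirror was never presented keeps its own mean
    and is flagged.
    """
    merged = responses.merge(trials[["trial_id", "prior_p", "like_p", "L_p", "L_s"]], on="trial_id")
    cell_means = (
        merged.groupby(["prior_p", "like_p"])
        .agg(L_c=("L_c", "mean"), L_p=("L_p", "first"), L_s=("L_s", "first"))
        .reset_index()
    )
    lookup = {
        (round(r.prior_p, 10), round(r.like_p, 10)): r.L_c for r in cell_means.itertuples()
    }
    rows = []
    for r in cell_means.itertuples():
        if r.L_p + r.L_s < -1e-12:
            continue
        mirror = (round(1 - r.prior_p, 10), round(1 - r.like_p, 10))
        if mirror in lookup:
            value = 0.5 * (r.L_c - lookup[mirror])
            flag = ""
        else:
            value = r.L_c
            flag = "missing_mirror"
        rows.append(
            {
                "prior_p": r.prior_p,
                "like_p": r.like_p,
                "L_p": r.L_p,
                "L_s": r.L_s,
                "avg_L_c": value,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).sort_values(["prior_p", "like_p"]).reset_index(drop=True)
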