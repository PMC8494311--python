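"""Run the trait-association statistics on a synthetic null cohort.

Builds the model-free regressors (absolute confidence, absolute
likelihood, prior congruency), fits the core mixed-effects variant,
defines the extreme-AQ and diagnosis groups, and runs the association
battery (Kendall tau-b of each parameter vs AQ/PDI; Mann-Whitney U with
the common-language effect size f for the group contrasts) with
Benjamini-Hochberg adjustment.  On a null cohort the battery should
return no adjusted-significant association — the study's main result.

For speed the battery is run on the generating parameters; swap in
`fit_participants` output to run it on refitted values.
"""

import warnings

from circinfer import (
    association_battery,
    build_regressors,
    define_groups,
    fit_lme_variants,
    simulate_cohort,
)
from circinfer.models import PARAM_NAMES
from circinfer.traitstats import LME_VARIANTS

warnings.filterwarnings("ignore")

cohort = simulate_cohort(n=176, seed=21)
reg = build_regressors(cohort.responses, cohort.trials, cohort.profiles)

lme = fit_lme_variants(reg, {"LME_core": LME_VARIANTS["LME_core"]})["LME_core"]
print("LME_core fixed effects (response = |c - 0.5|):")
print(lme.coefficients.round(3).to_string())
print(f"BIC {lme.bic:.1f}; random structure: {lme.random_structure}")

groups = define_groups(cohort.profiles)
print("\nAQ groups:", groups["aq_group"].value_counts().to_dict())

fits = cohort.profiles[["participant_id", *PARAM_NAMES]].assign(model="CINI")
battery = association_battery(fits, cohort.profiles, groups)
cols = ["table", "contrast", "parameter", "statistic", "f", "p", "p_adjusted"]
print("\nassociation battery (null cohort):")
print(battery[cols].round(3).to_string(index=False))
n_sig = int((battery["p_adjusted"] < 0.05).sum())
print(f"\nadjusted-significant associations: {n_sig} (expected 0 on a null cohort;"
      "\nthe cue regressors in the LME stay strongly significant because"
      "\nparticipants really do use both cues)")
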