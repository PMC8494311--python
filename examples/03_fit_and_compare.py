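"""Fit all four observer models to a small cohort and select the winner.

Simulates 12 participants from CINI, fits SB/WB/CII/CINI to each by
least squares on the logit confidences, and compares the models at the
group level two ways: summed Delta-BIC against the CII baseline (fixed
effects) and random-effects Bayesian model selection (a Dirichlet
posterior over population model frequencies, evidence approximated as
-BIC/2).
"""

import warnings

from circinfer import (
    bic_to_log_evidence,
    fit_participants,
    group_delta_bic,
    random_effects_bms,
    simulate_cohort,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)

cohort = simulate_cohort(n=12, seed=3)
fits = fit_participants(cohort.responses, cohort.trials, models=("SB", "WB", "CII", "CINI"))
print("one row per (participant, model):")
print(fits.head(4).round(3).to_string(index=False))

delta = group_delta_bic(fits, baseline="CII")
print("\nGroup Delta-BIC vs CII (lower is better):")
print(delta.round(1).to_string())

bms = random_effects_bms(bic_to_log_evidence(fits), seed=0)
print("\nRandom-effects model selection:")
for m, r, xp in zip(bms.models, bms.expected_probabilities, bms.exceedance):
    print(f"  {m:4s}  expected frequency {r:.3f}  exceedance {xp:.3f}")
print(
    "\nThe generating model (CINI) should carry the lowest Delta-BIC and"
    "\nthe bulk of the exceedance probability; SB/WB, which cannot express"
    "\nreverberation, trail far behind."
)
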