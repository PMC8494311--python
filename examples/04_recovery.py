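"""Validate the pipeline by parameter and model recovery (reduced scale).

Parameter recovery: draw generating parameters, simulate 130-trial
responses at logit noise SD 1, refit, and correlate generated vs
recovered values.  Weights recover excellently; reverberation
parameters only moderately — the same split the full-scale validation
shows.  Model recovery: simulate from CINI and from CII, fit both,
assign by lower BIC, and tabulate the confusion matrix.

Uses small simulant counts so the script runs in about a minute; the
full-scale validation lives in the test suite and acceptance script.
"""

import warnings

from circinfer import model_recovery, parameter_recovery

warnings.filterwarnings("ignore", category=RuntimeWarning)

rep = parameter_recovery("CINI", n_sim=30, noise_sd=1.0, seed=11)
print("parameter recovery (CINI, 30 simulants, noise SD 1):")
print("  Pearson r generated-vs-recovered:")
print(rep.pearson.round(2).to_string())

cm = model_recovery(n_per_model=20, noise_sd=1.0, seed=11)
print("\nmodel recovery confusion matrix (rows = generating model):")
print(cm.counts.to_string())
print("correct fraction per row:")
print(cm.correct_fraction.round(2).to_string())
print(
    "\nWeight correlations near 1 and clearly diagonal-heavy confusion"
    "\ncounts mean fitted parameters and BIC attributions on this design"
    "\ncan be interpreted; reverberation correlations sit lower because"
    "\nnoise trades off against the a parameters on only 130 trials."
)
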