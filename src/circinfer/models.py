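"""Observer models for the fisher task.

Four nested models map a trial's prior and likelihood logits (L_p, L_s)
to a predicted logit confidence L_c:

* **SB** (Simple Bayes): ``L_c = L_p + L_s`` — ideal Bayesian integration.
* **WB** (Weighted Bayes): ``L_c = F(L_p, w_p) + F(L_s, w_s)`` — each cue
  passes through a saturating sigmoid ``F`` that discounts it according
  to a weight ``w`` (w = 1 transmits the cue unchanged, w = 0.5 nulls it).
* **CII** (circular inference with interference): both cues are
  reverberated, and the pooled reverberation ``I`` corrupts both channels
  jointly, so the influence of one cue depends on the strength of the
  other.
* **CINI** (circular inference, no interference): each cue reverberates
  only within its own channel and the channels are summed, keeping the
  cue contributions additive.

Reverberation parameters ``a_p, a_s`` count how many extra times the
corresponding signal re-enters the inference loop; ``a = 0`` recovers WB.

True parameter ranges are w in [0.5, 1] and a in [0, 60]; parameters are
stored rescaled to [0, 1] (``w_rescaled = (w - 0.5)/0.5``,
``a_rescaled = a/60``), the convention in which results in this literature
are reported, and mapped back to the true scale only inside the
prediction functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODELS = ("SB", "WB", "CII", "CINI")

#: Free-parameter count per model: SB none, WB the two weights,
#: CII/CINI the two weights plus the two reverberation parameters.
N_FREE_PARAMS = {"SB": 0, "WB": 2, "CII": 4, "CINI": 4}

W_TRUE_RANGE = (0.5, 1.0)
A_TRUE_RANGE = (0.0, 60.0)

PARAM_NAMES = ("w_p", "w_s", "a_p", "a_s")


def rescale_w(w):
    """Map a true-scale weight [0.5, 1] to the rescaled [0, 1] convention."""
    return (np.asarray(w, dtype=float) - 0.5) / 0.5


def unrescale_w(w):
    """Inverse of :func:`rescale_w`."""
    return 0.5 + 0.5 * np.asarray(w, dtype=float)


def rescale_a(a):
    """Map a true-scale reverberation [0, 60] to the rescaled [0, 1]."""
    return np.asarray(a, dtype=float) / 60.0


def unrescale_a(a):
    """Inverse of :func:`rescale_a`."""
    return 60.0 * np.asarray(a, dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """Observer parameters, stored in the rescaled [0, 1] convention.

    ``w_p``/``w_s`` weight the prior and likelihood cues; ``a_p``/``a_s``
    are the corresponding reverberation strengths.  SB ignores all four;
    WB ignores the reverberations.
    """

    w_p: float = 1.0
    w_s: float = 1.0
    a_p: float = 0.0
    a_s: float = 0.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"rescaled {name} must lie in [0, 1]; got {v}")

    @classmethod
    def from_true(cls, w_p=1.0, w_s=1.0, a_p=0.0, a_s=0.0) -> "ModelParams":
        """Build from true-scale values (w in [0.5, 1], a in [0, 60])."""
        if not (0.5 <= w_p <= 1.0 and 0.5 <= w_s <= 1.0):
            raise ValueError(f"true-scale weights must lie in [0.5, 1]; got {w_p}, {w_s}")
        if not (0.0 <= a_p <= 60.0 and 0.0 <= a_s <= 60.0):
            raise ValueError(f"true-scale reverberation must lie in [0, 60]; got {a_p}, {a_s}")
        return cls(
            w_p=float(rescale_w(w_p)),
            w_s=float(rescale_w(w_s)),
            a_p=float(rescale_a(a_p)),
            a_s=float(rescale_a(a_s)),
        )

    @property
    def true_values(self) -> tuple[float, float, float, float]:
        """(w_p, w_s, a_p, a_s) on the true scale."""
        return (
            float(unrescale_w(self.w_p)),
            float(unrescale_w(self.w_s)),
            float(unrescale_a(self.a_p)),
            float(unrescale_a(self.a_s)),
        )

    def as_array(self) -> np.ndarray:
        """Rescaled parameter vector in the order w_p, w_s, a_p, a_s."""
        return np.array([self.w_p, self.w_s, self.a_p, self.a_s])


def _F(L, w):
    """Sigmoid cue transform, no validation, numerically stable.

    ln((w e^L + 1-w) / ((1-w) e^L + w)) computed via logaddexp so that
    |L| up to ~700 neither overflows nor loses the saturation level
    +-ln(w/(1-w)).
    """
    L = np.asarray(L, dtype=float)
    w = np.asarray(w, dtype=float)
    with np.errstate(divide="ignore"):  # log(0) = -inf is the w=1 limit
        lw = np.log(w)
        l1w = np.log1p(-w)
    return np.logaddexp(lw + L, l1w) - np.logaddexp(l1w + L, lw)


def sigmoid_F(L, w):
    """Weighted-Bayes sigmoid ``F(L, w) = ln((w e^L + 1-w)/((1-w) e^L + w))``.

    ``w`` is on the true scale: w = 1 is the identity, w = 0.5 nulls the
    signal, and for w < 1 the output saturates at ``+-ln(w/(1-w))``.

    Raises
    ------
    ValueError
        If ``w`` is outside [0.5, 1] (never silently clipped) or ``L``
        is not finite.
    """
    L = np.asarray(L, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any((w < 0.5) | (w > 1.0)) or not np.all(np.isfinite(w)):
        raise ValueError(f"true-scale weight must lie in [0.5, 1]; got {w!r}")
    if not np.all(np.isfinite(L)):
        raise ValueError("log-odds input must be finite")
    out = _F(L, w)
    return float(out) if out.ndim == 0 else out


def predict_sb(L_p, L_s):
    """Simple Bayes: sum of the two cue logits."""
    out = np.asarray(L_p, dtype=float) + np.asarray(L_s, dtype=float)
    return float(out) if out.ndim == 0 else out


def predict_wb(L_p, L_s, params: ModelParams):
    """Weighted Bayes: each cue discounted through the sigmoid."""
    w_p, w_s, _, _ = params.true_values
    out = _F(L_p, w_p) + _F(L_s, w_s)
    return float(out) if np.ndim(out) == 0 else out


def predict_cii(L_p, L_s, params: ModelParams):
    """Circular inference with interference.

    The pooled reverberation ``I = F(a_p L_p, w_p) + F(a_s L_s, w_s)``
    contaminates both channels before the final weighting, so prior and
    likelihood corrupt each other's contribution.
    """
    w_p, w_s, a_p, a_s = params.true_values
    L_p = np.asarray(L_p, dtype=float)
    L_s = np.asarray(L_s, dtype=float)
    I = _F(a_p * L_p, w_p) + _F(a_s * L_s, w_s)
    out = _F(L_p + I, w_p) + _F(L_s + I, w_s)
    return float(out) if np.ndim(out) == 0 else out


def predict_cini(L_p, L_s, params: ModelParams):
    """Circular inference without interference: channel-wise reverberation.

    Each cue is inflated only by its own reverberated copy, keeping the
    two channels additive (prediction curves stay parallel across priors).
    """
    w_p, w_s, a_p, a_s = params.true_values
    L_p = np.asarray(L_p, dtype=float)
    L_s = np.asarray(L_s, dtype=float)
    out = _F(L_p + _F(a_p * L_p, w_p), w_p) + _F(L_s + _F(a_s * L_s, w_s), w_s)
    return float(out) if np.ndim(out) == 0 else out


def predict(model: str, L_p, L_s, params: ModelParams | None = None):
    """Dispatch to the named model's prediction function."""
    if model == "SB":
        return predict_sb(L_p, L_s)
    if params is None:
        raise ValueError(f"model {model} requires parameters")
    if model == "WB":
        return predict_wb(L_p, L_s, params)
    if model == "CII":
        return predict_cii(L_p, L_s, params)
    if model == "CINI":
        return predict_cini(L_p, L_s, params)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def predict_trials(model: str, trials, params: ModelParams | None = None):
    """Predict logit confidence for every row of a trial-set DataFrame."""
    return predict(model, trials["L_p"].to_numpy(), trials["L_s"].to_numpy(), params)
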