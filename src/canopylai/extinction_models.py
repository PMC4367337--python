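"""Light extinction coefficient schemes.

Three ways to supply the Beer's-law extinction coefficient k for the LAI
calculation:

* ``constant_k`` — one fixed value for every image (default 0.68, the
  whole-dataset mean measured for apple trees).
* ``k_from_ff`` — k predicted from the foliage cover fraction by a fitted
  exponential (k = a·exp(b·f_f)) or linear (k = a·f_f + b) model.  These
  calibrations are site- and cultivar-specific; the fitted apple-orchard
  coefficients ship as named presets.
* ``k_from_ic`` — k proxied by the instantaneous fraction of light
  intercepted by the canopy, k = slope·I_c, with the through-origin slope
  close to 1 (the measured relation is nearly the 1:1 line).

Fitting routines recover such models from (f_f, k_M) or (I_c, k_M) data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ExtinctionEstimate",
    "FfModel",
    "IcModel",
    "FF_MODEL_PRESETS",
    "DEFAULT_CONSTANT_K",
    "DEFAULT_IC_SLOPE",
    "constant_k",
    "k_from_ff",
    "k_from_ic",
    "fit_ff_model",
    "fit_ic_model",
]

DEFAULT_CONSTANT_K = 0.68
DEFAULT_IC_SLOPE = 0.99

Scheme = Literal["constant_k", "k_from_ff", "k_from_ic"]


@dataclass(frozen=True)
class ExtinctionEstimate:
    """An extinction coefficient and the scheme that produced it."""

    k: float
    scheme: Scheme
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"extinction coefficient must be positive, got {self.k}")


@dataclass(frozen=True)
class FfModel:
    """k as a function of foliage cover.

    ``exponential``: k = a·exp(b·f_f).  ``linear``: k = a·f_f + b
    (a is the slope, b the intercept).  ``r2`` is reported on the scale the
    fit was performed on — the log scale for the exponential form.
    """

    form: Literal["exponential", "linear"]
    a: float
    b: float
    r2: float | None = None

    def predict(self, f_f: float) -> float:
        if self.form == "exponential":
            return self.a * math.exp(self.b * f_f)
        return self.a * f_f + self.b


@dataclass(frozen=True)
class IcModel:
    """Through-origin linear relation k = slope · I_c."""

    slope: float
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("through-origin slope must be positive")


#: fitted apple-orchard calibrations of k against foliage cover
FF_MODEL_PRESETS: dict[str, FfModel] = {
    "whole_dataset_exp": FfModel("exponential", 0.136, 1.99, r2=0.67),
    "trial1_exp": FfModel("exponential", 0.031, 4.44, r2=0.93),
    "trial2_exp": FfModel("exponential", 0.096, 2.37, r2=0.46),
    "whole_dataset_linear": FfModel("linear", 1.08, -0.17, r2=0.62),
    "trial1_linear": FfModel("linear", 2.02, -0.73, r2=0.87),
    "trial2_linear": FfModel("linear", 1.63, -0.65, r2=0.42),
}


def constant_k(k: float = DEFAULT_CONSTANT_K) -> ExtinctionEstimate:
    """Fixed extinction coefficient, applied unchanged to every image."""
    if k <= 0:
        raise ValueError(f"constant k must be positive, got {k}")
    return ExtinctionEstimate(k, "constant_k", {"k": k})


def k_from_ff(f_f: float, model: FfModel | str = "whole_dataset_exp") -> ExtinctionEstimate:
    """Predict k from foliage cover with a fitted model (or preset name)."""
    if isinstance(model, str):
        try:
            model = FF_MODEL_PRESETS[model]
        except KeyError:
            raise KeyError(
                f"unknown model preset {model!r}; "
                f"available: {sorted(FF_MODEL_PRESETS)}"
            ) from None
    if not 0.0 <= f_f <= 1.0:
        raise ValueError(f"f_f must be in [0, 1], got {f_f}")
    k = model.predict(f_f)
    if k <= 0:
        raise ValueError(
            f"{model.form} model (a={model.a}, b={model.b}) predicts "
            f"non-positive k={k:.4g} at f_f={f_f}"
        )
    return ExtinctionEstimate(
        k, "k_from_ff", {"form": model.form, "a": model.a, "b": model.b}
    )


def k_from_ic(i_c: float, slope: float = DEFAULT_IC_SLOPE) -> ExtinctionEstimate:
    """Proxy k from the intercepted light fraction: k = slope · I_c."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if i_c <= 0:
        raise ValueError(
            f"intercepted fraction must be positive to define k, got {i_c}"
        )
    if i_c > 1.0 + 1e-9:
        raise ValueError(f"intercepted fraction cannot exceed 1, got {i_c}")
    return ExtinctionEstimate(slope * i_c, "k_from_ic", {"slope": slope})


def fit_ff_model(
    f_f_values: Sequence[float],
    k_values: Sequence[float],
    form: Literal["exponential", "linear"] = "exponential",
) -> FfModel:
    """Least-squares fit of k against foliage cover.

    Linear: ordinary least squares of k on f_f.  Exponential: least squares
    of ln(k) on f_f, back-transformed (k = exp(intercept)·exp(slope·f_f));
    its r² is therefore on the log scale.
    """
    x = np.asarray(f_f_values, dtype=float)
    y = np.asarray(k_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("f_f_values and k_values must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("at least 3 points are required to fit a k(f_f) model")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in f_f: model unidentifiable")
    if form == "exponential":
        if (y <= 0).any():
            raise ValueError("exponential fit requires all k > 0")
        target = np.log(y)
    elif form == "linear":
        target = y
    else:
        raise ValueError(f"unknown model form {form!r}")

    slope, intercept = np.polyfit(x, target, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((target - fitted) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    if form == "exponential":
        return FfModel("exponential", a=float(np.exp(intercept)), b=float(slope), r2=r2)
    return FfModel("linear", a=float(slope), b=float(intercept), r2=r2)


def fit_ic_model(
    i_c_values: Sequence[float], k_values: Sequence[float]
) -> IcModel:
    """Through-origin least squares of k on I_c: slope = Σxy / Σx².

    r² is computed against the through-origin fit with the total sum of
    squares about zero (the model has no intercept).
    """
    x = np.asarray(i_c_values, dtype=float)
    y = np.asarray(k_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("i_c_values and k_values must be equal-length 1-D sequences")
    if len(x) < 2:
        raise ValueError("at least 2 points are required")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("all i_c values are zero: slope unidentifiable")
    slope = float(np.dot(x, y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IcModel(slope=slope, r2=r2)
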