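"""Descriptive least-squares fits of scaling relationships.

Used in two places: extrapolating the order parameter of the missing-data
entropy estimators to zero missingness, and summarising how sweep metrics
depend on aggregation parameters.  Fits are descriptive only — no inference
is attached to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class ScalingFit:
    xs: np.ndarray
    ys: np.ndarray
    form: str  # linear | offset_exponential | exponential | logarithmic
    coefficients: tuple[float, ...]
    r_squared: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            return c[0] * x + c[1]
        if self.form == "offset_exponential":
            return c[0] * np.exp(c[1] * x) + c[2]
        if self.form == "exponential":
            return c[0] * np.exp(c[1] * x)
        if self.form == "logarithmic":
            return c[0] * np.log(x) + c[1]
        raise ValueError(f"unknown form {self.form!r}")


def _r_squared(ys: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(((ys - pred) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # constant data: a fit reproducing it is perfect
        return 1.0 if ss_res < 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot


def _fit_one(xs: np.ndarray, ys: np.ndarray, form: str) -> ScalingFit | None:
    try:
        if form == "linear":
            coef = tuple(np.polyfit(xs, ys, 1))
        elif form == "logarithmic":
            if np.any(xs <= 0):
                return None
            coef = tuple(np.polyfit(np.log(xs), ys, 1))
        elif form == "exponential":
            b0 = -1.0 if ys[0] > ys[-1] else 1.0
            coef, _ = curve_fit(
                lambda x, a, b: a * np.exp(b * x),
                xs,
                ys,
                p0=[max(abs(ys[0]), 1e-6) * np.sign(ys[0] if ys[0] != 0 else 1), b0],
                maxfev=10000,
            )
            coef = tuple(coef)
        elif form == "offset_exponential":
            if len(xs) < 3:
                return None
            b0 = -1.0 if ys[0] > ys[-1] else 1.0
            coef, _ = curve_fit(
                lambda x, a, b, c: a * np.exp(b * x) + c,
                xs,
                ys,
                p0=[ys[0] - ys[-1] if ys[0] != ys[-1] else 1e-3, b0, ys[-1]],
                maxfev=10000,
            )
            coef = tuple(coef)
        else:
            raise ValueError(f"unknown form {form!r}")
    except (RuntimeError, np.linalg.LinAlgError):
        return None
    fit = ScalingFit(xs, ys, form, tuple(float(v) for v in coef), 0.0)
    fit.r_squared = _r_squared(ys, fit.predict(xs))
    return fit


def fit_relationship(xs, ys, forms=("linear", "offset_exponential")) -> ScalingFit:
    """Fit each requested functional form and return the best (highest R^2).

    Raises ValueError when no form can be fitted (e.g. too few points for
    every requested form).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 2:
        raise ValueError("need at least two (x, y) points")
    fits = [f for form in forms if (f := _fit_one(xs, ys, form)) is not None]
    if not fits:
        raise ValueError(f"no requested form could be fitted: {forms}")
    return max(fits, key=lambda f: f.r_squared)
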