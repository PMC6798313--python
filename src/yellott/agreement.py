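"""Method-agreement statistics: percent differences, Bland-Altman limits of
agreement (optionally on log10-transformed data), and the power-law fit of
intercell distance against retinal eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "BlandAltmanResult",
    "EccentricityFit",
    "percent_difference",
    "bland_altman",
    "fit_eccentricity_curve",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, spread, and 95% limits of agreement between two methods.

    ``LOA = bias +/- 1.96 * spread`` where spread is the sample SD (n-1) of
    the paired differences.  When ``log_transformed`` the differences are
    of log10 values and the linear-scale ratio interpretation (``10**bias``
    and its LOA) is also populated.
    """

    bias_dbar: float
    spread_s: float
    loa_low: float
    loa_high: float
    n: int
    log_transformed: bool
    normality_p: float
    zero_variance: bool = False
    ratio_bias: float | None = None
    ratio_loa_low: float | None = None
    ratio_loa_high: float | None = None

    def to_dict(self) -> dict:
        return {
            "bias_dbar": self.bias_dbar,
            "spread_s": self.spread_s,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
            "log_transformed": self.log_transformed,
            "normality_p": self.normality_p,
            "zero_variance": self.zero_variance,
            "ratio_bias": self.ratio_bias,
            "ratio_loa_low": self.ratio_loa_low,
            "ratio_loa_high": self.ratio_loa_high,
        }


@dataclass(frozen=True)
class EccentricityFit:
    """Power-law fit ``icd(x) = a * (x - b)**c`` of spacing vs eccentricity."""

    a: float
    b: float
    c: float
    r_squared: float
    ci95: dict
    x_dist: np.ndarray
    fitted: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.power(np.asarray(x, dtype=float) - self.b, self.c)


def percent_difference(x: float, y: float) -> float:
    """Symmetric percent difference: 100 * |x - y| / mean(x, y)."""
    x = float(x)
    y = float(y)
    if x <= 0 or y <= 0:
        raise ValueError("percent difference requires positive inputs")
    return 100.0 * abs(x - y) / ((x + y) / 2.0)


def bland_altman(
    pairs: np.ndarray,
    log10_transform: bool = False,
) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of paired measurements.

    ``pairs`` is an (n, 2) array of (method 1, method 2) values, n >= 3.
    Differences are method 2 minus method 1, optionally after a log10
    transform (both values must then be positive).  Shapiro-Wilk normality
    of the differences is reported but not enforced; the caller decides
    whether the parametric limits are appropriate.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("pairs must be an (n, 2) array with n >= 3")
    if log10_transform:
        if np.any(arr <= 0):
            raise ValueError("log10 transform requires positive values")
        work = np.log10(arr)
    else:
        work = arr
    diffs = work[:, 1] - work[:, 0]
    dbar = float(diffs.mean())
    s = float(diffs.std(ddof=1))
    loa_low = dbar - 1.96 * s
    loa_high = dbar + 1.96 * s
    zero_var = s == 0.0
    normality_p = float("nan") if zero_var else float(stats.shapiro(diffs).pvalue)
    ratio_bias = ratio_lo = ratio_hi = None
    if log10_transform:
        ratio_bias = float(10.0**dbar)
        ratio_lo = float(10.0**loa_low)
        ratio_hi = float(10.0**loa_high)
    return BlandAltmanResult(
        bias_dbar=dbar,
        spread_s=s,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        n=arr.shape[0],
        log_transformed=bool(log10_transform),
        normality_p=normality_p,
        zero_variance=zero_var,
        ratio_bias=ratio_bias,
        ratio_loa_low=ratio_lo,
        ratio_loa_high=ratio_hi,
    )


def fit_eccentricity_curve(x_dist: np.ndarray, icd: np.ndarray) -> EccentricityFit:
    """Nonlinear least-squares fit of ``icd = a * (x_dist - b)**c``.

    ``x_dist`` is eccentricity in micrometers from the foveal center.  The
    offset ``b`` is bounded below ``min(x_dist)`` so the power stays real;
    95% confidence intervals come from the asymptotic covariance with a
    Student-t critical value.
    """
    x = np.asarray(x_dist, dtype=float)
    y = np.asarray(icd, dtype=float)
    if x.size != y.size or x.size < 6:
        raise ValueError("need at least 6 matched (x_dist, icd) points")
    if x.max() < 2.0 * max(x.min(), np.finfo(float).tiny):
        raise ValueError("x_dist must spread over more than twice its minimum")

    def model(xv, a, b, c):
        return a * np.power(xv - b, c)

    b_hi = float(x.min()) - 1e-9
    p0 = (float(y[0]), min(0.0, b_hi - 1.0), 0.3)
    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, -np.inf], [np.inf, b_hi, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"eccentricity fit did not converge: {exc}") from exc
    fitted = model(x, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(1, x.size - 3)
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    names = ("a", "b", "c")
    ci95 = {
        name: (float(p - tcrit * e), float(p + tcrit * e))
        for name, p, e in zip(names, popt, se)
    }
    return EccentricityFit(
        a=float(popt[0]),
        b=float(popt[1]),
        c=float(popt[2]),
        r_squared=r2,
        ci95=ci95,
        x_dist=x,
        fitted=fitted,
    )
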