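"""Statistical procedures for the kymograph analyses.

Covers: Pearson correlation of per-flagellum metrics against length;
comparison of treatment groups via residuals about the control regression
line (unpaired Welch t); a parametric-bootstrap dispersion test of
inter-event intervals against the Poisson (exponential-interval) null;
and the sigmoid (Hill) calibration of GCaMP intensity against free Ca²⁺
with its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sstats

__all__ = [
    "HillParams",
    "RegressionModel",
    "pearson",
    "fit_regression",
    "residual_shift_test",
    "interval_dispersion_test",
    "hill_fit",
    "hill_curve",
    "ca_from_intensity",
]


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation ρ and r² = ρ².

    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho = float(sstats.pearsonr(x, y).statistic)
    return rho, rho * rho


@dataclass
class RegressionModel:
    """Fitted mean relation y(x); ``form`` is 'linear' (a + b·x) or
    'decay' (a + b/x)."""

    form: str
    a: float
    b: float
    residual_sd: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.a + self.b * x
        return self.a + self.b / x

    def residuals(self, x, y):
        return np.asarray(y, dtype=float) - self.predict(x)


def fit_regression(x, y, form: str = "linear") -> RegressionModel:
    """Least-squares fit of a linear or reciprocal-decay mean relation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if form == "linear":
        X = np.column_stack([np.ones_like(x), x])
    elif form == "decay":
        if np.any(x == 0):
            raise ValueError("decay form undefined at x = 0")
        X = np.column_stack([np.ones_like(x), 1.0 / x])
    else:
        raise ValueError("form must be 'linear' or 'decay'")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    model = RegressionModel(form=form, a=float(coef[0]), b=float(coef[1]), residual_sd=0.0)
    res = model.residuals(x, y)
    model.residual_sd = float(np.std(res, ddof=2)) if x.size > 2 else 0.0
    return model


def residual_shift_test(control, treatment, form: str = "linear"):
    """Mean treatment offset from the control regression line.

    Fits the mean relation on the control (x, y) table, computes both
    groups' residuals about that line, and compares them with an unpaired
    two-tailed Welch t test.  Returns ``(mean_difference, t, p)`` where
    ``mean_difference`` is mean(treatment residuals) − mean(control
    residuals).
    """
    cx, cy = (np.asarray(a, dtype=float) for a in control)
    tx, ty = (np.asarray(a, dtype=float) for a in treatment)
    model = fit_regression(cx, cy, form)
    rc = model.residuals(cx, cy)
    rt = model.residuals(tx, ty)
    diff = float(np.mean(rt) - np.mean(rc))
    if np.std(rc) == 0 and np.std(rt) == 0:
        # degenerate: identical deterministic residuals
        t_stat, p = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
    else:
        res = sstats.ttest_ind(rt, rc, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return diff, t_stat, p


def interval_dispersion_test(
    event_times,
    n_mc: int = 999,
    rng: np.random.Generator | int | None = None,
):
    """Test whether event times are consistent with a Poisson process.

    The statistic is the Kolmogorov–Smirnov distance between the observed
    inter-event intervals and an exponential distribution with the rate
    estimated from those intervals.  Because the rate is estimated, the
    null distribution is obtained by parametric bootstrap: ``n_mc``
    replicate interval sets are drawn from the fitted exponential, each
    refit before computing its KS distance.  Returns ``(statistic, p)``;
    small p indicates non-Poisson (e.g. bursty or regularised) timing.
    """
    times = np.sort(np.asarray(event_times, dtype=float))
    if times.size < 5:
        raise ValueError("need at least 5 events for the dispersion test")
    intervals = np.diff(times)
    n = intervals.size
    mean = intervals.mean()
    if mean <= 0:
        raise ValueError("event times must be strictly increasing")
    rng = np.random.default_rng(rng)

    def ks_exp(x):
        """KS distance to Expon(mean of x), row-wise for 2-D input."""
        xs = np.sort(x, axis=-1)
        m = xs.mean(axis=-1, keepdims=True)
        cdf = 1.0 - np.exp(-xs / m)
        k = xs.shape[-1]
        grid_hi = np.arange(1, k + 1) / k
        grid_lo = np.arange(0, k) / k
        return np.maximum(
            (grid_hi - cdf).max(axis=-1), (cdf - grid_lo).max(axis=-1)
        )

    d_obs = float(ks_exp(intervals))
    d_null = ks_exp(rng.exponential(mean, size=(n_mc, n)))
    p = (1.0 + np.sum(d_null >= d_obs)) / (n_mc + 1.0)
    return d_obs, float(p)


@dataclass(frozen=True)
class HillParams:
    """Sigmoid calibration of indicator intensity against free Ca²⁺.

    ``I(C) = I_min + (I_max − I_min) · Cⁿ / (EC50ⁿ + Cⁿ)``
    """

    I_min: float
    I_max: float
    EC50: float
    n_hill: float

    def __post_init__(self):
        if self.I_max <= self.I_min:
            raise ValueError("I_max must exceed I_min")
        if self.EC50 <= 0 or self.n_hill <= 0:
            raise ValueError("EC50 and n_hill must be positive")


def hill_curve(params: HillParams, conc):
    """Intensity predicted by the sigmoid calibration at concentration(s)."""
    c = np.asarray(conc, dtype=float)
    cn = c**params.n_hill
    return params.I_min + (params.I_max - params.I_min) * cn / (
        params.EC50**params.n_hill + cn
    )


def hill_fit(ca, intensity) -> HillParams:
    """Least-squares Hill fit of intensity vs free Ca²⁺ concentration.

    Fitting is parametrised by log₁₀ EC50 so that nanomolar-scale EC50
    values are well conditioned.  Zero-concentration points anchor I_min.
    """
    c = np.asarray(ca, dtype=float)
    I = np.asarray(intensity, dtype=float)
    if c.size != I.size or c.size < 4:
        raise ValueError("need at least 4 (concentration, intensity) pairs")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")

    pos = c > 0
    logc = np.log10(c[pos])

    def model(logC, I_min, I_max, pEC50, n):
        return I_min + (I_max - I_min) / (1.0 + 10.0 ** (n * (pEC50 - logC)))

    I_min0 = float(I.min())
    I_max0 = float(I.max())
    mid = 0.5 * (I_min0 + I_max0)
    pEC50_0 = float(np.interp(mid, I[pos][np.argsort(I[pos])], logc[np.argsort(I[pos])]))
    p0 = (I_min0, I_max0, pEC50_0, 1.0)
    popt, _ = optimize.curve_fit(
        model, logc, I[pos], p0=p0, maxfev=20000,
        bounds=([-np.inf, -np.inf, -18.0, 1e-3], [np.inf, np.inf, 2.0, 20.0]),
    )
    I_min, I_max, pEC50, n = popt
    # zero-concentration points pin I_min exactly when present and clean
    return HillParams(
        I_min=float(I_min), I_max=float(I_max), EC50=float(10.0**pEC50), n_hill=float(n)
    )


def ca_from_intensity(params: HillParams, intensity):
    """Invert the sigmoid calibration: intensity → free Ca²⁺ (molar).

    Returns ``(concentration, in_range)`` where ``in_range`` is False for
    intensities at or outside the (I_min, I_max) dynamic range; those are
    clipped just inside the range before inversion, so the concentration
    is a saturation bound, not a measurement.
    """
    I = np.asarray(intensity, dtype=float)
    span = params.I_max - params.I_min
    frac = (I - params.I_min) / span
    in_range = (frac > 0.0) & (frac < 1.0)
    eps = 1e-12
    frac_c = np.clip(frac, eps, 1.0 - eps)
    conc = params.EC50 * (frac_c / (1.0 - frac_c)) ** (1.0 / params.n_hill)
    if np.isscalar(intensity) or I.ndim == 0:
        return float(conc), bool(in_range)
    return conc, in_range
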