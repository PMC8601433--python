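"""Four-parameter spectral characterization and concentration regressions.

Two empirical functions condense a phantom's broadband optical properties
into four numbers:

* absorption, linear in wavelength:      mu_a(lambda) = c*lambda + d
* reduced scattering, power law:         mu_s'(lambda) = a (lambda/500)^-b

d tracks the absorber (CBP) load (d ~ rho_a sigma_a), a tracks the scatterer
(TDP) load (a ~ rho_s sigma_s (1-g)), while c and b describe spectral shape
and should be insensitive to concentration; b = 4 in the Rayleigh limit and
falls as particles grow comparable to the wavelength.

Fits are inverse-variance weighted when k=1 uncertainties are supplied; the
coefficient of determination (COD) is always reported unweighted,
1 - SS_res/SS_tot with SS_tot about the mean, for comparability with
conventional printed CODs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AbsorptionFit",
    "ScatteringFit",
    "fit_absorption",
    "fit_scattering",
    "concentration_regression",
    "RegressionLine",
]


@dataclass(frozen=True)
class AbsorptionFit:
    """mu_a(lambda) = c*lambda + d; c in 1/(cm nm), d in 1/cm."""

    c: float
    d: float
    cod: float
    covariance: np.ndarray  # 2x2, order (c, d)

    @property
    def u_c(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def u_d(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def __call__(self, wavelengths_nm):
        return self.c * np.asarray(wavelengths_nm, dtype=float) + self.d


@dataclass(frozen=True)
class ScatteringFit:
    """mu_s'(lambda) = a (lambda/500)^-b; a in 1/cm, b dimensionless."""

    a: float
    b: float
    cod: float
    covariance: np.ndarray  # 2x2, order (a, b)

    @property
    def u_a(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def u_b(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def __call__(self, wavelengths_nm):
        return self.a * (np.asarray(wavelengths_nm, dtype=float) / 500.0) ** (-self.b)


def _cod(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_absorption(
    wavelengths_nm: np.ndarray,
    mu_a: np.ndarray,
    u_k1: np.ndarray | None = None,
) -> AbsorptionFit:
    """Weighted linear least squares of mu_a(lambda) = c*lambda + d."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    y = np.asarray(mu_a, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 wavelengths")
    if np.ptp(lam) == 0:
        raise ValueError("degenerate wavelength grid")
    if u_k1 is not None:
        u = np.asarray(u_k1, dtype=float)
        if np.any(u <= 0):
            raise ValueError("uncertainties must be positive for weighting")
        w = 1.0 / u**2
    else:
        w = np.ones_like(lam)
    X = np.column_stack([lam, np.ones_like(lam)])
    WX = X * w[:, None]
    A = X.T @ WX
    beta = np.linalg.solve(A, WX.T @ y)
    yhat = X @ beta
    if u_k1 is not None:
        cov = np.linalg.inv(A)
    else:
        dof = max(lam.size - 2, 1)
        s2 = float(np.sum((y - yhat) ** 2)) / dof
        cov = np.linalg.inv(A) * s2
    return AbsorptionFit(c=float(beta[0]), d=float(beta[1]), cod=_cod(y, yhat), covariance=cov)


def fit_scattering(
    wavelengths_nm: np.ndarray,
    mu_s_prime: np.ndarray,
    u_k1: np.ndarray | None = None,
) -> ScatteringFit:
    """Nonlinear least squares of mu_s'(lambda) = a (lambda/500)^-b.

    Initialized from a log--log linear regression (requires strictly
    positive data); analytic Jacobian; inverse-variance weighted when
    uncertainties are given.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    y = np.asarray(mu_s_prime, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 wavelengths")
    if np.any(y <= 0):
        raise ValueError("mu_s' must be positive at all wavelengths")
    x = lam / 500.0
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    p0 = np.array([np.exp(intercept), -slope])

    sigma = None if u_k1 is None else np.asarray(u_k1, dtype=float)
    if sigma is not None and np.any(sigma <= 0):
        raise ValueError("uncertainties must be positive for weighting")

    def model(xv, a, b):
        return a * xv ** (-b)

    def jac(xv, a, b):
        f = xv ** (-b)
        return np.column_stack([f, -a * np.log(xv) * f])

    popt, pcov = optimize.curve_fit(
        model, x, y, p0=p0, sigma=sigma,
        absolute_sigma=sigma is not None, jac=jac, maxfev=10000,
    )
    yhat = model(x, *popt)
    return ScatteringFit(
        a=float(popt[0]), b=float(popt[1]), cod=_cod(y, yhat), covariance=pcov
    )


@dataclass(frozen=True)
class RegressionLine:
    """OLS line y = slope*x + intercept with standard errors and COD."""

    slope: float
    intercept: float
    slope_se: float
    cod: float
    n: int

    @property
    def slope_consistent_with_zero(self) -> bool:
        """|slope| <= 2 SE — no evidence of correlation."""
        return abs(self.slope) <= 2.0 * self.slope_se


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionLine:
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    res = stats.linregress(x, y)
    return RegressionLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        cod=float(res.rvalue**2),
        n=int(len(x)),
    )


def _partial_slope(
    partner: np.ndarray, x: np.ndarray, y: np.ndarray, u_y: np.ndarray | None
) -> RegressionLine:
    """Slope of y on x at fixed partner level, pooled across levels.

    Both x and y are centered within each partner level (removing the
    partner's effect), then a single slope is fitted through all points.
    When per-point uncertainties ``u_y`` are available the slope's standard
    error is propagated from them (statistically well-behaved even with few
    points per level); otherwise it falls back to the residual estimate with
    the correct pooled degrees of freedom.
    """
    levels = np.unique(partner)
    xc = x.astype(float).copy()
    yc = y.astype(float).copy()
    for lv in levels:
        m = partner == lv
        xc[m] -= xc[m].mean()
        yc[m] -= yc[m].mean()
    sxx = float(np.sum(xc**2))
    if sxx == 0:
        raise ValueError("no within-level variation in the regressed concentration")
    slope = float(np.sum(xc * yc) / sxx)
    n = x.size
    dof = max(n - len(levels) - 1, 1)
    if u_y is not None:
        se = float(np.sqrt(np.sum((xc * np.asarray(u_y, dtype=float)) ** 2)) / sxx)
    else:
        ss_res = float(np.sum((yc - slope * xc) ** 2))
        se = float(np.sqrt(ss_res / dof / sxx))
    ss_tot = float(np.sum(yc**2))
    cod = 1.0 - float(np.sum((yc - slope * xc) ** 2)) / ss_tot if ss_tot else 0.0
    return RegressionLine(slope=slope, intercept=0.0, slope_se=se, cod=cod, n=n)


def concentration_regression(
    tdp_pct: np.ndarray,
    cbp_pct: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    u_a: np.ndarray | None = None,
    u_d: np.ndarray | None = None,
) -> dict:
    """Concentration-linearity and independence diagnostics across phantoms.

    Main regressions: d on CBP% and a on TDP% (expected strongly linear).
    Cross diagnostics of independence: the pooled partial slopes of a on CBP%
    and d on TDP% at fixed partner concentration (``*_partial``, expected
    consistent with zero), per-level lines for inspection, and the
    shape-parameter correlations (b on CBP%, c on TDP%). Returns a nested
    dict of :class:`RegressionLine` objects.
    """
    tdp = np.asarray(tdp_pct, dtype=float)
    cbp = np.asarray(cbp_pct, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)

    out: dict = {
        "d_vs_cbp": _ols(cbp, d),
        "a_vs_tdp": _ols(tdp, a),
        "b_vs_cbp": _ols(cbp, b),
        "c_vs_tdp": _ols(tdp, c),
        "a_vs_cbp_partial": _partial_slope(tdp, cbp, a, u_a),
        "d_vs_tdp_partial": _partial_slope(cbp, tdp, d, u_d),
    }

    def cross(partner, xvals, yvals):
        lines = {}
        for level in np.unique(partner):
            mask = partner == level
            if np.unique(xvals[mask]).size >= 3:
                lines[float(level)] = _ols(xvals[mask], yvals[mask])
        return lines

    out["a_vs_cbp_at_fixed_tdp"] = cross(tdp, cbp, a)
    out["d_vs_tdp_at_fixed_cbp"] = cross(cbp, tdp, d)
    return out
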