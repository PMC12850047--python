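"""Initial-rate extraction and the four kinetic/binding model fits.

Models
------
* Michaelis-Menten: v = V_max * S / (K_a + S), with K_a the substrate
  (PEP) concentration at half-maximal rate.
* Thermodynamic linkage of substrate affinity to an allosteric effector X:
  K_a(X) = K_ia0 * (K_ix0 + X) / (K_ix0 + Q_ax * X), where K_ia0 is the
  substrate dissociation constant with no effector, K_ix0 the effector
  dissociation constant with no substrate, and Q_ax the dimensionless
  coupling constant.  Q_ax = K_a(0) / K_a(inf); Q_ax > 1 means the
  effector enhances substrate affinity (activation).
* Activation dose-response: A(X) = a0 + (a_max - a0) * X^h/(AC50^h + X^h),
  Hill slope fixed to 1 by default.
* One-site binding isotherm: y(L) = B_max * L / (K_d + L).

All fits are unweighted nonlinear least squares (scipy) with positivity
bounds; standard errors come from the Jacobian-based covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import linkage_ka, linkage_rate

__all__ = [
    "MMFit",
    "LinkageModel",
    "DoseResponseFit",
    "BindingFit",
    "extract_initial_rate",
    "fit_michaelis",
    "fit_linkage",
    "coupling_ratio",
    "fit_dose_response",
    "fit_one_site",
]


class FitError(RuntimeError):
    """A model fit failed or the data are degenerate."""


def _curve_fit(f, x, y, p0, bounds):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
                f, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:  # non-convergence
        raise FitError(f"nonlinear least squares failed: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return popt, se, pcov


def _residual_ss(f, x, y, popt) -> float:
    r = y - f(x, *popt)
    return float(np.sum(r * r))


@dataclass
class MMFit:
    v_max: float
    k_a: float
    se: Mapping[str, float]
    residual_ss: float
    n_obs: int
    non_identifiable: bool = False


@dataclass
class LinkageModel:
    k_ia0: float
    k_ix0: float
    q_ax: float
    se: Mapping[str, float]
    ka_by_effector: Mapping[float, float]
    mode: str
    residual_ss: float
    at_bounds: bool = False

    @property
    def ka_at_zero(self) -> float:
        return self.k_ia0

    @property
    def ka_at_saturation(self) -> float:
        return self.k_ia0 / self.q_ax


@dataclass
class DoseResponseFit:
    a0: float
    a_max: float
    ac50: float
    hill: float
    se: Mapping[str, float]
    residual_ss: float
    non_identifiable: bool = False
    monotonicity_warning: bool = False


@dataclass
class BindingFit:
    b_max: float
    k_d: float
    se: Mapping[str, float]
    residual_ss: float


# ---------------------------------------------------------------------------
# initial rates
# ---------------------------------------------------------------------------

def extract_initial_rate(
    trace: pd.DataFrame,
    window_frac: float = 0.10,
    r2_threshold: float = 0.99,
    min_points: int = 5,
) -> float:
    """|slope| of an OLS line over the initial window of an absorbance trace.

    The window is the longer of (a) the first ``window_frac`` of the trace
    duration and (b) the longest prefix whose linear fit has R^2 >=
    ``r2_threshold``.  A flat trace (zero variance) counts as perfectly
    linear with slope 0.
    """
    t = np.asarray(trace["time_min"], dtype=float)
    y = np.asarray(trace["od340"], dtype=float)
    if t.size < min_points:
        raise FitError(f"need >= {min_points} points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise FitError("time must be strictly increasing")

    duration = t[-1] - t[0]
    n_frac = max(min_points, int(np.searchsorted(t, t[0] + window_frac * duration, side="right")))

    n_r2 = 0
    for n in range(min_points, t.size + 1):
        tt, yy = t[:n], y[:n]
        ss_tot = np.sum((yy - yy.mean()) ** 2)
        if ss_tot == 0.0:
            r2 = 1.0
        else:
            slope, intercept = np.polyfit(tt, yy, 1)
            ss_res = np.sum((yy - (slope * tt + intercept)) ** 2)
            r2 = 1.0 - ss_res / ss_tot
        if r2 >= r2_threshold:
            n_r2 = n
        elif n > min_points and n_r2 >= min_points:
            break

    n_win = max(n_frac, n_r2)
    n_win = min(n_win, t.size)
    if n_win < min_points:
        raise FitError("no linear initial window found")
    slope = np.polyfit(t[:n_win], y[:n_win], 1)[0]
    return float(abs(slope))


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------

def _mm(s, v_max, k_a):
    return v_max * s / (k_a + s)


def fit_michaelis(rates: pd.DataFrame) -> MMFit:
    """Fit v = V_max*S/(K_a+S) to a rate table at one effector level.

    Expects columns ``pep_conc`` and ``rate`` with >= 4 distinct substrate
    concentrations.  Flat data (all rates equal) are flagged
    non-identifiable with an unbounded K_a standard error.
    """
    s = np.asarray(rates["pep_conc"], dtype=float)
    v = np.asarray(rates["rate"], dtype=float)
    if np.unique(s).size < 4:
        raise FitError("need >= 4 distinct substrate concentrations")
    if not np.all(np.isfinite(v)):
        raise FitError("rates must be finite")

    if np.ptp(v) == 0.0:
        return MMFit(
            v_max=float(v[0]), k_a=np.nan,
            se={"v_max": 0.0, "k_a": np.inf},
            residual_ss=0.0, n_obs=v.size, non_identifiable=True,
        )

    v_max0 = float(np.max(v))
    half = 0.5 * v_max0
    k_a0 = float(s[np.argmin(np.abs(v - half))]) or float(np.median(s[s > 0]))
    popt, se, _ = _curve_fit(_mm, s, v, [v_max0, k_a0], ([0.0, 0.0], [np.inf, np.inf]))
    return MMFit(
        v_max=float(popt[0]), k_a=float(popt[1]),
        se={"v_max": float(se[0]), "k_a": float(se[1])},
        residual_ss=_residual_ss(_mm, s, v, popt), n_obs=v.size,
    )


# ---------------------------------------------------------------------------
# linked-function (coupling constant) analysis
# ---------------------------------------------------------------------------

def fit_linkage(
    rate_table: pd.DataFrame,
    mode: Literal["two_stage", "global"] = "two_stage",
) -> LinkageModel:
    """Fit the linkage model to a rate grid over substrate x effector.

    ``two_stage``: Michaelis-Menten K_a per effector level, then
    least-squares fit of K_a(X) = K_ia0*(K_ix0+X)/(K_ix0+Q_ax*X).
    ``global``: joint fit of v(S, X) with a shared V_max.
    """
    levels = np.sort(rate_table["effector_conc"].unique())
    if levels.size < 4:
        raise FitError("need >= 4 effector levels")
    if levels[0] != 0.0:
        raise FitError("effector grid must include a zero level")

    ka_by_level: dict[float, float] = {}
    for x in levels:
        sub = rate_table[rate_table["effector_conc"] == x]
        mm = fit_michaelis(sub)
        if mm.non_identifiable:
            raise FitError(f"K_a non-identifiable at effector level {x}")
        ka_by_level[float(x)] = mm.k_a

    ka = np.asarray([ka_by_level[float(x)] for x in levels])
    k_ia0_0 = ka[0]
    q0 = max(ka[0] / ka[-1], 1e-6)
    k_ix0_0 = float(np.median(levels[levels > 0]))

    if mode == "two_stage":
        popt, se, _ = _curve_fit(
            linkage_ka, levels, ka,
            [k_ia0_0, k_ix0_0, q0],
            ([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
        )
        k_ia0, k_ix0, q_ax = (float(p) for p in popt)
        se_map = {"k_ia0": float(se[0]), "k_ix0": float(se[1]), "q_ax": float(se[2])}
        rss = _residual_ss(linkage_ka, levels, ka, popt)
    elif mode == "global":
        s = np.asarray(rate_table["pep_conc"], dtype=float)
        x = np.asarray(rate_table["effector_conc"], dtype=float)
        v = np.asarray(rate_table["rate"], dtype=float)

        def surface(sx, v_max, k_ia0, k_ix0, q_ax):
            ss, xx = sx
            return linkage_rate(ss, xx, v_max, k_ia0, k_ix0, q_ax)

        v_max0 = float(np.max(v))
        popt, se, _ = _curve_fit(
            surface, (s, x), v,
            [v_max0, k_ia0_0, k_ix0_0, q0],
            ([1e-12] * 4, [np.inf] * 4),
        )
        k_ia0, k_ix0, q_ax = (float(p) for p in popt[1:])
        se_map = {
            "v_max": float(se[0]), "k_ia0": float(se[1]),
            "k_ix0": float(se[2]), "q_ax": float(se[3]),
        }
        rss = _residual_ss(surface, (s, x), v, popt)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    at_bounds = bool(q_ax <= 1e-10 or q_ax >= 1e10)
    if at_bounds:
        warnings.warn("fitted Q_ax is at its bound; estimate unreliable")
    return LinkageModel(
        k_ia0=k_ia0, k_ix0=k_ix0, q_ax=q_ax, se=se_map,
        ka_by_effector=ka_by_level, mode=mode, residual_ss=rss,
        at_bounds=at_bounds,
    )


def coupling_ratio(model: LinkageModel) -> float:
    """Coupling constant as the ratio of initial to final K_a.

    K_a(0)/K_a(inf) = K_ia0 / (K_ia0/Q_ax) = Q_ax; returned from the model
    limits so it is identically the fitted ``q_ax``.
    """
    return model.ka_at_zero / model.ka_at_saturation


# ---------------------------------------------------------------------------
# dose-response and binding
# ---------------------------------------------------------------------------

def _dose(x, a0, a_max, ac50, hill):
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(x > 0, x**hill / (ac50**hill + x**hill), 0.0)
    return a0 + (a_max - a0) * frac


def fit_dose_response(
    doses: pd.DataFrame,
    hill_free: bool = False,
) -> DoseResponseFit:
    """Fit the activation curve A(X); Hill slope fixed to 1 unless freed.

    Expects columns ``conc`` and ``activity`` with >= 5 concentrations
    including 0.  Flat data (a_max == a0) are flagged non-identifiable.
    A monotonicity warning is set when activity decreases with dose beyond
    what Spearman rank correlation can attribute to noise.
    """
    x = np.asarray(doses["conc"], dtype=float)
    y = np.asarray(doses["activity"], dtype=float)
    if np.unique(x).size < 5:
        raise FitError("need >= 5 distinct concentrations")
    if not np.any(x == 0):
        raise FitError("zero-concentration control required")

    if np.ptp(y) == 0.0:
        return DoseResponseFit(
            a0=float(y[0]), a_max=float(y[0]), ac50=np.nan, hill=1.0,
            se={"a0": 0.0, "a_max": 0.0, "ac50": np.inf},
            residual_ss=0.0, non_identifiable=True,
        )

    mono_warn = False
    rho = stats.spearmanr(x, y).statistic
    if np.isfinite(rho) and rho < -0.5:
        mono_warn = True
        warnings.warn("activity decreases with dose; activation model may not apply")

    a0_0 = float(y[x == 0].mean())
    a_max0 = float(np.max(y))
    half = 0.5 * (a0_0 + a_max0)
    pos = x > 0
    ac50_0 = float(x[pos][np.argmin(np.abs(y[pos] - half))])

    if hill_free:
        popt, se, _ = _curve_fit(
            _dose, x, y, [a0_0, a_max0, ac50_0, 1.0],
            ([0.0, 0.0, 1e-12, 1e-3], [np.inf] * 4),
        )
        a0, a_max, ac50, hill = (float(p) for p in popt)
        se_map = dict(zip(("a0", "a_max", "ac50", "hill"), (float(v) for v in se)))
        rss = _residual_ss(_dose, x, y, popt)
    else:
        def f(xx, a0, a_max, ac50):
            return _dose(xx, a0, a_max, ac50, 1.0)

        popt, se, _ = _curve_fit(
            f, x, y, [a0_0, a_max0, ac50_0],
            ([0.0, 0.0, 1e-12], [np.inf] * 3),
        )
        a0, a_max, ac50 = (float(p) for p in popt)
        hill = 1.0
        se_map = dict(zip(("a0", "a_max", "ac50"), (float(v) for v in se)))
        rss = _residual_ss(f, x, y, popt)

    return DoseResponseFit(
        a0=a0, a_max=a_max, ac50=ac50, hill=hill, se=se_map,
        residual_ss=rss, monotonicity_warning=mono_warn,
    )


def _one_site(L, b_max, k_d):
    return b_max * L / (k_d + L)


def fit_one_site(binding: pd.DataFrame) -> BindingFit:
    """Fit the one-site binding isotherm y = B_max*L/(K_d+L).

    Expects columns ``conc`` and ``signal`` with >= 6 ligand
    concentrations spanning K_d plus a zero control.  An all-saturated or
    all-zero series is rejected as non-identifiable.
    """
    L = np.asarray(binding["conc"], dtype=float)
    y = np.asarray(binding["signal"], dtype=float)
    pos = L > 0
    if np.unique(L[pos]).size < 6:
        raise FitError("need >= 6 positive ligand concentrations")
    if not np.any(L == 0):
        raise FitError("zero-concentration control required")
    if np.ptp(y) == 0.0 or np.allclose(y, 0.0):
        raise FitError("degenerate binding series (flat or all zero)")

    b_max0 = float(np.max(y))
    half = 0.5 * b_max0
    k_d0 = float(L[pos][np.argmin(np.abs(y[pos] - half))])
    # all points near saturation: K_d not bracketed by the series
    if np.min(y[pos]) > 0.95 * b_max0:
        raise FitError("series fully saturated; K_d non-identifiable")

    popt, se, _ = _curve_fit(
        _one_site, L, y, [b_max0, k_d0], ([0.0, 1e-12], [np.inf, np.inf])
    )
    return BindingFit(
        b_max=float(popt[0]), k_d=float(popt[1]),
        se={"b_max": float(se[0]), "k_d": float(se[1])},
        residual_ss=_residual_ss(_one_site, L, y, popt),
    )
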