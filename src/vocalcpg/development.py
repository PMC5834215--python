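"""Mapping the model's gamma1 axis onto postnatal days.

Lung mass grows roughly linearly with postnatal day over the first two
months, and a heavier lung slows the respiratory CPG, so the respiratory
time constant is taken to be an affine function of age:
``PND = beta0 + beta1 * gamma1`` (beta1 < 0: older animals, slower
breathing).  The two free coefficients are fitted by least squares between
the simulated trill/twitter proportion curves (functions of gamma1) and the
observed proportions by day, and fit quality is summarised by R^2.

Developmental trajectories of observed quantities are smoothed with cubic
smoothing splines; 95% confidence bands come from bootstrap resampling
(1,000 resamples by default) with pointwise percentile envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize

from .regimes import ProportionCurve

__all__ = [
    "DayMap",
    "CurveBand",
    "NonIdentifiableError",
    "fit_day_map",
    "r_squared",
    "bootstrap_spline_band",
]


class NonIdentifiableError(ValueError):
    """The simulated curve carries no information to pin down the day map."""


@dataclass(frozen=True)
class DayMap:
    """Affine map PND = beta0 + beta1 * gamma1 with its goodness of fit.

    ``r2`` pools trill and twitter residuals about the pooled observed
    mean (the default reading); ``r2_by_type`` reports each call type
    separately.
    """

    beta0: float
    beta1: float
    r2: float
    r2_by_type: dict

    def day_of(self, gamma1):
        return self.beta0 + self.beta1 * np.asarray(gamma1, dtype=float)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "r2": self.r2,
            "r2_by_type": dict(self.r2_by_type),
        }


def r_squared(sim_mapped: np.ndarray, obs: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    ``obs`` supplies both the residual reference and the mean for SS_tot.
    Can be negative when the simulation fits worse than the observed mean.
    """
    sim_mapped = np.asarray(sim_mapped, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim_mapped.shape != obs.shape:
        raise ValueError("sim and obs must have equal length")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = float(np.sum((obs - sim_mapped) ** 2))
    return 1.0 - ss_res / ss_tot


def _obs_interpolators(obs: pd.DataFrame, call_types):
    """Per-type linear interpolants day -> observed proportion."""
    interps = {}
    for ct in call_types:
        sub = (
            obs[obs["call_type"] == ct]
            .groupby("day", as_index=False)["proportion"]
            .mean()
            .sort_values("day")
        )
        if len(sub) < 2:
            raise ValueError(f"need >= 2 observed days for call type {ct!r}")
        interps[ct] = (sub["day"].to_numpy(float), sub["proportion"].to_numpy(float))
    return interps


def fit_day_map(
    sim: ProportionCurve,
    obs: pd.DataFrame,
    call_types=("trill", "twitter"),
    n_coarse: int = 60,
) -> DayMap:
    """Least-squares fit of PND = beta0 + beta1 * gamma1.

    Parameters
    ----------
    sim : ProportionCurve
        Simulated proportions over gamma1 (from the regime sweep).
    obs : DataFrame
        Tidy observed proportions with columns ``day``, ``call_type``,
        ``proportion`` (optionally ``subject``; values are averaged across
        subjects per day).
    call_types : tuple
        Call types entering the objective; the published fit uses the two
        developmentally disappearing types, trill and twitter.

    The objective sums, over call types and simulated gamma1 grid points,
    the squared difference between the simulated proportion and the
    observed curve linearly interpolated at the mapped day.  Minimised by a
    coarse grid over the (day at gamma1_max, day at gamma1_min) endpoints
    followed by Nelder-Mead refinement — the objective is cheap and the
    interpolation kinks rule out gradient methods.
    """
    gamma1 = sim.df["gamma1"].to_numpy(float)
    sim_props = {ct: sim.proportions(ct) for ct in call_types}
    if max(float(np.ptp(p)) for p in sim_props.values()) < 1e-12:
        raise NonIdentifiableError(
            "simulated proportions are constant over gamma1; day map not identifiable"
        )
    interps = _obs_interpolators(obs, call_types)

    g_lo, g_hi = gamma1.min(), gamma1.max()
    days = np.concatenate([v[0] for v in interps.values()])
    d_lo, d_hi = days.min(), days.max()
    span = d_hi - d_lo

    def objective(beta):
        beta0, beta1 = beta
        mapped = beta0 + beta1 * gamma1
        total = 0.0
        for ct in call_types:
            xs, ys = interps[ct]
            total += float(
                np.sum((sim_props[ct] - np.interp(mapped, xs, ys)) ** 2)
            )
        return total

    # coarse search over endpoint mappings: gamma1_max -> da, gamma1_min -> db
    cand = np.linspace(d_lo - 0.5 * span, d_hi + 0.5 * span, n_coarse)
    best, best_val = None, np.inf
    for da in cand:
        for db in cand:
            if abs(db - da) < 1e-9:
                continue
            beta1 = (db - da) / (g_lo - g_hi)
            beta0 = da - beta1 * g_hi
            v = objective((beta0, beta1))
            if v < best_val:
                best, best_val = (beta0, beta1), v
    res = minimize(objective, best, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-12})
    beta0, beta1 = (res.x if res.fun <= best_val else best)

    mapped = beta0 + beta1 * gamma1
    sim_all, obs_all, r2_by_type = [], [], {}
    for ct in call_types:
        xs, ys = interps[ct]
        o = np.interp(mapped, xs, ys)
        sim_all.append(sim_props[ct])
        obs_all.append(o)
        r2_by_type[ct] = r_squared(sim_props[ct], o)
    r2 = r_squared(np.concatenate(sim_all), np.concatenate(obs_all))
    return DayMap(beta0=float(beta0), beta1=float(beta1), r2=r2, r2_by_type=r2_by_type)


@dataclass
class CurveBand:
    """Smoothed developmental curve with a pointwise 95% bootstrap band."""

    day: np.ndarray
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if not (np.all(self.lower <= self.central + 1e-12)
                and np.all(self.central <= self.upper + 1e-12)):
            raise ValueError("band must bracket the central curve")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "central": self.central, "lower": self.lower, "upper": self.upper}
        )


def _fit_spline(x: np.ndarray, y: np.ndarray, lam):
    """Cubic smoothing spline on day-aggregated means (strictly increasing x)."""
    df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False)["y"].mean()
    xs = df["x"].to_numpy(float)
    ys = df["y"].to_numpy(float)
    if xs.size < 4:
        return None
    return make_smoothing_spline(xs, ys, lam=lam)


def bootstrap_spline_band(
    points: pd.DataFrame,
    smoothing: float | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> CurveBand:
    """Bootstrap 95% confidence band for a smoothed developmental curve.

    ``points`` holds one row per observation with columns ``day`` and
    ``value``.  Each of ``n_boot`` resamples (rows drawn with replacement)
    is fitted with a cubic smoothing spline; the band is the pointwise
    2.5/97.5 percentile envelope.  ``smoothing`` is the spline penalty
    ``lam`` (None selects it by generalised cross-validation, the default
    since the right amount of smoothing is data-dependent).

    Fewer than 100 resamples give an unreliable envelope; a warning-level
    signal (UserWarning) is emitted rather than an error.
    """
    import warnings

    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: percentile band will be noisy")
    day = points["day"].to_numpy(float)
    value = points["value"].to_numpy(float)
    if np.unique(day).size < 4:
        raise ValueError("need >= 4 distinct days for a cubic smoothing spline")
    if grid is None:
        grid = np.linspace(day.min(), day.max(), 101)

    central_spl = _fit_spline(day, value, smoothing)
    central = central_spl(grid)

    rng = np.random.default_rng(seed)
    curves = np.empty((n_boot, grid.size))
    n = day.size
    i = 0
    attempts = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        spl = _fit_spline(day[idx], value[idx], smoothing)
        attempts += 1
        if spl is None:  # resample collapsed onto < 4 distinct days
            if attempts > 10 * n_boot:
                raise RuntimeError("resamples repeatedly degenerate")
            continue
        curves[i] = spl(grid)
        i += 1
    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    # percentile envelopes of resampled fits need not bracket the all-data
    # fit exactly; clip to preserve the band invariant
    lower = np.minimum(lower, central)
    upper = np.maximum(upper, central)
    return CurveBand(day=grid, central=central, lower=lower, upper=upper)
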