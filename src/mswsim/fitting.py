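"""Growth-rate estimation and four-parameter Hill dose-response fitting.

Growth rates are the slope of an ordinary least-squares fit to
log-transformed cell counts over time (exponential growth). Per-condition
rates are then fit to the Hill curve
``g(c) = g_max + (g_min - g_max) c^nu / (ic50^nu + c^nu)``
by multi-start nonlinear least squares; (ic50, nu) are optimized in log
space for conditioning at large Hill coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .seascape import FitnessSeascape, HillCurve

__all__ = [
    "CountSeries",
    "GrowthRateEstimate",
    "HillFitResult",
    "growth_rate_from_counts",
    "fit_hill",
    "generate_counts",
    "read_count_series",
    "fit_seascape_from_counts",
]


@dataclass
class CountSeries:
    """Cell counts over time for one condition (drug concentration) and replicate."""

    times: np.ndarray  # hours
    counts: np.ndarray  # cells, >= 0
    condition: float = 0.0  # drug concentration
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


@dataclass
class GrowthRateEstimate:
    rate: float  # per hour
    stderr: float
    n_points: int
    dropped_zeros: int = 0


def growth_rate_from_counts(series: CountSeries) -> GrowthRateEstimate:
    """Exponential growth rate: OLS slope of ln(count) against time.

    Zero counts are dropped (with a warning) rather than pseudocounted; at
    least three positive counts are required.
    """
    pos = series.counts > 0
    dropped = int((~pos).sum())
    if dropped:
        warnings.warn(f"growth_rate_from_counts: dropped {dropped} zero count(s)")
    t, c = series.times[pos], series.counts[pos]
    if len(t) < 3:
        raise ValueError("need at least 3 positive counts to estimate a growth rate")
    res = stats.linregress(t, np.log(c))
    return GrowthRateEstimate(
        rate=float(res.slope), stderr=float(res.stderr), n_points=len(t), dropped_zeros=dropped
    )


@dataclass
class HillFitResult:
    curve: HillCurve
    loss: float
    covariance: Optional[np.ndarray]  # (g_max, g_min, log ic50, log nu) space
    n_starts: int
    converged: bool
    ic50_extrapolated: bool
    ic50_unidentifiable: bool = False


def _hill(c: np.ndarray, g_max: float, g_min: float, ic50: float, nu: float) -> np.ndarray:
    out = np.empty_like(c)
    zero = c <= 0
    cc = np.where(zero, 1.0, c)
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + (ic50 / cc) ** nu)
    return np.where(zero, g_max, g_max + (g_min - g_max) * frac)


def fit_hill(
    concs: Sequence[float],
    rates: Sequence[float],
    n_ic50_starts: int = 5,
    nu_starts: Sequence[float] = (0.5, 2.0, 8.0, 32.0),
    nu_bounds: Tuple[float, float] = (0.1, 50.0),
    ic50_bounds_factor: Tuple[float, float] = (0.1, 10.0),
) -> HillFitResult:
    """Four-parameter Hill fit by multi-start nonlinear least squares.

    IC50 initials are log-spaced over the positive sampled concentration
    range; IC50 bounds default to that range scaled by ``(0.1, 10)``; the
    Hill coefficient is bounded to ``(0.1, 50)``. The best-loss start wins.
    """
    concs = np.asarray(concs, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if concs.shape != rates.shape:
        raise ValueError("concs and rates must have the same shape")
    if len(np.unique(concs)) < 4:
        raise ValueError("need >= 4 distinct concentrations for a 4-parameter fit")
    pos = concs[concs > 0]
    if len(pos) < 2:
        raise ValueError("need at least 2 positive concentrations")
    c_lo, c_hi = pos.min(), pos.max()
    ic50_lo, ic50_hi = c_lo * ic50_bounds_factor[0], c_hi * ic50_bounds_factor[1]

    g_span = rates.max() - rates.min()
    flat = g_span < 1e-12 * max(1.0, abs(rates.max()))

    def residuals(theta: np.ndarray) -> np.ndarray:
        g_max, g_min, log_ic50, log_nu = theta
        return _hill(concs, g_max, g_min, np.exp(log_ic50), np.exp(log_nu)) - rates

    lb = [-np.inf, -np.inf, np.log(ic50_lo), np.log(nu_bounds[0])]
    ub = [np.inf, np.inf, np.log(ic50_hi), np.log(nu_bounds[1])]
    ic50_starts = np.geomspace(c_lo, c_hi, n_ic50_starts)
    best = None
    n_starts = 0
    for ic0 in ic50_starts:
        for nu0 in nu_starts:
            theta0 = np.array([rates.max(), rates.min(), np.log(ic0), np.log(nu0)])
            theta0[2] = np.clip(theta0[2], lb[2], ub[2])
            theta0[3] = np.clip(theta0[3], lb[3], ub[3])
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
            n_starts += 1
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success and best.cost > 1e-6:
        raise RuntimeError("Hill fit failed to converge from every start")
    g_max, g_min, log_ic50, log_nu = best.x
    ic50, nu = float(np.exp(log_ic50)), float(np.exp(log_nu))
    # Gauss-Newton covariance estimate in the fitted parameter space
    cov = None
    dof = len(concs) - 4
    if dof > 0:
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * 2.0 * best.cost / dof
        except np.linalg.LinAlgError:
            cov = None
    extrapolated = not (c_lo <= ic50 <= c_hi)
    if extrapolated or flat:
        warnings.warn("fit_hill: IC50 unidentifiable or outside the sampled range")
    return HillFitResult(
        curve=HillCurve(g_max=float(g_max), g_min=float(g_min), ic50=ic50, nu=nu),
        loss=float(best.cost),
        covariance=cov,
        n_starts=n_starts,
        converged=bool(best.success),
        ic50_extrapolated=extrapolated,
        ic50_unidentifiable=flat,
    )


def generate_counts(
    true_rate: float,
    n0: float,
    t_grid: Sequence[float],
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    condition: float = 0.0,
    replicate: int = 0,
) -> CountSeries:
    """Synthetic noisy exponential-growth count series.

    ``counts = n0 * exp(rate * t) * exp(N(0, sigma))`` — multiplicative
    lognormal measurement noise, reproducible from ``rng_seed``.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, noise_sigma, size=t.shape) if noise_sigma > 0 else 0.0
    counts = n0 * np.exp(true_rate * t + noise)
    return CountSeries(times=t, counts=counts, condition=condition, replicate=replicate)


def read_count_series(path) -> List[CountSeries]:
    """Read a tidy count CSV (`time_hr,concentration,replicate,count`)."""
    df = pd.read_csv(path)
    required = {"time_hr", "concentration", "replicate", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"count CSV must have columns {sorted(required)}")
    out = []
    for (conc, rep), grp in df.groupby(["concentration", "replicate"]):
        grp = grp.sort_values("time_hr")
        out.append(
            CountSeries(
                times=grp["time_hr"].to_numpy(),
                counts=grp["count"].to_numpy(),
                condition=float(conc),
                replicate=int(rep),
            )
        )
    return out


def fit_seascape_from_counts(
    series_by_genotype: Dict[str, List[CountSeries]],
    concentration_unit: str = "ug/mL",
    pool_replicates: bool = True,
) -> FitnessSeascape:
    """Fit a Hill-curve seascape from per-genotype count time series.

    For each genotype, growth rates are estimated per (concentration,
    replicate); replicate rates at the same concentration are pooled as
    separate observations (``pool_replicates=True``) or averaged first.
    """
    curves = {}
    for bits, series_list in series_by_genotype.items():
        rows = []
        for s in series_list:
            est = growth_rate_from_counts(s)
            rows.append((s.condition, est.rate))
        df = pd.DataFrame(rows, columns=["conc", "rate"])
        if not pool_replicates:
            df = df.groupby("conc", as_index=False)["rate"].mean()
        fit = fit_hill(df["conc"].to_numpy(), df["rate"].to_numpy())
        curves[bits] = fit.curve
    return FitnessSeascape(curves, concentration_unit=concentration_unit)
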