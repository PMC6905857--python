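"""Logistic decay model for stored-oocyte developmental capacity.

Hatch rate versus storage time follows sigmoidal kinetics: a high initial
plateau (fresh mature oocytes hatch at 90–96%), then a temperature-dependent
collapse to zero over one to four weeks.  We model the hatch probability at
storage day t as

    p(t) = h0 / (1 + exp(slope * (t - t50)))

a three-parameter logistic with the upper plateau h0 estimated, the lower
plateau fixed at 0, and t50 the half-life — the storage duration at which
hatch falls to h0/2 (about 7, 12 and 23 days at 29, 25 and 20 °C).

Fitting is least squares (scipy's bounded trust-region solver), weighted by
the binomial standard error of each day's observed fraction when egg counts
are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import hatch_probability


@dataclass
class AgingCurveFit:
    """Fitted logistic decay: plateau h0, slope (1/day), half-life t50 (days)."""

    h0: float
    slope: float
    t50: float
    se: dict = field(default_factory=dict)
    rmse: float = float("nan")
    n_obs: int = 0
    converged: bool = False
    message: str = ""

    def summary(self) -> str:
        if not self.converged:
            return f"fit did not converge: {self.message}"
        return (
            f"h0 = {self.h0:.4f} +/- {self.se.get('h0', float('nan')):.4f}\n"
            f"slope = {self.slope:.4f} /day +/- {self.se.get('slope', float('nan')):.4f}\n"
            f"t50 = {self.t50:.3f} days +/- {self.se.get('t50', float('nan')):.3f}\n"
            f"rmse = {self.rmse:.4f} on {self.n_obs} days"
        )


def _extract(data: pd.DataFrame):
    if "hatch_fraction" in data.columns:
        days = np.asarray(data["day"], dtype=float)
        frac = np.asarray(data["hatch_fraction"], dtype=float)
        return days, frac, None
    days = np.asarray(data["day"], dtype=float)
    n = np.asarray(data["n_eggs"], dtype=float)
    x = np.asarray(data["n_hatched"], dtype=float)
    if np.any(n <= 0):
        raise ValueError("n_eggs must be positive")
    if np.any((x < 0) | (x > n)):
        raise ValueError("n_hatched must lie in [0, n_eggs]")
    return days, x / n, n


def fit_decay_curve(data: pd.DataFrame) -> AgingCurveFit:
    """Fit the logistic decay to (day, n_eggs, n_hatched) or
    (day, hatch_fraction) data.

    Weighted by binomial SE (with an Agresti-style shrunk proportion so a
    day with 0 or 100% hatching still has finite weight) when counts are
    given; unweighted otherwise.  Initialization: h0 = max observed hatch,
    t50 = day whose hatch is closest to half of that, slope = 0.5/day.
    Degenerate (flat) data return an unconverged fit rather than a
    fabricated half-life.
    """
    days, frac, n = _extract(data)
    if len(np.unique(days)) < 4:
        raise ValueError("need >= 4 distinct days to fit a three-parameter curve")

    if float(np.ptp(frac)) < 1e-3:
        return AgingCurveFit(
            h0=float(frac.mean()),
            slope=float("nan"),
            t50=float("nan"),
            n_obs=len(days),
            converged=False,
            message="hatch rate is constant; decay parameters unidentifiable",
        )

    sigma = None
    if n is not None:
        shrunk = (frac * n + 0.5) / (n + 1.0)
        sigma = np.sqrt(shrunk * (1.0 - shrunk) / n)

    h0_init = float(frac.max())
    t50_init = float(days[np.argmin(np.abs(frac - h0_init / 2.0))])
    p0 = [min(h0_init, 1.0), 0.5, max(t50_init, 1e-3)]
    bounds = ([1e-6, 1e-6, 1e-6], [1.0, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(
            lambda t, h0, slope, t50: hatch_probability(t, h0, slope, t50),
            days,
            frac,
            p0=p0,
            sigma=sigma,
            bounds=bounds,
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return AgingCurveFit(
            h0=float("nan"),
            slope=float("nan"),
            t50=float("nan"),
            n_obs=len(days),
            converged=False,
            message=str(exc),
        )
    perr = np.sqrt(np.diag(pcov))
    resid = frac - hatch_probability(days, *popt)
    return AgingCurveFit(
        h0=float(popt[0]),
        slope=float(popt[1]),
        t50=float(popt[2]),
        se={"h0": float(perr[0]), "slope": float(perr[1]), "t50": float(perr[2])},
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_obs=len(days),
        converged=bool(np.all(np.isfinite(perr))),
        message="converged",
    )


def predict_hatch(fit: AgingCurveFit, days) -> np.ndarray:
    """Evaluate the fitted curve; monotone non-increasing in storage time."""
    if not fit.converged:
        raise ValueError("cannot predict from an unconverged fit")
    return hatch_probability(np.asarray(days, dtype=float), fit.h0, fit.slope, fit.t50)
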