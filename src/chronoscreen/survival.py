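"""Per-strain survival curves and mean-lifespan estimates.

A strain's absolute viability cannot be read off a barcode array directly —
the array measures relative representation.  Multiplying the fold change of
a strain's (averaged) aging profile by the pool's CFU/mL at the same day
reconstructs an approximate per-strain CFU curve, normalized to 100% at the
reference day.  Mean lifespan is then estimated by least-squares fitting of
a Boltzmann sigmoid and reading off where the fitted curve crosses 50%
absolute survival; the area under the survival curve is reported alongside
as a fit-free summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError
from .simulate import boltzmann
from .tagio import AgingProfileMatrix

__all__ = [
    "BoltzmannFit",
    "SurvivalCurves",
    "reconstruct_survival",
    "fit_boltzmann",
    "mean_lifespan",
    "survival_auc",
    "fit_all_strains",
]

T50_MARGIN = 10.0  # allowed days beyond the sampled range for the fitted midpoint
MIN_RANGE = 5.0  # % span below which a curve is too flat to fit


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann sigmoid ``V(t) = bottom + (top-bottom)/(1+exp((t-t50)/tau))``."""

    top: float
    bottom: float
    t50: float
    tau: float
    rss: float
    converged: bool
    degenerate: bool = False
    extrapolated: bool = False  # t50 outside the sampled day range

    def predict(self, t):
        return boltzmann(t, self.top, self.bottom, self.t50, self.tau)


@dataclass
class SurvivalCurves:
    """Reconstructed per-strain survival: estimated CFU and percent-of-reference."""

    estimated_cfu: pd.DataFrame  # strain x day
    percent: pd.DataFrame  # strain x day, reference column = 100
    reference_day: int

    @property
    def days(self) -> list:
        return list(self.percent.columns)


def reconstruct_survival(
    profiles: AgingProfileMatrix, pool_cfu: pd.DataFrame
) -> SurvivalCurves:
    """Per-strain survival curves from averaged profiles x pool CFUs.

    ``estimated_cfu[s, t] = 2^r[s, t] * poolCFU(t)`` with the pool CFU
    averaged across replicates; percent survival is relative to the
    reference day (identically 100 there).
    """
    avg = profiles.averaged
    cfu_by_day = pool_cfu.groupby("day")["cfu_per_ml"].mean()
    missing = [d for d in avg.columns if d not in cfu_by_day.index]
    if missing:
        raise InputError(f"pool CFU missing for day(s) {missing}")
    cfu = cfu_by_day.reindex(avg.columns).to_numpy()
    est = np.power(2.0, avg.to_numpy(dtype=float)) * cfu[None, :]
    est_df = pd.DataFrame(est, index=avg.index, columns=avg.columns)
    ref = est_df[profiles.reference_day].to_numpy()
    percent = pd.DataFrame(
        100.0 * est / ref[:, None], index=avg.index, columns=avg.columns
    )
    percent[profiles.reference_day] = np.where(np.isnan(ref), np.nan, 100.0)
    return SurvivalCurves(estimated_cfu=est_df, percent=percent, reference_day=profiles.reference_day)


def fit_boltzmann(days, percent) -> BoltzmannFit:
    """Least-squares Boltzmann sigmoid fit to one percent-survival curve.

    Initialization: top = max, bottom = min, t50 = sampled day nearest the
    50%-of-range level, tau = span/8; bounded optimization keeps tau > 0 and
    t50 within ``[first - 10, last + 10]`` days.  A flat (< 5% range) or
    monotone-increasing curve is flagged degenerate and not fitted; a fitted
    midpoint outside the sampled days is flagged extrapolated, not rejected.
    """
    order = np.argsort(np.asarray(days, dtype=float))
    t = np.asarray(days, dtype=float)[order]
    y = np.asarray(percent, dtype=float)[order]
    if len(t) < 4:
        raise InputError("Boltzmann fit needs at least 4 points")
    span = float(y.max() - y.min())
    increasing = bool(np.all(np.diff(y) >= 0) and y[-1] > y[0])
    if span < MIN_RANGE or increasing:
        return BoltzmannFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, degenerate=True)

    mid_level = y.min() + span / 2.0
    t50_0 = float(t[np.argmin(np.abs(y - mid_level))])
    width = float(t[-1] - t[0])
    x0 = [float(y.max()), float(y.min()), t50_0, width / 8.0]
    lo = [0.0, 0.0, t[0] - T50_MARGIN, 1e-3]
    hi = [2.0 * float(y.max()), float(y.max()), t[-1] + T50_MARGIN, 4.0 * width]
    x0 = np.clip(x0, lo, hi)

    def resid(p):
        return boltzmann(t, *p) - y

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    top, bottom, t50, tau = map(float, sol.x)
    converged = bool(sol.success) and bottom <= top
    return BoltzmannFit(
        top=top,
        bottom=bottom,
        t50=t50,
        tau=tau,
        rss=float(2.0 * sol.cost),
        converged=converged,
        extrapolated=not (t[0] <= t50 <= t[-1]),
    )


def mean_lifespan(fit: BoltzmannFit) -> float:
    """Day at which the fitted curve crosses 50% absolute survival.

    Closed form ``t50 + tau * ln((top - 50) / (50 - bottom))``; equals the
    midpoint parameter t50 when top = 100 and bottom = 0.  NaN when the
    fitted curve never crosses 50% (bottom >= 50 or top <= 50).
    """
    if not fit.converged:
        raise InputError("mean lifespan requires a converged fit")
    if fit.bottom >= 50.0 or fit.top <= 50.0:
        return float("nan")
    return fit.t50 + fit.tau * math.log((fit.top - 50.0) / (50.0 - fit.bottom))


def survival_auc(days, percent) -> float:
    """Trapezoidal area under the survival curve, in % x days."""
    order = np.argsort(np.asarray(days, dtype=float))
    t = np.asarray(days, dtype=float)[order]
    y = np.asarray(percent, dtype=float)[order]
    if len(t) < 2:
        raise InputError("AUC needs at least 2 points")
    return float(np.trapezoid(y, t))


def fit_all_strains(curves: SurvivalCurves) -> pd.DataFrame:
    """Boltzmann fit, mean lifespan and AUC for every reconstructed strain."""
    rows = []
    t = np.asarray(curves.days, dtype=float)
    for sid, y in curves.percent.iterrows():
        yv = y.to_numpy(dtype=float)
        ok = ~np.isnan(yv)
        row: dict = {"strain_id": sid}
        if ok.sum() >= 2:
            row["auc"] = survival_auc(t[ok], yv[ok])
        else:
            row["auc"] = np.nan
        if ok.sum() >= 4:
            fit = fit_boltzmann(t[ok], yv[ok])
            row.update(
                top=fit.top, bottom=fit.bottom, t50=fit.t50, tau=fit.tau,
                rss=fit.rss, converged=fit.converged, degenerate=fit.degenerate,
                extrapolated=fit.extrapolated,
                mean_lifespan=mean_lifespan(fit) if fit.converged else np.nan,
            )
        else:
            row.update(
                top=np.nan, bottom=np.nan, t50=np.nan, tau=np.nan, rss=np.nan,
                converged=False, degenerate=False, extrapolated=False, mean_lifespan=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("strain_id")
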