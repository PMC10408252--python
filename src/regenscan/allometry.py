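"""Per-limb power-law mass~size fits and the limb-mass -> energy calibration.

The limb model is ``mass = a * CW**b`` fitted by nonlinear least squares on
the mass scale (unweighted, despite known heteroskedasticity, to keep the
residual threshold on the raw gram scale).  Starting values come from an
ordinary least-squares fit of ``log(mass)`` on ``log(CW)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from regenscan.synthetic import STATUS_INTACT, limb_mass_col, limb_status_col

XTOL = 1e-8
MAX_ITER = 500
MIN_LIMBS = 10


def _power_law(cw, a, b):
    return a * np.power(cw, b)


@dataclass
class AllometricFit:
    """A fitted per-limb power law with its mass-scale residuals.

    Residuals (observed minus predicted mass, grams) are defined exactly for
    the limbs used in the fit: physically present limbs with measurable mass,
    which includes partially regenerated ones.
    """

    limb_id: int
    a: float
    b: float
    n_limbs_used: int
    residuals: pd.Series = field(repr=False)
    residual_sd: float = np.nan
    converged: bool = True


@dataclass
class EnergyCalibration:
    """OLS calibration of limb energy content (kJ) against dry mass (g)."""

    slope: float
    slope_se: float
    intercept: float
    t_statistic: float
    r_squared: float
    n: int


def fit_limb_allometry(crabs: pd.DataFrame, limb_id: int) -> AllometricFit:
    """Fit ``mass = a * CW**b`` for one limb slot across a crab table.

    Only limbs with status ``intact`` (which includes historically lost limbs
    that have partially regrown) enter the fit.  Requires at least
    ``MIN_LIMBS`` present limbs with positive mass and carapace width.
    """
    scol, mcol = limb_status_col(limb_id), limb_mass_col(limb_id)
    present = crabs[scol] == STATUS_INTACT
    sub = crabs.loc[present, ["crab_id", "carapace_width_mm", mcol]].dropna()
    sub = sub[(sub[mcol] > 0) & (sub["carapace_width_mm"] > 0)]
    if len(sub) < MIN_LIMBS:
        raise ValueError(
            f"limb {limb_id}: only {len(sub)} present limbs, need >= {MIN_LIMBS}"
        )

    cw = sub["carapace_width_mm"].to_numpy(float)
    mass = sub[mcol].to_numpy(float)

    # log-log OLS start values
    logc, logm = np.log(cw), np.log(mass)
    b0, loga0 = np.polyfit(logc, logm, 1)
    p0 = (float(np.exp(loga0)), float(b0))

    converged = True
    try:
        popt, _ = curve_fit(
            _power_law, cw, mass, p0=p0, xtol=XTOL, maxfev=MAX_ITER * 10
        )
        a_hat, b_hat = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        a_hat, b_hat = p0

    resid = pd.Series(
        mass - _power_law(cw, a_hat, b_hat), index=sub["crab_id"].to_numpy()
    )
    return AllometricFit(
        limb_id=limb_id,
        a=a_hat,
        b=b_hat,
        n_limbs_used=len(sub),
        residuals=resid,
        residual_sd=float(resid.std(ddof=2)),
        converged=converged,
    )


def fit_all_limbs(crabs: pd.DataFrame) -> dict:
    """Fit all 10 limb slots; returns ``{limb_id: AllometricFit}``."""
    return {limb_id: fit_limb_allometry(crabs, limb_id) for limb_id in range(1, 11)}


def predict_limb_mass(fit: AllometricFit, cw) -> float:
    """Expected limb mass ``a * cw**b`` at carapace width ``cw`` (mm)."""
    if not fit.converged:
        raise ValueError(f"limb {fit.limb_id}: fit did not converge; refusing to predict")
    cw = np.asarray(cw, dtype=float)
    if np.any(cw <= 0):
        raise ValueError("carapace width must be positive")
    out = _power_law(cw, fit.a, fit.b)
    return float(out) if out.ndim == 0 else out


def fits_table(fits: dict) -> pd.DataFrame:
    """Per-limb fit summary (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "limb_id": f.limb_id,
                "a": f.a,
                "b": f.b,
                "n_limbs_used": f.n_limbs_used,
                "residual_sd_g": f.residual_sd,
                "converged": f.converged,
            }
            for f in (fits[k] for k in sorted(fits))
        ]
    )


def fit_energy_mass_regression(
    leg_masses: Sequence[float], energies: Sequence[float]
) -> EnergyCalibration:
    """OLS of energy content (kJ) on leg dry mass (g).

    A positive, tightly linear slope supports using regenerated-limb mass as
    a proxy for the energy already allocated to regrowth.
    """
    x = np.asarray(leg_masses, dtype=float)
    y = np.asarray(energies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("leg_masses and energies must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 1e-12 * max(1.0, float(np.mean(x**2))) * n:
        raise ValueError("slope undefined: all leg masses identical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if n > 2 and sse > 0:
        se = float(np.sqrt(sse / (n - 2) / sxx))
    else:
        se = 0.0
    t = slope / se if se > 0 else np.inf if slope != 0 else np.nan
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return EnergyCalibration(
        slope=slope,
        slope_se=se,
        intercept=intercept,
        t_statistic=float(t),
        r_squared=float(r2),
        n=n,
    )
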