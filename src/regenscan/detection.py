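"""Residual-threshold detection of historically regenerating limbs.

A limb whose mass-scale allometric residual falls strictly below a negative
cutoff is classified as regenerating from a past loss.  The default cutoff is
a fixed -0.01 g for every limb; the ``gap`` method automates the visual
"break away from the main cluster" by scanning for the widest gap among
detached negative residuals, and ``quantile`` uses a lower residual quantile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from regenscan.allometry import AllometricFit, predict_limb_mass
from regenscan.config import LIMB_IDS
from regenscan.synthetic import (
    STATUS_BUD,
    STATUS_INTACT,
    STATUS_MISSING,
    limb_mass_col,
    limb_status_col,
)

logger = logging.getLogger(__name__)

MIN_RESIDUALS = 20


@dataclass
class CutoffSpec:
    """How to resolve the per-limb regeneration cutoff (grams, negative).

    method 'fixed': use ``value`` as-is.
    method 'gap': midpoint of the widest gap among negative residuals lying
    below the lower quartile of all residuals; falls back to 'fixed' when no
    detached negative cluster exists.
    method 'quantile': the ``quantile`` lower quantile of the residuals
    (falls back to 'fixed' if that quantile is non-negative).
    """

    method: str = "fixed"
    value: float = -0.01
    quantile: float = 0.05
    gap_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "gap", "quantile"):
            raise ValueError(f"unknown cutoff method {self.method!r}")
        if self.value >= 0:
            raise ValueError("fixed cutoff value must be negative")
        if not (0 < self.quantile < 0.5):
            raise ValueError("quantile must be in (0, 0.5)")


@dataclass
class RegenAssessment:
    """Per-crab injury summary used as model predictors downstream."""

    crab_id: str
    n_missing: int
    n_buds: int
    n_present: int
    regenerating_flags: Dict[int, bool] = field(repr=False)
    regen_mass_total: float = 0.0
    expected_missing_mass: float = 0.0
    corrected_body_mass: float = np.nan


def determine_cutoff(residuals, spec: CutoffSpec) -> float:
    """Resolve the regeneration cutoff (g) for one limb's residual set."""
    resid = np.sort(np.asarray(residuals, dtype=float))
    if len(resid) < MIN_RESIDUALS:
        raise ValueError(f"need >= {MIN_RESIDUALS} residuals, got {len(resid)}")

    if spec.method == "fixed":
        return float(spec.value)

    if spec.method == "quantile":
        q = float(np.quantile(resid, spec.quantile))
        if q >= 0:
            warnings.warn(
                "quantile cutoff is non-negative; falling back to fixed value",
                stacklevel=2,
            )
            return float(spec.value)
        return q

    # gap: candidates are negative residuals detached below the lower
    # quartile of the full residual set
    q1 = float(np.quantile(resid, 0.25))
    cand = resid[(resid < 0) & (resid < q1)]
    if len(cand) < 2:
        warnings.warn(
            "no detached negative residual cluster; falling back to fixed value",
            stacklevel=2,
        )
        return float(spec.value)
    gaps = np.diff(cand)
    k = int(np.argmax(gaps))
    largest = float(gaps[k])
    typical = float(np.median(gaps)) if len(gaps) > 1 else 0.0
    if largest <= 0 or (typical > 0 and largest < spec.gap_factor * typical):
        warnings.warn(
            "no gap clearly wider than typical spacing; falling back to fixed value",
            stacklevel=2,
        )
        return float(spec.value)
    cutoff = float((cand[k] + cand[k + 1]) / 2.0)
    if cutoff >= 0:  # pragma: no cover - cand < 0 guarantees this
        return float(spec.value)
    return cutoff


def classify_limbs(residuals: pd.Series, cutoff: float) -> pd.Series:
    """Flag regenerating limbs: residual strictly below the cutoff.

    Ties (residual exactly equal to the cutoff) are NOT flagged.
    """
    return residuals < cutoff


def regeneration_index(flags: Mapping[int, bool], limb_masses: Mapping[int, float]) -> float:
    """Summed dry mass (g) of flagged present limbs; buds are excluded.

    ``flags`` only ever covers present limbs, so bud masses never enter.
    """
    total = 0.0
    for limb_id, flagged in flags.items():
        if flagged:
            total += float(limb_masses[limb_id])
    return total


def impute_missing_limb_mass(fits: Mapping[int, AllometricFit], crab: pd.Series) -> float:
    """Summed expected mass (g) of absent limb slots (missing or bud).

    A bud is not a functioning limb and its mass was not recorded, so
    bud-bearing slots contribute their full predicted mass.
    """
    cw = float(crab["carapace_width_mm"])
    total = 0.0
    for limb_id in LIMB_IDS:
        status = crab[limb_status_col(limb_id)]
        if status in (STATUS_MISSING, STATUS_BUD):
            fit = fits.get(limb_id)
            if fit is None or not fit.converged:
                raise ValueError(
                    f"no converged allometric fit for absent limb {limb_id}"
                )
            total += predict_limb_mass(fit, cw)
    return total


def corrected_body_mass(crab: pd.Series, expected_missing_mass: float) -> float:
    """Body mass net of ovary/hepatopancreas, plus imputed missing-limb mass.

    ``body_rest_mass_g`` is already organ-free (organs were dissected out
    before drying), so no re-subtraction happens here.  For an uninjured crab
    this equals ``body_rest_mass_g`` exactly.
    """
    out = float(crab["body_rest_mass_g"]) + float(expected_missing_mass)
    if out < 0:
        raise ValueError(
            f"corrected body mass negative for crab {crab.get('crab_id')}; "
            "check input units"
        )
    return out


def assess_population(
    crabs: pd.DataFrame,
    fits: Mapping[int, AllometricFit],
    spec: CutoffSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, Dict[int, float]]:
    """Run cutoff resolution, classification and per-crab indices.

    Returns ``(assessments, flags, cutoffs)``: a per-crab assessment table,
    a per-crab boolean flag table (columns ``limb01`` .. ``limb10``) and the
    resolved per-limb cutoffs.
    """
    spec = spec or CutoffSpec()
    for limb_id in LIMB_IDS:
        if not fits[limb_id].converged:
            raise ValueError(
                f"limb {limb_id}: unconverged allometric fit; refusing to classify"
            )

    cutoffs: Dict[int, float] = {}
    flag_frame = pd.DataFrame(
        False, index=crabs["crab_id"].to_numpy(), columns=[f"limb{l:02d}" for l in LIMB_IDS]
    )
    for limb_id in LIMB_IDS:
        fit = fits[limb_id]
        cutoffs[limb_id] = determine_cutoff(fit.residuals.to_numpy(), spec)
        logger.info(
            "limb %d: cutoff %.5f g (method=%s)", limb_id, cutoffs[limb_id], spec.method
        )
        flagged = classify_limbs(fit.residuals, cutoffs[limb_id])
        flag_frame.loc[flagged.index[flagged], f"limb{limb_id:02d}"] = True

    rows = []
    for _, crab in crabs.iterrows():
        cid = crab["crab_id"]
        statuses = {l: crab[limb_status_col(l)] for l in LIMB_IDS}
        n_missing = sum(1 for s in statuses.values() if s == STATUS_MISSING)
        n_buds = sum(1 for s in statuses.values() if s == STATUS_BUD)
        n_present = sum(1 for s in statuses.values() if s == STATUS_INTACT)
        flags = {
            l: bool(flag_frame.at[cid, f"limb{l:02d}"])
            for l in LIMB_IDS
            if statuses[l] == STATUS_INTACT
        }
        masses = {
            l: crab[limb_mass_col(l)] for l in LIMB_IDS if statuses[l] == STATUS_INTACT
        }
        regen_total = regeneration_index(flags, masses)
        expected_missing = impute_missing_limb_mass(fits, crab)
        rows.append(
            {
                "crab_id": cid,
                "n_missing": n_missing,
                "n_buds": n_buds,
                "n_present": n_present,
                "regen_limb_count": int(sum(flags.values())),
                "regen_mass_total_g": regen_total,
                "expected_missing_mass_g": expected_missing,
                "corrected_body_mass_g": corrected_body_mass(crab, expected_missing),
            }
        )
    return pd.DataFrame(rows), flag_frame, cutoffs


def summarize_injury(
    crabs: pd.DataFrame, assessments: pd.DataFrame, flags: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-limb and population injury summary.

    The per-limb table counts, for each of the 10 limb slots, limbs missing
    with no bud, limbs missing with a bud, and present limbs classified as
    historically regenerating.  The population table reports totals under
    both counting conventions (missing excluding vs. including bud-bearing
    slots), percentages of all limb slots (denominator ``10 * n_crabs``) and
    of existing limbs, and per-crab means/SDs.
    """
    if len(assessments) < 1:
        raise ValueError("need assessments for at least one crab")
    n_crabs = len(crabs)
    per_limb_rows = []
    for limb_id in LIMB_IDS:
        status = crabs[limb_status_col(limb_id)]
        per_limb_rows.append(
            {
                "limb_id": limb_id,
                "n_missing_no_bud": int((status == STATUS_MISSING).sum()),
                "n_missing_with_bud": int((status == STATUS_BUD).sum()),
                "n_historically_regenerating": int(flags[f"limb{limb_id:02d}"].sum()),
            }
        )
    per_limb = pd.DataFrame(per_limb_rows)

    total_slots = 10 * n_crabs
    miss_no_bud = int(per_limb["n_missing_no_bud"].sum())
    miss_bud = int(per_limb["n_missing_with_bud"].sum())
    regen = int(per_limb["n_historically_regenerating"].sum())
    missing_incl = miss_no_bud + miss_bud
    existing = total_slots - missing_incl
    pop = pd.DataFrame(
        [
            {
                "n_crabs": n_crabs,
                "total_limb_slots": total_slots,
                "n_missing_excl_buds": miss_no_bud,
                "n_missing_with_bud": miss_bud,
                "n_missing_incl_buds": missing_incl,
                "n_historically_regenerating": regen,
                "pct_missing_of_all_limbs": 100.0 * missing_incl / total_slots,
                "pct_regenerating_of_existing": (
                    100.0 * regen / existing if existing else np.nan
                ),
                "pct_missing_or_regenerating": 100.0
                * (missing_incl + regen)
                / total_slots,
                "mean_regen_limbs_per_crab": float(
                    assessments["regen_limb_count"].mean()
                ),
                "sd_regen_limbs_per_crab": float(
                    assessments["regen_limb_count"].std(ddof=1)
                )
                if n_crabs > 1
                else np.nan,
                "mean_regen_mass_mg": float(
                    assessments["regen_mass_total_g"].mean() * 1000
                ),
                "sd_regen_mass_mg": float(
                    assessments["regen_mass_total_g"].std(ddof=1) * 1000
                )
                if n_crabs > 1
                else np.nan,
            }
        ]
    )
    return per_limb, pop
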