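"""Synthetic crab populations with known injury states and trade-off effects.

The generator produces cross-sectional snapshots only: each crab is drawn
independently, with a single within-crab molt-stage multiplier standing in
for soft-tissue growth between molts.  A complete truth table accompanies
every population so that downstream detection and inference stages can be
scored against known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from regenscan.config import LIMB_IDS, ORGANS, GeneratorConfig

logger = logging.getLogger(__name__)

STATUS_INTACT = "intact"
STATUS_MISSING = "missing"
STATUS_BUD = "bud"

ORGAN_COLUMNS = {
    "ovary": "ovary_mass_g",
    "hepatopancreas": "hepatopancreas_mass_g",
    "stomach": "stomach_mass_g",
    "body_rest": "body_rest_mass_g",
}


def limb_status_col(limb_id: int) -> str:
    return f"limb{limb_id:02d}_status"


def limb_mass_col(limb_id: int) -> str:
    return f"limb{limb_id:02d}_mass_g"


@dataclass
class SyntheticTruth:
    """Ground truth for a generated population.

    ``limb_truth`` has one row per generated limb (``crab_id``, ``limb``,
    ``true_status`` in {intact, missing, bud, partial}, ``regen_fraction``,
    ``expected_mass_g``); ``tradeoff_coeffs`` echoes the injected per-organ
    coefficients verbatim from the configuration.
    """

    limb_truth: pd.DataFrame
    tradeoff_coeffs: pd.DataFrame


def seasonal_effect(julian_day, amplitude: float, peak_day: float):
    """Cyclic seasonal multiplier ``1 + A * cos(2*pi*(day - peak)/365)``.

    The period is 365 days and the mean over a full year is ~1.  Amplitudes
    of 1 or more are rejected because they would permit non-positive
    multipliers.
    """
    if amplitude >= 1.0:
        raise ValueError("season amplitude must be < 1 to keep multipliers positive")
    if amplitude < 0.0:
        raise ValueError("season amplitude must be non-negative")
    day = np.asarray(julian_day, dtype=float)
    if np.any(day < 1) or np.any(day > 366):
        raise ValueError("julian_day must lie in [1, 366]")
    out = 1.0 + amplitude * np.cos(2.0 * np.pi * (day - peak_day) / 365.0)
    if np.isscalar(julian_day):
        return float(out)
    return out


def generate_population(config: GeneratorConfig) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a crab table plus its truth table.

    Per crab: carapace width is uniform on ``cw_range``; a molt-stage
    multiplier ``m`` is drawn once and shared by all that crab's limbs; each
    intact limb's mass is ``a_l * CW**b_l * m * exp(eps)`` with
    ``eps ~ N(0, limb_noise_sd)``.  Lost limbs become buds, partially
    regenerated limbs (recorded as present/intact with mass
    ``f * a_l * CW**b_l * m``) or are completely absent.  Organ masses follow
    per-organ power laws modulated by a seasonal cycle and lognormal noise,
    shifted additively by the configured trade-off coefficients and floored
    at zero (floor events are logged).

    Identical config (including seed) yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_crabs

    cw = rng.uniform(*config.cw_range, size=n)
    julian = rng.integers(config.julian_range[0], config.julian_range[1] + 1, size=n)
    molt = rng.uniform(*config.molt_stage_range, size=n)
    site = rng.choice(list(config.sites), size=n)

    # Per-crab loss propensity.  A Beta draw (moment-matched to p_loss /
    # p_loss_sd) induces the positive missing~bud correlation seen in field
    # samples, where injury-prone crabs accumulate both.
    if config.p_loss_sd > 0:
        p, v = config.p_loss, config.p_loss_sd**2
        kappa = p * (1 - p) / v - 1.0
        p_loss_i = rng.beta(p * kappa, (1 - p) * kappa, size=n)
    else:
        p_loss_i = np.full(n, config.p_loss)

    p_bud = config.p_bud_given_loss
    p_partial = config.p_partial_given_loss

    records = []
    truth_rows = []
    n_floor_events = 0
    for i in range(n):
        rec = {
            "crab_id": f"C{i + 1:05d}",
            "site": site[i],
            "julian_day": int(julian[i]),
            "carapace_width_mm": float(cw[i]),
        }
        n_missing = 0
        n_buds = 0
        partial_mass = 0.0
        for limb_id in LIMB_IDS:
            a, b = config.limb_allometry[limb_id - 1]
            expected = a * cw[i] ** b
            lost = rng.random() < p_loss_i[i]
            # noise draw consumed unconditionally to keep streams aligned
            eps = rng.normal(0.0, config.limb_noise_sd) if config.limb_noise_sd > 0 else 0.0
            u_state = rng.random()
            frac = np.nan
            if not lost:
                status, mass = STATUS_INTACT, expected * molt[i] * np.exp(eps)
                true_status = STATUS_INTACT
            elif u_state < p_bud:
                status = STATUS_BUD
                mass = expected * rng.uniform(*config.bud_mass_fraction_range)
                true_status = STATUS_BUD
                n_buds += 1
            elif u_state < p_bud + p_partial:
                frac = rng.uniform(*config.regen_fraction_range)
                status, mass = STATUS_INTACT, frac * expected * molt[i]
                true_status = "partial"
                partial_mass += mass
            else:
                status, mass = STATUS_MISSING, np.nan
                true_status = STATUS_MISSING
                n_missing += 1
            rec[limb_status_col(limb_id)] = status
            rec[limb_mass_col(limb_id)] = mass
            truth_rows.append(
                {
                    "crab_id": rec["crab_id"],
                    "limb": limb_id,
                    "true_status": true_status,
                    "regen_fraction": frac,
                    "expected_mass_g": expected,
                }
            )

        season = seasonal_effect(
            int(julian[i]), config.season_amplitude, config.season_peak_day
        )
        cw_mid = 0.5 * (config.cw_range[0] + config.cw_range[1])
        for organ, (alpha, beta), (b_miss, b_bud, b_regen) in zip(
            ORGANS, config.organ_allometry, config.tradeoff_coeffs
        ):
            eps_o = (
                rng.normal(0.0, config.organ_noise_sd)
                if config.organ_noise_sd > 0
                else 0.0
            )
            base = alpha * cw[i] ** beta * season
            if config.organ_noise_model == "lognormal":
                mass = base * np.exp(eps_o)
            else:
                mass = base + eps_o * alpha * cw_mid**beta
            mass += b_miss * n_missing + b_bud * n_buds + b_regen * partial_mass
            if mass < 0:
                n_floor_events += 1
                mass = 0.0
            rec[ORGAN_COLUMNS[organ]] = mass
        records.append(rec)

    if n_floor_events:
        logger.warning("floored %d negative organ masses at 0", n_floor_events)

    crabs = pd.DataFrame.from_records(records)
    coeffs = pd.DataFrame(
        [
            {"organ": organ, "beta_missing": c[0], "beta_bud": c[1], "beta_regen": c[2]}
            for organ, c in zip(ORGANS, config.tradeoff_coeffs)
        ]
    )
    truth = SyntheticTruth(
        limb_truth=pd.DataFrame.from_records(truth_rows), tradeoff_coeffs=coeffs
    )
    return crabs, truth


def write_population(crabs: pd.DataFrame, truth: SyntheticTruth, outdir) -> None:
    """Write the crab table and truth sidecars as CSV into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    crabs.to_csv(outdir / "population.csv", index=False)
    truth.limb_truth.to_csv(outdir / "truth_limbs.csv", index=False)
    truth.tradeoff_coeffs.to_csv(outdir / "truth_coeffs.csv", index=False)
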