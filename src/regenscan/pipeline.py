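"""Orchestration: validation, staged execution, manifests and CSV outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from regenscan import allometry, detection, models
from regenscan._version import __version__
from regenscan.config import LIMB_IDS, GeneratorConfig
from regenscan.detection import CutoffSpec
from regenscan.synthetic import (
    ORGAN_COLUMNS,
    STATUS_BUD,
    STATUS_INTACT,
    STATUS_MISSING,
    generate_population,
    limb_mass_col,
    limb_status_col,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    ["crab_id", "site", "julian_day", "carapace_width_mm"]
    + [limb_status_col(l) for l in LIMB_IDS]
    + [limb_mass_col(l) for l in LIMB_IDS]
    + list(ORGAN_COLUMNS.values())
)

ORGAN_MASS_COLUMNS = list(ORGAN_COLUMNS.values())

_STATUS_ALIASES = {
    "intact": STATUS_INTACT,
    "present": STATUS_INTACT,
    "i": STATUS_INTACT,
    "missing": STATUS_MISSING,
    "absent": STATUS_MISSING,
    "m": STATUS_MISSING,
    "bud": STATUS_BUD,
    "limb bud": STATUS_BUD,
    "limb_bud": STATUS_BUD,
    "b": STATUS_BUD,
}


@dataclass
class RunManifest:
    """Sample accounting and provenance for one pipeline run."""

    seed: int | None
    config_hash: str
    cutoff_method: str
    cutoffs: Mapping[int, float]
    n_input: int
    n_discarded: int
    n_analyzed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: list = field(default_factory=list)
    status: str = "ok"

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["cutoffs"] = {str(k): v for k, v in self.cutoffs.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def load_table(path, column_map: Mapping[str, str] | str | Path | None = None) -> pd.DataFrame:
    """Read a crab CSV, optionally renaming columns via a mapping file.

    The mapping (YAML, ``external_name: canonical_name``) adapts external
    datasets to the canonical schema without code changes.
    """
    df = pd.read_csv(path)
    if column_map is not None:
        if not isinstance(column_map, Mapping):
            with open(column_map) as fh:
                column_map = yaml.safe_load(fh) or {}
        df = df.rename(columns=dict(column_map))
    return df


def validate_input(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Schema-check a crab table; drop and log incomplete rows.

    Rows missing any organ mass or carapace width are discarded (with a
    reason per row).  Limb status strings are normalized.  Hard errors:
    missing columns, duplicate crab ids, unknown status tokens, negative
    masses.  Rows whose summed limb mass reaches the body mass only draw a
    warning (unit check), not a discard.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"input table lacks required columns: {missing_cols}")
    df = table.copy()

    dup = df["crab_id"][df["crab_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate crab_id values: {sorted(dup.unique())}")

    for limb_id in LIMB_IDS:
        col = limb_status_col(limb_id)
        norm = df[col].astype(str).str.strip().str.lower().map(_STATUS_ALIASES)
        bad = df[col][norm.isna()]
        if not bad.empty:
            raise ValueError(
                f"unknown limb status token(s) in {col}: {sorted(bad.unique())}"
            )
        df[col] = norm

    mass_cols = [limb_mass_col(l) for l in LIMB_IDS] + ORGAN_MASS_COLUMNS
    for col in mass_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals < 0).any():
            rows = df.index[vals < 0].tolist()
            raise ValueError(f"negative mass in {col} at rows {rows}")
        df[col] = vals

    reasons = []
    keep = pd.Series(True, index=df.index)
    for col in ORGAN_MASS_COLUMNS + ["carapace_width_mm"]:
        bad = df[col].isna()
        for idx in df.index[bad & keep]:
            reasons.append(
                {"crab_id": df.at[idx, "crab_id"], "reason": f"missing {col}"}
            )
        keep &= ~bad

    limb_mass_total = df[[limb_mass_col(l) for l in LIMB_IDS]].sum(axis=1)
    body_total = df[ORGAN_MASS_COLUMNS].sum(axis=1) + limb_mass_total
    suspicious = keep & (limb_mass_total >= body_total) & (body_total > 0)
    if suspicious.any():
        logger.warning(
            "%d rows have limb mass >= total body mass; check input units",
            int(suspicious.sum()),
        )

    clean = df[keep].reset_index(drop=True)
    discard_log = pd.DataFrame(reasons, columns=["crab_id", "reason"])
    logger.info("validated input: %d kept, %d discarded", len(clean), len(discard_log))
    return clean, discard_log


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode()
    ).hexdigest()[:16]


def run_pipeline(
    input_csv=None,
    config: GeneratorConfig | None = None,
    outdir=None,
    cutoff: CutoffSpec | None = None,
    responses=("stomach", "ovary", "hepatopancreas", "body"),
    squared_candidates=models.DEFAULT_SQUARED_CANDIDATES,
    alpha=None,
    column_map=None,
    cyclic_julian: bool = False,
    make_plots: bool = False,
    overwrite: bool = False,
) -> RunManifest:
    """Run validate -> allometry -> detect -> model -> report.

    Input is either a crab CSV (``input_csv``) or a generator config
    (``config``), not both.  All intermediate tables, a model comparison, the
    manifest and logs land in ``outdir``; outputs are deterministic for a
    fixed input/seed (images excluded).
    """
    if (input_csv is None) == (config is None):
        raise ValueError("provide exactly one of input_csv or config")
    if outdir is None:
        outdir = Path(f"regenscan_run_{time.strftime('%Y%m%d_%H%M%S')}")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty; pass overwrite=True to reuse")
    outdir.mkdir(parents=True, exist_ok=True)

    cutoff = cutoff or CutoffSpec()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stages = []

    def stage(name):
        logger.info("stage: %s", name)
        stages.append(name)

    truth = None
    if config is not None:
        stage("simulate")
        raw, truth = generate_population(config)
        raw.to_csv(outdir / "population.csv", index=False)
        truth.limb_truth.to_csv(outdir / "truth_limbs.csv", index=False)
        truth.tradeoff_coeffs.to_csv(outdir / "truth_coeffs.csv", index=False)
        config_hash = config.digest()
        seed = config.seed
    else:
        stage("load")
        raw = load_table(input_csv, column_map)
        config_hash = _table_hash(raw)
        seed = None

    manifest = RunManifest(
        seed=seed,
        config_hash=config_hash,
        cutoff_method=cutoff.method,
        cutoffs={},
        n_input=len(raw),
        n_discarded=0,
        n_analyzed=0,
        started=started,
        stages=stages,
    )

    try:
        stage("validate")
        crabs, discards = validate_input(raw)
        manifest.n_discarded = len(discards)
        manifest.n_analyzed = len(crabs)
        discards.to_csv(outdir / "discard_log.csv", index=False)
        crabs.to_csv(outdir / "analyzed.csv", index=False)

        stage("allometry")
        fits = allometry.fit_all_limbs(crabs)
        allometry.fits_table(fits).to_csv(outdir / "allometry_fits.csv", index=False)

        stage("detect")
        assessments, flags, cutoffs = detection.assess_population(crabs, fits, cutoff)
        manifest.cutoffs = cutoffs
        assessments.to_csv(outdir / "assessments.csv", index=False)
        per_limb, pop = detection.summarize_injury(crabs, assessments, flags)
        per_limb.to_csv(outdir / "injury_by_limb.csv", index=False)
        pop.to_csv(outdir / "injury_summary.csv", index=False)

        stage("model")
        budres = models.residualize_buds(
            assessments["n_buds"], assessments["n_missing"]
        )
        pd.DataFrame(
            [
                {
                    "intercept": budres.intercept,
                    "slope": budres.slope,
                    "z": budres.z,
                    "p": budres.pvalue,
                    "null_deviance": budres.null_deviance,
                    "residual_deviance": budres.residual_deviance,
                    "resid_type": budres.resid_type,
                }
            ]
        ).to_csv(outdir / "bud_residualization.csv", index=False)

        frame = models.build_model_frame(crabs, assessments, budres)
        comparison_rows = []
        selected = {}
        for resp in responses:
            linear = models.fit_tradeoff_gam(
                frame, resp, alpha=alpha, cyclic_julian=cyclic_julian,
                label=f"{resp}:linear",
            )
            if resp in squared_candidates:
                quad = models.fit_tradeoff_gam(
                    frame,
                    resp,
                    include_squared=("bud_resid",),
                    alpha=alpha,
                    cyclic_julian=cyclic_julian,
                    label=f"{resp}:quadratic",
                )
                chosen, d_aic = models.select_model(linear, quad)
            else:
                chosen, d_aic = linear, np.nan
            selected[resp] = chosen
            chosen.terms.to_csv(outdir / f"model_{resp}_terms.csv", index=False)
            comparison_rows.append(
                {
                    "response": resp,
                    "selected": chosen.label,
                    "aic": chosen.aic,
                    "delta_aic_rejected": d_aic,
                    "deviance_explained": chosen.deviance_explained,
                    "n": chosen.n,
                }
            )
        pd.DataFrame(comparison_rows).to_csv(
            outdir / "model_comparison.csv", index=False
        )

        stage("report")
        if truth is not None:
            report = models.recovery_report(selected, truth.tradeoff_coeffs)
            report.to_csv(outdir / "recovery_report.csv", index=False)
        if make_plots:
            _figure_residual_plots(frame, responses, outdir, alpha, cyclic_julian)
    except Exception:
        manifest.status = "failed"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.to_json(outdir / "manifest.json")
        raise

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _figure_residual_plots(frame, responses, outdir, alpha, cyclic_julian):
    """Figure-style displays: size/season-adjusted residuals vs injury."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for resp in responses:
        resid = models.plotting_residuals(
            frame, resp, alpha=alpha, cyclic_julian=cyclic_julian
        )
        sub = frame.loc[resid.index]
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, var in zip(axes[:2], ("n_missing", "n_buds")):
            groups = sorted(sub[var].unique())
            ax.boxplot(
                [resid[sub[var] == g] for g in groups],
                tick_labels=[str(int(g)) for g in groups],
            )
            ax.axhline(0.0, ls="--", color="gray")
            ax.set_xlabel(var)
            ax.set_ylabel("Pearson residual")
        axes[2].scatter(sub["regen_mass"], resid, s=8, alpha=0.5)
        axes[2].axhline(0.0, ls="--", color="gray")
        axes[2].set_xlabel("regenerated limb mass (g)")
        fig.suptitle(resp)
        fig.tight_layout()
        fig.savefig(outdir / f"residuals_{resp}.png", dpi=120)
        plt.close(fig)
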