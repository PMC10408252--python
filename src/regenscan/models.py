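"""Trade-off inference: bud-count decorrelation and additive models.

The four hypothesis models (stomach, ovary, hepatopancreas, corrected body
mass) share one structure: a Gaussian additive model with parametric injury
predictors (missing-limb count, decorrelated bud count, cumulative
regenerated limb mass, optional squared terms) and penalized-spline smooths
of carapace width and Julian sampling day.  Bud counts are decorrelated from
missing-limb counts beforehand with a Poisson regression, and the residual
from that regression replaces the raw bud count in every model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, CyclicCubicSplines, GLMGam

PARAMETRIC_TERMS = ("n_missing", "bud_resid", "regen_mass")
SMOOTH_VARS = ("carapace_width_mm", "julian_day")

RESPONSE_COLUMNS = {
    "stomach": "stomach_mass_g",
    "ovary": "ovary_mass_g",
    "hepatopancreas": "hepatopancreas_mass_g",
    "body": "corrected_body_mass_g",
}

#: responses whose bud term is tested for curvature by default
DEFAULT_SQUARED_CANDIDATES = ("stomach", "hepatopancreas")


@dataclass
class BudResidualization:
    """Poisson regression of bud count on missing-limb count, plus residuals.

    The residuals (Pearson type by default; deviance available) carry the bud signal that is not
    explained by current limb loss, breaking the collinearity between the two
    counts.
    """

    intercept: float
    slope: float
    z: float
    pvalue: float
    null_deviance: float
    residual_deviance: float
    residuals: pd.Series = field(repr=False)
    resid_type: str = "pearson"


@dataclass
class SmoothStat:
    variable: str
    edf: float
    statistic: float
    pvalue: float


@dataclass
class TradeoffModelResult:
    """One fitted trade-off model."""

    response: str
    label: str
    terms: pd.DataFrame  # term, estimate, se, t, p
    smooth_stats: list
    deviance_explained: float
    aic: float
    n: int
    rows: pd.Index = field(repr=False)
    alpha: tuple = ()
    results: object = field(default=None, repr=False)

    def term(self, name: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no parametric term {name!r} in model {self.label}")
        return row.iloc[0]


def residualize_buds(
    n_buds: Sequence[int], n_missing: Sequence[int], resid_type: str = "pearson"
) -> BudResidualization:
    """Fit ``buds ~ Poisson(exp(b0 + b1 * missing))`` and return residuals."""
    buds = pd.Series(np.asarray(n_buds, dtype=float))
    missing = np.asarray(n_missing, dtype=float)
    if len(buds) < 30:
        raise ValueError("need at least 30 crabs to residualize bud counts")
    if np.any(buds < 0) or np.any(missing < 0):
        raise ValueError("counts must be non-negative")
    if resid_type not in ("deviance", "pearson"):
        raise ValueError("resid_type must be 'deviance' or 'pearson'")
    if not np.any(buds):
        warnings.warn("all bud counts are zero; residuals set to 0", stacklevel=2)
        return BudResidualization(
            intercept=-np.inf,
            slope=0.0,
            z=np.nan,
            pvalue=np.nan,
            null_deviance=0.0,
            residual_deviance=0.0,
            residuals=pd.Series(np.zeros(len(buds)), index=buds.index),
            resid_type=resid_type,
        )
    exog = sm.add_constant(missing)
    res = sm.GLM(buds.to_numpy(), exog, family=sm.families.Poisson()).fit()
    resid = res.resid_deviance if resid_type == "deviance" else res.resid_pearson
    return BudResidualization(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        z=float(res.tvalues[1]),
        pvalue=float(res.pvalues[1]),
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        residuals=pd.Series(np.asarray(resid), index=buds.index),
        resid_type=resid_type,
    )


def build_model_frame(
    crabs: pd.DataFrame, assessments: pd.DataFrame, budres: BudResidualization
) -> pd.DataFrame:
    """Merge crab covariates, injury predictors and responses into one frame."""
    frame = crabs[
        [
            "crab_id",
            "carapace_width_mm",
            "julian_day",
            "stomach_mass_g",
            "ovary_mass_g",
            "hepatopancreas_mass_g",
        ]
    ].merge(
        assessments[
            [
                "crab_id",
                "n_missing",
                "n_buds",
                "regen_mass_total_g",
                "corrected_body_mass_g",
            ]
        ],
        on="crab_id",
        validate="one_to_one",
    )
    frame = frame.rename(columns={"regen_mass_total_g": "regen_mass"})
    frame["bud_resid"] = budres.residuals.to_numpy()
    return frame


def _make_smoother(frame: pd.DataFrame, df: int, cyclic_julian: bool):
    x = frame[list(SMOOTH_VARS)].to_numpy(float)
    if cyclic_julian:
        return CyclicCubicSplines(x, df=[df, df])
    return BSplines(x, df=[df, df], degree=[3, 3])


def _parametric_matrix(
    frame: pd.DataFrame, include_squared: Iterable[str]
) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)
    for term in PARAMETRIC_TERMS:
        X[term] = frame[term].to_numpy(float)
    for term in include_squared:
        if term not in PARAMETRIC_TERMS:
            raise ValueError(f"cannot square unknown term {term!r}")
        X[term + "_sq"] = frame[term].to_numpy(float) ** 2
    return X


def _check_design(X: pd.DataFrame, n_smooth_params: int) -> None:
    n, k = X.shape
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        # name the columns involved in the dependence
        bad = []
        for col in X.columns:
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    n_params = k + n_smooth_params
    if n < 10 * n_params:
        raise ValueError(
            f"refusing to fit: n={n} < 10 x {n_params} parameters"
        )


def fit_tradeoff_gam(
    frame: pd.DataFrame,
    response: str,
    include_squared: Iterable[str] = (),
    alpha=None,
    spline_df: int = 10,
    cyclic_julian: bool = False,
    label: str | None = None,
) -> TradeoffModelResult:
    """Fit one Gaussian additive trade-off model.

    ``response`` is a key of :data:`RESPONSE_COLUMNS` or a column name of
    ``frame``.  ``include_squared`` adds squared copies of the named
    parametric terms.  ``alpha`` fixes the two smoothing penalties; when
    ``None`` they are selected by the AIC-based criterion of the GAM engine.
    """
    include_squared = tuple(include_squared)
    col = RESPONSE_COLUMNS.get(response, response)
    if col not in frame.columns:
        raise KeyError(f"response column {col!r} not in model frame")
    needed = [col, *PARAMETRIC_TERMS, *SMOOTH_VARS]
    frame = frame.dropna(subset=needed)

    y = frame[col].to_numpy(float)
    X = _parametric_matrix(frame, include_squared)
    smoother = _make_smoother(frame, spline_df, cyclic_julian)
    _check_design(X, smoother.dim_basis)

    if alpha is None:
        gam = GLMGam(y, exog=X, smoother=smoother, alpha=[1.0, 1.0])
        gam.fit()  # select_penweight needs an initial scale estimate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alpha = gam.select_penweight()[0]
    alpha = tuple(float(a) for a in np.atleast_1d(alpha))
    gam = GLMGam(y, exog=X, smoother=smoother, alpha=list(alpha))
    res = gam.fit()

    k_param = X.shape[1]
    terms = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": np.asarray(res.params[:k_param], float),
            "se": np.asarray(res.bse[:k_param], float),
            "t": np.asarray(res.tvalues[:k_param], float),
            "p": np.asarray(res.pvalues[:k_param], float),
        }
    )

    smooth_stats = []
    offset = k_param
    for i, var in enumerate(SMOOTH_VARS):
        dim = smoother.smoothers[i].dim_basis
        edf = float(np.sum(res.edf[offset : offset + dim]))
        offset += dim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                wt = res.test_significance(i)
                stat = float(np.squeeze(wt.statistic))
                pval = float(np.squeeze(wt.pvalue))
            except Exception:  # pragma: no cover - degenerate smooths
                stat, pval = np.nan, np.nan
        smooth_stats.append(SmoothStat(variable=var, edf=edf, statistic=stat, pvalue=pval))

    dev_expl = 1.0 - res.deviance / res.null_deviance
    return TradeoffModelResult(
        response=col,
        label=label or (response + ("+sq" if include_squared else "")),
        terms=terms,
        smooth_stats=smooth_stats,
        deviance_explained=float(dev_expl),
        aic=float(res.aic),
        n=len(frame),
        rows=frame.index,
        alpha=alpha,
        results=res,
    )


def select_model(
    linear: TradeoffModelResult, quadratic: TradeoffModelResult
) -> tuple[TradeoffModelResult, float]:
    """AIC selection between nested linear/quadratic forms.

    Returns ``(selected, delta_aic)`` with
    ``delta_aic = AIC(rejected) - AIC(selected) >= 0``; ties prefer the
    simpler (linear) model.
    """
    if not linear.rows.equals(quadratic.rows):
        raise ValueError("models were fitted on different row sets")
    if quadratic.aic < linear.aic:
        return quadratic, float(linear.aic - quadratic.aic)
    return linear, float(quadratic.aic - linear.aic)


def plotting_residuals(
    frame: pd.DataFrame,
    response: str,
    alpha=None,
    spline_df: int = 10,
    cyclic_julian: bool = False,
) -> pd.Series:
    """Pearson residuals from ``response ~ s(CW) + s(julian)`` only.

    These residuals strip size and season effects for figure-style displays;
    they carry no injury adjustment and are never used for inference.
    """
    col = RESPONSE_COLUMNS.get(response, response)
    frame = frame.dropna(subset=[col, *SMOOTH_VARS])
    y = frame[col].to_numpy(float)
    X = pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)
    smoother = _make_smoother(frame, spline_df, cyclic_julian)
    _check_design(X, smoother.dim_basis)
    if alpha is None:
        gam = GLMGam(y, exog=X, smoother=smoother, alpha=[1.0, 1.0])
        gam.fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alpha = gam.select_penweight()[0]
    res = GLMGam(
        y, exog=X, smoother=smoother, alpha=list(np.atleast_1d(alpha))
    ).fit()
    return pd.Series(np.asarray(res.resid_pearson), index=frame.index)


TERM_TO_TRUTH = {
    "n_missing": "beta_missing",
    "bud_resid": "beta_bud",
    "regen_mass": "beta_regen",
}


def recovery_report(
    results: Mapping[str, TradeoffModelResult],
    truth_coeffs: pd.DataFrame,
    terms: Sequence[str] = ("regen_mass",),
) -> pd.DataFrame:
    """Bias / 2-SE coverage of fitted coefficients against injected truth.

    ``results`` maps organ names (keys of the truth table's ``organ`` column,
    with ``body_rest`` matched to the ``body`` response) to fitted models.
    """
    truth_idx = truth_coeffs.set_index("organ")
    rows = []
    for organ, result in results.items():
        truth_organ = "body_rest" if organ == "body" else organ
        if truth_organ not in truth_idx.index:
            raise ValueError(f"no injected truth for organ {organ!r}")
        for term in terms:
            truth = float(truth_idx.at[truth_organ, TERM_TO_TRUTH[term]])
            est = result.term(term)
            bias = float(est["estimate"]) - truth
            se = float(est["se"])
            rows.append(
                {
                    "organ": organ,
                    "term": term,
                    "truth": truth,
                    "estimate": float(est["estimate"]),
                    "se": se,
                    "bias": bias,
                    "abs_bias_over_se": abs(bias) / se if se > 0 else np.inf,
                    "covered_2se": abs(bias) <= 2 * se,
                    "sign_agrees": np.sign(est["estimate"]) == np.sign(truth)
                    or truth == 0,
                }
            )
    return pd.DataFrame(rows)
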