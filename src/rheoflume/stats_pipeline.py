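"""Statistical workflow for the trial-level rheotaxis metrics.

For each of the four response variables a separate linear model is fitted
with pool type (Above / Between / Below), river, and their interaction as
fixed factors, and mass, generation (F0/F1) and mean trial temperature as
candidate covariates. Covariates are pruned by backward AIC selection in a
fixed order; the factors are never dropped. Skewed responses (cumulative
upstream movement, mean flow regime) are log transformed. Two a priori
planned contrasts compare Above against the downstream pools and Between
against Below. Temporal group-mean profiles are fitted with per-river
penalized spline smooths and an AR(1) residual correction (see
:mod:`rheoflume.smoothing`).

No multiple-testing correction is applied across the four responses; the
report notes this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.stattools import durbin_watson

from .smoothing import FactorSmoothGAM
from .synthetic_data import TrialRecord
from .trajectory_metrics import TrialMetrics

logger = logging.getLogger(__name__)

ALPHA = 0.05
POOL_LEVELS = ("Above", "Between", "Below")

#: response column -> transform used in the study's final models
RESPONSE_TRANSFORMS = {
    "net_displacement_cm": "identity",
    "cumulative_upstream_cm": "log",
    "mean_flow_regime": "log",
    "upstream_orientation": "identity",
}

#: fixed backward-selection drop order for the candidate covariates
COVARIATE_DROP_ORDER = ("mass_g", "generation", "mean_temp_c")

_CATEGORICAL = {"generation", "pool", "river"}


class StatsError(ValueError):
    """Ill-posed model or data for the statistical pipeline."""


def build_trial_table(
    records: Sequence[TrialRecord], metrics: Sequence[TrialMetrics]
) -> pd.DataFrame:
    """Join trial metadata with measured metrics into one modeling table."""
    by_id = {m.trial_id: m for m in metrics}
    missing = [r.trial_id for r in records if r.trial_id not in by_id]
    if missing:
        raise StatsError(f"metrics missing for trials: {missing[:5]}")
    rows = []
    for r in records:
        m = by_id[r.trial_id]
        rows.append(
            dict(
                trial_id=r.trial_id, river=r.river, pool=r.pool,
                generation=r.generation, mass_g=r.mass_g, mean_temp_c=r.mean_temp_c,
                net_displacement_cm=m.net_displacement,
                cumulative_upstream_cm=m.cumulative_upstream,
                mean_flow_regime=m.mean_flow_regime,
                upstream_orientation=m.upstream_orientation,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outlier exclusion
# ---------------------------------------------------------------------------

def exclude_outliers(
    table: pd.DataFrame,
    k: float = 4.0,
    response: str = "net_displacement_cm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively drop trials whose |response| is >= k times the others' mean.

    In each pass the single worst offender (largest ratio of its absolute
    response to the mean absolute response of the remaining trials) is
    removed if the ratio reaches ``k``; passes repeat until no trial
    qualifies. Returns the reduced table and a report of removed trials with
    their ratios. Tables with fewer than 3 rows are returned unchanged with
    a warning.
    """
    table = table.reset_index(drop=True)
    removed: list[dict] = []
    if len(table) < 3:
        logger.warning("table has %d rows; outlier exclusion skipped", len(table))
        return table, pd.DataFrame(columns=["trial_id", "ratio"])
    if math.isinf(k):
        return table, pd.DataFrame(columns=["trial_id", "ratio"])
    work = table.copy()
    while len(work) >= 3:
        y = work[response].abs().to_numpy(dtype=float)
        total = y.sum()
        n = len(y)
        others_mean = (total - y) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(others_mean > 0, y / others_mean, np.where(y > 0, np.inf, 0.0))
        worst = int(np.argmax(ratios))
        if ratios[worst] < k:
            break
        row = work.iloc[worst]
        removed.append(dict(trial_id=row["trial_id"], ratio=float(ratios[worst])))
        logger.warning(
            "excluding outlier %s: |%s| is %.1fx the others' mean",
            row["trial_id"], response, ratios[worst],
        )
        work = work.drop(work.index[worst])
    return work.reset_index(drop=True), pd.DataFrame(removed, columns=["trial_id", "ratio"])


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One response's model: transform, retained covariates, ANOVA flavor.

    The pool and river factors and their interaction are always retained;
    only the covariates are candidates for backward AIC dropping, in the
    fixed order mass, generation, mean temperature.
    """

    response: str
    transform: str = "identity"
    covariates: tuple[str, ...] = COVARIATE_DROP_ORDER
    anova_type: str = "marginal"

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise StatsError(f"unknown transform {self.transform!r}")
        if self.anova_type not in ("marginal", "sequential"):
            raise StatsError(f"anova_type must be marginal or sequential")

    def formula(self) -> str:
        terms = [_term(c) for c in self.covariates]
        terms += ["C(pool)", "C(river)", "C(pool):C(river)"]
        return "_y ~ " + " + ".join(terms)


def _term(col: str) -> str:
    return f"C({col})" if col in _CATEGORICAL else col


def default_model_spec(response: str, anova_type: str = "marginal") -> ModelSpec:
    return ModelSpec(
        response=response,
        transform=RESPONSE_TRANSFORMS.get(response, "identity"),
        anova_type=anova_type,
    )


def _transformed_response(spec: ModelSpec, table: pd.DataFrame) -> pd.Series:
    y = table[spec.response].astype(float)
    if spec.transform == "log":
        bad = table.loc[y <= 0, "trial_id"].tolist()
        if bad:
            raise StatsError(
                f"log transform of {spec.response!r} requires positive values; "
                f"offending trials: {bad}"
            )
        y = np.log(y)
    return y


def _fit_ols(spec: ModelSpec, table: pd.DataFrame):
    data = table.copy()
    data["_y"] = _transformed_response(spec, table)
    model = ols(spec.formula(), data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise StatsError(
            f"rank-deficient design for {spec.response!r}: aliased terms among "
            f"{list(model.exog_names)}"
        )
    return model.fit()


@dataclass
class FitResult:
    """Fitted linear model: coefficients, per-term F table, fit indices."""

    spec: ModelSpec
    params: pd.Series
    anova: pd.DataFrame
    adj_r2: float
    aic: float
    nobs: int
    df_resid: float
    mse_resid: float
    diagnostics: dict
    results: object = field(repr=False)  # statsmodels RegressionResults

    def term_p(self, term: str) -> float:
        return float(self.anova.loc[term, "PR(>F)"])


def fit_lm(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """OLS fit of one response on covariates + pool * river.

    Term F tests follow ``spec.anova_type``: "sequential" is a type-I table
    in model order, "marginal" a type-II table (each term adjusted for all
    others at or below its marginality level, the interaction entered last).
    """
    fit = _fit_ols(spec, table)
    scale = max(float(np.var(fit.model.endog)), 1e-12)
    if not np.isfinite(fit.mse_resid) or fit.mse_resid <= 1e-12 * scale:
        raise StatsError(f"zero residual variance for {spec.response!r}")
    typ = 1 if spec.anova_type == "sequential" else 2
    table_anova = anova_lm(fit, typ=typ)
    resid = np.asarray(fit.resid)
    diagnostics = {
        "resid_sd": float(np.std(resid, ddof=1)),
        "shapiro_p": float(sps.shapiro(resid).pvalue) if len(resid) <= 5000 else np.nan,
        "durbin_watson": float(durbin_watson(resid)),
    }
    return FitResult(
        spec=spec,
        params=fit.params,
        anova=table_anova,
        adj_r2=float(fit.rsquared_adj),
        aic=float(fit.aic),
        nobs=int(fit.nobs),
        df_resid=float(fit.df_resid),
        mse_resid=float(fit.mse_resid),
        diagnostics=diagnostics,
        results=fit,
    )


def select_model_aic(spec: ModelSpec, table: pd.DataFrame) -> ModelSpec:
    """Backward AIC pruning of the candidate covariates in their fixed order.

    Each candidate is tested once, in order; it is dropped iff removing it
    does not increase the AIC of the current model (ties drop, favoring
    parsimony). The factors are never candidates.
    """
    current = spec
    current_aic = _fit_ols(current, table).aic
    for cov in spec.covariates:
        reduced = replace(current, covariates=tuple(c for c in current.covariates if c != cov))
        reduced_aic = _fit_ols(reduced, table).aic
        if reduced_aic <= current_aic:
            logger.info(
                "dropping %s from %s (AIC %.2f -> %.2f)",
                cov, spec.response, current_aic, reduced_aic,
            )
            current, current_aic = reduced, reduced_aic
    return current


# ---------------------------------------------------------------------------
# planned contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """A planned comparison of pool-level means on the model's response scale."""

    label: str
    weights: tuple[float, float, float]  # over (Above, Between, Below)
    estimate: float
    se: float
    t: float
    p: float

    def __post_init__(self) -> None:
        assert abs(sum(self.weights)) < 1e-9


#: contrast 1 reads "Above minus the mean of the downstream pools"
PLANNED_CONTRASTS = (
    ("Above vs downstream", (1.0, -0.5, -0.5)),
    ("Between vs Below", (0.0, 1.0, -1.0)),
)


def planned_contrasts(fit: FitResult, table: pd.DataFrame) -> list[ContrastResult]:
    """The two a priori pool contrasts, using the fit's residual variance.

    Estimates are weighted sums of raw pool-level means of the (transformed)
    response; the standard error is ``sqrt(sigma^2 * sum(w_j^2 / n_j))`` with
    sigma^2 and degrees of freedom taken from the fitted model.
    """
    y = _transformed_response(fit.spec, table)
    pools = table["pool"]
    means, ns = [], []
    for level in POOL_LEVELS:
        sel = pools == level
        if not sel.any():
            raise StatsError(f"pool level {level!r} missing from the table")
        means.append(float(y[sel].mean()))
        ns.append(int(sel.sum()))
    means = np.asarray(means)
    ns = np.asarray(ns, dtype=float)
    out = []
    for label, weights in PLANNED_CONTRASTS:
        w = np.asarray(weights)
        est = float(w @ means)
        se = math.sqrt(fit.mse_resid * float(np.sum(w * w / ns)))
        t = est / se
        p = 2.0 * float(sps.t.sf(abs(t), fit.df_resid))
        out.append(ContrastResult(label, tuple(weights), est, se, t, p))
    return out


# ---------------------------------------------------------------------------
# temporal smooths
# ---------------------------------------------------------------------------

@dataclass
class SmoothFitResult:
    """Per-river temporal smooths with the river factor test.

    ``curves`` maps each river to (frame, fit, lower, upper) arrays of the
    fitted smooth and its pointwise 95% band; ``river_f``/``river_p`` test
    the river offset; ``ar1_rho`` is the fitted residual autocorrelation.
    """

    response: str
    curves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    river_f: float
    river_p: float
    ar1_rho: float
    basis_dim: int
    edf: float
    lambda_: float
    sigma2: float


def fit_temporal_smooth(
    profiles: Sequence,
    response: str = "zone",
    basis_dim: int = 15,
    ar1: bool = True,
    penalty: float | None = None,
) -> SmoothFitResult:
    """Fit per-group penalized smooths over frame index to temporal profiles.

    ``profiles`` are :class:`~rheoflume.trajectory_metrics.TemporalProfile`
    objects sharing one frame grid; ``response`` selects their mean zone
    score ("zone") or mean alignment proportion ("alignment") series. The
    group (river) factor is tested with a Wald F on the group offsets; with
    ``ar1`` the residuals are modeled as AR(1) by iterated prewhitening.
    """
    if response not in ("zone", "alignment"):
        raise StatsError("response must be 'zone' or 'alignment'")
    if len(profiles) < 1:
        raise StatsError("no profiles given")
    series = [
        p.mean_zone if response == "zone" else p.mean_alignment for p in profiles
    ]
    n = len(series[0])
    if any(len(s) != n for s in series):
        raise StatsError("profiles do not share one frame grid")
    t = np.concatenate([np.arange(n, dtype=float)] * len(profiles))
    y = np.concatenate([np.asarray(s, dtype=float) for s in series])
    codes = np.concatenate(
        [np.full(n, p.group, dtype=object) for p in profiles]
    )
    gam = FactorSmoothGAM(basis_dim=basis_dim, ar1=ar1, penalty=penalty)
    gam.fit(t, y, codes)
    curves = {}
    for p in profiles:
        frames, fitted, lo, hi = gam.curve(p.group)
        curves[p.group] = (frames, fitted, lo, hi)
    return SmoothFitResult(
        response=response,
        curves=curves,
        river_f=float(gam.group_f_),
        river_p=float(gam.group_p_),
        ar1_rho=float(gam.rho_),
        basis_dim=basis_dim,
        edf=float(gam.edf_),
        lambda_=float(gam.lambda_),
        sigma2=float(gam.sigma2_),
    )
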