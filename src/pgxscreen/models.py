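"""Regression model comparison: binary logistic and proportional-odds fits,
AIC ranking, ROC curves and best-cutoff operating points.

The model battery mirrors the study's ten candidate predictors of
chemotherapy response: the empty model, each SNP genotype (additive 0/1/2
coding), the clinical covariates (creatinine grade, prior chemotherapy), and
their combinations.  By default the AIC comparison uses the four-level
ordered RECIST outcome under a proportional-odds fit, while ROC operating
characteristics are computed from the fitted scores against the binary
responder grouping (CR+PR vs NC+PD) — each model therefore gets both an
ordinal likelihood and a binary discrimination summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .core_data import RECIST_LEVELS

__all__ = [
    "ModelSpec",
    "FittedModel",
    "RocCurve",
    "ten_model_preset",
    "fit_binary_logistic",
    "fit_proportional_odds",
    "roc_curve",
    "best_cutoff",
    "compare_models",
]


@dataclass
class ModelSpec:
    """Named covariate list; the NULL model has no terms."""

    name: str
    terms: list[str] = field(default_factory=list)


def ten_model_preset(snp_a: str, snp_b: str) -> list[ModelSpec]:
    """The ten-model battery over two SNPs and two clinical covariates.

    ``snp_a`` is the newly screened SNP, ``snp_b`` the previously known one;
    Cr = creatinine grade, Chem = prior chemotherapy.
    """
    return [
        ModelSpec("NULL", []),
        ModelSpec(snp_b, [snp_b]),
        ModelSpec("Cr", ["cr_grade"]),
        ModelSpec("Chem", ["chem_history"]),
        ModelSpec("Cr+Chem", ["cr_grade", "chem_history"]),
        ModelSpec(snp_a, [snp_a]),
        ModelSpec(f"{snp_a}+{snp_b}", [snp_a, snp_b]),
        ModelSpec(f"{snp_a}+{snp_b}+Cr", [snp_a, snp_b, "cr_grade"]),
        ModelSpec(f"{snp_a}+{snp_b}+Chem", [snp_a, snp_b, "chem_history"]),
        ModelSpec(f"{snp_a}+{snp_b}+Cr+Chem", [snp_a, snp_b, "cr_grade", "chem_history"]),
    ]


@dataclass
class FittedModel:
    spec: ModelSpec
    kind: str  # "binary" or "ordinal"
    coefficients: pd.Series
    log_likelihood: float
    k_params: int
    scores: pd.Series  # higher = more likely responder
    separation: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.log_likelihood


_CONV_TOL = 1e-10
_MAX_ITER = 100


def _design(data: pd.DataFrame, terms: list[str]) -> np.ndarray:
    X = data[terms].to_numpy(dtype=float) if terms else np.empty((len(data), 0))
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; drop incomplete cases first")
    return X


def fit_binary_logistic(data: pd.DataFrame, spec: ModelSpec, response: str = "response") -> FittedModel:
    """Maximum-likelihood logistic fit of the binary responder outcome.

    Complete separation is detected (fitted probabilities saturate at the
    observed labels) and flagged rather than raised; the reported likelihood
    is the value at the stopped iterate.
    """
    y = data[response].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("binary response is constant; logistic fit undefined")
    X = sm.add_constant(_design(data, spec.terms), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=_MAX_ITER, tol=_CONV_TOL)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=_MAX_ITER)
    fitted = np.asarray(res.predict(X), dtype=float)
    # complete separation: scores perfectly split the classes and the
    # likelihood climbs to its supremum (0), with coefficients at the bound
    separation = bool(
        spec.terms
        and fitted[y == 1].min() > fitted[y == 0].max()
        and res.llf > -1e-3
    )
    names = ["intercept"] + list(spec.terms)
    return FittedModel(
        spec,
        "binary",
        pd.Series(np.asarray(res.params, dtype=float), index=names),
        float(res.llf),
        X.shape[1],
        pd.Series(fitted, index=data.index),
        separation,
    )


def fit_proportional_odds(
    data: pd.DataFrame, spec: ModelSpec, outcome: str = "recist"
) -> FittedModel:
    """Proportional-odds (cumulative-logit) fit of the ordered RECIST outcome.

    k = number of slopes + (levels - 1) thresholds.  When only two outcome
    levels are observed the model degenerates to a binary logistic fit on
    the merged grouping.  Scores are P(response <= PR | x), the predicted
    responder probability, so ROC analysis can use them directly.
    """
    y = data[outcome]
    if not isinstance(y.dtype, pd.CategoricalDtype):
        y = pd.Categorical(y, categories=RECIST_LEVELS, ordered=True)
        y = pd.Series(y, index=data.index)
    observed = [lv for lv in y.cat.categories if (y == lv).any()]
    if len(observed) < 2:
        raise ValueError("ordinal outcome has fewer than 2 observed levels")
    if len(observed) == 2:
        merged = data.copy()
        merged["response"] = (y == observed[0]).astype(int)
        fit = fit_binary_logistic(merged, spec)
        return FittedModel(
            spec, "ordinal", fit.coefficients, fit.log_likelihood, fit.k_params,
            fit.scores, fit.separation,
        )
    y = pd.Series(pd.Categorical(y, categories=observed, ordered=True), index=data.index)
    X = _design(data, spec.terms)
    n_thresh = len(observed) - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.terms:
            model = OrderedModel(y, X, distr="logit")
            res = model.fit(method="bfgs", disp=0, maxiter=200, gtol=1e-8)
            params = np.asarray(res.params, dtype=float)
            slopes = params[: len(spec.terms)]
            llf = float(res.llf)
            xb = X @ slopes
        else:
            # intercept-only: closed-form MLE = observed category frequencies
            counts = y.value_counts().reindex(observed).to_numpy(dtype=float)
            probs = counts / counts.sum()
            llf = float((counts * np.log(probs)).sum())
            slopes = np.array([])
            xb = np.zeros(len(data))
            params = np.concatenate([np.array([]), np.log(np.cumsum(probs)[:-1] / (1 - np.cumsum(probs)[:-1]))])
    k = len(spec.terms) + n_thresh
    # responder score: monotone decreasing in the latent predictor
    n_resp_levels = sum(1 for lv in observed if lv in ("CR", "PR"))
    if spec.terms:
        thresholds = _ordered_thresholds(params, len(spec.terms), n_thresh)
        cut = thresholds[n_resp_levels - 1] if 0 < n_resp_levels <= n_thresh else thresholds[0]
        score = 1.0 / (1.0 + np.exp(-(cut - xb)))
    else:
        score = np.full(len(data), 0.5)
    names = list(spec.terms) + [f"threshold_{i + 1}" for i in range(n_thresh)]
    coef = pd.Series(
        np.concatenate([slopes, _ordered_thresholds(params, len(slopes), n_thresh)]),
        index=names,
    )
    return FittedModel(
        spec, "ordinal", coef, llf, k, pd.Series(score, index=data.index)
    )


def _ordered_thresholds(params: np.ndarray, n_slopes: int, n_thresh: int) -> np.ndarray:
    """statsmodels stores thresholds as (first, log-increments); undo that."""
    raw = np.asarray(params[n_slopes: n_slopes + n_thresh], dtype=float)
    if len(raw) == 0:
        return raw
    out = raw.copy()
    out[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    return out


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float


def roc_curve(scores, binary_response) -> RocCurve:
    """ROC over all distinct score thresholds; AUC by trapezoid (equals the
    tie-corrected Mann-Whitney statistic)."""
    y = np.asarray(binary_response, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    cut, sens, spec = _best_operating_point(fpr, tpr, thr)
    return RocCurve(fpr, tpr, thr, auc, cut, sens, spec)


def _best_operating_point(fpr, tpr, thr) -> tuple[float, float, float]:
    # maximize Youden's J; ties -> maximum specificity, then maximum cutoff
    # (keys rounded so float noise cannot break exact ties like 2/3 vs 1 - 1/3)
    j = np.round(tpr - fpr, 9)
    order = np.lexsort((thr, np.round(-fpr, 9), j))  # j asc, spec asc within, thr asc
    best = order[-1]
    finite_thr = thr[best] if np.isfinite(thr[best]) else float(np.max(thr[np.isfinite(thr)]))
    return float(finite_thr), float(100 * tpr[best]), float(100 * (1 - fpr[best]))


def best_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """(cutoff, sensitivity %, specificity %) maximizing Youden's J."""
    return _best_operating_point(roc.fpr, roc.tpr, roc.thresholds)


def compare_models(
    specs: list[ModelSpec],
    data: pd.DataFrame,
    outcome: str = "ordinal",
) -> pd.DataFrame:
    """Fit every spec and tabulate AIC, AUC and best-cutoff operating point.

    ``outcome="ordinal"`` fits the 4-level proportional-odds model for the
    AIC comparison (scores against the binary grouping for ROC);
    ``outcome="binary"`` uses plain logistic fits throughout.  Rows are
    ranked by AIC.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model spec names")
    rows = []
    for spec in specs:
        fit = (
            fit_proportional_odds(data, spec)
            if outcome == "ordinal"
            else fit_binary_logistic(data, spec)
        )
        y = data["response"].to_numpy(dtype=int)
        if spec.terms:
            roc = roc_curve(fit.scores.to_numpy(), y)
            auc, sens, spec_pct, cut = roc.auc, roc.sensitivity_pct, roc.specificity_pct, roc.cutoff
        else:
            auc, sens, spec_pct, cut = 0.5, np.nan, np.nan, np.nan
        rows.append(
            {
                "model": spec.name,
                "n_terms": len(spec.terms),
                "log_likelihood": fit.log_likelihood,
                "aic": fit.aic,
                "auc": auc,
                "cutoff": cut,
                "sensitivity_pct": sens,
                "specificity_pct": spec_pct,
                "separation": fit.separation,
            }
        )
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["aic_rank"] = np.arange(1, len(out) + 1)
    return out
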