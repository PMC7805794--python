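"""Regression framework for DNAm-age analyses.

DNAm age is regressed on chronological age (optionally with an age-squared
term, which captures the plateau of clock accuracy in old age) and on
biological/technical covariates (sex, post-mortem interval, batch, neuronal
proportion), with a per-donor random intercept whenever donors contribute
multiple samples (several cortical regions from one brain are not
independent) and ordinary least squares otherwise.

Mixed models are fitted by restricted maximum likelihood
(``statsmodels.MixedLM``); fixed-effect p-values are Wald tests on the
normal approximation, which at the cohort sizes these analyses run at is
interchangeable with the Satterthwaite t-tests of the lme4/lmerTest stack.
The reported R² for mixed fits is the marginal (fixed-effects) R²:
var(Xb) / (var(Xb) + var(random intercept) + var(residual)).

Significance is flagged at the multiple-testing threshold p < 0.005 —
a labelled flag in the report, never silent filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = ["FitReport", "fit_age_association", "fit_covariate_association",
           "SIGNIFICANCE_THRESHOLD"]

SIGNIFICANCE_THRESHOLD = 0.005


@dataclass
class FitReport:
    """Per-term estimates from an (optionally mixed) linear model."""

    terms: pd.DataFrame  # term, coef, se, p, significant
    marginal_r2: float
    model_kind: str  # "ols" | "random_intercept"
    n_samples: int
    n_donors: int
    converged: bool = True
    singular: bool = False

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "coef"])

    def p(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    def se(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "se"])


def _check_lengths(**arrays) -> int:
    ns = {k: len(v) for k, v in arrays.items() if v is not None}
    if len(set(ns.values())) > 1:
        raise ValueError(f"length mismatch: {ns}")
    return next(iter(ns.values()))


def _terms_frame(names, coefs, ses, ps) -> pd.DataFrame:
    ps = np.clip(np.asarray(ps, dtype=float), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "term": list(names),
        "coef": np.asarray(coefs, dtype=float),
        "se": np.asarray(ses, dtype=float),
        "p": ps,
        "significant": ps < SIGNIFICANCE_THRESHOLD,
    })


def _fit(y: np.ndarray, X: pd.DataFrame, donors: np.ndarray | None) -> FitReport:
    """Dispatch to OLS or a REML random-intercept fit on donor."""
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    singular = rank < Xd.shape[1]
    if singular:
        warnings.warn("design matrix is singular (collinear covariates)", stacklevel=3)

    use_mixed = donors is not None and pd.Series(donors).duplicated().any()
    if use_mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, Xd, groups=donors)
            res = model.fit(reml=True)
        fe = res.fe_params
        names = list(Xd.columns)
        report = _terms_frame(names, fe, res.bse_fe, res.pvalues[:len(names)])
        var_u = float(res.cov_re.iloc[0, 0])
        var_e = float(res.scale)
        fitted_fixed = Xd.to_numpy() @ np.asarray(fe)
        var_f = float(np.var(fitted_fixed))
        r2 = var_f / (var_f + var_u + var_e) if (var_f + var_u + var_e) > 0 else np.nan
        return FitReport(terms=report, marginal_r2=r2, model_kind="random_intercept",
                         n_samples=len(y), n_donors=len(pd.unique(donors)),
                         converged=bool(res.converged), singular=singular)

    res = sm.OLS(y, Xd).fit()
    report = _terms_frame(list(Xd.columns), res.params, res.bse, res.pvalues)
    n_donors = len(pd.unique(donors)) if donors is not None else len(y)
    return FitReport(terms=report, marginal_r2=float(res.rsquared), model_kind="ols",
                     n_samples=len(y), n_donors=n_donors, singular=singular)


def fit_age_association(
    pred,
    chron,
    donor_ids=None,
    quadratic: bool = False,
    center_age: bool = False,
) -> FitReport:
    """Regress DNAm age on chronological age (and optionally age²).

    A random intercept per donor is used when any donor has more than one
    sample, otherwise OLS.  ``center_age`` subtracts the mean age before
    squaring (changes the linear term's interpretation, not the quadratic
    term's test).
    """
    pred = np.asarray(pred, dtype=float)
    chron = np.asarray(chron, dtype=float)
    n = _check_lengths(pred=pred, chron=chron, donor_ids=donor_ids)
    if n < 10:
        raise ValueError("need >= 10 samples")
    if np.ptp(chron) == 0:
        raise ValueError("chronological age is constant")
    age = chron - chron.mean() if center_age else chron
    X = pd.DataFrame({"age": age})
    if quadratic:
        X["age_sq"] = age ** 2
    donors = np.asarray(donor_ids) if donor_ids is not None else None
    return _fit(pred, X, donors)


def fit_covariate_association(
    pred,
    covariate,
    chron,
    neuronal_proportion=None,
    donor_ids=None,
    extra_fixed: pd.DataFrame | dict | None = None,
    covariate_name: str = "covariate",
    covariate_is_neuronal: bool = False,
) -> FitReport:
    """Association of DNAm age with one covariate, adjusted for ageing.

    The adjustment set is age, age² and (unless the covariate *is* the
    neuronal proportion) the neuronal proportion, plus any ``extra_fixed``
    columns (e.g. brain bank for post-mortem-interval models; non-numeric
    columns are dummy-coded).  Categorical covariates are dummy-coded the
    same way.  Random intercept per donor as in :func:`fit_age_association`.
    """
    pred = np.asarray(pred, dtype=float)
    chron = np.asarray(chron, dtype=float)
    cov = pd.Series(covariate).reset_index(drop=True)
    _check_lengths(pred=pred, chron=chron, covariate=cov, donor_ids=donor_ids)

    if cov.nunique(dropna=True) < 2:
        raise ValueError(f"covariate {covariate_name!r} has zero variance")

    X = pd.DataFrame(index=range(len(pred)))
    if pd.api.types.is_numeric_dtype(cov):
        X[covariate_name] = cov.astype(float)
    else:
        dummies = pd.get_dummies(cov, prefix=covariate_name, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    X["age"] = chron
    X["age_sq"] = chron ** 2
    if neuronal_proportion is not None and not covariate_is_neuronal:
        X["neuronal_proportion"] = np.asarray(neuronal_proportion, dtype=float)
    if extra_fixed is not None:
        extra = pd.DataFrame(extra_fixed).reset_index(drop=True)
        for col in extra.columns:
            if pd.api.types.is_numeric_dtype(extra[col]):
                X[col] = extra[col].astype(float)
            else:
                X = pd.concat(
                    [X, pd.get_dummies(extra[col], prefix=col, drop_first=True, dtype=float)],
                    axis=1)

    donors = np.asarray(donor_ids) if donor_ids is not None else None
    return _fit(pred, X, donors)
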