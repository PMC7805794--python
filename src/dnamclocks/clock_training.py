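"""Train a CpG clock: elastic-net regression of transformed age on betas.

The objective is the usual elastic net on raw beta values (betas share the
[0, 1] scale, so predictors are not standardized):

    (1/2n) * sum_i (F(age_i) - b0 - x_i'b)^2
        + lambda * [ alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ]

with an unpenalized intercept b0.  The shrinkage parameter lambda is chosen
by K-fold cross-validation over a log-spaced grid descending from lambda_max
(the smallest lambda with an all-zero solution).  Folds group samples by
donor by default, since donors contributing several cortical regions would
otherwise leak between training and validation halves.

The solver is scikit-learn's coordinate descent, whose objective is exactly
the one above (their ``alpha`` = lambda, ``l1_ratio`` = alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path

from .age_transform import TransformSpec, inverse_transform_age, transform_age
from .core_io import BetaMatrix, ClockDefinition, SampleSheet

__all__ = [
    "TrainingConfig",
    "CVCurve",
    "TrainingDiagnostics",
    "filter_training_probes",
    "fit_elastic_net_clock",
    "cross_validate_lambda",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Elastic-net training settings.

    alpha is the L1/L2 mixing parameter (0.5 = equal parts lasso and
    ridge); lambda is searched on ``lambda_grid`` ("auto" builds 100
    log-spaced values from lambda_max down to lambda_max * 1e-4) and picked
    by ``lambda_rule``: ``cv_min`` (minimum mean CV error) or ``one_se``
    (sparsest model within one standard error of the minimum).
    """

    alpha: float = 0.5
    n_folds: int = 10
    lambda_grid: Sequence[float] | str = "auto"
    lambda_rule: str = "cv_min"
    fold_grouping: str = "by_donor"
    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_rule not in ("cv_min", "one_se"):
            raise ValueError("lambda_rule must be 'cv_min' or 'one_se'")
        if self.fold_grouping not in ("by_donor", "by_sample"):
            raise ValueError("fold_grouping must be 'by_donor' or 'by_sample'")
        if not isinstance(self.lambda_grid, str):
            grid = np.asarray(self.lambda_grid, dtype=float)
            if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
                raise ValueError("lambda_grid must be strictly positive and decreasing")


@dataclass
class CVCurve:
    """Cross-validation profile: per-lambda mean and SE of held-out MSE."""

    lambdas: np.ndarray
    mean_mse: np.ndarray
    se_mse: np.ndarray
    n_folds: int

    def select(self, rule: str) -> float:
        i_min = int(np.argmin(self.mean_mse))
        if rule == "cv_min":
            return float(self.lambdas[i_min])
        if rule == "one_se":
            cutoff = self.mean_mse[i_min] + self.se_mse[i_min]
            ok = np.flatnonzero(self.mean_mse <= cutoff)
            return float(self.lambdas[ok[0]])  # grid descends: first = largest lambda
        raise ValueError(f"unknown rule {rule!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas, "mean_mse": self.mean_mse,
                             "se_mse": self.se_mse})


@dataclass
class TrainingDiagnostics:
    lambda_selected: float
    cv_curve: CVCurve
    n_nonzero: int
    n_samples: int
    n_sites_considered: int
    alpha: float
    lambda_rule: str
    training_rmse_years: float


def filter_training_probes(betas: BetaMatrix, annotation: pd.DataFrame) -> BetaMatrix:
    """Restrict to probes usable for training across array platforms.

    Keeps probes flagged present on both the 450K and EPIC arrays
    (annotation columns ``on_450k`` and ``on_epic``) that have no missing
    values in any training sample.  Raises if nothing survives.
    """
    for col in ("on_450k", "on_epic"):
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks column {col!r}")
    ann = annotation.reindex(betas.site_ids)
    both = (ann["on_450k"].fillna(False) & ann["on_epic"].fillna(False)).to_numpy(dtype=bool)
    if not both.any():
        raise ValueError("no probes present on both platforms")
    complete = ~betas.data.isna().any(axis=1).to_numpy()
    keep = [s for s, ok in zip(betas.site_ids, both & complete) if ok]
    if not keep:
        raise ValueError("no complete both-platform probes remain")
    return BetaMatrix(betas.data.loc[keep])


def _design(betas: BetaMatrix, samples: SampleSheet,
            transform: TransformSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    ids = betas.sample_ids
    ages = samples.ages_for(ids)
    if ages.isna().any():
        missing = ages.index[ages.isna()].tolist()
        raise ValueError(f"samples without age in sheet: {missing[:5]}")
    if betas.data.isna().any().any():
        raise ValueError("training betas must have no missing values "
                         "(run filter_training_probes first)")
    X = betas.data.to_numpy(dtype=float).T  # samples x sites
    y = transform_age(ages.to_numpy(dtype=float), transform)
    donors = samples.data.set_index("sample_id").loc[ids, "donor_id"].to_numpy()
    if np.ptp(y) == 0:
        raise ValueError("age vector is constant; nothing to regress on")
    return X, y, donors, ids


def _lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    # glmnet convention: guard the pure-ridge limit with a small alpha floor
    a = max(alpha, 1e-3)
    return float(np.max(np.abs(Xc.T @ yc)) / (len(y) * a))


def _make_grid(X, y, cfg: TrainingConfig) -> np.ndarray:
    if isinstance(cfg.lambda_grid, str):
        if cfg.lambda_grid != "auto":
            raise ValueError("lambda_grid must be 'auto' or an explicit grid")
        lmax = _lambda_max(X, y, cfg.alpha)
        return np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.n_lambda)
    return np.asarray(cfg.lambda_grid, dtype=float)


def _folds(donors: np.ndarray, cfg: TrainingConfig) -> list[np.ndarray]:
    """Validation-index list; by_donor keeps each donor within one fold."""
    rng = np.random.default_rng(cfg.seed)
    n = len(donors)
    if cfg.fold_grouping == "by_donor":
        units = pd.unique(donors)
        if len(units) < cfg.n_folds:
            raise ValueError("fewer donors than folds")
        order = rng.permutation(len(units))
        assign = {u: k % cfg.n_folds for k, u in enumerate(units[order])}
        fold_of = np.array([assign[d] for d in donors])
    else:
        if n < 2 * cfg.n_folds:
            raise ValueError("need at least 2 samples per fold")
        fold_of = rng.permutation(n) % cfg.n_folds
    return [np.flatnonzero(fold_of == k) for k in range(cfg.n_folds)]


def cross_validate_lambda(betas: BetaMatrix, samples: SampleSheet,
                          cfg: TrainingConfig,
                          transform: TransformSpec = TransformSpec()) -> CVCurve:
    """Held-out MSE (transformed-age scale) at every grid lambda.

    Deterministic given ``cfg.seed``; each fold fits the whole descending
    lambda path (warm-started coordinate descent), so the curve is computed
    at every grid point.
    """
    X, y, donors, _ = _design(betas, samples, transform)
    grid = _make_grid(X, y, cfg)
    folds = _folds(donors, cfg)
    fold_mse = np.empty((len(folds), len(grid)))
    for k, val_idx in enumerate(folds):
        tr = np.setdiff1d(np.arange(len(y)), val_idx)
        if len(val_idx) < 1 or len(tr) < 2:
            raise ValueError(f"fold {k} has too few samples")
        Xtr, ytr = X[tr], y[tr]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        # centering makes the intercept unpenalized, matching the objective
        _, coefs, _ = enet_path(Xtr - xm, ytr - ym, l1_ratio=cfg.alpha,
                                alphas=grid)
        pred = (X[val_idx] - xm) @ coefs + ym  # n_val x n_lambda
        fold_mse[k] = ((pred - y[val_idx, None]) ** 2).mean(axis=0)
    return CVCurve(
        lambdas=grid,
        mean_mse=fold_mse.mean(axis=0),
        se_mse=fold_mse.std(axis=0, ddof=1) / np.sqrt(len(folds)),
        n_folds=len(folds),
    )


def fit_elastic_net_clock(
    betas: BetaMatrix,
    samples: SampleSheet,
    cfg: TrainingConfig = TrainingConfig(),
    transform: TransformSpec = TransformSpec(),
    name: str = "trained_clock",
) -> tuple[ClockDefinition, TrainingDiagnostics]:
    """Fit the penalized clock and pick lambda by cross-validation.

    Returns the sparse clock (sites with nonzero coefficients; reference
    means are training-set site means) and diagnostics including the CV
    curve and the selected lambda.  At full shrinkage the clock is
    intercept-only with intercept = mean transformed age.
    """
    X, y, donors, ids = _design(betas, samples, transform)
    curve = cross_validate_lambda(betas, samples, cfg, transform)
    lam = curve.select(cfg.lambda_rule)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-zero lambda trips convergence chatter
        model = ElasticNet(alpha=lam, l1_ratio=cfg.alpha, fit_intercept=True,
                           max_iter=50_000, tol=1e-8)
        model.fit(X, y)

    coefs = model.coef_
    nz = np.flatnonzero(coefs)
    site_ids = np.array(betas.site_ids)
    sites = {site_ids[j]: float(coefs[j]) for j in nz}
    means = betas.data.mean(axis=1)
    ref = {site_ids[j]: float(np.clip(means.iloc[j], 0.0, 1.0)) for j in nz} or None

    clock = ClockDefinition(
        name=name,
        intercept=float(model.intercept_),
        sites=sites,
        reference_means=ref,
        transform=transform.kind,
        adult_age=transform.adult_age,
    )
    pred_years = inverse_transform_age(model.predict(X), transform)
    true_years = samples.ages_for(ids).to_numpy(dtype=float)
    diag = TrainingDiagnostics(
        lambda_selected=lam,
        cv_curve=curve,
        n_nonzero=len(nz),
        n_samples=len(y),
        n_sites_considered=X.shape[1],
        alpha=cfg.alpha,
        lambda_rule=cfg.lambda_rule,
        training_rmse_years=float(np.sqrt(np.mean((pred_years - true_years) ** 2))),
    )
    return clock, diag
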