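"""Elastic-net methylation clocks.

A clock is a sparse linear model predicting chronological age (years,
untransformed) from CpG beta values, fitted by penalized regression with
mixing parameter alpha = 0.5 and the penalty weight lambda chosen by
tenfold cross-validation over a log-spaced path.  Unbiased accuracy is
obtained by leave-one-out (LOO) estimation: for each sample a clock is
trained from scratch on the remaining n-1 samples — including its own
internal lambda search — and applied to the held-out sample.

The module follows the model/results idiom: :class:`EpigeneticClock` holds
the training data and hyperparameters, ``fit()`` returns a
:class:`ClockResults` carrying the fitted :class:`~epiclock.data.ClockModel`
plus diagnostics, and ``loo()`` returns leave-one-out predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .data import BetaMatrix, ClockModel, SampleTable

logger = logging.getLogger(__name__)

_LAMBDA_CONSTANT = np.inf  # recorded when the fit degenerates to a constant


@dataclass
class AgePredictions:
    """Predicted DNA-methylation age per sample, in years."""

    predictions: pd.Series          # index: sample_id, values: years
    protocol: str                   # {"refit", "loo"}

    def to_file(self, path) -> None:
        out = self.predictions.rename("dnam_age_years")
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.predictions[sample_id])


def _age_stratified_folds(ages: np.ndarray, n_folds: int, seed) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded fold assignment stratified by age quantile.

    Samples are ordered by age (seeded jitter breaks ties) and consecutive
    blocks of ``n_folds`` receive a random permutation of the fold labels,
    so every fold spans the age range.  This is the only randomness in
    training.
    """
    rng = np.random.default_rng(seed)
    n = len(ages)
    order = np.lexsort((rng.random(n), ages))
    labels = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start:start + n_folds]
        labels[block] = rng.permutation(n_folds)[: len(block)]
    idx = np.arange(n)
    return [(idx[labels != k], idx[labels == k]) for k in range(n_folds)]


def train_clock(
    beta: BetaMatrix,
    ages: pd.Series,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    lambda_: float | None = None,
    lambda_rule: str = "min",
    n_lambdas: int = 50,
    sex_scope: str = "all",
) -> ClockModel:
    """Fit an elastic-net clock; lambda chosen by cross-validation.

    Covariates are standardized internally; the returned weights are on the
    original beta scale.  ``lambda_`` forces a fixed penalty and skips the
    CV search; ``lambda_rule`` selects either the CV-error minimizer
    (``"min"``, the default) or the one-standard-error rule (``"1se"``).
    """
    ages = ages.loc[beta.sample_ids].astype(float)
    if ages.isna().any():
        raise ValueError("missing ages in training set")
    X = beta.values.to_numpy()
    if np.isnan(X).any():
        raise ValueError(
            "missing beta values in training set; impute or drop before training"
        )
    y = ages.to_numpy()
    n = len(y)
    if lambda_ is None and n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if float(np.std(y)) == 0.0:
        # degenerate training set: all ages equal; the constant predictor is
        # the exact penalized solution for any positive lambda
        return ClockModel(
            intercept=float(y[0]), weights={}, alpha=alpha, lambda_=_LAMBDA_CONSTANT,
            sex_scope=sex_scope, training_sample_ids=list(beta.sample_ids), seed=seed,
        )
    safe_sds = np.where(sds > 0, sds, 1.0)
    Xs = (X - means) / safe_sds

    if lambda_ is not None:
        est = ElasticNet(alpha=lambda_, l1_ratio=alpha, max_iter=50_000, tol=1e-6)
        est.fit(Xs, y)
        chosen = float(lambda_)
    else:
        folds = _age_stratified_folds(y, n_folds, seed)
        cv_est = ElasticNetCV(
            l1_ratio=alpha, alphas=n_lambdas, eps=1e-3, cv=folds,
            max_iter=20_000, tol=1e-3,
        )
        cv_est.fit(Xs, y)
        if lambda_rule == "min":
            est, chosen = cv_est, float(cv_est.alpha_)
        elif lambda_rule == "1se":
            mse = cv_est.mse_path_          # (n_lambdas, n_folds)
            mean = mse.mean(axis=1)
            se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
            best = int(np.argmin(mean))
            ok = np.flatnonzero(mean <= mean[best] + se[best])
            # alphas_ are descending; the smallest index is the strongest penalty
            pick = int(ok.min())
            chosen = float(cv_est.alphas_[pick])
            est = ElasticNet(alpha=chosen, l1_ratio=alpha, max_iter=50_000, tol=1e-6)
            est.fit(Xs, y)
        else:
            raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    w_std = np.asarray(est.coef_, dtype=float)
    w = w_std / safe_sds
    nz = np.flatnonzero(w)
    cpg_ids = np.asarray(beta.cpg_ids)
    weights = {str(cpg_ids[j]): float(w[j]) for j in nz}
    intercept = float(est.intercept_ - np.dot(w_std, means / safe_sds))
    tmeans = {str(cpg_ids[j]): float(means[j]) for j in nz}
    return ClockModel(
        intercept=intercept, weights=weights, alpha=alpha, lambda_=chosen,
        sex_scope=sex_scope, training_sample_ids=list(beta.sample_ids), seed=seed,
        training_means=tmeans,
    )


def predict_age(model: ClockModel, beta: BetaMatrix, missing: str = "error") -> AgePredictions:
    """Apply a clock: y_i = intercept + sum_j w_j * m_ij.

    Weighted CpGs absent from the matrix (or NaN in a sample) raise by
    default; ``missing="impute"`` substitutes the clock's stored training
    means and logs how many values were imputed.
    """
    cpgs = sorted(model.weights)
    absent = [c for c in cpgs if c not in beta.values.columns]
    frame = beta.values.reindex(columns=cpgs)
    n_missing = int(frame.isna().to_numpy().sum()) if cpgs else 0
    if (absent or n_missing) and missing == "error":
        raise ValueError(
            f"clock references missing data: {len(absent)} absent CpG(s) "
            f"{absent[:5]}{'...' if len(absent) > 5 else ''}, "
            f"{n_missing} missing value(s); use missing='impute' to fill with "
            "training means"
        )
    if n_missing:
        unknowable = [c for c in absent if c not in model.training_means]
        if unknowable:
            raise ValueError(
                f"cannot impute CpG(s) without stored training means: {unknowable[:5]}"
            )
        fill = pd.Series({c: model.training_means.get(c, np.nan) for c in cpgs})
        frame = frame.fillna(fill)
        logger.warning("imputed %d missing beta value(s) with training means", n_missing)
    w = np.array([model.weights[c] for c in cpgs])
    yhat = model.intercept + (frame.to_numpy() @ w if cpgs else 0.0)
    preds = pd.Series(np.broadcast_to(yhat, (beta.shape[0],)).copy(),
                      index=pd.Index(beta.sample_ids, name="sample_id"))
    return AgePredictions(predictions=preds, protocol="refit")


def loo_predict(
    beta: BetaMatrix,
    ages: pd.Series,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    **train_kwargs,
) -> AgePredictions:
    """Leave-one-out DNAm age: each sample predicted by a clock trained
    without it (the held-out sample influences nothing in its own
    prediction, including the lambda search)."""
    ids = beta.sample_ids
    if len(ids) < n_folds + 1:
        raise ValueError(f"LOO needs at least n_folds+1={n_folds + 1} samples")
    out = {}
    for sid in ids:
        rest = [s for s in ids if s != sid]
        model = train_clock(beta.subset_samples(rest), ages.loc[rest],
                            alpha=alpha, n_folds=n_folds, seed=seed, **train_kwargs)
        out[sid] = predict_age(model, beta.subset_samples([sid]))[sid]
    preds = pd.Series(out, name="dnam_age_years").loc[ids]
    preds.index.name = "sample_id"
    return AgePredictions(predictions=preds, protocol="loo")


def train_sex_specific(
    beta: BetaMatrix,
    samples: SampleTable,
    scope: str,
    **train_kwargs,
) -> ClockModel:
    """Train a clock on one sex only (a "female clock" or "male clock");
    cross-application to the other sex goes through ``predict_age``
    unchanged."""
    if scope not in ("female", "male"):
        raise ValueError(f"scope must be 'female' or 'male', got {scope!r}")
    ids = [s for s in beta.sample_ids if samples.frame.loc[s, "sex"] == scope]
    n_folds = train_kwargs.get("n_folds", 10)
    if len(ids) < n_folds:
        raise ValueError(
            f"only {len(ids)} {scope} samples; need at least n_folds={n_folds}"
        )
    sub = beta.subset_samples(ids)
    return train_clock(sub, samples.ages(ids), sex_scope=scope, **train_kwargs)


# ---------------------------------------------------------------------------
# model/results front-end


class EpigeneticClock:
    """Elastic-net age clock as a model object.

    Parameters
    ----------
    beta : BetaMatrix
        Training methylation matrix (samples x CpGs).
    ages : pandas.Series
        Chronological ages in years, indexed by sample id.
    alpha : float
        Elastic-net mixing parameter (1 = lasso, 0 = ridge).
    n_folds : int
        Folds of the internal lambda cross-validation.
    seed : int
        Seeds the fold assignment, the only randomness in training.
    """

    def __init__(self, beta: BetaMatrix, ages: pd.Series, alpha: float = 0.5,
                 n_folds: int = 10, seed: int = 0, **train_kwargs):
        self.beta = beta
        self.ages = ages.loc[beta.sample_ids].astype(float)
        self.alpha = alpha
        self.n_folds = n_folds
        self.seed = seed
        self.train_kwargs = train_kwargs

    @classmethod
    def from_dataframe(cls, beta_frame: pd.DataFrame, samples: SampleTable, **kwargs):
        beta = BetaMatrix(beta_frame)
        return cls(beta, samples.ages(beta.sample_ids), **kwargs)

    def fit(self) -> "ClockResults":
        model = train_clock(self.beta, self.ages, alpha=self.alpha,
                            n_folds=self.n_folds, seed=self.seed, **self.train_kwargs)
        fitted = predict_age(model, self.beta)
        return ClockResults(model=model, fitted=fitted, ages=self.ages)

    def loo(self) -> "ClockResults":
        preds = loo_predict(self.beta, self.ages, alpha=self.alpha,
                            n_folds=self.n_folds, seed=self.seed, **self.train_kwargs)
        model = train_clock(self.beta, self.ages, alpha=self.alpha,
                            n_folds=self.n_folds, seed=self.seed, **self.train_kwargs)
        return ClockResults(model=model, fitted=preds, ages=self.ages)


@dataclass
class ClockResults:
    """A fitted clock with its predictions and accuracy diagnostics."""

    model: ClockModel
    fitted: AgePredictions
    ages: pd.Series

    @property
    def predictions(self) -> pd.Series:
        return self.fitted.predictions

    @property
    def residuals(self) -> pd.Series:
        return self.predictions - self.ages

    @property
    def r2(self) -> float:
        y, yhat = self.ages.to_numpy(), self.predictions.to_numpy()
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    @property
    def median_abs_error(self) -> float:
        return float(np.median(np.abs(self.residuals)))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Epigenetic clock (elastic net)",
            "=" * 34,
            f"protocol        : {self.fitted.protocol}",
            f"sex scope       : {m.sex_scope}",
            f"n training      : {len(m.training_sample_ids)}",
            f"alpha (mixing)  : {m.alpha:g}",
            f"lambda (penalty): {m.lambda_:g}",
            f"non-zero CpGs   : {m.n_weights}",
            f"R^2             : {self.r2:.3f}",
            f"median |error|  : {self.median_abs_error:.3f} years",
        ]
        return "\n".join(lines)
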