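"""Age-trend models of DNAm age on chronological age, selected by AIC.

Three nested candidates describe how methylation-based age tracks
calendar age: no relationship (constant), a uniform tick rate (linear),
and a tick rate that slows with age (quadratic, negative curvature when
juveniles age epigenetically faster than adults).  The most parsimonious
model is chosen by AIC, with the convention that when a simpler model
sits within two AIC units of the best one, the simplest such model wins.
Akaike weights quantify the relative likelihood of each candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KINDS = ("constant", "linear", "quadratic")
_DEGREE = {"constant": 0, "linear": 1, "quadratic": 2}

#: models within this many AIC units of the best are considered equivalent,
#: and the simplest equivalent model is retained
PARSIMONY_DELTA = 2.0


@dataclass
class TrendFit:
    """One OLS polynomial fit of DNAm age on chronological age.

    ``coefficients`` are ordered (intercept, age, age^2) up to the model's
    degree.  The log-likelihood is the Gaussian maximum-likelihood value
    with sigma^2 = rss/n, and AIC = -2*loglik + 2k where k counts the
    regression coefficients plus the residual variance.
    """

    kind: str
    coefficients: tuple[float, ...]
    n: int
    rss: float
    sigma2: float
    loglik: float
    aic: float
    r2: float

    @property
    def k(self) -> int:
        return len(self.coefficients) + 1

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        powers = np.vstack([x ** d for d in range(len(self.coefficients))]).T
        return powers @ np.asarray(self.coefficients)


def fit_trend(x, y, kind: str) -> TrendFit:
    """Ordinary-least-squares polynomial fit of ``y`` on ``x``."""
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    degree = _DEGREE[kind]
    n, p = len(y), degree + 1
    if n <= p:
        raise ValueError(f"{kind} fit needs more than {p} observations, got {n}")
    if len(np.unique(x)) < p:
        raise np.linalg.LinAlgError(
            f"{kind} fit needs at least {p} distinct x values"
        )
    X = np.vstack([x ** d for d in range(p)]).T
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 > 0:
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    else:
        loglik = np.inf  # perfect fit: unbounded Gaussian likelihood
    k = p + 1
    aic = -2.0 * loglik + 2.0 * k
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return TrendFit(kind=kind, coefficients=tuple(float(c) for c in coef),
                    n=n, rss=rss, sigma2=sigma2, loglik=float(loglik),
                    aic=float(aic), r2=r2)


def aic_weights(aics) -> np.ndarray:
    """Akaike weights: w_m = exp(-delta_m/2) / sum exp(-delta/2).

    Invariant to adding a constant to every AIC; an infinite AIC gets
    weight 0.
    """
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0 or np.isnan(aics).any() or not (aics < np.inf).any():
        raise ValueError("need at least one finite AIC")
    if np.isneginf(aics).any():
        # perfect fits dominate absolutely; split the weight among them
        raw = np.isneginf(aics).astype(float)
        return raw / raw.sum()
    delta = aics - np.min(aics[np.isfinite(aics)])
    with np.errstate(over="ignore"):
        raw = np.where(np.isfinite(delta), np.exp(-0.5 * delta), 0.0)
    return raw / raw.sum()


def select_by_parsimony(aics, complexities, delta: float = PARSIMONY_DELTA) -> int:
    """Index of the selected model: the simplest one within ``delta`` AIC
    units of the overall best.  ``complexities`` orders the candidates
    (lower = simpler); ties in complexity resolve to the earlier entry."""
    aics = np.asarray(aics, dtype=float)
    best = np.min(aics)
    order = sorted(range(len(aics)), key=lambda i: (complexities[i], i))
    if np.isneginf(best):
        # perfect fits: simplest of the perfectly fitting candidates
        return next(i for i in order if np.isneginf(aics[i]))
    for i in order:
        if aics[i] < best + delta:
            return i
    raise ValueError("no candidate within the parsimony window")  # unreachable


@dataclass
class TrendSelection:
    """The three candidate fits with their AIC comparison and the pick."""

    fits: dict[str, TrendFit]
    delta_aic: dict[str, float]
    aic_weights: dict[str, float]
    selected: str

    @property
    def selected_fit(self) -> TrendFit:
        return self.fits[self.selected]

    def table(self) -> pd.DataFrame:
        rows = []
        for kind in KINDS:
            f = self.fits[kind]
            coef = list(f.coefficients) + [np.nan] * (3 - len(f.coefficients))
            rows.append({
                "model": kind, "intercept": coef[0], "age": coef[1],
                "age2": coef[2], "k": f.k, "rss": f.rss, "loglik": f.loglik,
                "aic": f.aic, "delta_aic": self.delta_aic[kind],
                "aic_weight": self.aic_weights[kind], "r2": f.r2,
                "selected": kind == self.selected,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tbl = self.table()
        lines = ["DNAm age ~ chronological age: AIC model comparison",
                 "=" * 52,
                 tbl.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
                 f"selected: {self.selected} (simplest within "
                 f"{PARSIMONY_DELTA:g} AIC of best)"]
        return "\n".join(lines)


def select_trend(x, y) -> TrendSelection:
    """Fit all three candidates and apply the AIC + parsimony rule, with
    simplicity ordered constant < linear < quadratic."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("trend selection needs at least 4 observations")
    fits = {kind: fit_trend(x, y, kind) for kind in KINDS}
    aics = np.array([fits[k].aic for k in KINDS])
    idx = select_by_parsimony(aics, complexities=[_DEGREE[k] for k in KINDS])
    weights = aic_weights(aics)
    best = np.min(aics)
    return TrendSelection(
        fits=fits,
        delta_aic={k: float(fits[k].aic - best) for k in KINDS},
        aic_weights={k: float(w) for k, w in zip(KINDS, weights)},
        selected=KINDS[idx],
    )


class AgeTrend:
    """Model object over (chronological age, DNAm age) pairs; ``fit()``
    returns the :class:`TrendSelection` results."""

    def __init__(self, ages, dnam_ages):
        self.ages = np.asarray(ages, dtype=float)
        self.dnam_ages = np.asarray(dnam_ages, dtype=float)

    @classmethod
    def from_predictions(cls, samples, predictions) -> "AgeTrend":
        ids = list(predictions.predictions.index)
        return cls(samples.ages(ids).to_numpy(), predictions.predictions.to_numpy())

    def fit(self) -> TrendSelection:
        return select_trend(self.ages, self.dnam_ages)
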