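"""Epigenetic age acceleration and its stage-specific covariate models.

Acceleration is the signed residual of DNAm age from the population-level
trend of DNAm age on chronological age (positive = biologically older than
the calendar says).  Residuals are computed once from the pooled trend over
all samples, then analysed within each survivorship life stage against sex,
population and body mass through a fixed candidate-model comparison:
fourteen OLS models for prime-age and senescent adults (every
marginality-respecting combination of the three covariates with at most one
two-way interaction and no three-way term), and — because juvenile samples
are few — only four for juveniles (constant, or a single linear effect of
mass, sex or population).  Selection reuses the AIC + parsimony machinery
of :mod:`epiclock.trend`, with model complexity measured by parameter
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .data import LifeStage, SampleTable
from .trend import TrendSelection, aic_weights, select_by_parsimony

logger = logging.getLogger(__name__)

TERMS = ("mass", "population", "sex")   # lexicographic term order breaks ties
_FORMULA_TERM = {"mass": "body_mass_kg", "population": "population", "sex": "sex"}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate acceleration model: main effects plus at most one
    two-way interaction (whose main effects are always included)."""

    terms: tuple[str, ...]
    interaction: tuple[str, str] | None = None

    def __post_init__(self):
        if self.interaction is not None:
            if not set(self.interaction) <= set(self.terms):
                raise ValueError("interaction terms must appear as main effects")

    @property
    def name(self) -> str:
        if not self.terms:
            return "constant"
        parts = list(self.terms)
        if self.interaction:
            parts.append(":".join(self.interaction))
        return " + ".join(parts)

    @property
    def formula(self) -> str:
        rhs = "1"
        if self.terms:
            rhs = " + ".join(_FORMULA_TERM[t] for t in self.terms)
            if self.interaction:
                rhs += " + " + ":".join(_FORMULA_TERM[t] for t in self.interaction)
        return f"acceleration ~ {rhs}"

    @property
    def n_params(self) -> int:
        # all covariates are one column each (binary factors or mass)
        return 1 + len(self.terms) + (1 if self.interaction else 0)


def epigenetic_acceleration(ages, dnam_ages, selection: TrendSelection) -> pd.Series:
    """Signed residuals of DNAm age from the selected age trend.

    ``selection`` must have been fitted on these same pairs; the OLS
    property that residuals sum to zero over the fitting set is verified as
    a guard against mismatched inputs.
    """
    ages = pd.Series(ages, dtype=float) if not isinstance(ages, pd.Series) else ages.astype(float)
    dnam = pd.Series(dnam_ages, dtype=float) if not isinstance(dnam_ages, pd.Series) else dnam_ages.astype(float)
    if len(ages) != len(dnam):
        raise ValueError("ages and DNAm ages have mismatched sample sets")
    fit = selection.selected_fit
    if fit.n != len(ages):
        raise ValueError(
            f"trend was fitted on n={fit.n} samples but got {len(ages)}"
        )
    resid = dnam.to_numpy() - fit.predict(ages.to_numpy())
    if abs(resid.sum()) > 1e-6 * max(1.0, np.abs(dnam.to_numpy()).sum()):
        raise ValueError(
            "residuals do not sum to ~0; was the trend fitted on these data?"
        )
    out = pd.Series(resid, index=dnam.index, name="acceleration")
    return out


def enumerate_candidate_models(stage: LifeStage | str) -> list[ModelSpec]:
    """The frozen candidate set per life stage.

    Juveniles: constant plus one single-effect model per covariate (4).
    Prime-age/senescent: constant; 3 single effects; 3 additive pairs;
    3 pairs with their interaction; the additive triple; 3 triples with one
    two-way interaction — 14 in all, no three-way interaction.  Output
    order is deterministic: ascending parameter count, then lexicographic.
    """
    stage = LifeStage(stage)
    singles = [ModelSpec(terms=(t,)) for t in TERMS]
    if stage is LifeStage.JUVENILE:
        return [ModelSpec(terms=())] + singles
    pairs = [(TERMS[i], TERMS[j]) for i in range(3) for j in range(i + 1, 3)]
    specs = [ModelSpec(terms=())]
    specs += singles
    specs += [ModelSpec(terms=p) for p in pairs]
    specs += [ModelSpec(terms=p, interaction=p) for p in pairs]
    specs += [ModelSpec(terms=TERMS)]
    specs += [ModelSpec(terms=TERMS, interaction=p) for p in pairs]
    specs.sort(key=lambda s: (s.n_params, s.name))
    return specs


@dataclass
class ModelComparisonResults:
    """AIC table over the candidate specs for one life stage."""

    stage: LifeStage
    table: pd.DataFrame              # one row per fitted spec
    coefficients: dict[str, pd.Series]
    selected: str

    @property
    def selected_coefficients(self) -> pd.Series:
        return self.coefficients[self.selected]

    def summary(self) -> str:
        lines = [f"Epigenetic acceleration models — stage: {self.stage.value}",
                 "=" * 56,
                 self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
                 f"selected: {self.selected}"]
        sel = self.coefficients[self.selected]
        if len(sel) > 1 or self.selected != "constant":
            lines.append("coefficients of selected model:")
            lines.append(sel.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _gaussian_aic(rss: float, n: int, n_coef: int) -> tuple[float, float]:
    sigma2 = rss / n
    if sigma2 > 0:
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    else:
        loglik = np.inf
    return float(loglik), float(-2 * loglik + 2 * (n_coef + 1))


def fit_acceleration_models(
    acceleration: pd.Series,
    samples: SampleTable,
    stage: LifeStage | str,
) -> ModelComparisonResults:
    """Fit every candidate spec on the stage's samples and select by AIC.

    Specs with more parameters than available samples (or needing a missing
    mass column) are dropped with a logged warning rather than aborting the
    comparison.
    """
    stage = LifeStage(stage)
    meta = samples.frame.loc[acceleration.index]
    sub = meta[meta["stage"] == stage.value].copy()
    if sub.empty:
        raise ValueError(f"no samples in stage {stage.value}")
    sub["acceleration"] = acceleration.loc[sub.index]

    rows, coefs, kept = [], {}, []
    for spec in enumerate_candidate_models(stage):
        if "mass" in spec.terms and ("body_mass_kg" not in sub.columns
                                     or sub["body_mass_kg"].isna().any()):
            logger.warning("dropping spec %r: body mass unavailable", spec.name)
            continue
        if len(sub) <= spec.n_params:
            logger.warning("dropping spec %r: %d samples for %d parameters",
                           spec.name, len(sub), spec.n_params)
            continue
        res = smf.ols(spec.formula, data=sub).fit()
        loglik, aic = _gaussian_aic(float(res.ssr), int(res.nobs), spec.n_params)
        rows.append({"model": spec.name, "k": spec.n_params, "n": int(res.nobs),
                     "rss": float(res.ssr), "loglik": loglik, "aic": aic})
        coefs[spec.name] = res.params
        kept.append(spec)
    if not rows:
        raise ValueError(f"no candidate model could be fitted for stage {stage.value}")

    table = pd.DataFrame(rows)
    idx = select_by_parsimony(table["aic"].to_numpy(),
                              complexities=[s.n_params for s in kept])
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["aic_weight"] = aic_weights(table["aic"].to_numpy())
    table["selected"] = [i == idx for i in range(len(table))]
    return ModelComparisonResults(stage=stage, table=table, coefficients=coefs,
                                  selected=table.loc[idx, "model"])


class AccelerationAnalysis:
    """Model object tying a trend selection to the stage-wise covariate
    comparisons; ``fit()`` computes residual accelerations and runs every
    stage present in the data."""

    def __init__(self, samples: SampleTable, dnam_ages: pd.Series,
                 selection: TrendSelection):
        self.samples = samples
        self.dnam_ages = dnam_ages
        self.selection = selection

    def fit(self) -> "AccelerationResults":
        ids = list(self.dnam_ages.index)
        accel = epigenetic_acceleration(self.samples.ages(ids), self.dnam_ages,
                                        self.selection)
        stage_results = {}
        for stage in LifeStage:
            if (self.samples.frame.loc[ids, "stage"] == stage.value).any():
                stage_results[stage.value] = fit_acceleration_models(
                    accel, self.samples, stage)
        return AccelerationResults(acceleration=accel, by_stage=stage_results,
                                   trend_kind=self.selection.selected)


@dataclass
class AccelerationResults:
    acceleration: pd.Series
    by_stage: dict[str, ModelComparisonResults]
    trend_kind: str

    def table(self, samples: SampleTable) -> pd.DataFrame:
        out = pd.DataFrame({
            "sample_id": self.acceleration.index,
            "acceleration": self.acceleration.to_numpy(),
            "stage": samples.frame.loc[self.acceleration.index, "stage"].to_numpy(),
        })
        out["trend_kind"] = self.trend_kind
        return out

    def summary(self) -> str:
        return "\n\n".join(r.summary() for r in self.by_stage.values())
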