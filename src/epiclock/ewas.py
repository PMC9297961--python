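"""Per-CpG association screens (EWAS).

The age screen correlates each CpG's beta values with chronological age
and reports the Student t statistic of the correlation (the field calls
this a "Z statistic"): z = r*sqrt(n-2)/sqrt(1-r^2), with a two-sided
p-value from the t distribution on n-2 degrees of freedom.  The sex screen
is an age-adjusted OLS (beta ~ age + sex), the interaction screen adds
age x sex, and the stratified screen runs the age EWAS within each sex and
correlates the two z vectors.

Direction convention: female is the reference level everywhere, so a
positive sex or interaction statistic means higher methylation (or a
steeper age slope) in males.  This is stated in output headers; flipping
the reference only flips signs.

Top-CpG selection applies the fixed genome-wide threshold (p < 1e-8 by
default, a Bonferroni-style correction for five million tests) and keeps
up to 500 CpGs per direction ranked by |z|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import BetaMatrix

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 1e-8          # 0.05 / 5e6 independent tests
DEFAULT_CAP_PER_DIRECTION = 500

#: |r| at least this close to 1 is treated as a perfect correlation and
#: flagged with explicit sentinels (z = +/-inf, p = 0) instead of relying
#: on floating overflow
_PERFECT_R_TOL = 1e-12

EWAS_COLUMNS = ("n_used", "r", "z", "p", "direction", "flag", "screen")


def _finish_table(cpg_ids, n_used, r, z, p, flag, screen) -> pd.DataFrame:
    direction = np.sign(z)
    direction[~np.isfinite(z) & (flag != "perfect")] = 0.0
    tbl = pd.DataFrame({
        "n_used": n_used, "r": r, "z": z, "p": p,
        "direction": direction, "flag": flag, "screen": screen,
    }, index=pd.Index(cpg_ids, name="cpg_id"))
    return tbl


def ewas_age(beta: BetaMatrix, ages: pd.Series, screen: str = "age") -> pd.DataFrame:
    """Correlation-t screen of every CpG against age.

    Missing betas are removed pairwise per CpG (``n_used`` records the
    count).  Zero-variance CpGs are flagged ``"zero variance"`` with
    undefined statistics; |r| = 1 is flagged ``"perfect"`` with z = +/-inf
    and p = 0 sentinels.
    """
    ages = ages.loc[beta.sample_ids].astype(float)
    M = beta.values.to_numpy()
    x = ages.to_numpy()
    n_samp, n_cpg = M.shape

    mask = ~np.isnan(M)
    n_used = mask.sum(axis=0)
    xs = np.where(mask, x[:, None], 0.0)
    ms = np.where(mask, M, 0.0)
    sx = xs.sum(axis=0)
    sm = ms.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n_used
        mean_m = sm / n_used
        sxx = (xs ** 2).sum(axis=0) - n_used * mean_x ** 2
        smm = (ms ** 2).sum(axis=0) - n_used * mean_m ** 2
        sxm = (xs * ms).sum(axis=0) - n_used * mean_x * mean_m
        r = sxm / np.sqrt(sxx * smm)
    r = np.clip(r, -1.0, 1.0)

    flag = np.full(n_cpg, "ok", dtype=object)
    bad = (n_used < 3) | ~np.isfinite(r)
    zero_var = np.nan_to_num(smm) <= 0
    flag[zero_var] = "zero variance"
    flag[(n_used < 3) & ~zero_var] = "insufficient n"
    perfect = (np.abs(r) >= 1.0 - _PERFECT_R_TOL) & ~bad
    flag[perfect] = "perfect"

    z = np.full(n_cpg, np.nan)
    p = np.full(n_cpg, np.nan)
    ok = ~bad & ~perfect
    df = n_used - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        z[ok] = r[ok] * np.sqrt(df[ok]) / np.sqrt(1.0 - r[ok] ** 2)
    p[ok] = 2.0 * stats.t.sf(np.abs(z[ok]), df[ok])
    z[perfect] = np.sign(r[perfect]) * np.inf
    p[perfect] = 0.0
    r[bad] = np.nan
    return _finish_table(beta.cpg_ids, n_used, r, z, p, flag, screen)


def _ols_screen(beta: BetaMatrix, design: np.ndarray, coef_idx: int,
                screen: str) -> pd.DataFrame:
    """Vectorized per-CpG OLS; z/p report the t test of one coefficient.

    The shared design matrix is solved once for all complete CpGs; CpGs
    with missing values fall back to a per-CpG solve on their complete
    rows.
    """
    M = beta.values.to_numpy()
    n, k = design.shape
    n_cpg = M.shape[1]
    flag = np.full(n_cpg, "ok", dtype=object)
    est = np.full(n_cpg, np.nan)
    z = np.full(n_cpg, np.nan)
    p = np.full(n_cpg, np.nan)
    n_used = np.full(n_cpg, n)

    xtx_inv = np.linalg.inv(design.T @ design)
    hat = xtx_inv @ design.T
    var_scale = xtx_inv[coef_idx, coef_idx]

    has_nan = np.isnan(M).any(axis=0)

    def solve(X, Y):
        B = hat @ Y if X is design else np.linalg.lstsq(X, Y, rcond=None)[0]
        resid = Y - X @ B
        dof = X.shape[0] - X.shape[1]
        rss = (resid ** 2).sum(axis=0)
        sigma2 = rss / dof
        if X is design:
            vs = var_scale
        else:
            vs = np.linalg.inv(X.T @ X)[coef_idx, coef_idx]
        se = np.sqrt(sigma2 * vs)
        return B[coef_idx], se, dof

    full = ~has_nan
    if full.any():
        b, se, dof = solve(design, M[:, full])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = b / se
        est[full], z[full] = b, t
        p[full] = 2.0 * stats.t.sf(np.abs(t), dof)
        degen = ~np.isfinite(t)
        idxs = np.flatnonzero(full)[degen]
        flag[idxs] = "zero variance"
        z[idxs] = np.nan
        p[idxs] = np.nan

    for j in np.flatnonzero(has_nan):
        rows = ~np.isnan(M[:, j])
        n_used[j] = int(rows.sum())
        X = design[rows]
        if n_used[j] <= k or np.linalg.matrix_rank(X) < k:
            flag[j] = "insufficient n"
            continue
        b, se, dof = solve(X, M[rows, j][:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = float(b[0] / se[0])
        if not np.isfinite(t):
            flag[j] = "zero variance"
            continue
        est[j], z[j] = float(b[0]), t
        p[j] = 2.0 * stats.t.sf(abs(t), dof)

    tbl = _finish_table(beta.cpg_ids, n_used, np.full(n_cpg, np.nan), z, p, flag, screen)
    tbl["coefficient"] = est
    return tbl


def _sex_indicator(sex: pd.Series) -> np.ndarray:
    vals = set(sex.unique())
    if not vals <= {"female", "male"}:
        raise ValueError(f"unexpected sex values {sorted(vals)}")
    if len(vals) < 2:
        raise ValueError("both sexes must be present")
    # female is the reference: positive coefficients mean higher in males
    return (sex == "male").to_numpy().astype(float)


def ewas_sex_adjusted(beta: BetaMatrix, ages: pd.Series, sex: pd.Series) -> pd.DataFrame:
    """Basal sex-difference screen: per CpG, OLS beta ~ age + sex; the
    statistic tests the sex coefficient (male vs female reference)."""
    ages = ages.loc[beta.sample_ids].astype(float)
    male = _sex_indicator(sex.loc[beta.sample_ids])
    X = np.column_stack([np.ones(len(male)), ages.to_numpy(), male])
    return _ols_screen(beta, X, coef_idx=2, screen="sex_adjusted")


def ewas_interaction(beta: BetaMatrix, ages: pd.Series, sex: pd.Series) -> pd.DataFrame:
    """Sex-specific ageing screen: per CpG, OLS beta ~ age + sex +
    age x sex; the statistic tests the interaction coefficient."""
    ages = ages.loc[beta.sample_ids].astype(float)
    male = _sex_indicator(sex.loc[beta.sample_ids])
    for lab, m in (("female", male == 0), ("male", male == 1)):
        if m.sum() < 3:
            raise ValueError(f"need at least 3 {lab} samples, got {int(m.sum())}")
    a = ages.to_numpy()
    X = np.column_stack([np.ones(len(male)), a, male, a * male])
    return _ols_screen(beta, X, coef_idx=3, screen="interaction")


def stratified_age_ewas(
    beta: BetaMatrix, ages: pd.Series, sex: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Age EWAS within each sex plus the cross-sex correlation of the two
    z vectors over CpGs with defined statistics in both."""
    sex = sex.loc[beta.sample_ids]
    tables = {}
    for scope in ("female", "male"):
        ids = [s for s, v in sex.items() if v == scope]
        if len(ids) < 3:
            raise ValueError(f"need at least 3 {scope} samples")
        sub = beta.subset_samples(ids)
        tables[scope] = ewas_age(sub, ages.loc[ids], screen=f"age_in_{scope}s")
    zf = tables["female"]["z"]
    zm = tables["male"]["z"]
    both = np.isfinite(zf) & np.isfinite(zm)
    if both.sum() < 3:
        raise ValueError("too few CpGs defined in both sexes")
    r = float(np.corrcoef(zf[both], zm[both])[0, 1])
    return tables["female"], tables["male"], r


@dataclass
class TopCpGSet:
    """Genome-wide-significant CpGs split by direction of the statistic."""

    hyper: list[str]                 # positive z: methylation gain
    hypo: list[str]                  # negative z: methylation loss
    p_threshold: float = GENOME_WIDE_P
    cap_per_direction: int = DEFAULT_CAP_PER_DIRECTION

    @property
    def all_ids(self) -> list[str]:
        return list(self.hyper) + list(self.hypo)

    def direction_of(self, cpg_id: str) -> str:
        if cpg_id in set(self.hyper):
            return "hyper"
        if cpg_id in set(self.hypo):
            return "hypo"
        raise KeyError(cpg_id)


def select_top_cpgs(
    table: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    cap_per_direction: int = DEFAULT_CAP_PER_DIRECTION,
) -> TopCpGSet:
    """Threshold-and-cap selection: CpGs with p below the threshold, split
    by the sign of z, each side ranked by |z| descending and truncated at
    the cap.  Undefined statistics are excluded; ties and row order are
    broken deterministically by cpg_id."""
    ok = table[(table["flag"].isin(["ok", "perfect"])) & (table["p"] < p_threshold)]
    ok = ok.reset_index() if "cpg_id" not in ok.columns else ok.copy()
    ok["_absz"] = ok["z"].abs()
    out = {}
    for label, side in (("hyper", ok[ok["z"] > 0]), ("hypo", ok[ok["z"] < 0])):
        ranked = side.sort_values(["_absz", "cpg_id"], ascending=[False, True])
        out[label] = ranked["cpg_id"].head(cap_per_direction).tolist()
    return TopCpGSet(hyper=out["hyper"], hypo=out["hypo"],
                     p_threshold=p_threshold, cap_per_direction=cap_per_direction)
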