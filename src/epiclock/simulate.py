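"""Synthetic methylation cohorts with the statistical structure of a wild
deer ageing study.

The generator emulates a blood-methylation survey of two intensively
monitored roe deer populations: ~83 animals captured over two consecutive
winters (a subset recaptured in both, giving ~94 samples), ages spanning
eight months to 13.5 years, both sexes, and an array of ~30k CpGs of which
subsets carry (i) age trends that accumulate faster during growth than in
adulthood, (ii) basal sex offsets, and (iii) sex-specific age slopes.
Juvenile body mass is coupled to a latent biological-age offset so that the
downstream age-acceleration analysis has a planted, recoverable signal.

Methylation is generated on the logit scale and mapped through the logistic
function, which keeps every beta value strictly inside (0, 1):

    logit(m_ij) = mu_j + s_j * f(a_i + delta_i) + b_j^sex * male_i
                  + b_j^int * male_i * f(a_i + delta_i) + eps_ij

with eps ~ Normal(0, noise_sd_logit) and f the tick-rate transform below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data import BetaMatrix, CpGAnnotation, SampleTable, derive_stage, LifeStage

REGION_CLASS_PROPS = {
    "promoter": 0.15,
    "5'UTR": 0.05,
    "exon": 0.20,
    "intron": 0.30,
    "3'UTR": 0.05,
    "intergenic/other": 0.25,
}

AUTOSOMAL_SCAFFOLDS = [f"scaffold_{i:02d}" for i in range(1, 21)]
GONOSOMAL_SCAFFOLDS = ["gonosome_1", "gonosome_2"]


def tick_rate_transform(age_years, growth_multiplier: float, maturity_age: float):
    """Effective epigenetic age under an elevated juvenile tick rate.

    Methylation-based age accumulates ``growth_multiplier`` times faster
    per calendar year before ``maturity_age`` than after it:

        f(a) = lambda * a                         for a <= a_mat
        f(a) = lambda * a_mat + (a - a_mat)       for a >  a_mat

    Continuous, strictly increasing, and the identity when lambda = 1.
    """
    lam, a_mat = growth_multiplier, maturity_age
    if lam < 1:
        raise ValueError("growth multiplier must be >= 1")
    if a_mat <= 0:
        raise ValueError("maturity age must be positive")
    a = np.asarray(age_years, dtype=float)
    out = np.where(a <= a_mat, lam * a, lam * a_mat + (a - a_mat))
    return out if out.ndim else float(out)


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults mirror the study design."""

    seed: int = 0
    site_seed: int | None = None          # per-CpG biology; defaults to seed, fix it
                                          # to share the array across replicate cohorts
    n_animals: int = 83
    repeat_fraction: float = 11 / 83      # animals sampled in both years
    juvenile_fraction: float = 8 / 94     # share of samples that are 8-month-olds
    n_cpgs: int = 4000                    # 29,846 supported for full-array runs
    n_age_cpgs: int = 240
    n_sex_basal_cpgs: int = 120
    n_interaction_cpgs: int = 60
    age_slope_logit: float = 0.15         # logit units per effective year
    sex_offset_logit: float = 1.0
    interaction_slope_logit: float = 0.10
    growth_multiplier: float = 3.0        # juvenile tick rate, >= 1
    maturity_age: float = 1.5             # years; calibrated so the tick-rate
                                          # knee sits below the adult (>=2 y) range
    noise_sd_logit: float = 0.3
    mass_coupling: float = 0.1            # years of biological age per kg (juveniles)
    age_range: tuple[float, float] = (0.67, 13.5)
    juvenile_mass_mean: float = 15.0      # kg, winter mass at 8 months
    juvenile_mass_sd: float = 2.0
    adult_mass_mean: float = 25.0
    adult_mass_sd: float = 3.0
    sex_linked_proportion: float = 0.8    # sex/interaction CpGs on gonosomal scaffolds
    hyper_promoter_enrichment: float = 3.0  # promoter/island weighting of hyper age-CpGs
    island_proportion: float = 0.3

    def __post_init__(self) -> None:
        planted = self.n_age_cpgs + self.n_sex_basal_cpgs + self.n_interaction_cpgs
        if planted > self.n_cpgs:
            raise ValueError(
                f"planted CpG classes ({planted}) exceed n_cpgs ({self.n_cpgs})"
            )
        if self.growth_multiplier < 1:
            raise ValueError("growth_multiplier must be >= 1")
        if self.noise_sd_logit < 0:
            raise ValueError("noise_sd_logit must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``cpgs`` has one row per CpG (class label in {age, sex_basal,
    interaction, null} and true logit-scale coefficients); ``samples`` has
    one row per sample (biological-age offset delta in years and the
    effective age actually used to generate its methylation).
    """

    cpgs: pd.DataFrame
    samples: pd.DataFrame

    def cpg_ids_of_class(self, label: str) -> list[str]:
        return self.cpgs.index[self.cpgs["class"] == label].tolist()


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _sample_cohort(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_repeat = int(round(cfg.repeat_fraction * cfg.n_animals))
    n_samples = cfg.n_animals + n_repeat
    n_juv = int(round(cfg.juvenile_fraction * n_samples))
    n_juv = min(n_juv, cfg.n_animals)

    animals = pd.DataFrame({
        "animal_id": [f"A{i+1:03d}" for i in range(cfg.n_animals)],
        "sex": rng.choice(["female", "male"], size=cfg.n_animals),
        "population": rng.choice(["TF", "CH"], size=cfg.n_animals),
    })
    # juveniles are all first captured at the winter capture age (~8 months)
    juv_age = cfg.age_range[0]
    ages = np.concatenate([
        np.full(n_juv, juv_age),
        rng.uniform(1.0, cfg.age_range[1], size=cfg.n_animals - n_juv),
    ])
    animals["age_years"] = ages

    # repeat captures: adults only, so the juvenile share refers to first capture
    adult_idx = np.flatnonzero(animals["age_years"] >= 1.0)
    repeat_idx = rng.choice(adult_idx, size=min(n_repeat, adult_idx.size), replace=False)

    rows = []
    for i, row in animals.iterrows():
        rows.append({
            "sample_id": f"S{len(rows)+1:03d}",
            "animal_id": row["animal_id"],
            "age_years": row["age_years"],
            "sex": row["sex"],
            "population": row["population"],
            "capture_year": 2016,
        })
    for i in sorted(repeat_idx):
        row = animals.iloc[i]
        rows.append({
            "sample_id": f"S{len(rows)+1:03d}",
            "animal_id": row["animal_id"],
            "age_years": row["age_years"] + 1.0,   # resampled one year later
            "sex": row["sex"],
            "population": row["population"],
            "capture_year": 2017,
        })
    cohort = pd.DataFrame(rows)

    juv_mask = cohort["age_years"] < 1.0
    mass = np.where(
        juv_mask,
        rng.normal(cfg.juvenile_mass_mean, cfg.juvenile_mass_sd, size=len(cohort)),
        rng.normal(cfg.adult_mass_mean, cfg.adult_mass_sd, size=len(cohort)),
    )
    cohort["body_mass_kg"] = np.clip(mass, 1.0, None)
    return cohort


def _assign_annotation(cfg: SimConfig, rng: np.random.Generator,
                       cpg_ids: Sequence[str], classes: np.ndarray,
                       slopes: np.ndarray) -> CpGAnnotation:
    n = len(cpg_ids)
    region_names = list(REGION_CLASS_PROPS)
    base_probs = np.array([REGION_CLASS_PROPS[r] for r in region_names])

    regions = np.empty(n, dtype=object)
    islands = np.empty(n, dtype=object)
    scaffolds = np.empty(n, dtype=object)
    positions = rng.integers(1, 5_000_000, size=n)

    hyper_age = (classes == "age") & (slopes > 0)
    weighted = base_probs.copy()
    for enriched in ("promoter", "5'UTR"):
        weighted[region_names.index(enriched)] *= cfg.hyper_promoter_enrichment
    weighted /= weighted.sum()

    for i in range(n):
        probs = weighted if hyper_age[i] else base_probs
        regions[i] = rng.choice(region_names, p=probs)
        p_island = cfg.island_proportion
        if hyper_age[i]:
            p_island = min(1.0, cfg.island_proportion * cfg.hyper_promoter_enrichment)
        islands[i] = "island" if rng.random() < p_island else "non-island"
        if classes[i] in ("sex_basal", "interaction") and rng.random() < cfg.sex_linked_proportion:
            scaffolds[i] = rng.choice(GONOSOMAL_SCAFFOLDS)
        else:
            scaffolds[i] = rng.choice(AUTOSOMAL_SCAFFOLDS)

    genes = [f"GENE{1 + (i % max(1, n // 4)):04d}" for i in range(n)]
    return CpGAnnotation(pd.DataFrame({
        "cpg_id": list(cpg_ids),
        "scaffold": scaffolds,
        "position": positions,
        "nearest_gene": genes,
        "region_class": regions,
        "island_status": islands,
    }))


def simulate_dataset(cfg: SimConfig) -> tuple[BetaMatrix, SampleTable, CpGAnnotation, SimTruth]:
    """Generate a full synthetic cohort: betas, metadata, annotation, truth.

    Deterministic under ``cfg.seed``: the same config yields bit-identical
    outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    site_rng = np.random.default_rng(cfg.seed if cfg.site_seed is None else cfg.site_seed)
    cohort = _sample_cohort(cfg, rng)
    n_samples = len(cohort)

    # latent biological-age offset: juveniles only, proportional to how far
    # their winter mass sits from the juvenile stage mean
    juv = cohort["age_years"] < 1.0
    delta = np.zeros(n_samples)
    if juv.any():
        juv_mass = cohort.loc[juv, "body_mass_kg"]
        delta[juv.to_numpy()] = cfg.mass_coupling * (juv_mass - juv_mass.mean())
    eff_age = tick_rate_transform(cohort["age_years"].to_numpy() + delta,
                                  cfg.growth_multiplier, cfg.maturity_age)
    male = (cohort["sex"] == "male").to_numpy().astype(float)

    cpg_ids = [f"cg{j+1:06d}" for j in range(cfg.n_cpgs)]
    classes = np.array(
        ["age"] * cfg.n_age_cpgs
        + ["sex_basal"] * cfg.n_sex_basal_cpgs
        + ["interaction"] * cfg.n_interaction_cpgs
        + ["null"] * (cfg.n_cpgs - cfg.n_age_cpgs - cfg.n_sex_basal_cpgs
                      - cfg.n_interaction_cpgs),
        dtype=object,
    )

    slopes = np.zeros(cfg.n_cpgs)
    sex_offsets = np.zeros(cfg.n_cpgs)
    int_slopes = np.zeros(cfg.n_cpgs)
    is_age = classes == "age"
    is_sex = classes == "sex_basal"
    is_int = classes == "interaction"
    slopes[is_age] = cfg.age_slope_logit * site_rng.choice([-1.0, 1.0], size=is_age.sum())
    sex_offsets[is_sex] = cfg.sex_offset_logit * site_rng.choice([-1.0, 1.0], size=is_sex.sum())
    # interaction CpGs age in both sexes but faster in males: a base slope
    # plus a same-signed male surplus (males are the epigenetically
    # faster-ageing sex at these sites)
    int_sign = site_rng.choice([-1.0, 1.0], size=is_int.sum())
    slopes[is_int] = cfg.age_slope_logit * int_sign
    int_slopes[is_int] = cfg.interaction_slope_logit * int_sign

    # baselines: null CpGs bimodal (mostly un/fully methylated, as on real
    # arrays); planted CpGs mid-range so their trends stay visible
    mu = np.empty(cfg.n_cpgs)
    is_null = classes == "null"
    n_null = int(is_null.sum())
    lowhigh = site_rng.random(n_null) < 0.5
    mu_null = np.where(
        lowhigh,
        site_rng.normal(_logit(0.05), 0.5, size=n_null),
        site_rng.normal(_logit(0.95), 0.5, size=n_null),
    )
    mu[is_null] = mu_null
    mu[~is_null] = site_rng.normal(0.0, 0.5, size=int((~is_null).sum()))

    # age effects are centered at the cohort-mean effective age so planted
    # sites stay mid-range across the cohort instead of all saturating at
    # the old end (mu is the logit level of an average-aged animal)
    eff_centered = eff_age - eff_age.mean()
    logit_m = (
        mu[None, :]
        + np.outer(eff_centered, slopes)
        + np.outer(male, sex_offsets)
        + np.outer(male * eff_centered, int_slopes)
        + rng.normal(0.0, cfg.noise_sd_logit, size=(n_samples, cfg.n_cpgs))
    )
    betas = 1.0 / (1.0 + np.exp(-logit_m))

    beta = BetaMatrix(pd.DataFrame(betas, index=cohort["sample_id"], columns=cpg_ids))
    samples = SampleTable(cohort)
    truth_cpgs = pd.DataFrame({
        "class": classes,
        "mu": mu,
        "age_slope": slopes,
        "sex_offset": sex_offsets,
        "interaction_slope": int_slopes,
    }, index=pd.Index(cpg_ids, name="cpg_id"))
    truth_samples = pd.DataFrame({
        "delta_years": delta,
        "effective_age": eff_age,
    }, index=pd.Index(cohort["sample_id"], name="sample_id"))
    annotation = _assign_annotation(cfg, site_rng, cpg_ids, classes, slopes)
    return beta, samples, annotation, SimTruth(cpgs=truth_cpgs, samples=truth_samples)
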