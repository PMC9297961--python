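"""End-to-end reproducible runs: simulate -> LOO clock -> trend ->
acceleration -> EWAS -> enrichment, with a manifest tying every artifact
to the config hash and seed that produced it."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .acceleration import AccelerationAnalysis
from .clock import AgePredictions, EpigeneticClock, loo_predict, predict_age, train_clock
from .data import (BetaMatrix, CpGAnnotation, SampleTable, read_annotation,
                   read_beta_matrix, read_sample_table)
from .enrichment import enrichment_table, region_enrichment
from .ewas import (ewas_age, ewas_interaction, ewas_sex_adjusted,
                   select_top_cpgs, stratified_age_ewas)
from .simulate import SimConfig, simulate_dataset
from .trend import AgeTrend

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; every random operation gets an explicit seed."""

    seed: int
    simulate: dict | None = None          # SimConfig fields; seed injected
    inputs: dict | None = None            # {"beta":…, "samples":…, "annotation":…}
    clock: dict | None = None             # alpha, n_folds, lambda_rule, …
    trend_protocol: str = "loo"           # {"loo", "refit"}
    ewas_p_threshold: float = 1e-8
    ewas_cap_per_direction: int = 500
    enrichment_fields: tuple[str, ...] = ("region_class", "island_status")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must specify a seed")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must specify exactly one of simulate/inputs")

    @classmethod
    def from_yaml(cls, path, seed_override: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed_override is not None:
            raw["seed"] = seed_override
        if "seed" not in raw or raw["seed"] is None:
            raise ValueError(f"config {path} is missing the mandatory seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "enrichment_fields" in raw:
            raw["enrichment_fields"] = tuple(raw["enrichment_fields"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "simulate": self.simulate, "inputs": self.inputs,
            "clock": self.clock, "trend_protocol": self.trend_protocol,
            "ewas_p_threshold": self.ewas_p_threshold,
            "ewas_cap_per_direction": self.ewas_cap_per_direction,
            "enrichment_fields": list(self.enrichment_fields),
        }

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_table(frame: pd.DataFrame, path: Path, config_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim["seed"] = cfg.seed
        beta, samples, annotation, truth = simulate_dataset(SimConfig.from_dict(sim))
        return beta, samples, annotation
    beta = read_beta_matrix(cfg.inputs["beta"])
    samples = read_sample_table(cfg.inputs["samples"])
    annotation = read_annotation(cfg.inputs["annotation"]) if cfg.inputs.get("annotation") else None
    return beta, samples, annotation


def run_all(cfg: PipelineConfig, outdir) -> Path:
    """Run the whole analysis and write every intermediate artifact.

    Rerunning with the same config is bit-identical; the manifest records
    the seed, package version, config hash and per-file digests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.hash()
    clock_kwargs = dict(cfg.clock or {})
    clock_kwargs.setdefault("seed", cfg.seed)

    beta, samples, annotation = load_inputs(cfg)
    ages = samples.ages(beta.sample_ids)

    logger.info("clock stage: %s protocol on %d samples x %d CpGs",
                cfg.trend_protocol, *beta.shape)
    if cfg.trend_protocol == "loo":
        preds = loo_predict(beta, ages, **clock_kwargs)
    else:
        model = train_clock(beta, ages, **clock_kwargs)
        preds = predict_age(model, beta)
    _write_table(preds.predictions.rename("dnam_age_years").reset_index(),
                 outdir / "predictions.tsv", chash)

    selection = AgeTrend.from_predictions(samples, preds).fit()
    _write_table(selection.table(), outdir / "trend.tsv", chash)

    accel_res = AccelerationAnalysis(samples, preds.predictions, selection).fit()
    _write_table(accel_res.table(samples), outdir / "acceleration.tsv", chash)
    for stage, res in accel_res.by_stage.items():
        _write_table(res.table, outdir / f"acceleration_models_{stage}.tsv", chash)

    sex = samples.frame.loc[beta.sample_ids, "sex"]
    age_tbl = ewas_age(beta, ages)
    _write_table(age_tbl.reset_index(), outdir / "ewas_age.tsv", chash)
    sex_tbl = ewas_sex_adjusted(beta, ages, sex)
    _write_table(sex_tbl.reset_index(), outdir / "ewas_sex_adjusted.tsv", chash)
    int_tbl = ewas_interaction(beta, ages, sex)
    _write_table(int_tbl.reset_index(), outdir / "ewas_interaction.tsv", chash)
    fem_tbl, male_tbl, z_corr = stratified_age_ewas(beta, ages, sex)
    _write_table(fem_tbl.reset_index(), outdir / "ewas_age_in_females.tsv", chash)
    _write_table(male_tbl.reset_index(), outdir / "ewas_age_in_males.tsv", chash)

    top = select_top_cpgs(age_tbl, p_threshold=cfg.ewas_p_threshold,
                          cap_per_direction=cfg.ewas_cap_per_direction)
    top_frame = pd.DataFrame(
        [{"cpg_id": c, "direction": "hyper"} for c in top.hyper]
        + [{"cpg_id": c, "direction": "hypo"} for c in top.hypo])
    _write_table(top_frame, outdir / "top_cpgs.tsv", chash)

    enrichment_files = []
    if annotation is not None:
        for fld in cfg.enrichment_fields:
            rows = region_enrichment(top, annotation, annotation_field=fld)
            _write_table(enrichment_table(rows), outdir / f"enrichment_{fld}.tsv", chash)
            enrichment_files.append(f"enrichment_{fld}.tsv")

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": chash,
        "seed": cfg.seed,
        "package_version": __version__,
        "trend_selected": selection.selected,
        "cross_sex_z_correlation": z_corr,
        "n_top_cpgs": {"hyper": len(top.hyper), "hypo": len(top.hypo)},
        "artifacts": {},
    }
    for f in sorted(p.name for p in outdir.glob("*.tsv")):
        manifest["artifacts"][f] = _digest(outdir / f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
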