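"""Seeded end-to-end orchestration: synth -> instruments -> MR -> CLPM ->
mediation -> association/attrition reports.

Artifacts are deterministic under a fixed config + seed; a manifest records
the package version, seed, and a hash of the configuration. JSON is used for
statistical results (permutation nulls, bootstrap summaries), CSV for tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import attrition_table, partial_correlation, usage_summary, wave_summary
from .clpm import fit_two_wave_clpm
from .config import WAVES, TrueModelConfig
from .exceptions import ConfigurationError, InstrumentValidationError
from .instruments import DEFAULT_THRESHOLDS, ValidPRSGrid
from .io import write_genotypes, write_gwas, write_phenotypes
from .mediation import fit_serial_mediation, fit_simple_mediation
from .mr import LongitudinalMRTest, residualize
from .synth import simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline run configuration (synthetic-cohort mode)."""

    synth: TrueModelConfig = field(default_factory=TrueModelConfig)
    B: int = 1000
    n_boot: int = 10_000
    seed: int = 0
    covariates: tuple[str, ...] = ("sex", "site")
    subgroup: str = "all"  # all | male | female
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    force_stage2: bool = False

    def __post_init__(self) -> None:
        if self.subgroup not in ("all", "male", "female"):
            raise ConfigurationError("subgroup must be one of all/male/female")
        if isinstance(self.synth, dict):
            self.synth = TrueModelConfig.from_dict(self.synth)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict()
        d["covariates"] = list(self.covariates)
        d["thresholds"] = [float(t) for t in self.thresholds]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "synth" in d:
            d["synth"] = TrueModelConfig.from_dict(d["synth"])
        for key in ("covariates", "thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Run all six stages, writing one artifact set per stage.

    Returns the run directory. On stage failure the error is re-raised with
    the stage name; artifacts of completed stages are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    _dump_json(
        {"package": "validmr", "version": __version__, "seed": cfg.seed, "config_sha256": cfg_hash},
        out / "manifest.json",
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)

    stage = "synth"
    try:
        synth_cfg = cfg.synth.replace(seed=cfg.synth.seed if cfg.synth.seed else cfg.seed)
        panel, gwas_exposure, gwas_outcome, phenos = simulate_cohort(synth_cfg)
        write_gwas(gwas_exposure, out / "gwas_exposure.tsv")
        write_gwas(gwas_outcome, out / "gwas_outcome.tsv")
        write_genotypes(panel, out / "dosages.tsv", out / "snp_meta.tsv")
        write_phenotypes(phenos, out / "phenotypes.csv")

        if cfg.subgroup != "all":
            want = 1 if cfg.subgroup == "male" else 0
            keep_ids = set(
                phenos.loc[(phenos["wave"] == "BL") & (phenos["sex"] == want), "participant_id"]
            )
            mask = np.array([i in keep_ids for i in panel.individual_ids])
            panel = dataclasses.replace(
                panel,
                dosages=panel.dosages[mask],
                individual_ids=panel.individual_ids[mask],
            )
            phenos = phenos.loc[phenos["participant_id"].isin(keep_ids)].reset_index(drop=True)

        stage = "instruments"
        grid_mdd = ValidPRSGrid(thresholds=cfg.thresholds).fit(gwas_exposure, gwas_outcome, panel).grid_
        grid_alc = ValidPRSGrid(thresholds=cfg.thresholds).fit(gwas_outcome, gwas_exposure, panel).grid_
        grid_mdd.scores_frame().to_csv(out / "scores_exposure_instrument.csv", index=False)
        grid_alc.scores_frame().to_csv(out / "scores_outcome_instrument.csv", index=False)
        grid_mdd.retained_frame().to_csv(out / "retained_snps_exposure.csv", index=False)
        grid_alc.retained_frame().to_csv(out / "retained_snps_outcome.csv", index=False)

        stage = "mr"
        covs = [c for c in cfg.covariates if cfg.subgroup == "all" or c != "sex"]
        resid = residualize(phenos, covariates=covs)
        mr_results = {}
        for name, grid, expo, outc in (
            ("exposure_to_outcome", grid_mdd, "depression", "alcohol_problems"),
            ("outcome_to_exposure", grid_alc, "alcohol_consumption", "depression"),
        ):
            test = LongitudinalMRTest(
                exposure_phenotype=expo,
                outcome_phenotype=outc,
                B=cfg.B,
                seed=cfg.seed,
                force=cfg.force_stage2,
            )
            try:
                test.fit(grid, resid)
                mr_results[name] = {
                    "stage1": test.validation_.to_dict(),
                    "stage2": test.causal_.to_dict(),
                }
                logger.info(
                    "MR %s: stage-1 p=%.4f, stage-2 r_mean=%.4f p=%.4f",
                    name,
                    test.validation_.p_longitudinal,
                    test.r_mean_,
                    test.p_value_,
                )
            except InstrumentValidationError as exc:
                mr_results[name] = {"error": str(exc)}
                logger.warning("MR %s refused: %s", name, exc)
        _dump_json(mr_results, out / "mr_results.json")

        stage = "clpm"
        rows = []
        for wave_t, wave_t1 in zip(WAVES, WAVES[1:]):
            for x, y, control in (
                ("depression", "alcohol_problems", ("alcohol_consumption",)),
                ("depression", "alcohol_consumption", ("alcohol_problems",)),
            ):
                res = fit_two_wave_clpm(resid, x, y, wave_t, wave_t1, control=control)
                frame = res.to_frame()
                frame.insert(0, "x", x)
                frame.insert(1, "y", y)
                rows.append(frame)
        pd.concat(rows, ignore_index=True).to_csv(out / "clpm_results.csv", index=False)

        stage = "mediation"
        bl = resid.loc[resid["wave"] == "BL"].set_index("participant_id")
        fu1 = resid.loc[resid["wave"] == "FU1"].set_index("participant_id")
        med_data = pd.DataFrame(
            {
                "prs_exposure": pd.Series(
                    grid_mdd.scores[:, 0], index=pd.Index(grid_mdd.individual_ids)
                ),
                "hopelessness": bl["hopelessness"],
                "impulsivity": bl["impulsivity"],
                "alcohol_problems_fu1": fu1["alcohol_problems"],
            }
        ).dropna()
        med = {
            "simple_hopelessness": fit_simple_mediation(
                med_data, "prs_exposure", "hopelessness", "alcohol_problems_fu1",
                n_boot=cfg.n_boot, direction="+", seed=cfg.seed,
            ).to_dict(),
            "serial_hopelessness_impulsivity": fit_serial_mediation(
                med_data, "prs_exposure", "hopelessness", "impulsivity", "alcohol_problems_fu1",
                n_boot=cfg.n_boot, direction="+", seed=cfg.seed,
            ).to_dict(),
        }
        _dump_json(med, out / "mediation_results.json")

        stage = "assoc"
        pcors = []
        for wave in WAVES:
            sub = resid.loc[(resid["wave"] == wave) & resid["present"].astype(bool)]
            for x, y, z in (
                ("depression", "alcohol_consumption", ("alcohol_problems",)),
                ("depression", "alcohol_problems", ("alcohol_consumption",)),
            ):
                pc = partial_correlation(sub, x, y, z)
                pcors.append({"wave": wave, "x": x, "y": y, **pc.to_dict()})
        pd.DataFrame(pcors).to_csv(out / "partial_correlations.csv", index=False)
        attrition_table(phenos).to_csv(out / "attrition.csv", index=False)
        _dump_json(usage_summary(phenos).to_dict(), out / "usage_summary.json")
        wave_summary(phenos).to_csv(out / "wave_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
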