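"""Plain-text readers and writers for the package's data containers.

Formats:

* GWAS summary — tab-separated with header ``SNP	EA	BETA	P``
  (PLINK-association dialect).
* Genotypes — a dosage matrix TSV (individuals x SNPs, first column
  ``participant_id``) plus a SNP metadata TSV
  (``SNP	EA	POS	BLOCK	MAF``).
* Phenotypes — long-format CSV, one row per (participant, wave).
* Configs — YAML (see :meth:`TrueModelConfig.to_yaml`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import GenotypePanel, GwasSummary


def write_gwas(gwas: GwasSummary, path) -> None:
    gwas.to_frame().to_csv(path, sep="\t", index=False)


def read_gwas(path, trait: str = "") -> GwasSummary:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "EA": str})
    missing = {"SNP", "EA", "BETA", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table {path} lacks columns {sorted(missing)}")
    return GwasSummary(
        snp_id=df["SNP"].to_numpy(),
        effect_allele=df["EA"].to_numpy(),
        beta=df["BETA"].to_numpy(float),
        p=df["P"].to_numpy(float),
        trait=trait or Path(path).stem,
    )


def write_genotypes(panel: GenotypePanel, dosage_path, meta_path) -> None:
    dm = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    dm.insert(0, "participant_id", panel.individual_ids)
    dm.to_csv(dosage_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "EA": panel.effect_alleles,
            "POS": panel.positions,
            "BLOCK": panel.ld_blocks,
            "MAF": panel.mafs,
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_genotypes(dosage_path, meta_path) -> GenotypePanel:
    dm = pd.read_csv(dosage_path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"SNP": str, "EA": str})
    ids = dm["participant_id"].to_numpy(str)
    dosages = dm.drop(columns="participant_id").to_numpy(float)
    snp_ids = meta["SNP"].to_numpy()
    if list(dm.columns[1:]) != list(snp_ids):
        raise ValueError("dosage matrix columns and SNP metadata rows disagree")
    return GenotypePanel(
        dosages=dosages,
        snp_ids=snp_ids,
        effect_alleles=meta["EA"].to_numpy(),
        positions=meta["POS"].to_numpy(int),
        ld_blocks=meta["BLOCK"].to_numpy(int),
        mafs=meta["MAF"].to_numpy(float),
        individual_ids=ids,
    )


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "wave": str, "site": str})
    df["present"] = df["present"].astype(bool)
    return df
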