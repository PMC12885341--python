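"""Configuration objects for the synthetic cohort and pipeline runs.

The synthetic cohort is governed by :class:`TrueModelConfig`, which pins down the
full data-generating process: genotype architecture (minor-allele frequencies, LD
blocks, SNP effect classes), the discovery-GWAS noise scale, the standardized
panel-VAR coefficients that link depression and the two alcohol-use measures
across four assessment waves, the mediator paths, and the attrition model.
All lag coefficients are standardized: every phenotype is calibrated to unit
variance at every wave, so a configured coefficient is directly comparable to a
standardized path estimate from downstream models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigurationError

WAVES = ("BL", "FU1", "FU2", "FU3")


@dataclass
class MediatorPaths:
    """Standardized serial-mediation paths.

    ``a``   depression -> first mediator (hopelessness),
    ``d21`` first mediator -> second mediator (impulsivity),
    ``b``   second mediator -> next-wave alcohol-use problems.
    """

    a: float = 0.30
    d21: float = 0.35
    b: float = 0.25


@dataclass
class TrueModelConfig:
    """Ground-truth parameters of the synthetic cohort.

    Defaults encode a "self-medication" scenario: depression raises later
    alcohol-use problems (positive cross-lag) while alcohol consumption lowers
    later depression (negative cross-lag), with genetic effects entering each
    trait through its own true polygenic score.
    """

    n_individuals: int = 2000
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_exposure_only: float = 0.20
    frac_outcome_only: float = 0.20
    frac_pleiotropic: float = 0.10
    gwas_n: int = 75_000
    h2_exposure: float = 0.09
    h2_outcome: float = 0.09
    ar_depression: float = 0.35
    ar_alcohol: float = 0.40
    cross_dep_to_alc: float = 0.15
    cross_alc_to_dep: float = -0.10
    mediator_paths: MediatorPaths = field(default_factory=MediatorPaths)
    attrition_per_wave: tuple[float, float, float] = (0.20, 0.12, 0.12)
    attrition_male_logodds: float = 0.35
    attrition_alcohol_logodds: float = 0.25
    ld_block_size: int = 10
    ld_block_rho: float = 0.8
    n_sites: int = 8
    sex_effect_depression: float = -0.10  # males (coded 1) lower
    sex_effect_alcohol: float = 0.15
    site_effect_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be positive")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("frac_exposure_only", "frac_outcome_only", "frac_pleiotropic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_exposure_only + self.frac_outcome_only + self.frac_pleiotropic > 1.0 + 1e-12:
            raise ConfigurationError("frac_exposure_only + frac_outcome_only + frac_pleiotropic must be <= 1")
        if self.gwas_n < 1:
            raise ConfigurationError("gwas_n must be positive")
        for name in ("h2_exposure", "h2_outcome"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        for p in self.attrition_per_wave:
            if not (0.0 <= p < 1.0):
                raise ConfigurationError("attrition_per_wave probabilities must be in [0, 1)")
        if isinstance(self.mediator_paths, dict):
            self.mediator_paths = MediatorPaths(**self.mediator_paths)
        mp = self.mediator_paths
        if abs(mp.a) >= 1 or abs(mp.d21) >= 1:
            raise ConfigurationError("mediator_paths a and d21 must have magnitude < 1")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_block_rho < 1.0):
            raise ConfigurationError("ld_block_rho must be in [0, 1)")
        rad = self.spectral_radius()
        if rad >= 1.0:
            raise ConfigurationError(
                f"lag coefficients are non-stationary (spectral radius {rad:.3f} >= 1): "
                "check ar_depression/ar_alcohol/cross_dep_to_alc/cross_alc_to_dep"
            )

    def lag_matrix(self) -> np.ndarray:
        """Transition matrix over (depression, consumption, problems)."""
        mp = self.mediator_paths
        # mediators are contemporaneous functions of depression, so the total
        # depression -> problems lag equals cross_dep_to_alc by construction
        return np.array(
            [
                [self.ar_depression, self.cross_alc_to_dep, 0.0],
                [0.0, self.ar_alcohol, 0.0],
                [self.cross_dep_to_alc, 0.0, self.ar_alcohol],
            ]
        )

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.lag_matrix()))))

    def snp_class_counts(self) -> dict[str, int]:
        """SNPs per class by the largest-remainder rule (totals exact)."""
        m = self.n_snps
        frac_null = 1.0 - (self.frac_exposure_only + self.frac_outcome_only + self.frac_pleiotropic)
        fracs = {
            "exposure": self.frac_exposure_only,
            "outcome": self.frac_outcome_only,
            "pleiotropic": self.frac_pleiotropic,
            "null": max(frac_null, 0.0),
        }
        raw = {k: v * m for k, v in fracs.items()}
        counts = {k: int(np.floor(v + 1e-9)) for k, v in raw.items()}
        remainder = {k: raw[k] - counts[k] for k in raw}
        short = m - sum(counts.values())
        for k in sorted(raw, key=lambda k: (-remainder[k], k)):
            if short <= 0:
                break
            counts[k] += 1
            short -= 1
        return counts

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["attrition_per_wave"] = list(self.attrition_per_wave)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrueModelConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "attrition_per_wave" in d:
            d["attrition_per_wave"] = tuple(d["attrition_per_wave"])
        if isinstance(d.get("mediator_paths"), dict):
            d["mediator_paths"] = MediatorPaths(**d["mediator_paths"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrueModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "TrueModelConfig":
        return dataclasses.replace(self, **kw)


def self_medication_config(n_individuals: int = 2000, n_snps: int = 1000, seed: int = 0, **kw) -> TrueModelConfig:
    """Default scenario: depression -> problems positive, consumption -> depression negative."""
    return TrueModelConfig(n_individuals=n_individuals, n_snps=n_snps, seed=seed, **kw)


def null_config(n_individuals: int = 1000, n_snps: int = 300, seed: int = 0, **kw) -> TrueModelConfig:
    """Null scenario for size checks: no depression -> alcohol-problems path of any
    kind (cross-lag and mediated), and no pleiotropic SNPs, so the MDD instrument
    is independent of alcohol-use problems by construction."""
    kw.setdefault("cross_dep_to_alc", 0.0)
    kw.setdefault("frac_pleiotropic", 0.0)
    kw.setdefault("mediator_paths", MediatorPaths(a=0.30, d21=0.35, b=0.0))
    return TrueModelConfig(n_individuals=n_individuals, n_snps=n_snps, seed=seed, **kw)
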