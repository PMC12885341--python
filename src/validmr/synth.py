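"""Synthetic cohort generator with known causal structure.

Three stages share one :class:`~validmr.config.TrueModelConfig`:

* :func:`simulate_genotypes` — biallelic dosages in blocks of correlated SNPs
  (Gaussian copula with exchangeable latent correlation inside each block,
  independence across blocks), Hardy–Weinberg marginals per SNP.
* :func:`simulate_gwas_pair` — two discovery-GWAS summary tables for an
  exposure and an outcome trait. Each SNP belongs to a hidden class
  (exposure-only / outcome-only / pleiotropic / null); estimated effects are
  the true per-allele effects plus Gaussian estimation noise with variance
  1 / (gwas_n * 2*MAF*(1-MAF)), and p-values come from the Wald statistic.
* :func:`simulate_phenotypes` — a four-wave long-format phenotype panel
  following a standardized panel VAR over (depression, alcohol consumption,
  alcohol-use problems) with per-wave genetic injection through the true
  polygenic scores, contemporaneous mediators downstream of depression, sex
  and site covariate effects, and monotone missing-at-random attrition driven
  by sex and baseline alcohol consumption.

The three stages use disjoint deterministic substreams of ``cfg.seed``, so the
hidden genetic architecture is identical between the GWAS tables and the
phenotypes without threading private state between calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import WAVES, TrueModelConfig
from .exceptions import ConfigurationError, DimensionError

# substream tags (seed sequences are spawned as default_rng([tag, seed]))
_STREAM_GENO = 11
_STREAM_ARCH = 17
_STREAM_GWAS = 23
_STREAM_PHENO = 31

_ALLELES = np.array(["A", "G", "C", "T"])

PHENOTYPE_COLUMNS = (
    "depression",
    "alcohol_consumption",
    "alcohol_problems",
    "hopelessness",
    "impulsivity",
    "anxiety",
    "neuroticism",
)


def _rng(cfg: TrueModelConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([tag, cfg.seed])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with SNP metadata and an LD proxy."""

    dosages: np.ndarray  # (n, m) values in [0, 2]
    snp_ids: np.ndarray
    effect_alleles: np.ndarray
    positions: np.ndarray  # monotone integer coordinates
    ld_blocks: np.ndarray  # block index per SNP
    mafs: np.ndarray
    individual_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.individual_ids is None:
            self.individual_ids = np.array([f"S{i:06d}" for i in range(self.dosages.shape[0])])
        if len(np.unique(self.snp_ids)) != len(self.snp_ids):
            raise DimensionError("snp_ids must be unique")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise DimensionError("dosage column count must equal number of SNP ids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise DimensionError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column_index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            from .exceptions import UnknownSNPError

            raise UnknownSNPError(f"SNP id not in panel: {exc.args[0]!r}") from None


@dataclass
class GwasSummary:
    """Per-SNP association table for one trait (PLINK-association dialect).

    ``true_beta`` and ``snp_class`` carry the hidden simulation truth for
    testing; they are ``None`` for tables read from disk.
    """

    snp_id: np.ndarray
    effect_allele: np.ndarray
    beta: np.ndarray
    p: np.ndarray
    trait: str = ""
    true_beta: np.ndarray | None = None
    snp_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id)
        self.beta = np.asarray(self.beta, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(np.unique(self.snp_id)) != len(self.snp_id):
            raise DimensionError("GWAS snp_ids must be unique")
        if not np.all(np.isfinite(self.beta)):
            raise DimensionError("GWAS betas must be finite")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise DimensionError("GWAS p-values must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SNP": self.snp_id, "EA": self.effect_allele, "BETA": self.beta, "P": self.p}
        )


@dataclass
class PhenotypeTruth:
    """Hidden generating quantities kept for tests: true standardized polygenic
    scores and the pre-attrition phenotype matrices per wave."""

    g_exposure: np.ndarray
    g_outcome: np.ndarray
    full_panel: pd.DataFrame  # pre-attrition long panel


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: TrueModelConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw dosages as Binomial(2, MAF) per SNP via a Gaussian copula.

    SNPs are grouped into consecutive blocks of ``cfg.ld_block_size``; within a
    block the latent Gaussians share an exchangeable correlation
    ``cfg.ld_block_rho`` (one common factor per block), across blocks they are
    independent. Marginals are exactly Hardy–Weinberg.
    """
    cfg.validate()
    if rng is None:
        rng = _rng(cfg, _STREAM_GENO)
    n, m = cfg.n_individuals, cfg.n_snps
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    n_blocks = int(np.ceil(m / cfg.ld_block_size))
    blocks = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:m]
    rho = cfg.ld_block_rho
    common = rng.standard_normal((n, n_blocks))
    idio = rng.standard_normal((n, m))
    z = np.sqrt(rho) * common[:, blocks] + np.sqrt(1.0 - rho) * idio
    u = special.ndtr(z)
    # binomial(2, maf) quantile: thresholds P(X=0) and P(X<=1)
    p0 = (1.0 - mafs) ** 2
    p01 = 1.0 - mafs**2
    dosages = (u > p0).astype(float) + (u > p01)
    # unambiguous (non-palindromic) allele pairs: effect allele A or C paired with G/T
    effect_alleles = rng.choice(_ALLELES, size=m)
    panel = GenotypePanel(
        dosages=dosages,
        snp_ids=np.array([f"rs{i + 1:06d}" for i in range(m)]),
        effect_alleles=effect_alleles,
        positions=(np.arange(m, dtype=int) + 1) * 10_000,
        ld_blocks=blocks,
        mafs=mafs,
    )
    return panel


# ---------------------------------------------------------------------------
# hidden architecture (shared between GWAS and phenotypes)
# ---------------------------------------------------------------------------


@dataclass
class _Architecture:
    classes: np.ndarray  # str per SNP
    u_exposure: np.ndarray  # standardized-genotype effects
    u_outcome: np.ndarray


def _architecture(cfg: TrueModelConfig) -> _Architecture:
    """Hidden SNP classes and true joint effects.

    Classes are laid out block-coherently: causal loci of the two traits
    occupy disjoint LD blocks except for the explicitly pleiotropic class
    (mirroring the sparse colocalization of distinct traits' hits relative to
    LD-block size), with the block order randomly permuted. Counts per class
    are exact; only class-boundary blocks can mix classes.
    """
    rng = _rng(cfg, _STREAM_ARCH)
    counts = cfg.snp_class_counts()
    labels = np.concatenate(
        [
            np.repeat("exposure", counts["exposure"]),
            np.repeat("outcome", counts["outcome"]),
            np.repeat("pleiotropic", counts["pleiotropic"]),
            np.repeat("null", counts["null"]),
        ]
    )
    bs = cfg.ld_block_size
    n_blocks = int(np.ceil(cfg.n_snps / bs))
    block_order = rng.permutation(n_blocks)
    labels = np.concatenate([labels[b * bs : (b + 1) * bs] for b in block_order])
    exp_causal = np.flatnonzero((labels == "exposure") | (labels == "pleiotropic"))
    out_causal = np.flatnonzero((labels == "outcome") | (labels == "pleiotropic"))
    u_exp = np.zeros(cfg.n_snps)
    u_out = np.zeros(cfg.n_snps)
    if exp_causal.size:
        u_exp[exp_causal] = rng.normal(0.0, np.sqrt(cfg.h2_exposure / exp_causal.size), exp_causal.size)
    if out_causal.size:
        u_out[out_causal] = rng.normal(0.0, np.sqrt(cfg.h2_outcome / out_causal.size), out_causal.size)
    return _Architecture(classes=labels, u_exposure=u_exp, u_outcome=u_out)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def simulate_gwas_pair(
    cfg: TrueModelConfig,
    panel: GenotypePanel,
    rng: np.random.Generator | None = None,
) -> tuple[GwasSummary, GwasSummary]:
    """Emulate a discovery GWAS pair for the exposure and outcome traits.

    GWAS report *marginal* per-SNP associations, so the true effect each SNP's
    estimate centres on is the joint effect projected through the local LD:
    within each block, u_marginal = R @ u_joint with R the empirical dosage
    correlation matrix of the block (blocks are independent). Estimated
    per-allele effect = marginal true effect + N(0, 1/(gwas_n * 2*MAF*(1-MAF)));
    two-sided p from the Wald z. Hidden class labels and true marginal effects
    ride along on the returned tables for testing.
    """
    cfg.validate()
    if panel.n_snps != cfg.n_snps:
        raise DimensionError(
            f"panel has {panel.n_snps} SNPs but config specifies {cfg.n_snps}"
        )
    if rng is None:
        rng = _rng(cfg, _STREAM_GWAS)
    arch = _architecture(cfg)
    geno_var = 2.0 * panel.mafs * (1.0 - panel.mafs)
    sd_g = np.sqrt(geno_var)
    se = 1.0 / np.sqrt(cfg.gwas_n * geno_var)

    def marginalize(u: np.ndarray) -> np.ndarray:
        out = np.empty_like(u)
        for block in np.unique(panel.ld_blocks):
            idx = np.flatnonzero(panel.ld_blocks == block)
            if idx.size == 1:
                out[idx] = u[idx]
                continue
            R = np.corrcoef(panel.dosages[:, idx], rowvar=False)
            out[idx] = R @ u[idx]
        return out

    def one(u: np.ndarray, trait: str) -> GwasSummary:
        beta_true = marginalize(u) / sd_g  # per-allele marginal scale
        beta_hat = beta_true + rng.normal(0.0, se)
        z = beta_hat / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        return GwasSummary(
            snp_id=panel.snp_ids.copy(),
            effect_allele=panel.effect_alleles.copy(),
            beta=beta_hat,
            p=p,
            trait=trait,
            true_beta=beta_true,
            snp_class=arch.classes.copy(),
        )

    return one(arch.u_exposure, "exposure"), one(arch.u_outcome, "outcome")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def true_polygenic_scores(cfg: TrueModelConfig, panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance true polygenic scores of the exposure and outcome traits."""
    arch = _architecture(cfg)
    sd_g = np.sqrt(2.0 * panel.mafs * (1.0 - panel.mafs))
    z = (panel.dosages - 2.0 * panel.mafs) / sd_g

    def score(u: np.ndarray) -> np.ndarray:
        # standardized empirically: under LD the score variance is u'Ru, not |u|^2
        g = z @ u
        sd = g.std()
        if sd == 0:
            return np.zeros(panel.n_individuals)
        return (g - g.mean()) / sd

    return score(arch.u_exposure), score(arch.u_outcome)


def _calibrated_step(linpart: np.ndarray, rng: np.random.Generator, floor: float = 0.02) -> np.ndarray:
    """Add innovation noise scaled so the result has (sample) unit variance."""
    v = float(np.var(linpart))
    resid = 1.0 - v
    if resid < floor:
        raise ConfigurationError(
            f"systematic variance {v:.3f} leaves residual < {floor}; "
            "coefficient set is too strong for unit-variance calibration"
        )
    return linpart + np.sqrt(resid) * rng.standard_normal(linpart.shape[0])


def simulate_phenotypes(
    cfg: TrueModelConfig,
    panel: GenotypePanel,
    rng: np.random.Generator | None = None,
    attrition: bool = True,
    return_truth: bool = False,
):
    """Generate the four-wave long-format phenotype panel.

    Structural equations per transition t -> t+1 (all variables ~ unit variance):

    .. code-block:: text

        dep'   = ar_dep * dep + cross_alc_to_dep * cons + g_d*G_dep + sex/site + e
        cons'  = ar_alc * cons + g_a*G_alc + sex/site + e
        probs' = ar_alc * probs + (cross_dep_to_alc - b*d21*a) * dep
                 + b * impulsivity + site + e

    with contemporaneous mediators ``hopelessness = a*dep + e`` and
    ``impulsivity = d21*hopelessness + e`` (so the total standardized
    depression -> problems lag equals ``cross_dep_to_alc`` exactly). Baseline is
    produced after two burn-in transitions, so BL already reflects the causal
    structure. Attrition is monotone and missing-at-random given sex and
    baseline alcohol consumption.
    """
    cfg.validate()
    if panel.n_snps != cfg.n_snps:
        raise DimensionError(
            f"panel has {panel.n_snps} SNPs but config specifies {cfg.n_snps}"
        )
    if panel.n_individuals != cfg.n_individuals:
        raise DimensionError(
            f"panel has {panel.n_individuals} individuals but config specifies {cfg.n_individuals}"
        )
    if rng is None:
        rng = _rng(cfg, _STREAM_PHENO)
    n = cfg.n_individuals
    mp = cfg.mediator_paths
    g_d = np.sqrt(cfg.h2_exposure)
    g_a = np.sqrt(cfg.h2_outcome)
    g_exp, g_out = true_polygenic_scores(cfg, panel)

    sex = rng.integers(0, 2, size=n)  # 1 = male
    site = rng.integers(0, cfg.n_sites, size=n)
    site_eff = {
        k: rng.normal(0.0, cfg.site_effect_sd, cfg.n_sites)[site]
        for k in ("depression", "alcohol_consumption", "alcohol_problems")
    }
    sex_c = sex - 0.5

    forcing_dep = g_d * g_exp + cfg.sex_effect_depression * sex_c + site_eff["depression"]
    forcing_cons = g_a * g_out + cfg.sex_effect_alcohol * sex_c + site_eff["alcohol_consumption"]
    forcing_probs = 0.5 * cfg.sex_effect_alcohol * sex_c + site_eff["alcohol_problems"]

    def mediators(dep: np.ndarray) -> dict[str, np.ndarray]:
        hop = mp.a * dep + np.sqrt(1.0 - mp.a**2) * rng.standard_normal(n)
        imp = mp.d21 * hop + np.sqrt(1.0 - mp.d21**2) * rng.standard_normal(n)
        anx = 0.40 * dep + np.sqrt(1.0 - 0.40**2) * rng.standard_normal(n)
        neu = 0.45 * dep + np.sqrt(1.0 - 0.45**2) * rng.standard_normal(n)
        return {"hopelessness": hop, "impulsivity": imp, "anxiety": anx, "neuroticism": neu}

    cross_direct = cfg.cross_dep_to_alc - mp.b * mp.d21 * mp.a

    # initial state (two transitions before baseline)
    dep = _calibrated_step(forcing_dep, rng)
    cons = _calibrated_step(forcing_cons, rng)
    probs = _calibrated_step(forcing_probs, rng)
    med = mediators(dep)

    n_burnin = 2
    records: list[dict[str, np.ndarray]] = []
    for step in range(n_burnin + len(WAVES) - 1 + 1):
        if step > 0:
            new_dep = _calibrated_step(
                cfg.ar_depression * dep + cfg.cross_alc_to_dep * cons + forcing_dep, rng
            )
            new_cons = _calibrated_step(cfg.ar_alcohol * cons + forcing_cons, rng)
            new_probs = _calibrated_step(
                cfg.ar_alcohol * probs
                + cross_direct * dep
                + mp.b * med["impulsivity"]
                + forcing_probs,
                rng,
            )
            dep, cons, probs = new_dep, new_cons, new_probs
            med = mediators(dep)
        if step >= n_burnin:
            records.append(
                {
                    "depression": dep.copy(),
                    "alcohol_consumption": cons.copy(),
                    "alcohol_problems": probs.copy(),
                    **{k: v.copy() for k, v in med.items()},
                }
            )

    # attrition: monotone dropout, log-odds offsets for male sex and baseline alcohol
    present = np.ones((n, len(WAVES)), dtype=bool)
    if attrition:
        cons_bl = records[0]["alcohol_consumption"]
        cons_bl_z = (cons_bl - cons_bl.mean()) / cons_bl.std()
        for w, p_drop in enumerate(cfg.attrition_per_wave, start=1):
            if p_drop <= 0:
                continue
            base = np.log(p_drop / (1.0 - p_drop))
            logit = (
                base
                + cfg.attrition_male_logodds * (sex - 0.5)
                + cfg.attrition_alcohol_logodds * cons_bl_z
            )
            drop = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
            present[:, w] = present[:, w - 1] & ~drop

    ids = panel.individual_ids
    rows = []
    for w, wave in enumerate(WAVES):
        rec = records[w]
        df = pd.DataFrame({"participant_id": ids, "wave": wave})
        for col in PHENOTYPE_COLUMNS:
            vals = rec[col].astype(float).copy()
            vals[~present[:, w]] = np.nan
            df[col] = vals
        df["sex"] = sex
        df["site"] = np.array([f"site{s + 1}" for s in site])
        df["present"] = present[:, w]
        rows.append(df)
    long = pd.concat(rows, ignore_index=True)

    if return_truth:
        full_rows = []
        for w, wave in enumerate(WAVES):
            df = pd.DataFrame({"participant_id": ids, "wave": wave})
            for col in PHENOTYPE_COLUMNS:
                df[col] = records[w][col]
            df["sex"] = sex
            df["site"] = np.array([f"site{s + 1}" for s in site])
            df["present"] = True
            full_rows.append(df)
        truth = PhenotypeTruth(
            g_exposure=g_exp, g_outcome=g_out, full_panel=pd.concat(full_rows, ignore_index=True)
        )
        return long, truth
    return long


def simulate_cohort(cfg: TrueModelConfig, attrition: bool = True):
    """Convenience: genotypes + GWAS pair + phenotype panel under one config."""
    panel = simulate_genotypes(cfg)
    exposure, outcome = simulate_gwas_pair(cfg, panel)
    phenos = simulate_phenotypes(cfg, panel, attrition=attrition)
    return panel, exposure, outcome, phenos


# ---------------------------------------------------------------------------
# standalone mediation generator (linear-Gaussian recursive system)
# ---------------------------------------------------------------------------


def simulate_mediation_data(
    n: int,
    a1: float,
    d21: float,
    b2: float,
    direct: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """x -> m1 -> m2 -> y recursive linear-Gaussian system with unit-variance
    exogenous noise; serial indirect effect is exactly ``a1 * d21 * b2``."""
    rng = np.random.default_rng([41, seed])
    x = rng.standard_normal(n)
    m1 = a1 * x + rng.standard_normal(n)
    m2 = d21 * m1 + rng.standard_normal(n)
    y = b2 * m2 + direct * x + rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
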