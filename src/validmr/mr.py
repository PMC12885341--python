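"""Longitudinal Mendelian-randomization permutation test.

The observed statistic is the mean (``r_mean``) of the Pearson correlations
between each valid-PRS threshold column and the phenotype at each assessment
wave — a 10 x 4 grid of r-values under the default threshold grid. The null
distribution of ``r_mean`` is built by reshuffling the union of participant ids
identically across waves: each permutation reassigns whole phenotype records
(values and per-wave missingness travel together, within-person linkage is
preserved) while the instrument scores stay attached to their genotypes. The
two-sided empirical p-value uses the add-one form (1 + #{|null| >= |obs|}) /
(B + 1).

Stage-1 instrument validation runs the identical machinery against the
exposure's own phenotype: a valid instrument must correlate with its exposure
before any causal claim about the outcome is made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import WAVES
from .exceptions import (
    DegenerateInstrumentError,
    InstrumentValidationError,
    UnknownColumnError,
)
from .instruments import InstrumentGrid

logger = logging.getLogger(__name__)

MIN_PAIRS = 3


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, covariates: list[str], wave: str) -> np.ndarray | None:
    """Intercept + numeric covariates + indicator contrasts for categoricals.

    Covariates constant within the wave are dropped with a warning.
    """
    cols = [np.ones(len(df))]
    for cov in covariates:
        if cov not in df.columns:
            raise UnknownColumnError(f"covariate {cov!r} not in panel")
        s = df[cov]
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                logger.warning("covariate %r is constant within wave %s; dropped", cov, wave)
                continue
            cols.append(dummies.to_numpy())
        else:
            v = s.to_numpy(dtype=float)
            if np.nanstd(v) == 0:
                logger.warning("covariate %r is constant within wave %s; dropped", cov, wave)
                continue
            cols.append(v[:, None])
    return np.column_stack(cols)


def residualize(
    phenos: pd.DataFrame,
    covariates: list[str] = ("sex", "site"),
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Replace each phenotype column, per wave, by least-squares residuals on
    the covariates among rows where the value is observed. Missingness is
    preserved."""
    covariates = list(covariates)
    out = phenos.copy()
    if columns is None:
        reserved = {"participant_id", "wave", "present", *covariates}
        columns = [
            c
            for c in phenos.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(phenos[c])
        ]
    for wave, idx in phenos.groupby("wave", sort=False).groups.items():
        sub = phenos.loc[idx]
        X_full = _design(sub, covariates, str(wave))
        for col in columns:
            y = sub[col].to_numpy(dtype=float)
            mask = np.isfinite(y)
            if mask.sum() <= X_full.shape[1]:
                continue
            X = X_full[mask]
            beta, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
            resid = np.full_like(y, np.nan)
            resid[mask] = y[mask] - X @ beta
            out.loc[idx, col] = resid
    return out


# ---------------------------------------------------------------------------
# the r grid
# ---------------------------------------------------------------------------


@dataclass
class RGrid:
    """Correlation grid (thresholds x waves) with pairwise-complete counts."""

    values: np.ndarray
    n_pairs: np.ndarray
    thresholds: tuple[float, ...]
    waves: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.thresholds), columns=list(self.waves))

    @property
    def r_mean(self) -> float:
        return float(np.nanmean(self.values))

    def wave_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)


def panel_to_wide(
    phenos: pd.DataFrame, column: str, ids: np.ndarray, waves: tuple[str, ...] = WAVES
) -> np.ndarray:
    """Union-id x wave matrix of one phenotype (NaN where unobserved)."""
    if column not in phenos.columns:
        raise UnknownColumnError(f"phenotype {column!r} not in panel")
    # pivot (not pivot_table) so duplicate (participant, wave) rows raise
    wide = phenos.pivot(index="participant_id", columns="wave", values=column)
    wide = wide.reindex(index=pd.Index(ids), columns=list(waves))
    return wide.to_numpy(dtype=float)


def _grid_corr(scores: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between every score column and every wave column of Y,
    pairwise-complete over rows where the wave's phenotype is observed."""
    T = scores.shape[1]
    W = Y.shape[1]
    vals = np.full((T, W), np.nan)
    n_pairs = np.zeros((T, W), dtype=int)
    score_ok = np.isfinite(scores).all(axis=0)
    for w in range(W):
        y = Y[:, w]
        mask = np.isfinite(y)
        n = int(mask.sum())
        n_pairs[:, w] = n
        if n < MIN_PAIRS:
            continue
        ym = y[mask]
        yc = ym - ym.mean()
        ynorm = np.sqrt((yc**2).sum())
        if ynorm == 0:
            continue
        S = scores[mask][:, score_ok]
        Sc = S - S.mean(axis=0)
        snorm = np.sqrt((Sc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Sc.T @ yc) / (snorm * ynorm)
        r[snorm == 0] = np.nan
        vals[score_ok, w] = r
    return vals, n_pairs


def correlate_grid(
    grid: InstrumentGrid,
    phenos: pd.DataFrame,
    phenotype: str,
    waves: tuple[str, ...] = WAVES,
) -> RGrid:
    """Observed instrument-phenotype correlation grid."""
    Y = panel_to_wide(phenos, phenotype, grid.individual_ids, waves)
    vals, n_pairs = _grid_corr(grid.scores, Y)
    return RGrid(values=vals, n_pairs=n_pairs, thresholds=grid.thresholds, waves=tuple(waves))


# ---------------------------------------------------------------------------
# union-id permutation
# ---------------------------------------------------------------------------


def permute_union_ids(
    phenos: pd.DataFrame,
    rng: np.random.Generator,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Reassign whole phenotype records by a single permutation of the union of
    participant ids, applied identically at every wave.

    Participant identity (and so the attached instrument score, sex, site)
    stays put; the phenotype record — values of all phenotype columns plus the
    per-wave presence flag — moves. Within-person linkage across waves travels
    with the permuted records.
    """
    ids = np.unique(phenos["participant_id"].to_numpy())
    perm = rng.permutation(len(ids))
    source_of = dict(zip(ids, ids[perm]))
    if columns is None:
        exclude = {"participant_id", "wave", "sex", "site"}
        columns = [c for c in phenos.columns if c not in exclude]
    out = phenos.copy()
    for wave, idx in phenos.groupby("wave", sort=False).groups.items():
        sub = phenos.loc[idx].set_index("participant_id")
        donors = [source_of[p] for p in phenos.loc[idx, "participant_id"]]
        out.loc[idx, columns] = sub.loc[donors, columns].to_numpy()
    return out


# ---------------------------------------------------------------------------
# the permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationTestResult:
    observed: RGrid
    r_mean_observed: float
    null_r_means: np.ndarray
    p_longitudinal: float
    per_wave: pd.DataFrame  # wave, r_mean, p
    n_permutations: int
    seed: int
    phenotype: str = ""

    @property
    def significant(self) -> bool:
        return self.p_longitudinal < 0.05

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "r_mean_observed": self.r_mean_observed,
            "p_longitudinal": self.p_longitudinal,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "per_wave": self.per_wave.to_dict(orient="records"),
            "observed_grid": self.observed.to_frame().to_dict(),
            "null_r_means": self.null_r_means.tolist(),
        }


def _empirical_p(observed: float, null: np.ndarray) -> float:
    null = null[np.isfinite(null)]
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (len(null) + 1))


def longitudinal_test(
    grid: InstrumentGrid,
    phenos: pd.DataFrame,
    phenotype: str,
    B: int = 1000,
    seed: int = 0,
    waves: tuple[str, ...] = WAVES,
) -> PermutationTestResult:
    """Observed r_mean of the threshold x wave grid against its union-id
    permutation null."""
    if B < 100:
        raise ValueError("B must be at least 100 for a usable empirical null")
    Y = panel_to_wide(phenos, phenotype, grid.individual_ids, waves)
    obs_vals, n_pairs = _grid_corr(grid.scores, Y)
    if not np.isfinite(obs_vals).any():
        raise DegenerateInstrumentError(
            "all grid cells are degenerate; no observed r_mean exists"
        )
    observed = RGrid(values=obs_vals, n_pairs=n_pairs, thresholds=grid.thresholds, waves=tuple(waves))
    r_obs = observed.r_mean
    wave_obs = observed.wave_means()

    rng = np.random.default_rng(seed)
    n_union = Y.shape[0]
    null_means = np.empty(B)
    null_wave = np.empty((B, len(waves)))
    for b in range(B):
        perm = rng.permutation(n_union)
        vals, _ = _grid_corr(grid.scores, Y[perm])
        with np.errstate(invalid="ignore"):
            null_means[b] = np.nanmean(vals)
            null_wave[b] = np.nanmean(vals, axis=0)

    p_long = _empirical_p(r_obs, null_means)
    per_wave = pd.DataFrame(
        {
            "wave": list(waves),
            "r_mean": wave_obs,
            "p": [
                _empirical_p(wave_obs[w], null_wave[:, w]) if np.isfinite(wave_obs[w]) else np.nan
                for w in range(len(waves))
            ],
        }
    )
    return PermutationTestResult(
        observed=observed,
        r_mean_observed=r_obs,
        null_r_means=null_means,
        p_longitudinal=p_long,
        per_wave=per_wave,
        n_permutations=B,
        seed=seed,
        phenotype=phenotype,
    )


def validate_instrument(
    grid: InstrumentGrid,
    phenos: pd.DataFrame,
    exposure_phenotype: str,
    B: int = 1000,
    seed: int = 0,
    waves: tuple[str, ...] = WAVES,
) -> PermutationTestResult:
    """Stage-1 check: the instrument must correlate with its own exposure
    phenotype longitudinally before any causal inference is meaningful."""
    return longitudinal_test(grid, phenos, exposure_phenotype, B=B, seed=seed, waves=waves)


class LongitudinalMRTest(BaseEstimator):
    """Two-stage longitudinal MR: validate the instrument against the exposure
    phenotype, then test it against the outcome phenotype.

    Parameters
    ----------
    exposure_phenotype, outcome_phenotype : str
        Panel columns for the stage-1 validation and stage-2 causal test.
    B : int
        Number of union-id permutations (field-standard default 1000).
    alpha_stage1 : float
        Significance level the stage-1 longitudinal p must beat.
    force : bool
        Run stage-2 even if validation fails (logged); for sensitivity runs.

    Attributes (after ``fit``)
    --------------------------
    validation_ : PermutationTestResult for the exposure phenotype.
    causal_ : PermutationTestResult for the outcome phenotype.
    r_mean_ : observed stage-2 r_mean.  p_value_ : stage-2 longitudinal p.
    """

    def __init__(
        self,
        exposure_phenotype: str,
        outcome_phenotype: str,
        B: int = 1000,
        seed: int = 0,
        alpha_stage1: float = 0.05,
        force: bool = False,
        waves: tuple[str, ...] = WAVES,
    ) -> None:
        self.exposure_phenotype = exposure_phenotype
        self.outcome_phenotype = outcome_phenotype
        self.B = B
        self.seed = seed
        self.alpha_stage1 = alpha_stage1
        self.force = force
        self.waves = waves

    def fit(self, grid: InstrumentGrid, phenos: pd.DataFrame):
        self.validation_ = validate_instrument(
            grid, phenos, self.exposure_phenotype, B=self.B, seed=self.seed, waves=self.waves
        )
        if not self.validation_.significant:
            msg = (
                f"instrument failed stage-1 validation against "
                f"{self.exposure_phenotype!r} (p={self.validation_.p_longitudinal:.4f})"
            )
            if not self.force:
                raise InstrumentValidationError(msg)
            logger.warning("%s; proceeding because force=True", msg)
        self.causal_ = longitudinal_test(
            grid, phenos, self.outcome_phenotype, B=self.B, seed=self.seed + 1, waves=self.waves
        )
        self.r_mean_ = self.causal_.r_mean_observed
        self.p_value_ = self.causal_.p_longitudinal
        return self
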