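"""Pleiotropy-filtered polygenic-score instruments (valid-PRS).

The instrument for an exposure A against an outcome B is a polygenic score
restricted to SNPs associated with A (p < 0.05) but *not* with B (p > c), for a
grid of purging thresholds c in {0.05, 0.10, ..., 0.50}. Larger c purges more
aggressively. SNPs are LD-clumped greedily (most significant exposure SNP kept,
correlated neighbours within a window removed) before scoring.

Clumping is performed once on the exposure-significant SNP set; the per-c
outcome filter is applied afterwards. This guarantees that the retained set for
a larger c is a subset of the retained set for a smaller c while every retained
SNP still satisfies the selection rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegenerateInstrumentError,
    DegenerateScoreError,
    EmptyIntersectionError,
    UnknownSNPError,
)
from .synth import GenotypePanel, GwasSummary

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(1, 11) * 0.05, 2))
EXPOSURE_P = 0.05
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def harmonize(
    exposure: GwasSummary, outcome: GwasSummary, panel: GenotypePanel
) -> pd.DataFrame:
    """Inner-join the two GWAS tables on SNP id, restricted to panel SNPs.

    Where the outcome's effect allele disagrees with the exposure's, the outcome
    beta is sign-flipped onto the exposure's effect-allele convention. SNPs
    absent from the panel are dropped (count logged).
    """
    exp = exposure.to_frame().rename(
        columns={"EA": "ea_exposure", "BETA": "beta_exposure", "P": "p_exposure"}
    )
    out = outcome.to_frame().rename(
        columns={"EA": "ea_outcome", "BETA": "beta_outcome", "P": "p_outcome"}
    )
    joined = exp.merge(out, on="SNP", how="inner")
    if joined.empty:
        raise EmptyIntersectionError("exposure and outcome GWAS share no SNPs")
    in_panel = joined["SNP"].isin(panel.snp_ids)
    n_dropped = int((~in_panel).sum())
    if n_dropped:
        logger.info("harmonize: dropped %d SNPs absent from the genotype panel", n_dropped)
    joined = joined.loc[in_panel].copy()
    if joined.empty:
        raise EmptyIntersectionError("no overlapping SNPs are present in the genotype panel")
    flip = joined["ea_outcome"].to_numpy() != joined["ea_exposure"].to_numpy()
    joined["beta_outcome"] = np.where(flip, -joined["beta_outcome"], joined["beta_outcome"])
    meta = pd.DataFrame(
        {"SNP": panel.snp_ids, "position": panel.positions, "_order": np.arange(panel.n_snps)}
    )
    joined = joined.merge(meta, on="SNP").sort_values("_order").drop(columns="_order")
    return joined.reset_index(drop=True)


def drop_palindromic(joined: pd.DataFrame) -> pd.DataFrame:
    """Drop strand-ambiguous SNPs (A/T, C/G effect-allele pairs across tables).

    The synthetic generator emits unambiguous harmonized tables; this stub exists
    for externally supplied summary statistics.
    """
    pairs = list(zip(joined["ea_exposure"], joined["ea_outcome"]))
    mask = np.array([p not in _PALINDROMIC for p in pairs])
    return joined.loc[mask].reset_index(drop=True)


def select_valid_snps(joined: pd.DataFrame, c: float, p_exposure: float = EXPOSURE_P) -> list[str]:
    """SNPs associated with the exposure (p < 0.05) but not the outcome (p > c)."""
    if not (0.0 < c <= 0.5):
        warnings.warn(
            f"purging threshold c={c} lies outside the conventional (0, 0.5] grid",
            stacklevel=2,
        )
    keep = (joined["p_exposure"] < p_exposure) & (joined["p_outcome"] > c)
    return joined.loc[keep, "SNP"].tolist()


def clump(
    joined: pd.DataFrame,
    candidate_ids: list[str],
    panel: GenotypePanel,
    r2_max: float = 0.1,
    window: int = 250_000,
) -> list[str]:
    """Greedy LD clumping by ascending exposure p-value.

    Repeatedly keep the remaining SNP with the smallest exposure p (ties broken
    by ascending position, then lexicographic id) and discard all remaining
    SNPs within ``window`` coordinate units whose dosage r-squared with it
    exceeds ``r2_max``.
    """
    if not candidate_ids:
        return []
    sub = joined.set_index("SNP").loc[list(candidate_ids)]
    cols = panel.column_index(sub.index.to_numpy())
    order = np.lexsort((sub.index.to_numpy(), sub["position"].to_numpy(), sub["p_exposure"].to_numpy()))
    pos = sub["position"].to_numpy()
    D = panel.dosages[:, cols]
    Dc = D - D.mean(axis=0)
    denom = np.sqrt((Dc**2).sum(axis=0))
    alive = np.ones(len(order), dtype=bool)
    kept: list[str] = []
    ids = sub.index.to_numpy()
    for k in order:
        if not alive[k]:
            continue
        alive[k] = False
        kept.append(ids[k])
        near = alive & (np.abs(pos - pos[k]) <= window)
        if not near.any():
            continue
        idx = np.flatnonzero(near)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Dc[:, idx].T @ Dc[:, k]) / (denom[idx] * denom[k])
        r2 = np.nan_to_num(r**2, nan=1.0)  # zero-variance SNPs treated as redundant
        alive[idx[r2 > r2_max]] = False
    return kept


def score_prs(
    panel: GenotypePanel,
    snp_ids: list[str],
    betas: np.ndarray,
    standardize: bool = True,
) -> np.ndarray:
    """Weighted allelic score: score_i = sum_j beta_j * dosage_ij.

    Missing dosages are mean-imputed to 2*MAF (column mean). Raises
    :class:`DegenerateScoreError` when standardization is requested but the raw
    score has zero variance (e.g. empty SNP list).
    """
    betas = np.asarray(betas, dtype=float)
    if len(snp_ids) != len(betas):
        raise ValueError("snp_ids and betas must have equal length")
    if len(snp_ids) == 0:
        raw = np.zeros(panel.n_individuals)
    else:
        cols = panel.column_index(snp_ids)
        D = panel.dosages[:, cols]
        if np.isnan(D).any():
            fill = 2.0 * panel.mafs[cols]
            D = np.where(np.isnan(D), fill, D)
        raw = D @ betas
    if not standardize:
        return raw
    sd = raw.std()
    if sd == 0:
        raise DegenerateScoreError("polygenic score has zero variance; cannot standardize")
    return (raw - raw.mean()) / sd


@dataclass
class InstrumentGrid:
    """Per-threshold valid-PRS vectors plus retained-SNP bookkeeping."""

    thresholds: tuple[float, ...]
    retained_snps: dict[float, list[str]]
    scores: np.ndarray  # (n_individuals, n_thresholds); NaN column if degenerate
    exposure_label: str
    outcome_label: str
    individual_ids: np.ndarray
    degenerate: dict[float, bool] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    def assert_monotone(self) -> None:
        """Retained set for larger c must nest inside that for smaller c."""
        ordered = sorted(self.thresholds)
        for small, large in zip(ordered, ordered[1:]):
            if not set(self.retained_snps[large]) <= set(self.retained_snps[small]):
                raise AssertionError(
                    f"retained SNPs at c={large} are not a subset of c={small}"
                )

    def scores_frame(self) -> pd.DataFrame:
        frames = []
        for j, c in enumerate(self.thresholds):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": self.individual_ids,
                        "c": c,
                        "score": self.scores[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def retained_frame(self) -> pd.DataFrame:
        rows = [
            {"c": c, "n_snps": len(snps), "snps": ";".join(snps)}
            for c, snps in self.retained_snps.items()
        ]
        return pd.DataFrame(rows)


class ValidPRSGrid(BaseEstimator, TransformerMixin):
    """Builds the valid-PRS instrument grid from a harmonized GWAS pair.

    Parameters follow common PRS practice: exposure inclusion at p < 0.05 (the
    selection rule's fixed arm), greedy clumping at ``r2_max`` within ``window``
    coordinate units, and standardized scores.

    After :meth:`fit`, ``grid_`` holds the :class:`InstrumentGrid`;
    :meth:`transform` scores a (possibly different) genotype panel with the
    fitted per-threshold SNP weights.
    """

    def __init__(
        self,
        thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
        p_exposure: float = EXPOSURE_P,
        r2_max: float = 0.1,
        window: int = 250_000,
        standardize: bool = True,
    ) -> None:
        self.thresholds = thresholds
        self.p_exposure = p_exposure
        self.r2_max = r2_max
        self.window = window
        self.standardize = standardize

    def fit(self, exposure: GwasSummary, outcome: GwasSummary, panel: GenotypePanel):
        joined = harmonize(exposure, outcome, panel)
        exposure_hits = joined.loc[joined["p_exposure"] < self.p_exposure, "SNP"].tolist()
        clumped = clump(joined, exposure_hits, panel, r2_max=self.r2_max, window=self.window)
        clumped_set = set(clumped)
        betas = joined.set_index("SNP")["beta_exposure"]
        p_out = joined.set_index("SNP")["p_outcome"]
        n = panel.n_individuals
        scores = np.full((n, len(self.thresholds)), np.nan)
        retained: dict[float, list[str]] = {}
        degenerate: dict[float, bool] = {}
        weights: dict[float, pd.Series] = {}
        for j, c in enumerate(self.thresholds):
            snps = [s for s in clumped if p_out[s] > c and s in clumped_set]
            retained[float(c)] = snps
            w = betas.loc[snps]
            weights[float(c)] = w
            try:
                scores[:, j] = score_prs(panel, snps, w.to_numpy(), standardize=self.standardize)
                degenerate[float(c)] = False
            except DegenerateScoreError:
                logger.warning("instrument grid cell c=%.2f is degenerate (no usable SNPs)", c)
                degenerate[float(c)] = True
        if all(degenerate.values()):
            raise DegenerateInstrumentError("every threshold produced a degenerate score")
        self.joined_ = joined
        self.weights_ = weights
        self.grid_ = InstrumentGrid(
            thresholds=tuple(float(c) for c in self.thresholds),
            retained_snps=retained,
            scores=scores,
            exposure_label=exposure.trait or "exposure",
            outcome_label=outcome.trait or "outcome",
            individual_ids=panel.individual_ids,
            degenerate=degenerate,
        )
        self.grid_.assert_monotone()
        return self

    def transform(self, panel: GenotypePanel) -> InstrumentGrid:
        if not hasattr(self, "grid_"):
            raise RuntimeError("ValidPRSGrid must be fitted before transform")
        n = panel.n_individuals
        scores = np.full((n, len(self.thresholds)), np.nan)
        degenerate: dict[float, bool] = {}
        for j, c in enumerate(self.grid_.thresholds):
            w = self.weights_[c]
            try:
                scores[:, j] = score_prs(panel, list(w.index), w.to_numpy(), standardize=self.standardize)
                degenerate[c] = False
            except (DegenerateScoreError, UnknownSNPError):
                degenerate[c] = True
        return InstrumentGrid(
            thresholds=self.grid_.thresholds,
            retained_snps=self.grid_.retained_snps,
            scores=scores,
            exposure_label=self.grid_.exposure_label,
            outcome_label=self.grid_.outcome_label,
            individual_ids=panel.individual_ids,
            degenerate=degenerate,
        )


def build_instrument_grid(
    exposure: GwasSummary,
    outcome: GwasSummary,
    panel: GenotypePanel,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    **kw,
) -> InstrumentGrid:
    """Functional wrapper: select -> clump -> score over the threshold grid."""
    return ValidPRSGrid(thresholds=thresholds, **kw).fit(exposure, outcome, panel).grid_
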