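"""Behavioural correlations, attrition comparisons, and usage summaries.

* :func:`partial_correlation` — Pearson correlation of the least-squares
  residuals of x and y on a conditioning set z, with a Fisher-z confidence
  interval (degrees of freedom adjusted for |z|) and a two-tailed p-value.
* :func:`attrition_compare` — retained-vs-dropped comparisons on baseline
  variables (Welch t for continuous measures, Pearson chi-square for sex).
* :func:`usage_summary` — per-wave prevalence of any alcohol use and the
  count/percentage of complete-data participants who never initiated alcohol
  use, supporting the MR sensitivity exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import WAVES
from .exceptions import ComparisonError, DegenerateInputError, UnknownColumnError


@dataclass
class PartialCorResult:
    r: float
    ci95: tuple[float, float]
    p: float
    n: int
    controlled_for: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "ci95": list(self.ci95),
            "p": self.p,
            "n": self.n,
            "controlled_for": list(self.controlled_for),
        }


def _residuals(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def partial_correlation(
    data: pd.DataFrame, x: str, y: str, z: tuple[str, ...] = ()
) -> PartialCorResult:
    """Partial Pearson correlation of x and y given z on complete cases."""
    z = tuple(z)
    for col in (x, y, *z):
        if col not in data.columns:
            raise UnknownColumnError(f"column {col!r} not in table")
    mat = data[[x, y, *z]].to_numpy(dtype=float)
    mat = mat[np.isfinite(mat).all(axis=1)]
    n, k = mat.shape[0], len(z)
    if n <= k + 3:
        raise DegenerateInputError(f"need more than |z| + 3 = {k + 3} complete cases, got {n}")
    Z = np.column_stack([np.ones(n), mat[:, 2:]])
    rx = _residuals(mat[:, 0], Z)
    ry = _residuals(mat[:, 1], Z)
    if rx.std() < 1e-12 * max(1.0, np.abs(mat[:, 0]).max()) or ry.std() < 1e-12 * max(
        1.0, np.abs(mat[:, 1]).max()
    ):
        raise DegenerateInputError("residual variance is zero after conditioning")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - k - 3)
    ci = (float(np.tanh(zr - 1.959963984540054 * se)), float(np.tanh(zr + 1.959963984540054 * se)))
    return PartialCorResult(r=r, ci95=ci, p=p, n=n, controlled_for=z)


def attrition_compare(
    baseline: pd.DataFrame,
    retained_flag: str,
    continuous: tuple[str, ...] = ("depression", "alcohol_consumption", "alcohol_problems"),
    categorical: tuple[str, ...] = ("sex",),
    welch: bool = True,
) -> pd.DataFrame:
    """Compare retained vs dropped participants on baseline variables.

    One output row per variable: Welch (or pooled) two-sample t for continuous
    measures, Pearson chi-square (no continuity correction) for categoricals.
    """
    flag = baseline[retained_flag].astype(bool)
    if flag.nunique() < 2:
        raise ComparisonError("both retained and dropped groups are required")
    rows = []
    for var in continuous:
        a = baseline.loc[flag, var].dropna()
        b = baseline.loc[~flag, var].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "variable": var,
                "test": "welch-t" if welch else "t",
                "statistic": float(t),
                "p": float(p),
                "mean_retained": float(a.mean()),
                "mean_dropped": float(b.mean()),
            }
        )
    for var in categorical:
        table = pd.crosstab(baseline[var], flag)
        if table.shape[0] < 2:  # constant within this sample (e.g. sex-stratified run)
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append(
            {
                "variable": var,
                "test": "chi2",
                "statistic": float(chi2),
                "p": float(p),
                "mean_retained": float(baseline.loc[flag, var].mean()),
                "mean_dropped": float(baseline.loc[~flag, var].mean()),
            }
        )
    return pd.DataFrame(rows)


def attrition_table(
    phenos: pd.DataFrame,
    continuous: tuple[str, ...] = ("depression", "alcohol_consumption", "alcohol_problems"),
    welch: bool = True,
) -> pd.DataFrame:
    """Retained-vs-dropped comparisons at each follow-up based on baseline data."""
    bl = phenos.loc[phenos["wave"] == "BL"].set_index("participant_id")
    frames = []
    for wave in WAVES[1:]:
        fu = phenos.loc[phenos["wave"] == wave].set_index("participant_id")
        base = bl.copy()
        base["retained"] = fu.loc[base.index, "present"].to_numpy()
        cmp = attrition_compare(base, "retained", continuous=continuous, welch=welch)
        cmp.insert(0, "follow_up", wave)
        frames.append(cmp)
    return pd.concat(frames, ignore_index=True)


@dataclass
class UsageSummary:
    prevalence_by_wave: dict[str, float]  # % with any alcohol use among observed
    n_complete: int
    n_never_initiators: int
    pct_never_initiators: float  # two decimals

    def to_dict(self) -> dict:
        return {
            "prevalence_by_wave": self.prevalence_by_wave,
            "n_complete": self.n_complete,
            "n_never_initiators": self.n_never_initiators,
            "pct_never_initiators": self.pct_never_initiators,
        }


def usage_summary(phenos: pd.DataFrame) -> UsageSummary:
    """Prevalence of any alcohol use per wave and never-initiator counts.

    "Any use" is a total alcohol score (consumption or problems) > 0 at a wave;
    never-initiators are participants with complete data at all waves and no
    alcohol use at any of them.
    """
    any_use = (phenos["alcohol_consumption"] > 0) | (phenos["alcohol_problems"] > 0)
    observed = phenos["present"].astype(bool)
    prevalence = {}
    for wave in WAVES:
        m = (phenos["wave"] == wave) & observed
        prevalence[wave] = round(float(100.0 * any_use[m].mean()), 2) if m.any() else np.nan
    present_all = phenos.groupby("participant_id")["present"].all()
    complete_ids = present_all.index[present_all]
    used = (
        phenos.loc[phenos["participant_id"].isin(complete_ids)]
        .assign(any_use=any_use)
        .groupby("participant_id")["any_use"]
        .any()
    )
    n_complete = int(len(complete_ids))
    n_never = int((~used).sum())
    pct = round(100.0 * n_never / n_complete, 2) if n_complete else np.nan
    return UsageSummary(
        prevalence_by_wave=prevalence,
        n_complete=n_complete,
        n_never_initiators=n_never,
        pct_never_initiators=pct,
    )


def exclude_never_initiators(phenos: pd.DataFrame) -> pd.DataFrame:
    """Drop complete-data participants who never used alcohol at any wave
    (the MR sensitivity exclusion)."""
    any_use = (phenos["alcohol_consumption"] > 0) | (phenos["alcohol_problems"] > 0)
    present_all = phenos.groupby("participant_id")["present"].all()
    complete_ids = set(present_all.index[present_all])
    used = phenos.assign(any_use=any_use).groupby("participant_id")["any_use"].any()
    never = {pid for pid, u in used.items() if not u and pid in complete_ids}
    return phenos.loc[~phenos["participant_id"].isin(never)].reset_index(drop=True)


def wave_summary(
    phenos: pd.DataFrame,
    measures: tuple[str, ...] = ("depression", "alcohol_consumption", "alcohol_problems"),
) -> pd.DataFrame:
    """Mean, SD and n per measure per wave (cohort-characteristics layout)."""
    rows = []
    for wave in WAVES:
        sub = phenos.loc[(phenos["wave"] == wave) & phenos["present"].astype(bool)]
        for m in measures:
            v = sub[m].dropna()
            rows.append(
                {"wave": wave, "measure": m, "mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(v.size)}
            )
    return pd.DataFrame(rows)
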