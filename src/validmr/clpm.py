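"""Two-wave cross-lagged panel model (CLPM) on standardized residualized data.

The saturated two-wave path model regresses each time-(t+1) variable on both
time-t variables (plus any stated time-t controls). For a saturated model the
maximum-likelihood point estimates coincide with per-equation least squares, so
each equation is fitted by OLS on standardized complete cases; standardized
paths are reported with Wald 95% confidence intervals and two-tailed p-values,
plus R^2 per equation as the model-fit summary (a saturated path model has no
omnibus fit indices: df = 0).

Missing data are handled by listwise deletion within the wave pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exceptions import InsufficientDataError, SingularityError, UnknownColumnError

COLLINEARITY_R = 0.999


@dataclass
class ClpmResult:
    """Standardized path estimates for one wave pair."""

    wave_pair: str
    x: str
    y: str
    beta_x_to_y: float
    beta_y_to_x: float
    ar_x: float
    ar_y: float
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p: dict[str, float]
    r2: dict[str, float]
    n: int

    PATHS = ("x_to_y", "y_to_x", "ar_x", "ar_y")

    def estimate(self, path: str) -> float:
        return {
            "x_to_y": self.beta_x_to_y,
            "y_to_x": self.beta_y_to_x,
            "ar_x": self.ar_x,
            "ar_y": self.ar_y,
        }[path]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for path in self.PATHS:
            lo, hi = self.ci95[path]
            rows.append(
                {
                    "wave_pair": self.wave_pair,
                    "path": path,
                    "estimate": self.estimate(path),
                    "se": self.se[path],
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": self.p[path],
                    "n": self.n,
                }
            )
        return pd.DataFrame(rows)


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


class TwoWaveCLPM(BaseEstimator):
    """Cross-lagged panel estimator for one pair of consecutive waves.

    ``x`` and ``y`` are the two focal variables; ``control`` lists additional
    time-t variables entered as predictors in *both* equations (e.g. the other
    alcohol-use measure). The panel is expected to be residualized for
    covariates beforehand.
    """

    def __init__(
        self,
        x: str,
        y: str,
        wave_t: str,
        wave_t1: str,
        control: tuple[str, ...] = (),
    ) -> None:
        self.x = x
        self.y = y
        self.wave_t = wave_t
        self.wave_t1 = wave_t1
        self.control = control

    def fit(self, phenos: pd.DataFrame):
        control = list(self.control)
        for col in (self.x, self.y, *control):
            if col not in phenos.columns:
                raise UnknownColumnError(f"variable {col!r} not in panel")
        t = phenos.loc[phenos["wave"] == self.wave_t].set_index("participant_id")
        t1 = phenos.loc[phenos["wave"] == self.wave_t1].set_index("participant_id")
        common = t.index.intersection(t1.index)
        cols_t = [self.x, self.y, *control]
        mat = np.column_stack(
            [
                t.loc[common, cols_t].to_numpy(dtype=float),
                t1.loc[common, [self.x, self.y]].to_numpy(dtype=float),
            ]
        )
        complete = np.isfinite(mat).all(axis=1)
        mat = mat[complete]
        n = mat.shape[0]
        n_pred = len(cols_t)
        if n < n_pred + 2:
            raise InsufficientDataError(
                f"{n} complete cases for {n_pred} predictors (need >= {n_pred + 2})"
            )
        if np.any(mat.std(axis=0, ddof=1) == 0):
            raise SingularityError("a model variable is constant on the complete cases")
        Z = _standardize(mat)
        X = Z[:, :n_pred]
        corr = np.corrcoef(X, rowvar=False)
        if n_pred > 1 and np.any(np.abs(corr[np.triu_indices(n_pred, 1)]) > COLLINEARITY_R):
            raise SingularityError("time-t predictors are (near-)collinear")
        design = sm.add_constant(X)

        def one(target: np.ndarray):
            fit = sm.OLS(target, design).fit()
            return fit

        fit_y = one(Z[:, n_pred + 1])  # y_{t+1} ~ x_t + y_t + controls
        fit_x = one(Z[:, n_pred])  # x_{t+1} ~ x_t + y_t + controls

        # design columns: const, x_t, y_t, controls...
        def pick(fit, j):
            ci = fit.conf_int()
            return float(fit.params[j]), float(fit.bse[j]), (float(ci[j, 0]), float(ci[j, 1])), float(fit.pvalues[j])

        bxy, se_xy, ci_xy, p_xy = pick(fit_y, 1)
        ary, se_ary, ci_ary, p_ary = pick(fit_y, 2)
        arx, se_arx, ci_arx, p_arx = pick(fit_x, 1)
        byx, se_yx, ci_yx, p_yx = pick(fit_x, 2)

        self.result_ = ClpmResult(
            wave_pair=f"{self.wave_t}→{self.wave_t1}",
            x=self.x,
            y=self.y,
            beta_x_to_y=bxy,
            beta_y_to_x=byx,
            ar_x=arx,
            ar_y=ary,
            se={"x_to_y": se_xy, "y_to_x": se_yx, "ar_x": se_arx, "ar_y": se_ary},
            ci95={"x_to_y": ci_xy, "y_to_x": ci_yx, "ar_x": ci_arx, "ar_y": ci_ary},
            p={"x_to_y": p_xy, "y_to_x": p_yx, "ar_x": p_arx, "ar_y": p_ary},
            r2={"eq_y": float(fit_y.rsquared), "eq_x": float(fit_x.rsquared)},
            n=n,
        )
        self.n_ = n
        return self


def fit_two_wave_clpm(
    phenos: pd.DataFrame,
    x: str,
    y: str,
    wave_t: str,
    wave_t1: str,
    control: tuple[str, ...] = (),
) -> ClpmResult:
    return TwoWaveCLPM(x, y, wave_t, wave_t1, control=control).fit(phenos).result_
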