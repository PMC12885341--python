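"""Baron–Kenny mediation with percentile-bootstrap inference.

Simple mediation (x -> m -> y):

* ``a`` from ``m ~ x``; ``b`` and the direct effect from ``y ~ x + m``;
  total effect from ``y ~ x``; indirect = a * b.

Serial mediation (x -> m1 -> m2 -> y) from the three-equation recursive system
``m1 ~ x``; ``m2 ~ x + m1``; ``y ~ x + m1 + m2``; the serial indirect effect is
the product a1 * d21 * b2.

Inference is a nonparametric case-resampling bootstrap of the indirect-effect
product. Because the hypothesized direction is stated in advance, the p-value
is one-tailed — the proportion of bootstrap indirect estimates on the wrong
side of zero relative to the stated direction — and the confidence interval is
the matching one-sided percentile interval (e.g. [q05, +inf) for direction
``+``). The bootstrap is implemented with multinomial resampling weights so
large inputs are handled in fixed-size chunks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import DegenerateInputError, SingularityError

MIN_BOOT = 1000
_COLLINEAR_R = 0.999
_CHUNK_ELEMS = 20_000_000  # max floats per bootstrap weight chunk


@dataclass
class MediationResult:
    paths: dict[str, float]
    indirect: float
    c_total: float
    c_direct: float
    proportion: float  # NaN when flagged
    proportion_flag: str  # "" | "suppression" | "zero-total"
    p_bootstrap: float
    ci: tuple[float, float]
    direction: str
    n: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        d = {
            "paths": self.paths,
            "indirect": self.indirect,
            "c_total": self.c_total,
            "c_direct": self.c_direct,
            "proportion": None if np.isnan(self.proportion) else self.proportion,
            "proportion_flag": self.proportion_flag,
            "p_bootstrap": self.p_bootstrap,
            "ci": [None if np.isinf(v) else v for v in self.ci],
            "direction": self.direction,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        return d


def _check_columns(data: pd.DataFrame, cols: list[str]) -> np.ndarray:
    mat = data[cols].to_numpy(dtype=float)
    mat = mat[np.isfinite(mat).all(axis=1)]
    if mat.shape[0] < len(cols) + 2:
        raise DegenerateInputError("too few complete cases for mediation")
    sd = mat.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise DegenerateInputError(f"zero variance in {bad}")
    corr = np.corrcoef(mat, rowvar=False)
    iu = np.triu_indices(len(cols), 1)
    if np.any(np.abs(corr[iu]) > _COLLINEAR_R):
        raise SingularityError("mediation variables are (near-)collinear")
    return mat


def _ols_from_moments(S: np.ndarray, xy_idx: list[int], y_idx: int) -> np.ndarray:
    """Coefficients of y ~ 1 + X given the moment matrix S = Wᵀ[1,V] over
    columns [1, v1, v2, ...]; indices address columns of the augmented matrix."""
    rows = [0] + [i for i in xy_idx]
    A = S[np.ix_(rows, rows)]
    bvec = S[rows, y_idx]
    return np.linalg.solve(A, bvec)[1:]


def _paths_from_moments(S, serial: bool) -> tuple[dict[str, float], float, float, float]:
    """Path estimates from the moment matrix of [1, x, m..., y]."""
    if serial:
        # columns: 0=1, 1=x, 2=m1, 3=m2, 4=y
        a1 = _ols_from_moments(S, [1], 2)[0]
        m2_coef = _ols_from_moments(S, [1, 2], 3)
        a2, d21 = m2_coef
        y_coef = _ols_from_moments(S, [1, 2, 3], 4)
        c_direct, b1, b2 = y_coef
        c_total = _ols_from_moments(S, [1], 4)[0]
        paths = {"a1": a1, "a2": a2, "d21": d21, "b1": b1, "b2": b2}
        indirect = a1 * d21 * b2
    else:
        # columns: 0=1, 1=x, 2=m, 3=y
        a = _ols_from_moments(S, [1], 2)[0]
        y_coef = _ols_from_moments(S, [1, 2], 3)
        c_direct, b = y_coef
        c_total = _ols_from_moments(S, [1], 3)[0]
        paths = {"a": a, "b": b}
        indirect = a * b
    return paths, indirect, c_total, c_direct


def _batch_ols(S: np.ndarray, x_idx: list[int], y_idx: int) -> np.ndarray:
    """Slope coefficients of y ~ 1 + X for a stack of moment matrices."""
    rows = [0] + list(x_idx)
    A = S[:, rows][:, :, rows]
    bvec = S[:, rows, y_idx]
    return np.linalg.solve(A, bvec[..., None])[:, 1:, 0]


def _batch_indirect(S: np.ndarray, serial: bool) -> np.ndarray:
    if serial:
        a1 = _batch_ols(S, [1], 2)[:, 0]
        d21 = _batch_ols(S, [1, 2], 3)[:, 1]
        b2 = _batch_ols(S, [1, 2, 3], 4)[:, 2]
        return a1 * d21 * b2
    a = _batch_ols(S, [1], 2)[:, 0]
    b = _batch_ols(S, [1, 2], 3)[:, 1]
    return a * b


def _bootstrap_indirect(
    mat: np.ndarray, n_boot: int, seed: int, serial: bool
) -> np.ndarray:
    """Indirect-effect product for ``n_boot`` case resamples.

    Resampling is expressed as multinomial case weights so each draw's moment
    matrix is one weighted cross-product; draws are processed in fixed-size
    chunks and the per-draw OLS systems are solved in batch."""
    n = mat.shape[0]
    V = np.column_stack([np.ones(n), mat])
    k = V.shape[1]
    P = (V[:, :, None] * V[:, None, :]).reshape(n, k * k)
    rng = np.random.default_rng([53, seed])
    out = np.empty(n_boot)
    chunk = max(1, min(n_boot, _CHUNK_ELEMS // n))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        W = np.empty((b, n))
        for d in range(b):
            W[d] = np.bincount(rng.integers(0, n, n), minlength=n)
        S = (W @ P).reshape(b, k, k)
        try:
            out[done : done + b] = _batch_indirect(S, serial)
        except np.linalg.LinAlgError:  # a degenerate resample: fall back per draw
            for d in range(b):
                try:
                    _, ind, _, _ = _paths_from_moments(S[d], serial)
                except np.linalg.LinAlgError:
                    ind = np.nan
                out[done + d] = ind
        done += b
    return out


def _one_tailed(boot: np.ndarray, direction: str) -> tuple[float, tuple[float, float]]:
    boot = boot[np.isfinite(boot)]
    if direction == "+":
        p = float(np.mean(boot <= 0.0))
        ci = (float(np.quantile(boot, 0.05)), np.inf)
    elif direction == "-":
        p = float(np.mean(boot >= 0.0))
        ci = (-np.inf, float(np.quantile(boot, 0.95)))
    else:
        raise ValueError("direction must be '+' or '-'")
    return p, ci


def _proportion(indirect: float, c_total: float) -> tuple[float, str]:
    if c_total == 0:
        return np.nan, "zero-total"
    if np.sign(indirect) != np.sign(c_total):
        return np.nan, "suppression"
    return indirect / c_total, ""


class _BaseMediation(BaseEstimator):
    serial = False

    def _fit(self, data: pd.DataFrame, cols: list[str]):
        if self.n_boot < MIN_BOOT:
            raise ValueError(f"n_boot must be >= {MIN_BOOT}")
        mat = _check_columns(data, cols)
        n = mat.shape[0]
        V = np.column_stack([np.ones(n), mat])
        S = V.T @ V
        paths, indirect, c_total, c_direct = _paths_from_moments(S, self.serial)
        boot = _bootstrap_indirect(mat, self.n_boot, self.seed, self.serial)
        p, ci = _one_tailed(boot, self.direction)
        prop, flag = _proportion(indirect, c_total)
        self.result_ = MediationResult(
            paths={k: float(v) for k, v in paths.items()},
            indirect=float(indirect),
            c_total=float(c_total),
            c_direct=float(c_direct),
            proportion=float(prop) if not isinstance(prop, str) else prop,
            proportion_flag=flag,
            p_bootstrap=p,
            ci=ci,
            direction=self.direction,
            n=n,
            n_boot=self.n_boot,
            seed=self.seed,
        )
        self.boot_indirect_ = boot
        self.indirect_ = float(indirect)
        self.p_bootstrap_ = p
        return self


class SimpleMediation(_BaseMediation):
    """x -> m -> y mediation with one-tailed percentile-bootstrap inference."""

    serial = False

    def __init__(self, x: str, m: str, y: str, n_boot: int = 10_000, direction: str = "+", seed: int = 0):
        self.x = x
        self.m = m
        self.y = y
        self.n_boot = n_boot
        self.direction = direction
        self.seed = seed

    def fit(self, data: pd.DataFrame):
        return self._fit(data, [self.x, self.m, self.y])


class SerialMediation(_BaseMediation):
    """x -> m1 -> m2 -> y serial mediation; indirect effect a1 * d21 * b2."""

    serial = True

    def __init__(
        self, x: str, m1: str, m2: str, y: str, n_boot: int = 10_000, direction: str = "+", seed: int = 0
    ):
        self.x = x
        self.m1 = m1
        self.m2 = m2
        self.y = y
        self.n_boot = n_boot
        self.direction = direction
        self.seed = seed

    def fit(self, data: pd.DataFrame):
        return self._fit(data, [self.x, self.m1, self.m2, self.y])


def fit_simple_mediation(
    data: pd.DataFrame, x: str, m: str, y: str, n_boot: int = 10_000, direction: str = "+", seed: int = 0
) -> MediationResult:
    return SimpleMediation(x, m, y, n_boot=n_boot, direction=direction, seed=seed).fit(data).result_


def fit_serial_mediation(
    data: pd.DataFrame,
    x: str,
    m1: str,
    m2: str,
    y: str,
    n_boot: int = 10_000,
    direction: str = "+",
    seed: int = 0,
) -> MediationResult:
    return (
        SerialMediation(x, m1, m2, y, n_boot=n_boot, direction=direction, seed=seed).fit(data).result_
    )
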