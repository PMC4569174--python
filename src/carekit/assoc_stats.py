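"""Spearman correlation screen with a permutation-calibrated omnibus test.

Each predictor is rank-correlated with each fitness proxy per sex; the set
of p-values is combined with Fisher's omnibus statistic X = -2 * sum(ln p),
chi-square with 2k df.  Because the component tests share data, X is also
calibrated by permutation: the response is shuffled against the intact
predictor matrix (preserving inter-predictor dependence) and X recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError

__all__ = [
    "CorrelationResult",
    "FotResult",
    "spearman",
    "fot_statistic",
    "fot_analytic_p",
    "fot_permutation",
    "screen",
]

_TINY_P = 1e-300


@dataclass(frozen=True)
class CorrelationResult:
    predictor: str
    response: str
    sex: str
    n: int
    rho: Optional[float]
    p: Optional[float]


@dataclass(frozen=True)
class FotResult:
    X: float
    df: int
    p_analytic: float
    p_permutation: Optional[float]
    n_perm: int


def _midranks(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[Optional[float], Optional[float], int]:
    """Spearman rho (mid-rank Pearson) and two-sided t-approximation p.

    Pairs with a missing value are dropped; returns (rho, p, n).  A constant
    vector yields (None, None, n) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError(f"need n >= 3 after pairwise deletion, got {n}")
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant vector in spearman; rho undefined")
        return None, None, n
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    p = _t_approx_p(np.array([rho]), n)[0]
    return rho, float(p), n


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = rho * sqrt((n-2)/(1-rho^2)), clamped into (0, 1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 0.0))
        t = np.where(np.abs(rho) >= 1.0, np.inf * np.sign(rho), t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.clip(p, _TINY_P, 1.0)


def fot_statistic(p_values: Sequence[float]) -> tuple[float, int]:
    """X = -2 * sum(ln p_i), df = 2k."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValidationError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum()), 2 * p.size


def fot_analytic_p(X: float, df: int) -> float:
    """Chi-square survival-function p for the omnibus statistic."""
    return float(stats.chi2.sf(X, df))


def fot_permutation(
    response: Sequence[float],
    predictors: np.ndarray | pd.DataFrame,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> FotResult:
    """Omnibus test of one response against k predictors, permutation-calibrated.

    Rows with any missing value are dropped (complete-case), so every
    permutation recomputes all k correlations on the same rows.  The response
    is shuffled jointly against the intact predictor matrix;
    p_permutation = (1 + #{X_perm >= X_obs}) / (n_perm + 1).
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(response, dtype=float)
    P = np.asarray(predictors, dtype=float)
    if P.ndim != 2 or len(y) != P.shape[0]:
        raise ValidationError("predictors must be a matrix with one row per response value")
    keep = ~(np.isnan(y) | np.isnan(P).any(axis=1))
    y, P = y[keep], P[keep]
    n, k = P.shape
    if n < 3:
        raise ValidationError(f"need n >= 3 complete rows, got {n}")

    ry = _midranks(y)
    rp = np.column_stack([_midranks(P[:, j]) for j in range(k)])
    sd_y = ry.std()
    sd_p = rp.std(axis=0)
    if sd_y == 0 or (sd_p == 0).any():
        raise ValidationError("constant column; omnibus statistic undefined")
    zy = (ry - ry.mean()) / sd_y
    zp = (rp - rp.mean(axis=0)) / sd_p

    def x_of(zy_rows: np.ndarray) -> np.ndarray:
        rho = np.clip(zy_rows @ zp / n, -1.0, 1.0)
        p = _t_approx_p(rho, n)
        return -2.0 * np.log(p).sum(axis=1)

    x_obs = float(x_of(zy[None, :])[0])
    if n_perm > 0:
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
        x_perm = x_of(zy[perms])
        count = int((x_perm >= x_obs - 1e-12).sum())
    else:
        count = 0
    p_perm = (1 + count) / (n_perm + 1)
    return FotResult(
        X=x_obs,
        df=2 * k,
        p_analytic=fot_analytic_p(x_obs, 2 * k),
        p_permutation=p_perm,
        n_perm=n_perm,
    )


def screen(
    predictor_table: pd.DataFrame,
    responses: pd.DataFrame,
    sexes: pd.Series | dict,
    predictor_columns: Sequence[str],
    response_columns: Sequence[str],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Correlation screen shaped like a predictor-by-proxy results table.

    ``predictor_table`` and ``responses`` are joined on ``focal_id``/``id``;
    per (response, sex) the report carries one row per predictor (n, rho, p)
    plus a fisher_omnibus row (X, df, analytic and permutation p).
    """
    if rng is None:
        rng = np.random.default_rng()
    sexes = dict(sexes)
    merged = predictor_table.merge(
        responses, left_on="focal_id", right_on="id", how="inner"
    )
    merged["sex"] = merged["focal_id"].map(sexes)
    rows = []
    for response in response_columns:
        for sex in sorted(merged["sex"].dropna().unique()):
            sub = merged[(merged["sex"] == sex) & merged[response].notna()]
            if len(sub) < 3:
                continue
            pvals = []
            for pred in predictor_columns:
                x = sub[pred].to_numpy(dtype=float)
                y = sub[response].to_numpy(dtype=float)
                pair_n = int((~(np.isnan(x) | np.isnan(y))).sum())
                if pair_n < 3:
                    rho, p = None, None
                else:
                    rho, p, pair_n = spearman(x, y)
                if p is not None:
                    pvals.append(p)
                rows.append(
                    {
                        "response": response,
                        "predictor": pred,
                        "sex": sex,
                        "n": pair_n,
                        "rho": rho,
                        "p": p,
                        "fot_X": None,
                        "fot_df": None,
                        "fot_p_analytic": None,
                        "fot_p_permutation": None,
                    }
                )
            try:
                fot = fot_permutation(
                    sub[response].to_numpy(dtype=float),
                    sub[list(predictor_columns)].to_numpy(dtype=float),
                    n_perm=n_perm,
                    rng=rng,
                )
            except ValidationError as exc:
                warnings.warn(
                    f"omnibus test skipped for ({response}, {sex}): {exc}"
                )
                fot = FotResult(float("nan"), 2 * len(predictor_columns),
                                float("nan"), None, 0)
            rows.append(
                {
                    "response": response,
                    "predictor": "fisher_omnibus",
                    "sex": sex,
                    "n": len(sub),
                    "rho": None,
                    "p": None,
                    "fot_X": fot.X,
                    "fot_df": fot.df,
                    "fot_p_analytic": fot.p_analytic,
                    "fot_p_permutation": fot.p_permutation,
                }
            )
    return pd.DataFrame(rows)


def significance_label(p: float) -> str:
    """Reporting convention: p <= 0.05 significant, 0.05 < p <= 0.1 trend."""
    if p <= 0.05:
        return "significant"
    if p <= 0.1:
        return "trend"
    return "ns"
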