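"""Growth-curve age normalization and morphometric indices.

Body masses measured at slightly different ages are normalized onto a
standard age per measurement occasion: fit candidate growth curves (linear,
quadratic, logarithmic in age), pick the one with the lowest AIC, take each
individual's residual as a fixed deviation from normal growth, and add it to
the fitted mass at the standard age.  Also: mass gain between occasions, the
Quetelet index, and body-mass-corrected ellipsoid testis volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core_io import ValidationError

__all__ = [
    "GrowthFit",
    "fit_growth_candidates",
    "normalize_mass",
    "mass_gain",
    "quetelet_index",
    "testis_volume",
    "STANDARD_AGES",
]

#: Standard ages (days) per period: P1 = 3 months -> 1.25 y, P2 = 3 months -> 4.25 y.
STANDARD_AGES = {"P1": (90, 455), "P2": (90, 1552)}

CANDIDATES = ("linear", "squared", "logarithmic")


@dataclass(frozen=True)
class GrowthFit:
    candidate: str
    coefficients: tuple[float, ...]
    aic: float
    residuals: dict[str, float]

    def fitted_at(self, age_days: float) -> float:
        c = self.coefficients
        if self.candidate == "linear":
            return c[0] + c[1] * age_days
        if self.candidate == "squared":
            return c[0] + c[1] * age_days + c[2] * age_days**2
        return c[0] + c[1] * math.log(age_days)


def _design(candidate: str, ages: np.ndarray) -> np.ndarray:
    if candidate == "linear":
        return np.column_stack([np.ones_like(ages), ages])
    if candidate == "squared":
        return np.column_stack([np.ones_like(ages), ages, ages**2])
    return np.column_stack([np.ones_like(ages), np.log(ages)])


def _ls_aic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    n = len(y)
    rss = float(resid @ resid)
    # Gaussian AIC with variance profiled out; additive constant dropped
    # (cancels in comparisons).  Parameter count = regression coefficients.
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * x.shape[1]
    return beta, resid, aic


def fit_growth_candidates(measurements: pd.DataFrame) -> GrowthFit:
    """AIC-select a growth curve from one measurement occasion.

    ``measurements`` needs columns id, age_days, bm_kg (one row per
    individual; sexes pooled).  Ages must be positive (log candidate).
    """
    df = measurements
    if df["id"].duplicated().any():
        raise ValidationError("duplicate ids in one measurement occasion")
    ages = df["age_days"].to_numpy(dtype=float)
    y = df["bm_kg"].to_numpy(dtype=float)
    if len(y) < 4:
        raise ValidationError(f"need >= 4 measurement points, got {len(y)}")
    if not (ages > 0).all():
        raise ValidationError("ages must be > 0")
    best = None
    for candidate in CANDIDATES:
        x = _design(candidate, ages)
        if len(y) < x.shape[1]:
            raise ValidationError("fewer points than parameters")
        beta, resid, aic = _ls_aic(x, y)
        if best is None or aic < best[2]:
            best = (candidate, beta, aic, resid)
    candidate, beta, aic, resid = best
    residuals = dict(zip(df["id"], (float(r) for r in resid)))
    return GrowthFit(candidate, tuple(float(b) for b in beta), aic, residuals)


def normalize_mass(fit: GrowthFit, standard_age_day: int) -> dict[str, float]:
    """Fitted mass at the standard age plus each individual's residual."""
    base = fit.fitted_at(standard_age_day)
    return {id_: base + r for id_, r in fit.residuals.items()}


def mass_gain(
    norm_start: Mapping[str, float], norm_end: Mapping[str, float]
) -> dict[str, Optional[float]]:
    """end - start per id; ids missing either endpoint get None."""
    out: dict[str, Optional[float]] = {}
    for id_ in set(norm_start) | set(norm_end):
        if id_ in norm_start and id_ in norm_end:
            out[id_] = norm_end[id_] - norm_start[id_]
        else:
            out[id_] = None
    return out


def quetelet_index(bm_kg: float, crl_cm: float) -> float:
    """Ponderal index: body mass over squared crown-rump length, x1000."""
    if not (bm_kg > 0 and crl_cm > 0):
        raise ValidationError("quetelet_index requires positive inputs")
    return bm_kg / (crl_cm * crl_cm) * 1000.0


def testis_volume(testis_len_mm: float, testis_wid_mm: float, bm_kg: float) -> float:
    """Ellipsoid testis volume (4/3)*pi*L*W^2 per kg body mass.

    L and W are each the mean over both testes of triplicate measurements.
    """
    if not (testis_len_mm > 0 and testis_wid_mm > 0 and bm_kg > 0):
        raise ValidationError("testis_volume requires positive inputs")
    return (4.0 / 3.0) * math.pi * testis_len_mm * testis_wid_mm**2 / bm_kg
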