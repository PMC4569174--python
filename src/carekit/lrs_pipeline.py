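"""Lifetime reproductive success, parent-offspring co-residence, and the
Poisson mixed model tying them together.

LRS counts a subject's offspring that survived their first year.
Co-residence counts the days (capped at 1461, the immaturity window) on
which parent and offspring were simultaneously alive and members of the same
group.  The model: Poisson log-link GLMM of LRS on sex, z(father
co-residence) and z(log mother co-residence), with random intercepts for
mother, sire, cohort and birth group, and random slopes of father
co-residence within cohort and birth group.  Diagnostics: full-vs-null LRT,
Pearson dispersion, VIF from a plain linear model, and leave-one-level-out
stability.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glmm import GlmmFit, PoissonGLMM, RandomTerm
from .core_io import GroupMembership, Individual, ValidationError

__all__ = [
    "DEFAULT_CAP_DAYS",
    "DEFAULT_SURVIVAL_DAYS",
    "compute_lrs",
    "co_residence_days",
    "build_lrs_records",
    "transform_covariates",
    "fit_lrs_glmm",
    "lrt_full_vs_null",
    "dispersion_parameter",
    "vif",
    "stability_check",
]

logger = logging.getLogger(__name__)

DEFAULT_CAP_DAYS = 1461
DEFAULT_SURVIVAL_DAYS = 365

FIXED_EFFECTS = ["intercept", "sex_male", "father_cores_z", "mother_cores_logz"]
RANDOM_FACTORS = ["mother_id", "sire_id", "cohort", "birth_group"]


def compute_lrs(
    subject: Individual,
    offspring: Iterable[Individual],
    survival_days: int = DEFAULT_SURVIVAL_DAYS,
) -> int:
    """Number of the subject's offspring alive at ``survival_days`` of age."""
    count = 0
    for o in offspring:
        if subject.id not in (o.mother_id, o.sire_id):
            continue
        if o.death_day is None or o.death_day - o.birth_day >= survival_days:
            count += 1
    return count


def _life_interval(ind: Individual, hi: float) -> tuple[int, float]:
    return ind.birth_day, ind.death_day if ind.death_day is not None else hi


def co_residence_days(
    offspring: Individual,
    parent: Individual,
    memberships: Iterable[GroupMembership],
    cap_days: int = DEFAULT_CAP_DAYS,
) -> int:
    """Days in the offspring's first ``cap_days`` with both alive and co-resident.

    All intervals are half-open; the answer is a sum of interval-intersection
    lengths over same-group membership pairs.
    """
    lo = offspring.birth_day
    hi = offspring.birth_day + cap_days
    memberships = list(memberships)
    off_iv = [m for m in memberships if m.id == offspring.id]
    par_iv = [m for m in memberships if m.id == parent.id]
    if not off_iv or not par_iv:
        warnings.warn(
            f"no membership data for {'offspring' if not off_iv else 'parent'} "
            f"({offspring.id} / {parent.id}); co-residence 0"
        )
        return 0
    ob, od = _life_interval(offspring, hi)
    pb, pd_ = _life_interval(parent, hi)
    total = 0
    for a in off_iv:
        for b in par_iv:
            if a.group != b.group:
                continue
            start = max(a.start_day, b.start_day, lo, ob, pb)
            end = min(a.end_day, b.end_day, hi, od, pd_)
            if end > start:
                total += int(end - start)
    return total


def build_lrs_records(
    individuals: Sequence[Individual],
    memberships: Sequence[GroupMembership],
    subjects: Optional[Sequence[str]] = None,
    cap_days: int = DEFAULT_CAP_DAYS,
    survival_days: int = DEFAULT_SURVIVAL_DAYS,
) -> pd.DataFrame:
    """Per-subject LRS with co-residence covariates and grouping factors.

    When ``subjects`` is not given, subjects are the individuals with both
    parents known and a recorded death (they completed their lifespan, so
    LRS is fully observed).
    """
    by_id = {i.id: i for i in individuals}
    if subjects is None:
        subjects = [
            i.id
            for i in individuals
            if i.mother_id is not None
            and i.sire_id is not None
            and i.death_day is not None
        ]
    offspring_of: dict[str, list[Individual]] = {}
    for i in individuals:
        for parent in (i.mother_id, i.sire_id):
            if parent is not None:
                offspring_of.setdefault(parent, []).append(i)
    rows = []
    for sid in subjects:
        subj = by_id[sid]
        mother = by_id.get(subj.mother_id) if subj.mother_id else None
        sire = by_id.get(subj.sire_id) if subj.sire_id else None
        rows.append(
            {
                "id": sid,
                "sex": subj.sex,
                "lrs": compute_lrs(subj, offspring_of.get(sid, ()), survival_days),
                "father_cores_days": co_residence_days(
                    subj, sire, memberships, cap_days
                )
                if sire is not None
                else 0,
                "mother_cores_days": co_residence_days(
                    subj, mother, memberships, cap_days
                )
                if mother is not None
                else 0,
                "mother_id": subj.mother_id,
                "sire_id": subj.sire_id,
                "cohort": subj.cohort,
                "birth_group": subj.natal_group,
            }
        )
    return pd.DataFrame(rows)


def transform_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Model covariates: sex dummy, z(father days), z(log mother days).

    The mother term is log-transformed before z-scoring (log-then-z); zero
    mother co-residence is an error, listed by id.
    """
    zero = records.loc[records["mother_cores_days"] <= 0, "id"].tolist()
    if zero:
        raise ValidationError(
            f"mother co-residence must be > 0 for the log transform; offending ids: {zero}"
        )

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValidationError("constant covariate cannot be z-transformed")
        return (v - v.mean()) / sd

    out = pd.DataFrame(index=records.index)
    out["sex_male"] = (records["sex"] == "male").astype(float)
    out["father_cores_z"] = z(records["father_cores_days"].to_numpy(dtype=float))
    out["mother_cores_logz"] = z(
        np.log(records["mother_cores_days"].to_numpy(dtype=float))
    )
    return out


def _random_terms(
    records: pd.DataFrame, design: pd.DataFrame, random_slopes: bool
) -> list[RandomTerm]:
    terms = []
    for factor in RANDOM_FACTORS:
        labels = records[factor].to_numpy()
        if len(np.unique(labels)) < 2:
            logger.warning("dropping degenerate random factor %s (<2 levels)", factor)
            continue
        terms.append(RandomTerm.from_labels(factor, labels))
    if random_slopes:
        slope_cov = design["father_cores_z"].to_numpy(dtype=float)
        for factor in ("cohort", "birth_group"):
            labels = records[factor].to_numpy()
            if len(np.unique(labels)) < 2:
                continue
            terms.append(
                RandomTerm.from_labels(f"father_cores_z|{factor}", labels, slope_cov)
            )
    return terms


def fit_lrs_glmm(
    records: pd.DataFrame,
    random_slopes: bool = True,
    include_fixed: bool = True,
    theta0: Optional[np.ndarray] = None,
) -> GlmmFit:
    """Fit the LRS model (or, with ``include_fixed=False``, the null model)."""
    design = transform_covariates(records)
    if design["sex_male"].nunique() < 2 and include_fixed:
        raise ValidationError(
            "sex is constant across subjects; the sex fixed effect cannot be fit"
        )
    y = records["lrs"].to_numpy(dtype=float)
    if include_fixed:
        X = np.column_stack(
            [
                np.ones(len(records)),
                design["sex_male"],
                design["father_cores_z"],
                design["mother_cores_logz"],
            ]
        )
        names = list(FIXED_EFFECTS)
    else:
        X = np.ones((len(records), 1))
        names = ["intercept"]
    terms = _random_terms(records, design, random_slopes)
    return PoissonGLMM(y, X, terms, fixed_names=names).fit(theta0=theta0)


def lrt_full_vs_null(full: GlmmFit, null: GlmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the fixed effects (chi-square reference).

    The boundary caveat (variance components present in both models) is the
    user's to keep in mind; it is the conventional comparison nonetheless.
    """
    stat = 2.0 * (full.loglik - null.loglik)
    df = len(full.fixed_names) - len(null.fixed_names)
    if stat < -1e-6:
        warnings.warn(
            f"negative LRT statistic ({stat:.3g}): possible convergence failure"
        )
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def dispersion_parameter(mu: np.ndarray, y: np.ndarray, n_fixed: int) -> float:
    """Sum of squared Pearson residuals over residual df (n - fixed effects)."""
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y, dtype=float)
    if (mu <= 0).any():
        raise ValidationError("fitted means must be positive")
    pearson = (y - mu) / np.sqrt(mu)
    return float((pearson**2).sum() / (len(y) - n_fixed))


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation per predictor from an ordinary linear model.

    VIF_j = 1 / (1 - R^2_j), regressing predictor j on the others (plus an
    intercept).  Perfect collinearity reports inf.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValidationError("need >= 2 fixed effects for VIF")
    out = {}
    M = design.to_numpy(dtype=float)
    n = M.shape[0]
    for j, col in enumerate(cols):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        if tss == 0:
            raise ValidationError(f"constant predictor {col!r}")
        r2 = 1.0 - (resid @ resid) / tss
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def stability_check(
    records: pd.DataFrame,
    random_slopes: bool = True,
    factors: Sequence[str] = tuple(RANDOM_FACTORS),
) -> pd.DataFrame:
    """Leave-one-level-out refits: estimate range per fixed effect.

    For each level of each requested random factor, the model is refit
    without that level's records; failures are flagged, not fatal.  Returns
    one row per (factor, level, effect) plus the full-data estimate.
    """
    full = fit_lrs_glmm(records, random_slopes=random_slopes)
    rows = []
    for factor in factors:
        for level in sorted(records[factor].dropna().unique()):
            sub = records[records[factor] != level]
            if len(sub) < len(FIXED_EFFECTS) + 1:
                continue
            try:
                fit = fit_lrs_glmm(sub, random_slopes=random_slopes)
            except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                logger.warning("refit without %s=%s failed: %s", factor, level, exc)
                rows.append(
                    {
                        "factor": factor,
                        "level": level,
                        "effect": None,
                        "estimate": None,
                        "failed": True,
                    }
                )
                continue
            for name, est in zip(fit.fixed_names, fit.beta):
                rows.append(
                    {
                        "factor": factor,
                        "level": level,
                        "effect": name,
                        "estimate": float(est),
                        "failed": False,
                    }
                )
    for name, est in zip(full.fixed_names, full.beta):
        rows.append(
            {
                "factor": "(all data)",
                "level": "",
                "effect": name,
                "estimate": float(est),
                "failed": False,
            }
        )
    return pd.DataFrame(rows)
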