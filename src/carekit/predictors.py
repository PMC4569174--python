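"""Per-focal predictors of male-immature affiliation over an age window.

Five predictors: mean male-focal affiliation rate, mean paternal affiliation
rate, mean focal rank, male-rank-weighted affiliation rate, and evenness of
the affiliation distribution across available adult-male partners.  Rates are
denominated by protocol days (days the focal was actually observed).  All
windows are half-open day intervals.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import GroupMembership, Individual, ValidationError
from .dominance import (
    DEFAULT_ADULT_AGE_DAYS,
    FEMALE_IMMATURE_HIERARCHY,
    MALE,
    MALE_HIERARCHY,
)

__all__ = [
    "mean_male_affiliation",
    "mean_paternal_affiliation",
    "mean_focal_rank",
    "rank_weighted_affiliation",
    "affiliation_evenness",
    "available_partner_pool",
    "build_predictor_table",
    "INFANCY_WINDOW",
    "IMMATURITY_WINDOW",
]

logger = logging.getLogger(__name__)

INFANCY_WINDOW = (0, 365)
IMMATURITY_WINDOW = (0, 1461)

PREDICTOR_COLUMNS = [
    "mean_male_affil",
    "mean_paternal_affil",
    "focal_rank",
    "weighted_affil",
    "evenness",
]


def _protocol_days(protocols: pd.DataFrame, focal: str, lo: int, hi: int) -> np.ndarray:
    sel = protocols[
        (protocols["focal_id"] == focal)
        & (protocols["day"] >= lo)
        & (protocols["day"] < hi)
    ]
    return np.unique(sel["day"].to_numpy())


def _focal_events(events: pd.DataFrame, focal: str, lo: int, hi: int) -> pd.DataFrame:
    return events[
        (events["focal_id"] == focal) & (events["day"] >= lo) & (events["day"] < hi)
    ]


def mean_male_affiliation(
    events: pd.DataFrame, protocols: pd.DataFrame, focal: str, window: tuple[int, int]
) -> Optional[float]:
    """Affiliation events with any adult male per protocol day in the window.

    Returns None (with a warning) when the focal has no protocol days there.
    """
    lo, hi = window
    days = _protocol_days(protocols, focal, lo, hi)
    if days.size == 0:
        warnings.warn(f"focal {focal}: no protocol days in window [{lo}, {hi})")
        return None
    return len(_focal_events(events, focal, lo, hi)) / days.size


def mean_paternal_affiliation(
    events: pd.DataFrame,
    protocols: pd.DataFrame,
    focal: str,
    sire_id: Optional[str],
    window: tuple[int, int],
) -> Optional[float]:
    """As mean_male_affiliation restricted to the sire; None if sire unknown."""
    if sire_id is None:
        logger.info("focal %s: sire unknown, paternal affiliation absent", focal)
        return None
    lo, hi = window
    days = _protocol_days(protocols, focal, lo, hi)
    if days.size == 0:
        warnings.warn(f"focal {focal}: no protocol days in window [{lo}, {hi})")
        return None
    ev = _focal_events(events, focal, lo, hi)
    return int((ev["partner_id"] == sire_id).sum()) / days.size


def mean_focal_rank(
    ranks: pd.DataFrame, focal: str, window: tuple[int, int]
) -> Optional[float]:
    """Mean of the focal's daily standardized ranks over days in the window."""
    lo, hi = window
    sel = ranks[
        (ranks["id"] == focal)
        & (ranks["day"] >= lo)
        & (ranks["day"] < hi)
        & (ranks["hierarchy"] == FEMALE_IMMATURE_HIERARCHY)
    ]
    if sel.empty:
        return None
    return float(sel["rank"].mean())


def rank_weighted_affiliation(
    events: pd.DataFrame,
    protocols: pd.DataFrame,
    ranks: pd.DataFrame,
    focal: str,
    window: tuple[int, int],
) -> Optional[float]:
    """Sum of partners' male ranks on event days, per protocol day.

    High values require frequent affiliation with high-ranking males; every
    event partner must hold a male-hierarchy rank on the event day.
    """
    lo, hi = window
    days = _protocol_days(protocols, focal, lo, hi)
    if days.size == 0:
        warnings.warn(f"focal {focal}: no protocol days in window [{lo}, {hi})")
        return None
    ev = _focal_events(events, focal, lo, hi)
    if ev.empty:
        return 0.0
    male_ranks = ranks[ranks["hierarchy"] == MALE_HIERARCHY]
    merged = ev.merge(
        male_ranks[["id", "day", "rank"]],
        left_on=["partner_id", "day"],
        right_on=["id", "day"],
        how="left",
    )
    if merged["rank"].isna().any():
        bad = merged[merged["rank"].isna()].iloc[0]
        raise ValidationError(
            f"no male rank for partner {bad['partner_id']!r} on day {int(bad['day'])} "
            f"(focal {focal})"
        )
    return float(merged["rank"].sum()) / days.size


def available_partner_pool(
    individuals: Iterable[Individual],
    memberships: Iterable[GroupMembership],
    group: str,
    window: tuple[int, int],
    adult_age_days: int = DEFAULT_ADULT_AGE_DAYS,
) -> set[str]:
    """Adult males alive and resident in ``group`` on >= 1 day of the window."""
    lo, hi = window
    males = {i.id: i for i in individuals if i.sex == MALE}
    pool: set[str] = set()
    for m in memberships:
        if m.group != group or m.id not in males or m.id in pool:
            continue
        ind = males[m.id]
        start = max(m.start_day, lo, ind.birth_day + adult_age_days)
        end = min(m.end_day, hi, ind.death_day if ind.death_day is not None else hi)
        if start < end:
            pool.add(m.id)
    return pool


def affiliation_evenness(
    events: pd.DataFrame,
    focal: str,
    window: tuple[int, int],
    available_partners: set[str],
) -> Optional[float]:
    """Shannon evenness of the focal's affiliation distribution.

    With counts c_m over partners, H = -sum p_m ln p_m over partners with
    c_m > 0, divided by its maximum ln(S) where S is the number of adult
    males available to the focal in the window.  Absent when S == 1 or when
    the focal had no events.
    """
    if not available_partners:
        raise ValidationError(f"focal {focal}: empty partner pool")
    ev = _focal_events(events, focal, *window)
    counts = ev.groupby("partner_id").size()
    outside = set(counts.index) - set(available_partners)
    if outside:
        raise ValidationError(
            f"focal {focal}: event partners outside available pool: {sorted(outside)}"
        )
    total = counts.sum()
    s = len(available_partners)
    if total == 0 or s == 1:
        return None
    p = counts.to_numpy(dtype=float) / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(s)


def build_predictor_table(
    events: pd.DataFrame,
    protocols: pd.DataFrame,
    ranks: pd.DataFrame,
    individuals: Sequence[Individual],
    memberships: Sequence[GroupMembership],
    group: str,
    focals: Sequence[str],
    window: tuple[int, int] = INFANCY_WINDOW,
    sire_map: Optional[dict[str, str]] = None,
    adult_age_days: int = DEFAULT_ADULT_AGE_DAYS,
) -> pd.DataFrame:
    """One row per focal with the five predictors over a birth-relative window.

    ``window`` is [start, end) in days relative to each focal's birth; it is
    shifted per focal onto absolute days.  ``sire_map`` overrides the sire_id
    recorded in the demography (e.g. with paternity-pipeline output).
    """
    by_id = {i.id: i for i in individuals}
    sire_map = sire_map or {}
    rows = []
    for focal in focals:
        ind = by_id[focal]
        lo = ind.birth_day + window[0]
        hi = ind.birth_day + window[1]
        abs_window = (lo, hi)
        sire = sire_map.get(focal, ind.sire_id)
        pool = available_partner_pool(
            individuals, memberships, group, abs_window, adult_age_days
        )
        days = _protocol_days(protocols, focal, lo, hi)
        ev = _focal_events(events, focal, lo, hi)
        rows.append(
            {
                "focal_id": focal,
                "window_start": window[0],
                "window_end": window[1],
                "mean_male_affil": mean_male_affiliation(
                    events, protocols, focal, abs_window
                ),
                "mean_paternal_affil": mean_paternal_affiliation(
                    events, protocols, focal, sire, abs_window
                ),
                "focal_rank": mean_focal_rank(ranks, focal, abs_window),
                "weighted_affil": rank_weighted_affiliation(
                    events, protocols, ranks, focal, abs_window
                ),
                "evenness": affiliation_evenness(events, focal, abs_window, pool)
                if pool
                else None,
                "n_protocol_days": int(days.size),
                "n_partners": int(ev["partner_id"].nunique()),
            }
        )
    return pd.DataFrame(rows)
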