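"""Daily dominance hierarchies.

Adult-male ranks come from sequential Elo ratings of dyadic agonistic
outcomes; female/immature ranks come from a maintained adult-female ordering
with each mother's living offspring inserted directly below her, youngest
first.  Both hierarchies are standardized per day onto [0, 1] (lowest 0,
highest 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import (
    MALE,
    AgonisticEvent,
    GroupMembership,
    Individual,
    ValidationError,
)

__all__ = [
    "EloState",
    "FemaleOrder",
    "elo_update",
    "expected_score",
    "standardize_ranks",
    "male_daily_ranks",
    "female_immature_daily_ranks",
    "daily_adult_male_roster",
]

MALE_HIERARCHY = "male"
FEMALE_IMMATURE_HIERARCHY = "female_immature"

#: Age (days) from which a male is treated as adult for the male hierarchy.
DEFAULT_ADULT_AGE_DAYS = 1461


@dataclass(frozen=True)
class EloState:
    """Current ratings plus the update parameters.

    Unrated individuals enter at ``start_rating`` the first time they appear.
    """

    ratings: Mapping[str, float] = field(default_factory=dict)
    start_rating: float = 1000.0
    k: float = 100.0

    def rating(self, id: str) -> float:
        return self.ratings.get(id, self.start_rating)


@dataclass(frozen=True)
class FemaleOrder:
    """Adult-female ordering, highest-ranking first."""

    ordered_ids: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.ordered_ids)) != len(self.ordered_ids):
            raise ValidationError("duplicate ids in female order")


def expected_score(r_winner: float, r_loser: float) -> float:
    """Winner's expected score before the event (logistic, base-10/400)."""
    return 1.0 / (1.0 + 10.0 ** ((r_loser - r_winner) / 400.0))


def elo_update(state: EloState, event: AgonisticEvent) -> EloState:
    """Apply one agonistic outcome; winner gains k*(1-E), loser loses it."""
    if event.winner_id == event.loser_id:
        raise ValidationError("winner_id == loser_id")
    rw = state.rating(event.winner_id)
    rl = state.rating(event.loser_id)
    delta = state.k * (1.0 - expected_score(rw, rl))
    ratings = dict(state.ratings)
    ratings[event.winner_id] = rw + delta
    ratings[event.loser_id] = rl - delta
    return dataclasses.replace(state, ratings=ratings)


def standardize_ranks(ordering: Sequence[str]) -> dict[str, float]:
    """Map an ordering (highest first) onto equally spaced values in [0, 1].

    Position ``i`` of ``n`` (1-based) gets ``(n - i) / (n - 1)``; a singleton
    hierarchy standardizes to 1.0.
    """
    ordering = list(ordering)
    if not ordering:
        raise ValidationError("empty ordering")
    if len(set(ordering)) != len(ordering):
        raise ValidationError("duplicate ids in ordering")
    n = len(ordering)
    if n == 1:
        return {ordering[0]: 1.0}
    return {id_: (n - i) / (n - 1) for i, id_ in enumerate(ordering, start=1)}


def daily_adult_male_roster(
    individuals: Iterable[Individual],
    memberships: Iterable[GroupMembership],
    group: str,
    days: Iterable[int],
    adult_age_days: int = DEFAULT_ADULT_AGE_DAYS,
) -> dict[int, set[str]]:
    """Adult males alive and resident in ``group`` for each requested day."""
    males = {i.id: i for i in individuals if i.sex == MALE}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for m in memberships:
        if m.group == group and m.id in males:
            intervals.setdefault(m.id, []).append((m.start_day, m.end_day))
    days = sorted(set(days))
    roster: dict[int, set[str]] = {d: set() for d in days}
    for mid, ivs in intervals.items():
        ind = males[mid]
        for start, end in ivs:
            for d in days:
                if (
                    start <= d < end
                    and ind.alive_on(d)
                    and d - ind.birth_day >= adult_age_days
                ):
                    roster[d].add(mid)
    return roster


def male_daily_ranks(
    events: Sequence[AgonisticEvent],
    roster: Mapping[int, set[str]],
    start_rating: float = 1000.0,
    k: float = 100.0,
) -> pd.DataFrame:
    """Daily standardized Elo ranks for the adult-male hierarchy.

    Events must be sorted by day; within a day they are processed in input
    order and the day's rank is taken after the last event.  Equal ratings
    (e.g. two males who never fought) are broken by id for determinism.

    Returns a DataFrame with columns id, day, hierarchy, rank.
    """
    events = list(events)
    for a, b in zip(events, events[1:]):
        if b.day < a.day:
            raise ValidationError("events must be sorted by day")
    by_day: dict[int, list[AgonisticEvent]] = {}
    for e in events:
        by_day.setdefault(e.day, []).append(e)

    state = EloState(ratings={}, start_rating=start_rating, k=k)
    rows = []
    for day in sorted(roster):
        present = roster[day]
        for e in by_day.get(day, ()):
            if e.winner_id not in present or e.loser_id not in present:
                missing = {e.winner_id, e.loser_id} - present
                raise ValidationError(
                    f"event participant(s) {sorted(missing)} absent from roster on day {day}"
                )
            state = elo_update(state, e)
        if not present:
            continue
        ordering = sorted(present, key=lambda m: (-state.rating(m), m))
        for id_, rank in standardize_ranks(ordering).items():
            rows.append((id_, day, MALE_HIERARCHY, rank))
    return pd.DataFrame(rows, columns=["id", "day", "hierarchy", "rank"])


def _daily_fi_ordering(
    order: FemaleOrder,
    day: int,
    present: set[str],
    offspring_by_mother: Mapping[str, list[Individual]],
) -> list[str]:
    ordering: list[str] = []
    for fid in order.ordered_ids:
        if fid in present:
            ordering.append(fid)
        kids = [
            o for o in offspring_by_mother.get(fid, ()) if o.id in present
        ]
        # directly below the mother, youngest (latest-born) first
        kids.sort(key=lambda o: (-o.birth_day, o.id))
        ordering.extend(o.id for o in kids)
    return ordering


def female_immature_daily_ranks(
    order: FemaleOrder,
    individuals: Iterable[Individual],
    memberships: Iterable[GroupMembership],
    group: str,
    days: Iterable[int],
) -> pd.DataFrame:
    """Daily standardized ranks for the female/immature hierarchy.

    The daily ordering is the supplied adult-female order restricted to
    females alive and resident that day, with each mother's living resident
    offspring inserted directly below her in inverse birth order.  Immatures
    (individuals carrying a mother_id, not themselves in the order) whose
    mother is absent from the order are a validation error.
    """
    individuals = list(individuals)
    by_id = {i.id: i for i in individuals}
    order_set = set(order.ordered_ids)
    immatures = [
        i for i in individuals if i.id not in order_set and i.mother_id is not None
    ]
    orphans = sorted(i.id for i in immatures if i.mother_id not in order_set)
    if orphans:
        raise ValidationError(
            f"immatures with mother absent from female order: {orphans}"
        )
    offspring_by_mother: dict[str, list[Individual]] = {}
    for i in immatures:
        offspring_by_mother.setdefault(i.mother_id, []).append(i)

    intervals: dict[str, list[tuple[int, int]]] = {}
    for m in memberships:
        if m.group == group and m.id in by_id:
            intervals.setdefault(m.id, []).append((m.start_day, m.end_day))

    relevant = order_set | {i.id for i in immatures}
    rows = []
    for day in sorted(set(days)):
        present = {
            rid
            for rid in relevant
            if by_id[rid].alive_on(day)
            and any(s <= day < e for s, e in intervals.get(rid, ()))
        }
        if not present:
            continue
        ordering = _daily_fi_ordering(order, day, present, offspring_by_mother)
        for id_, rank in standardize_ranks(ordering).items():
            rows.append((id_, day, FEMALE_IMMATURE_HIERARCHY, rank))
    return pd.DataFrame(rows, columns=["id", "day", "hierarchy", "rank"])
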