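"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: mid-ranks are
computed by counting, correlations by the raw Pearson formula, co-residence
by day-by-day enumeration, and Mendelian compatibility by exhausting allele
combinations.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence


def brute_midranks(values: Sequence[float]) -> list[float]:
    """Mid-ranks by counting smaller and equal values."""
    out = []
    for v in values:
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(smaller + (equal + 1) / 2.0)
    return out


def brute_pearson(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return None
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def brute_spearman(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    return brute_pearson(brute_midranks(x), brute_midranks(y))


def day_by_day_co_residence(
    offspring, parent, memberships, cap_days: int
) -> int:
    """Enumerate each day of the offspring's first ``cap_days``."""

    def group_on(ind_id: str, day: int) -> set[str]:
        return {
            m.group
            for m in memberships
            if m.id == ind_id and m.start_day <= day < m.end_day
        }

    def alive(ind, day: int) -> bool:
        return ind.birth_day <= day and (
            ind.death_day is None or day < ind.death_day
        )

    total = 0
    for day in range(offspring.birth_day, offspring.birth_day + cap_days):
        if not (alive(offspring, day) and alive(parent, day)):
            continue
        if group_on(offspring.id, day) & group_on(parent.id, day):
            total += 1
    return total


def mendel_locus_compatible(
    offspring: tuple[str, str],
    mother: tuple[str, str],
    candidate: tuple[str, str],
) -> bool:
    """Exhaustive check: can (mother, candidate) produce the offspring call?"""
    o = sorted(offspring)
    for ma in mother:
        for pa in candidate:
            if sorted((ma, pa)) == o:
                return True
    return False
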