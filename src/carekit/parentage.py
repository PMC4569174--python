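"""Exclusion-based paternity assignment from multi-locus genotypes.

Candidate sires must be older than 1250 days at the infant's birth and
present on the island at least 200 days before it.  Mismatches are counted
against the mother-offspring dyad (trio mode) or the offspring alone (dyad
mode); assignment requires a clean best candidate with a mismatch gap to the
runner-up (strict: 0 vs >= 2; relaxed: 0 vs 1; one-mismatch: 1 vs >= 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_io import MALE, GroupMembership, Individual, ValidationError

__all__ = [
    "Genotype",
    "PaternityAssignment",
    "candidate_sires",
    "count_mismatches",
    "assign_paternity",
    "genotypes_from_long_table",
    "RULE_STRICT",
    "RULE_RELAXED",
    "RULE_ONE_MISMATCH",
    "RULE_UNASSIGNED",
]

logger = logging.getLogger(__name__)

RULE_STRICT = "strict"
RULE_RELAXED = "relaxed"
RULE_ONE_MISMATCH = "one_mismatch_gap3"
RULE_UNASSIGNED = "unassigned"

MIN_SIRE_AGE_DAYS = 1250
MIN_PRESENCE_DAYS_BEFORE_BIRTH = 200


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid calls per locus; a homozygote repeats its allele."""

    id: str
    calls: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for locus, alleles in self.calls.items():
            if len(alleles) != 2:
                raise ValidationError(
                    f"{self.id}: locus {locus!r} needs exactly 2 alleles"
                )

    @property
    def n_loci(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class PaternityAssignment:
    offspring_id: str
    assigned_sire: Optional[str]
    rule: str
    mismatch_counts: Mapping[str, int]
    shared_loci: Mapping[str, int]
    tied: bool = False


def candidate_sires(
    infant: Individual,
    males: Iterable[Individual],
    memberships: Iterable[GroupMembership],
    min_age_days: int = MIN_SIRE_AGE_DAYS,
    presence_days_before: int = MIN_PRESENCE_DAYS_BEFORE_BIRTH,
) -> set[str]:
    """Males old enough and present early enough to have sired the infant.

    Presence means any membership interval (any group counts as island
    presence) covers the day ``birth - presence_days_before``.
    """
    check_day = infant.birth_day - presence_days_before
    intervals: dict[str, list[tuple[int, int]]] = {}
    for m in memberships:
        intervals.setdefault(m.id, []).append((m.start_day, m.end_day))
    out = set()
    for male in males:
        if male.sex != MALE or male.id == infant.id:
            continue
        if infant.birth_day - male.birth_day <= min_age_days:
            continue
        if any(s <= check_day < e for s, e in intervals.get(male.id, ())):
            out.add(male.id)
    return out


def _paternal_allele_sets(
    offspring: tuple[str, str], mother: Optional[tuple[str, str]]
) -> set[str]:
    """Alleles the true father could have contributed at one locus.

    If the mother carries neither offspring allele (maternal mismatch, e.g.
    genotyping error) the locus falls back to the dyad rule: either offspring
    allele is accepted as paternal.
    """
    o = set(offspring)
    if mother is None:
        return o
    m = set(mother)
    if len(o) == 1:
        return o  # homozygous offspring: the paternal allele is that allele
    maternal_possible = o & m
    if not maternal_possible:
        return o  # mother-offspring mismatch; degrade to dyad comparison
    if len(maternal_possible) == 2:
        return o  # either allele could be maternal, so either could be paternal
    return o - maternal_possible


def count_mismatches(
    offspring: Genotype,
    mother: Optional[Genotype],
    candidate: Genotype,
) -> tuple[int, int]:
    """(mismatches, shared loci) for one candidate sire.

    A shared locus is one typed in both offspring and candidate; the mother's
    call, when present, narrows the admissible paternal alleles.  A mismatch
    is a shared locus where the candidate carries no admissible allele.
    """
    shared = [l for l in offspring.calls if l in candidate.calls]
    if not shared:
        raise ValidationError(
            f"no shared loci between {offspring.id} and {candidate.id}"
        )
    mismatches = 0
    for locus in shared:
        mcall = mother.calls.get(locus) if mother is not None else None
        paternal = _paternal_allele_sets(offspring.calls[locus], mcall)
        if not paternal & set(candidate.calls[locus]):
            mismatches += 1
    return mismatches, len(shared)


def assign_paternity(
    offspring: Genotype,
    mother: Optional[Genotype],
    candidates: Sequence[Genotype],
    min_shared_loci: int = 12,
) -> PaternityAssignment:
    """Apply the exclusion rules over all eligible candidates.

    Candidates sharing fewer than ``min_shared_loci`` loci are dropped with a
    log warning.  Ties at the best mismatch count are left unassigned (the
    likelihood machinery that would break them is out of scope).
    """
    if not candidates:
        raise ValidationError(f"{offspring.id}: no candidate sires")
    mismatch_counts: dict[str, int] = {}
    shared_loci: dict[str, int] = {}
    for cand in candidates:
        mm, sh = count_mismatches(offspring, mother, cand)
        shared_loci[cand.id] = sh
        if sh < min_shared_loci:
            logger.warning(
                "dropping candidate %s for %s: only %d shared loci (< %d)",
                cand.id, offspring.id, sh, min_shared_loci,
            )
            continue
        mismatch_counts[cand.id] = mm
    if not mismatch_counts:
        return PaternityAssignment(
            offspring.id, None, RULE_UNASSIGNED, mismatch_counts, shared_loci
        )
    ranked = sorted(mismatch_counts.items(), key=lambda kv: (kv[1], kv[0]))
    best_id, best = ranked[0]
    if len(ranked) == 1:
        rule = RULE_STRICT if best == 0 else RULE_UNASSIGNED
        return PaternityAssignment(
            offspring.id,
            best_id if rule != RULE_UNASSIGNED else None,
            rule,
            mismatch_counts,
            shared_loci,
        )
    second = ranked[1][1]
    if second == best:
        return PaternityAssignment(
            offspring.id, None, RULE_UNASSIGNED, mismatch_counts, shared_loci,
            tied=True,
        )
    if best == 0 and second >= 2:
        rule = RULE_STRICT
    elif best == 0 and second == 1:
        rule = RULE_RELAXED
    elif best == 1 and second >= 3:
        rule = RULE_ONE_MISMATCH
    else:
        rule = RULE_UNASSIGNED
    return PaternityAssignment(
        offspring.id,
        best_id if rule != RULE_UNASSIGNED else None,
        rule,
        mismatch_counts,
        shared_loci,
    )


def genotypes_from_long_table(df: pd.DataFrame) -> dict[str, Genotype]:
    """Build Genotype objects from a long table (id, locus, allele1, allele2)."""
    out: dict[str, Genotype] = {}
    for id_, sub in df.groupby("id", sort=True):
        if sub["locus"].duplicated().any():
            raise ValidationError(f"duplicate locus rows for id {id_!r}")
        calls = {
            str(row.locus): (str(row.allele1), str(row.allele2))
            for row in sub.itertuples(index=False)
        }
        out[str(id_)] = Genotype(str(id_), calls)
    return out


def genotypes_to_long_frame(genotypes: Iterable[Genotype]) -> pd.DataFrame:
    rows = [
        (g.id, locus, a1, a2)
        for g in genotypes
        for locus, (a1, a2) in sorted(g.calls.items())
    ]
    return pd.DataFrame(rows, columns=["id", "locus", "allele1", "allele2"])
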