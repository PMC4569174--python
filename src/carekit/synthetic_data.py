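"""Seeded synthetic datasets with the statistical structure the analyses assume.

Two independent data sets are generated, mirroring the two analysis arms:

* a single-group focal cohort (demography, memberships, agonistic events,
  daily focal protocols, male-focal affiliation events, morphometrics,
  multi-locus genotypes) with known latent male strengths, true sires, and
  configurable effect injections from affiliation predictors into body-mass
  gain; and
* a multi-group demographic set for the lifetime-reproductive-success model,
  where parent-offspring co-residence is realized through actual group
  membership intervals so the pipeline recomputes it from raw tables.

Everything is deterministic given the seed; affiliation is generated at the
event level so partner counts and evenness are emergent properties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import dominance, predictors
from .core_io import (
    FEMALE,
    MALE,
    AffiliationEvent,
    AgonisticEvent,
    GroupMembership,
    Individual,
    MorphoRecord,
    ProtocolRecord,
)
from .dominance import FemaleOrder
from .parentage import Genotype, genotypes_to_long_frame

__all__ = ["SimConfig", "SimOutput", "simulate_population", "simulate_behavior",
           "simulate_morphometrics", "simulate_lrs_dataset", "simulate_all"]

_FAR_FUTURE = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults target the printed field descriptives
    (≈1.8 affiliations per protocol day, 23-43 partners, a ~55-infant cohort,
    92 demographic subjects with father co-residence 0-1461 d and mother
    co-residence 459-1461 d)."""

    seed: int = 0
    group: str = "R"
    # population
    n_focals: int = 55
    n_focal_females: int = 27
    n_adult_males: int = 40
    n_adult_females: int = 55
    observation_span_days: int = 1552
    birth_window_days: int = 150
    n_alive_p1: int = 47
    n_alive_p2: int = 28
    latent_strength_sd: float = 200.0
    paternity_skew: float = 1.5
    # behavior
    agonistic_per_day: int = 6
    protocols_per_week: int = 1
    affiliation_rate: float = 1.78
    focal_rate_sd: float = 0.15
    sire_bias: float = 2.0
    rank_attraction: float = 3.0
    # morphometrics
    growth_coef: tuple[float, float, float] = (0.5, 2.916e-3, 6.82e-7)
    growth_noise_sd: float = 0.15
    measurement_windows: tuple[tuple[int, int], ...] = (
        (10, 136),
        (407, 517),
        (1502, 1588),
    )
    effect_rank_gain: tuple[float, float] = (0.12, 0.0)  # (female, male) kg per SD
    effect_weighted_gain: tuple[float, float] = (0.10, 0.0)
    effect_evenness_gain: tuple[float, float] = (0.0, 0.12)
    crl_coef: tuple[float, float] = (41.0, 1.3)
    crl_noise_sd: float = 1.0
    testis_len_mean: float = 35.0
    testis_len_sd: float = 4.0
    testis_wid_mean: float = 20.0
    testis_wid_sd: float = 2.5
    # genotypes
    n_loci: int = 28
    mean_alleles_per_locus: float = 8.6
    genotyping_error: float = 0.0
    # LRS arm
    n_lrs_subjects: int = 92
    n_lrs_females: int = 30
    n_lrs_cohorts: int = 10
    n_lrs_groups: int = 6
    n_lrs_dams: int = 40
    n_lrs_sires: int = 40
    lrs_cap_days: int = 1461
    mother_cores_min: int = 459
    lrs_intercept: float = 2.0
    lrs_sex_coef: float = -0.25
    lrs_father_coef: float = -0.05
    lrs_mother_coef: float = 0.37
    lrs_re_sd_mother: float = 0.10
    lrs_re_sd_sire: float = 0.10
    lrs_re_sd_cohort: float = 0.10
    lrs_re_sd_group: float = 0.10
    lrs_re_sd_slope: float = 0.05
    lrs_male_lognormal_sd: float = 0.45

    def __post_init__(self):
        if self.n_adult_males < 1 or self.n_adult_females < self.n_focals:
            raise ValueError(
                "need >= 1 adult male and one adult female per focal"
            )
        for rate in (self.affiliation_rate, self.agonistic_per_day,
                     self.genotyping_error):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if not 0 <= self.genotyping_error <= 1:
            raise ValueError("genotyping_error must be a probability")


@dataclass
class Population:
    individuals: list[Individual]
    memberships: list[GroupMembership]
    female_order: FemaleOrder
    focal_ids: list[str]
    male_ids: list[str]
    strengths: dict[str, float]
    true_sires: dict[str, str]
    genotypes: list[Genotype]
    allele_freqs: dict[str, dict[str, float]]


@dataclass
class SimOutput:
    config: SimConfig
    population: Population
    agonistic: list[AgonisticEvent]
    protocols: list[ProtocolRecord]
    affiliations: list[AffiliationEvent]
    morpho: list[MorphoRecord]
    male_ranks: pd.DataFrame
    fi_ranks: pd.DataFrame
    predictor_truth: dict[tuple[int, int], pd.DataFrame]
    lrs_individuals: list[Individual]
    lrs_memberships: list[GroupMembership]
    lrs_truth: pd.DataFrame
    ground_truth: pd.DataFrame

    def genotype_frame(self) -> pd.DataFrame:
        return genotypes_to_long_frame(self.population.genotypes)


# ---------------------------------------------------------------------------
# population


def _simulate_genotypes(
    cfg: SimConfig,
    rng: np.random.Generator,
    parents: list[str],
    offspring: list[tuple[str, str, str]],  # (id, mother, sire)
) -> tuple[list[Genotype], dict[str, dict[str, float]]]:
    loci = [f"L{i + 1:02d}" for i in range(cfg.n_loci)]
    freqs: dict[str, dict[str, float]] = {}
    for locus in loci:
        k = max(2, int(rng.poisson(cfg.mean_alleles_per_locus - 2)) + 2)
        p = rng.dirichlet(np.ones(k))
        freqs[locus] = {str(a + 101): float(p[a]) for a in range(k)}

    def draw_allele(locus: str) -> str:
        names = list(freqs[locus])
        p = np.array([freqs[locus][a] for a in names])
        return names[rng.choice(len(names), p=p)]

    calls: dict[str, dict[str, tuple[str, str]]] = {}
    for pid in parents:
        calls[pid] = {l: (draw_allele(l), draw_allele(l)) for l in loci}
    for oid, mid, sid in offspring:
        g = {}
        for l in loci:
            maternal = calls[mid][l][rng.integers(2)]
            paternal = calls[sid][l][rng.integers(2)]
            if cfg.genotyping_error > 0:
                if rng.random() < cfg.genotyping_error:
                    maternal = draw_allele(l)
                if rng.random() < cfg.genotyping_error:
                    paternal = draw_allele(l)
            g[l] = (maternal, paternal)
        calls[oid] = g
    genotypes = [Genotype(pid, c) for pid, c in calls.items()]
    return genotypes, freqs


def simulate_population(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Matrilines, one focal birth cohort, adult males, true sires, genotypes."""
    span = cfg.observation_span_days
    end = span + _FAR_FUTURE

    females = [
        Individual(
            id=f"F{i + 1:03d}", sex=FEMALE,
            birth_day=int(rng.integers(-7000, -2500)), cohort="adults",
            natal_group=cfg.group,
        )
        for i in range(cfg.n_adult_females)
    ]
    female_order = FemaleOrder(tuple(f.id for f in females))

    males = [
        Individual(
            id=f"M{i + 1:03d}", sex=MALE,
            birth_day=int(rng.integers(-8000, -1600)), cohort="adults",
        )
        for i in range(cfg.n_adult_males)
    ]
    male_ids = [m.id for m in males]
    strengths = {
        m: float(s)
        for m, s in zip(male_ids, rng.normal(0.0, cfg.latent_strength_sd,
                                             cfg.n_adult_males))
    }

    # focal cohort: one infant per adult female, sexes fixed by count
    birth_days = np.sort(rng.integers(0, cfg.birth_window_days + 1, cfg.n_focals))
    sexes = [FEMALE] * cfg.n_focal_females + [MALE] * (cfg.n_focals - cfg.n_focal_females)
    order = rng.permutation(cfg.n_focals)
    # survivorship: n_alive_p2 stay; of the rest, enough leave late that
    # n_alive_p1 are still present for the second measurement occasion
    departures: dict[int, Optional[int]] = {}
    idx = list(rng.permutation(cfg.n_focals))
    stay = idx[: cfg.n_alive_p2]
    late = idx[cfg.n_alive_p2: cfg.n_alive_p1]
    early = idx[cfg.n_alive_p1:]
    for i in stay:
        departures[i] = None
    for i in late:
        departures[i] = int(rng.integers(600, 1450))
    for i in early:
        departures[i] = int(rng.integers(160, 390))

    # rank-skewed paternity
    s = np.array([strengths[m] for m in male_ids])
    w = np.exp(cfg.paternity_skew * (s - s.mean()) / max(s.std(), 1e-9))
    w /= w.sum()

    focals, true_sires = [], {}
    for i in range(cfg.n_focals):
        fid = f"I{i + 1:03d}"
        b = int(birth_days[i])
        dep = departures[i]
        sire = male_ids[int(rng.choice(cfg.n_adult_males, p=w))]
        true_sires[fid] = sire
        focals.append(
            Individual(
                id=fid, sex=sexes[order[i]], birth_day=b,
                death_day=None if dep is None else b + dep,
                mother_id=females[i].id, sire_id=sire,
                cohort="C1", natal_group=cfg.group,
            )
        )

    memberships = []
    for f in females:
        memberships.append(GroupMembership(f.id, cfg.group, f.birth_day, end))
    for m in males:
        arrival = int(rng.integers(-2000, -250))
        memberships.append(GroupMembership(m.id, cfg.group, arrival, end))
    for f in focals:
        memberships.append(
            GroupMembership(
                f.id, cfg.group, f.birth_day,
                f.death_day if f.death_day is not None else end,
            )
        )

    genotypes, freqs = _simulate_genotypes(
        cfg, rng,
        parents=[f.id for f in females] + male_ids,
        offspring=[(f.id, f.mother_id, true_sires[f.id]) for f in focals],
    )
    return Population(
        individuals=females + males + focals,
        memberships=memberships,
        female_order=female_order,
        focal_ids=[f.id for f in focals],
        male_ids=male_ids,
        strengths=strengths,
        true_sires=true_sires,
        genotypes=genotypes,
        allele_freqs=freqs,
    )


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    cfg: SimConfig, pop: Population, rng: np.random.Generator
) -> tuple[list[AgonisticEvent], list[ProtocolRecord], list[AffiliationEvent]]:
    """Agonistic outcomes from latent strengths; protocols; affiliation events."""
    span = cfg.observation_span_days
    male_ids = pop.male_ids
    s = np.array([pop.strengths[m] for m in male_ids])

    agonistic = []
    for day in range(span):
        for _ in range(cfg.agonistic_per_day):
            i, j = rng.choice(len(male_ids), size=2, replace=False)
            p_win = 1.0 / (1.0 + 10.0 ** (-(s[i] - s[j]) / 400.0))
            if rng.random() < p_win:
                agonistic.append(AgonisticEvent(day, male_ids[i], male_ids[j]))
            else:
                agonistic.append(AgonisticEvent(day, male_ids[j], male_ids[i]))

    by_id = {i.id: i for i in pop.individuals}
    pct = (np.argsort(np.argsort(s)) + 1) / len(s)  # strength percentile in (0,1]
    protocols: list[ProtocolRecord] = []
    affiliations: list[AffiliationEvent] = []
    for fid in pop.focal_ids:
        ind = by_id[fid]
        last = min(ind.death_day if ind.death_day is not None else span,
                   ind.birth_day + span)
        obs_days: list[int] = []
        week_start = ind.birth_day
        while week_start < last:
            week_days = [d for d in range(week_start, min(week_start + 7, last))
                         if 0 <= d < span]
            if week_days:
                take = min(cfg.protocols_per_week, len(week_days))
                picked = rng.choice(len(week_days), size=take, replace=False)
                obs_days.extend(week_days[k] for k in sorted(picked))
            week_start += 7
        obs_days = sorted(set(obs_days))

        weights = np.exp(cfg.rank_attraction * pct)
        sire_idx = male_ids.index(pop.true_sires[fid])
        weights[sire_idx] *= cfg.sire_bias
        weights = weights / weights.sum()
        rate = cfg.affiliation_rate * float(
            np.exp(rng.normal(-0.5 * cfg.focal_rate_sd**2, cfg.focal_rate_sd))
        )
        for day in obs_days:
            protocols.append(ProtocolRecord(f"{fid}-{day}", fid, day))
            n_events = rng.poisson(rate)
            if n_events == 0:
                continue
            partners = rng.choice(len(male_ids), size=n_events, p=weights)
            for k in partners:
                affiliations.append(
                    AffiliationEvent(day, f"{fid}-{day}", fid, male_ids[int(k)])
                )
    agonistic.sort(key=lambda e: e.day)
    return agonistic, protocols, affiliations


# ---------------------------------------------------------------------------
# morphometrics


def _growth(cfg: SimConfig, age: float) -> float:
    a0, a1, a2 = cfg.growth_coef
    return a0 + a1 * age + a2 * age * age


def _zscore(v: pd.Series) -> pd.Series:
    sd = v.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        return v * 0.0
    return (v - v.mean()) / sd


def simulate_morphometrics(
    cfg: SimConfig,
    pop: Population,
    predictor_truth: dict[tuple[int, int], pd.DataFrame],
    rng: np.random.Generator,
) -> list[MorphoRecord]:
    """Trapping-season measurements with configured effect injection.

    Body mass follows the quadratic growth curve plus, at the later
    occasions, sex-specific effects of the (pipeline-computed) predictor
    truths, so downstream correlation screens can recover them.
    """
    by_id = {i.id: i for i in pop.individuals}
    inf_truth = predictor_truth[predictors.INFANCY_WINDOW].set_index("focal_id")
    imm_truth = predictor_truth[predictors.IMMATURITY_WINDOW].set_index("focal_id")

    def effect(fid: str, z: dict[str, pd.Series]) -> float:
        ind = by_id[fid]
        sex_i = 0 if ind.sex == FEMALE else 1
        total = 0.0
        for col, sizes in (
            ("focal_rank", cfg.effect_rank_gain),
            ("weighted_affil", cfg.effect_weighted_gain),
            ("evenness", cfg.effect_evenness_gain),
        ):
            val = z[col].get(fid, np.nan)
            if np.isfinite(val):
                total += sizes[sex_i] * float(val)
        return total

    z_inf = {c: _zscore(inf_truth[c].astype(float)) for c in
             ("focal_rank", "weighted_affil", "evenness")}
    z_imm = {c: _zscore(imm_truth[c].astype(float)) for c in
             ("focal_rank", "weighted_affil", "evenness")}

    records = []
    for fid in pop.focal_ids:
        ind = by_id[fid]
        alive_until = ind.death_day - ind.birth_day if ind.death_day else 10**9
        for occ, (lo, hi) in enumerate(cfg.measurement_windows):
            age = int(rng.integers(lo, hi + 1))
            if age >= alive_until:
                continue
            bm = _growth(cfg, age) + float(rng.normal(0, cfg.growth_noise_sd))
            if occ == 1:
                bm += effect(fid, z_inf)
            elif occ == 2:
                bm += effect(fid, z_imm)
            bm = max(bm, 0.1)
            kwargs = {}
            if occ == 2:
                c0, c1 = cfg.crl_coef
                kwargs["crl_cm"] = max(
                    10.0, c0 + c1 * bm + float(rng.normal(0, cfg.crl_noise_sd))
                )
                if ind.sex == MALE:
                    kwargs["testis_len_mm"] = max(
                        5.0, float(rng.normal(cfg.testis_len_mean, cfg.testis_len_sd))
                    )
                    kwargs["testis_wid_mm"] = max(
                        3.0, float(rng.normal(cfg.testis_wid_mean, cfg.testis_wid_sd))
                    )
            records.append(
                MorphoRecord(id=fid, day=ind.birth_day + age, body_mass_kg=bm,
                             **kwargs)
            )
    return records


# ---------------------------------------------------------------------------
# LRS arm


def simulate_lrs_dataset(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[Individual], list[GroupMembership], pd.DataFrame]:
    """Multi-group demography whose raw tables reproduce the configured
    co-residence and LRS structure when fed through the pipeline.

    Mothers stay in the natal group; co-residence ends when the subject
    emigrates (mothers) or when the sire departs (fathers), so father
    co-residence can hit 0 while mother co-residence stays >= its floor.
    """
    groups = [f"G{g + 1}" for g in range(cfg.n_lrs_groups)]
    away_sires = "AWAY_S"
    away_subjects = "AWAY_P"
    cap = cfg.lrs_cap_days
    cohort_base = {c: c * 365 for c in range(cfg.n_lrs_cohorts)}
    span_hi = cfg.n_lrs_cohorts * 365 + cap + 2000

    dams = []
    dam_group = {}
    for i in range(cfg.n_lrs_dams):
        did = f"D{i + 1:03d}"
        dam_group[did] = groups[i % len(groups)]
        dams.append(Individual(id=did, sex=FEMALE, birth_day=-6000 + i,
                               natal_group=dam_group[did]))
    sires = []
    sire_group = {}
    sire_depart = {}
    for i in range(cfg.n_lrs_sires):
        sid = f"S{i + 1:03d}"
        sire_group[sid] = groups[i % len(groups)]
        sire_depart[sid] = int(rng.integers(-400, span_hi - 1500))
        sires.append(Individual(id=sid, sex=MALE, birth_day=-7000 + i))

    re_mother = {d.id: rng.normal(0, cfg.lrs_re_sd_mother) for d in dams}
    re_sire = {s.id: rng.normal(0, cfg.lrs_re_sd_sire) for s in sires}
    re_cohort = {c: rng.normal(0, cfg.lrs_re_sd_cohort)
                 for c in range(cfg.n_lrs_cohorts)}
    re_group = {g: rng.normal(0, cfg.lrs_re_sd_group) for g in groups}
    slope_cohort = {c: rng.normal(0, cfg.lrs_re_sd_slope)
                    for c in range(cfg.n_lrs_cohorts)}
    slope_group = {g: rng.normal(0, cfg.lrs_re_sd_slope) for g in groups}

    n = cfg.n_lrs_subjects
    sexes = [FEMALE] * cfg.n_lrs_females + [MALE] * (n - cfg.n_lrs_females)
    sex_order = rng.permutation(n)
    rows = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        cohort = int(i % cfg.n_lrs_cohorts)
        birth = cohort_base[cohort] + int(rng.integers(0, 120))
        dam = dams[int(rng.integers(cfg.n_lrs_dams))].id
        group = dam_group[dam]
        group_sires = [s.id for s in sires if sire_group[s.id] == group]
        sire = group_sires[int(rng.integers(len(group_sires)))]
        m_days = int(rng.integers(cfg.mother_cores_min, cap + 1))
        f_days = int(np.clip(min(sire_depart[sire] - birth, m_days), 0, cap))
        lifespan = int(rng.integers(1850, 8400))
        rows.append(
            {
                "id": pid, "sex": sexes[sex_order[i]], "birth_day": birth,
                "death_day": birth + lifespan, "mother_id": dam, "sire_id": sire,
                "cohort": f"K{cohort}", "birth_group": group,
                "m_days": m_days, "f_days": f_days,
            }
        )
    truth = pd.DataFrame(rows)

    # linear predictor with the same transforms the model applies
    f = truth["f_days"].to_numpy(dtype=float)
    m = np.log(truth["m_days"].to_numpy(dtype=float))
    fz = (f - f.mean()) / f.std(ddof=1)
    mz = (m - m.mean()) / m.std(ddof=1)
    male = (truth["sex"] == MALE).to_numpy(dtype=float)
    lp = (
        cfg.lrs_intercept
        + cfg.lrs_sex_coef * male
        + cfg.lrs_father_coef * fz
        + cfg.lrs_mother_coef * mz
        + truth["mother_id"].map(re_mother).to_numpy()
        + truth["sire_id"].map(re_sire).to_numpy()
        + np.array([re_cohort[int(k[1:])] for k in truth["cohort"]])
        + truth["birth_group"].map(re_group).to_numpy()
        + np.array([slope_cohort[int(k[1:])] for k in truth["cohort"]]) * fz
        + truth["birth_group"].map(slope_group).to_numpy() * fz
    )
    if cfg.lrs_male_lognormal_sd > 0:
        noise = rng.normal(
            -0.5 * cfg.lrs_male_lognormal_sd**2, cfg.lrs_male_lognormal_sd, n
        )
        lp = lp + male * noise
    lrs = rng.poisson(np.exp(lp))
    truth["lrs"] = lrs
    truth["linear_predictor"] = lp

    individuals = list(dams) + list(sires)
    memberships: list[GroupMembership] = []
    for d in dams:
        memberships.append(GroupMembership(d.id, dam_group[d.id], d.birth_day,
                                           span_hi + _FAR_FUTURE))
    for s in sires:
        start = -8000
        dep = sire_depart[s.id]
        memberships.append(GroupMembership(s.id, sire_group[s.id], start, dep))
        memberships.append(GroupMembership(s.id, away_sires, dep, span_hi + _FAR_FUTURE))

    offspring_counter = 0
    for row in truth.itertuples(index=False):
        subj = Individual(
            id=row.id, sex=row.sex, birth_day=int(row.birth_day),
            death_day=int(row.death_day), mother_id=row.mother_id,
            sire_id=row.sire_id, cohort=row.cohort, natal_group=row.birth_group,
        )
        individuals.append(subj)
        memberships.append(
            GroupMembership(row.id, row.birth_group, int(row.birth_day),
                            int(row.birth_day) + int(row.m_days))
        )
        memberships.append(
            GroupMembership(row.id, away_subjects, int(row.birth_day) + int(row.m_days),
                            int(row.death_day))
        )
        # surviving offspring (censored alive) plus a few early deaths that
        # must not count toward LRS
        n_extra = int(rng.poisson(1.0))
        for k in range(int(row.lrs) + n_extra):
            offspring_counter += 1
            ob = int(rng.integers(row.birth_day + 1825, row.death_day))
            survives = k < int(row.lrs)
            individuals.append(
                Individual(
                    id=f"O{offspring_counter:04d}",
                    sex=FEMALE if rng.random() < 0.5 else MALE,
                    birth_day=ob,
                    death_day=None if survives else ob + int(rng.integers(1, 365)),
                    mother_id=row.id if row.sex == FEMALE else None,
                    sire_id=row.id if row.sex == MALE else None,
                )
            )
    return individuals, memberships, truth


# ---------------------------------------------------------------------------
# convenience wrapper


def simulate_all(cfg: SimConfig) -> SimOutput:
    """Generate every table, including pipeline-derived predictor truths."""
    rng = np.random.default_rng(cfg.seed)
    pop = simulate_population(cfg, rng)
    agonistic, protocols, affiliations = simulate_behavior(cfg, pop, rng)

    span = cfg.observation_span_days
    days = range(span)
    roster = dominance.daily_adult_male_roster(
        pop.individuals, pop.memberships, cfg.group, days
    )
    male_ranks = dominance.male_daily_ranks(agonistic, roster)
    fi_ranks = dominance.female_immature_daily_ranks(
        pop.female_order, pop.individuals, pop.memberships, cfg.group, days
    )
    ranks = pd.concat([male_ranks, fi_ranks], ignore_index=True)

    ev = pd.DataFrame(
        [(e.day, e.protocol_id, e.focal_id, e.partner_id) for e in affiliations],
        columns=["day", "protocol_id", "focal_id", "partner_id"],
    )
    pr = pd.DataFrame(
        [(p.protocol_id, p.focal_id, p.day, p.duration_min) for p in protocols],
        columns=["protocol_id", "focal_id", "day", "duration_min"],
    )
    predictor_truth = {}
    for window in (predictors.INFANCY_WINDOW, predictors.IMMATURITY_WINDOW):
        predictor_truth[window] = predictors.build_predictor_table(
            ev, pr, ranks, pop.individuals, pop.memberships, cfg.group,
            pop.focal_ids, window=window, sire_map=pop.true_sires,
        )

    morpho = simulate_morphometrics(cfg, pop, predictor_truth, rng)
    lrs_individuals, lrs_memberships, lrs_truth = simulate_lrs_dataset(cfg, rng)

    ground_truth = pd.DataFrame(
        {
            "id": pop.focal_ids,
            "true_sire": [pop.true_sires[f] for f in pop.focal_ids],
        }
    )
    ground_truth["mother_id"] = [
        next(i.mother_id for i in pop.individuals if i.id == f)
        for f in pop.focal_ids
    ]
    return SimOutput(
        config=cfg,
        population=pop,
        agonistic=agonistic,
        protocols=protocols,
        affiliations=affiliations,
        morpho=morpho,
        male_ranks=male_ranks,
        fi_ranks=fi_ranks,
        predictor_truth=predictor_truth,
        lrs_individuals=lrs_individuals,
        lrs_memberships=lrs_memberships,
        lrs_truth=lrs_truth,
        ground_truth=ground_truth,
    )
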