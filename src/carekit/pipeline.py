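"""Stage functions shared by the CLI: each reads and writes declared tables
under a run directory and returns the list of files it produced."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import assoc_stats, dominance, lrs_pipeline, morphometrics, parentage
from . import predictors as predictors_mod
from .config import resolve_sim_config, resolved_config_yaml
from .core_io import (
    AffiliationEvent,
    AgonisticEvent,
    GroupMembership,
    Individual,
    MorphoRecord,
    ProtocolRecord,
    read_table,
    records_to_frame,
    write_empty_table,
    write_table,
)
from .dominance import FemaleOrder
from .synthetic_data import simulate_all

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ranks", "predictors", "morpho", "correlate", "paternity", "lrs")

RESPONSE_WINDOWS = {
    "gain_p1": "infancy",
    "gain_p2": "immaturity",
    "qi": "immaturity",
    "tv": "immaturity",
}


def _write_df(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _write_records(records, record_type, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    if records:
        write_table(records, path)
    else:
        write_empty_table(record_type, path)
    return path


def stage_simulate(out: Path, cfg: dict, seed: Optional[int] = None) -> list[Path]:
    sim_cfg = resolve_sim_config(cfg, seed)
    sim = simulate_all(sim_cfg)
    files = [
        _write_records(sim.population.individuals, Individual, out / "demography.csv"),
        _write_records(sim.population.memberships, GroupMembership, out / "memberships.csv"),
        _write_records(sim.agonistic, AgonisticEvent, out / "agonistic_events.csv"),
        _write_records(sim.protocols, ProtocolRecord, out / "protocols.csv"),
        _write_records(sim.affiliations, AffiliationEvent, out / "affiliation_events.csv"),
        _write_records(sim.morpho, MorphoRecord, out / "morphometrics.csv"),
        _write_df(sim.genotype_frame(), out / "genotypes.csv"),
        _write_df(sim.ground_truth, out / "ground_truth.csv"),
        _write_records(sim.lrs_individuals, Individual, out / "lrs_demography.csv"),
        _write_records(sim.lrs_memberships, GroupMembership, out / "lrs_memberships.csv"),
        _write_df(sim.lrs_truth, out / "lrs_truth.csv"),
    ]
    order_path = out / "female_order.txt"
    order_path.write_text(
        "\n".join(sim.population.female_order.ordered_ids) + "\n", encoding="utf-8"
    )
    files.append(order_path)
    config_path = out / "resolved_config.yaml"
    config_path.write_text(resolved_config_yaml(cfg, sim_cfg), encoding="utf-8")
    files.append(config_path)
    return files


def _load_core(out: Path):
    individuals = read_table(out / "demography.csv", Individual)
    memberships = read_table(out / "memberships.csv", GroupMembership)
    return individuals, memberships


def stage_ranks(
    out: Path, cfg: dict, group: str, span: int
) -> list[Path]:
    individuals, memberships = _load_core(out)
    events = read_table(out / "agonistic_events.csv", AgonisticEvent)
    order = FemaleOrder(
        tuple(
            line.strip()
            for line in (out / "female_order.txt").read_text().splitlines()
            if line.strip()
        )
    )
    days = range(span)
    roster = dominance.daily_adult_male_roster(individuals, memberships, group, days)
    male_ranks = dominance.male_daily_ranks(
        events, roster,
        start_rating=cfg["ranks"]["start_rating"], k=cfg["ranks"]["k"],
    )
    fi_ranks = dominance.female_immature_daily_ranks(
        order, individuals, memberships, group, days
    )
    ranks = pd.concat([male_ranks, fi_ranks], ignore_index=True)
    return [_write_df(ranks, out / "ranks.csv")]


def stage_predictors(out: Path, cfg: dict, group: str) -> list[Path]:
    individuals, memberships = _load_core(out)
    events = records_to_frame(read_table(out / "affiliation_events.csv", AffiliationEvent))
    protocols = records_to_frame(read_table(out / "protocols.csv", ProtocolRecord))
    ranks = pd.read_csv(out / "ranks.csv")
    focals = sorted(
        i.id for i in individuals if i.cohort is not None and i.cohort.startswith("C")
    )
    files = []
    for name, window in (
        ("infancy", predictors_mod.INFANCY_WINDOW),
        ("immaturity", predictors_mod.IMMATURITY_WINDOW),
    ):
        table = predictors_mod.build_predictor_table(
            events, protocols, ranks, individuals, memberships, group,
            focals, window=window,
        )
        files.append(_write_df(table, out / f"predictors_{name}.csv"))
    return files


def _occasion_frames(
    morpho: Sequence[MorphoRecord],
    by_id: dict[str, Individual],
    windows: Sequence[tuple[int, int]],
) -> list[pd.DataFrame]:
    buckets: list[list[tuple[str, int, float]]] = [[] for _ in windows]
    for r in morpho:
        if r.body_mass_kg is None:
            continue
        age = r.day - by_id[r.id].birth_day
        for k, (lo, hi) in enumerate(windows):
            if lo <= age <= hi:
                buckets[k].append((r.id, age, r.body_mass_kg))
                break
    return [
        pd.DataFrame(rows, columns=["id", "age_days", "bm_kg"]) for rows in buckets
    ]


def stage_morpho(out: Path, cfg: dict) -> list[Path]:
    individuals, _ = _load_core(out)
    by_id = {i.id: i for i in individuals}
    morpho = read_table(out / "morphometrics.csv", MorphoRecord)
    windows = tuple(
        tuple(w) for w in cfg.get("simulate", {}).get(
            "measurement_windows", ((10, 136), (407, 517), (1502, 1588))
        )
    )
    occ = _occasion_frames(morpho, by_id, windows)
    fits = [morphometrics.fit_growth_candidates(df) if len(df) >= 4 else None
            for df in occ]
    p1_ages = morphometrics.STANDARD_AGES["P1"]
    p2_ages = morphometrics.STANDARD_AGES["P2"]

    def norm(fit, age):
        return morphometrics.normalize_mass(fit, age) if fit is not None else {}

    gain_p1 = morphometrics.mass_gain(norm(fits[0], p1_ages[0]), norm(fits[1], p1_ages[1]))
    gain_p2 = morphometrics.mass_gain(norm(fits[0], p2_ages[0]), norm(fits[2], p2_ages[1]))

    qi, tv = {}, {}
    for r in morpho:
        age = r.day - by_id[r.id].birth_day
        if windows[2][0] <= age <= windows[2][1]:
            if r.body_mass_kg is not None and r.crl_cm is not None:
                qi[r.id] = morphometrics.quetelet_index(r.body_mass_kg, r.crl_cm)
            if (
                r.body_mass_kg is not None
                and r.testis_len_mm is not None
                and r.testis_wid_mm is not None
            ):
                tv[r.id] = morphometrics.testis_volume(
                    r.testis_len_mm, r.testis_wid_mm, r.body_mass_kg
                )

    ids = sorted({r.id for r in morpho})
    responses = pd.DataFrame(
        {
            "id": ids,
            "gain_p1": [gain_p1.get(i) for i in ids],
            "gain_p2": [gain_p2.get(i) for i in ids],
            "qi": [qi.get(i) for i in ids],
            "tv": [tv.get(i) for i in ids],
        }
    )
    fit_rows = [
        {
            "occasion": k,
            "candidate": f.candidate if f else None,
            "aic": f.aic if f else None,
            "coefficients": ";".join(f"{c:.10g}" for c in f.coefficients) if f else None,
        }
        for k, f in enumerate(fits)
    ]
    return [
        _write_df(responses, out / "responses.csv"),
        _write_df(pd.DataFrame(fit_rows), out / "growth_fits.csv"),
    ]


def stage_correlate(out: Path, cfg: dict, seed: int) -> list[Path]:
    individuals, _ = _load_core(out)
    sexes = {i.id: i.sex for i in individuals}
    responses = pd.read_csv(out / "responses.csv")
    tables = {
        "infancy": pd.read_csv(out / "predictors_infancy.csv"),
        "immaturity": pd.read_csv(out / "predictors_immaturity.csv"),
    }
    rng = np.random.default_rng(seed)
    parts = []
    for response, window in RESPONSE_WINDOWS.items():
        part = assoc_stats.screen(
            tables[window],
            responses[["id", response]],
            sexes,
            predictor_columns=predictors_mod.PREDICTOR_COLUMNS,
            response_columns=[response],
            n_perm=cfg["correlate"]["n_perm"],
            rng=rng,
        )
        parts.append(part)
    report = pd.concat(parts, ignore_index=True)
    return [_write_df(report, out / "table1_report.csv")]


def stage_paternity(out: Path, cfg: dict, min_shared_loci: int = 12) -> list[Path]:
    individuals, memberships = _load_core(out)
    by_id = {i.id: i for i in individuals}
    genotypes = parentage.genotypes_from_long_table(pd.read_csv(out / "genotypes.csv", dtype=str))
    males = [i for i in individuals if i.sex == "male"]
    rows = []
    for ind in individuals:
        if ind.cohort is None or not ind.cohort.startswith("C"):
            continue
        if ind.id not in genotypes:
            continue
        cand_ids = parentage.candidate_sires(ind, males, memberships)
        cands = [genotypes[c] for c in sorted(cand_ids) if c in genotypes]
        if not cands:
            continue
        mother = genotypes.get(ind.mother_id) if ind.mother_id else None
        a = parentage.assign_paternity(
            genotypes[ind.id], mother, cands, min_shared_loci=min_shared_loci
        )
        best = min(a.mismatch_counts.values()) if a.mismatch_counts else None
        rows.append(
            {
                "offspring_id": a.offspring_id,
                "assigned_sire": a.assigned_sire,
                "rule": a.rule,
                "best_mismatches": best,
                "n_candidates": len(cands),
                "tied": a.tied,
            }
        )
    return [_write_df(pd.DataFrame(rows), out / "paternity.csv")]


def stage_lrs(out: Path, cfg: dict) -> list[Path]:
    individuals = read_table(out / "lrs_demography.csv", Individual)
    memberships = read_table(out / "lrs_memberships.csv", GroupMembership)
    records = lrs_pipeline.build_lrs_records(
        individuals, memberships,
        cap_days=cfg["lrs"]["cap_days"], survival_days=cfg["lrs"]["survival_days"],
    )
    full = lrs_pipeline.fit_lrs_glmm(records)
    null = lrs_pipeline.fit_lrs_glmm(records, include_fixed=False)
    stat, df, p = lrs_pipeline.lrt_full_vs_null(full, null)
    design = lrs_pipeline.transform_covariates(records)
    diagnostics = {
        "lrt": {"stat": stat, "df": df, "p": p},
        "dispersion": lrs_pipeline.dispersion_parameter(
            full.mu, records["lrs"].to_numpy(float), len(full.fixed_names)
        ),
        "vif": lrs_pipeline.vif(design),
        "random_effect_sd": dict(zip(full.term_names, full.theta.tolist())),
        "converged": full.converged,
    }
    if cfg["lrs"].get("stability"):
        stability = lrs_pipeline.stability_check(
            records, factors=("cohort", "birth_group")
        )
        ok = stability[~stability["failed"] & stability["effect"].notna()]
        diagnostics["stability"] = {
            eff: {
                "min": float(sub["estimate"].min()),
                "max": float(sub["estimate"].max()),
            }
            for eff, sub in ok.groupby("effect")
        }
    table2 = pd.DataFrame(
        {
            "term": full.fixed_names,
            "estimate": full.beta,
            "se": full.se,
            "z": full.z_values,
            "p": full.p_values,
        }
    )
    files = [
        _write_df(records, out / "lrs_records.csv"),
        _write_df(table2, out / "table2_report.csv"),
    ]
    diag_path = out / "lrs_diagnostics.json"
    diag_path.write_text(json.dumps(diagnostics, indent=2, sort_keys=True),
                         encoding="utf-8")
    files.append(diag_path)
    return files


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    out: Path,
    cfg: dict,
    seed: int,
    stages: Sequence[str] = STAGES,
) -> dict:
    """Run the requested sub-chain in dependency order; write a manifest.

    Checksums of the produced tables are reproducible for a fixed seed and
    config; the manifest also logs every stage parameter actually used.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    sim_cfg = resolve_sim_config(cfg, seed)
    group = sim_cfg.group
    span = sim_cfg.observation_span_days
    produced: dict[str, list[str]] = {}
    for stage in stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                files = stage_simulate(out, cfg, seed)
            elif stage == "ranks":
                files = stage_ranks(out, cfg, group, span)
            elif stage == "predictors":
                files = stage_predictors(out, cfg, group)
            elif stage == "morpho":
                files = stage_morpho(out, cfg)
            elif stage == "correlate":
                files = stage_correlate(out, cfg, seed)
            elif stage == "paternity":
                files = stage_paternity(out, cfg)
            else:
                files = stage_lrs(out, cfg)
        except FileNotFoundError as exc:
            raise RuntimeError(
                f"stage {stage!r} failed: missing input table ({exc})"
            ) from exc
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        produced[stage] = [f.name for f in files]
        logger.info("stage %s finished in %.2fs", stage, time.time() - t0)

    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            resolved_config_yaml(cfg, sim_cfg).encode()
        ).hexdigest(),
        "parameters": {
            "ranks": cfg["ranks"],
            "correlate": cfg["correlate"],
            "lrs": cfg["lrs"],
        },
        "stages": produced,
        "checksums": {
            name: _sha256(out / name)
            for names in produced.values()
            for name in names
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
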