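# carekit

A tested, reusable pipeline for asking whether adult-male affiliation with
immature group members predicts proxies of immature fitness, and whether
parent–offspring co-residence predicts lifetime reproductive success (LRS) —
together with a seeded synthetic-data generator that stands in for the field
data, so every stage is testable offline.

## What it computes

| Module | Contents |
| --- | --- |
| `carekit.core_io` | Domain record types (demography, memberships, agonistic/affiliation events, protocols, morphometrics) and validated CSV readers/writers. Dates are integer day offsets; membership intervals are half-open. |
| `carekit.dominance` | Daily dominance ranks: sequential Elo ratings for adult males (logistic update, start 1000, k = 100, both configurable) and a maintained adult-female order with each mother's living offspring inserted directly below her, youngest first. Each hierarchy is standardized per day onto [0, 1]. |
| `carekit.predictors` | Five per-focal predictors over a birth-relative window: mean male affiliation rate, mean paternal affiliation rate, mean focal rank, male-rank-weighted affiliation rate, and Shannon evenness of the partner distribution. Rates are per protocol day. |
| `carekit.morphometrics` | AIC-selected growth curves (linear / quadratic / logarithmic in age), residual-based normalization of body mass to standard ages (90 → 455 d and 90 → 1552 d), mass gain, Quetelet index `BM/CRL²·1000`, and ellipsoid testis volume `(4/3)πLW²/BM`. |
| `carekit.assoc_stats` | Spearman correlations (mid-rank, t-approximation p) of every predictor against every fitness proxy per sex, combined per set with Fisher's omnibus statistic `X = −2Σln p` (df = 2k) and calibrated by permutation of the response against the intact predictor matrix. |
| `carekit.parentage` | Exclusion-based paternity: candidate sires must be > 1250 d old at the birth and present ≥ 200 d before it; assignment needs a clean best candidate with a mismatch gap (strict 0 vs ≥ 2, relaxed 0 vs 1, or 1 vs ≥ 3), over ≥ 12 shared loci. |
| `carekit.lrs_pipeline` | LRS (offspring surviving their first year), capped co-residence day counts from membership intervals, and a Poisson log-link mixed model of LRS on sex, z(father co-residence) and z(log mother co-residence) with crossed random intercepts (mother, sire, cohort, birth group) and father-co-residence random slopes — plus LRT, Pearson dispersion, VIF and leave-one-level-out stability diagnostics. The Laplace-ML fitter lives in `carekit._glmm`. |
| `carekit.synthetic_data` | Deterministic generator for both data arms with known latent strengths, true sires, injected predictor→mass-gain effects and a co-residence/LRS model realized through actual membership intervals. |

## Command line

One subcommand per stage plus an orchestrator; every stage reads and writes
CSV tables in the run directory:

```sh
carekit run --out runs/demo --seed 7                 # full chain
carekit run --out runs/demo --seed 7 --stages simulate,ranks
carekit simulate --out runs/demo --seed 7 --config config.yaml
carekit ranks --out runs/demo --k 100 --start-rating 1000
carekit predictors --out runs/demo
carekit morpho --out runs/demo
carekit correlate --out runs/demo --n-perm 1000 --seed 7
carekit paternity --out runs/demo --min-shared-loci 12
carekit lrs --out runs/demo --cap-days 1461 --survival-days 365
```

`run` produces, among others, `table1_report.csv` (per-sex correlation
screen with omnibus rows), `table2_report.csv` (GLMM fixed effects),
`lrs_diagnostics.json` (LRT, dispersion, VIF, random-effect SDs) and
`run_manifest.json` with SHA-256 checksums — bit-identical across reruns
with the same seed and config.

A YAML config can override generator and stage parameters:

```yaml
simulate: {n_focals: 55, affiliation_rate: 1.78}
correlate: {n_perm: 1000}
lrs: {cap_days: 1461, survival_days: 365, stability: true}
```

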