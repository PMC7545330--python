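# iladyn

Emotion dynamics from intensive longitudinal assessments.

`iladyn` computes 11 person-level emotion-dynamics measures — mean PA/NA
level, variability (within-person SD), instability (RMSSD), inertia
(empirical-Bayes autoregressive slope), emotion network density, mixed
emotions (MIN index), and emotional dialecticism — from affect ratings
collected under three assessment designs:

* **EMA** — momentary smartphone prompts, ~6 per day over a week;
* **EOD** — one end-of-day diary rating per day;
* **DRM** — one day reconstructed as self-defined episodes rated 0–6
  (rescaled to 0–100 at ingest via `100 * (raw + 0.5) / 7`).

It then runs a cross-method comparability analysis: repeated-measures
ANOVA with Bonferroni pairwise tests, Wald tests for equality of
dependent correlations (Fisher-z scale, Olkin–Siotani covariance, with a
bootstrap fallback), within-method correlation networks with
node-strength centrality, and health-outcome associations with
incremental-validity regressions.

Because the original panel data are not deposited, a synthetic-study
generator stands in: all three methods sample one shared per-person
latent bivariate VAR(1) affect process with person-random set-points,
AR/cross-lag coefficients, innovation scales, and PA–NA innovation
correlation, so every measure has a known ground truth.

## CLI

The pipeline runs as three stages with CSV files as contracts, so real
study data can replace the simulator at the `observations.csv` boundary:

```sh
ila simulate --seed 1 --out data/            # observations/episodes/health CSVs + truth.json
ila dynamics --data data/ --out profiles/    # profiles.csv: 11 measures per person x method
ila compare  --data profiles/ --out results/ # comparison/network/strength/health tables
```

`ila simulate --config cfg.yaml` accepts a YAML/JSON file mirroring
`GeneratorConfig` field names. Useful flags: `--min-obs` (inclusion
filter, default 4 observations per method), `--no-center` (disable
within-person centering of lagged predictors), `--rank` (Spearman
correlations), `--plot` (network PNGs). Every stage writes a
`*_meta.json` sidecar recording the seed and flags; identical seed and
config reproduce outputs byte-for-byte. Validation errors exit with
code 2.

Input formats (RFC-4180 CSV with header):

* `observations.csv`: `person_id, method, timestamp (ISO-8601), day_index, pa, na`
* `episodes.csv`: `person_id, date, start_time, end_time, raw_pa, raw_na, label`
* `health.csv`: `person_id, day_index, general_health (1–5, 5 = excellent), pain (0–100), fatigue (0–100)`

## Notes on conventions

* Lag pairs for instability/inertia/density follow per-method gap rules:
  EMA drops overnight pairs and gaps > 10 h; DRM uses episode-midpoint
  timestamps with the 10 h cap; EOD keeps only consecutive-day pairs.
* Mixed models are REML via statsmodels MixedLM, full random-effects
  covariance first with an automatic diagonal fallback (flagged in the
  fit) on non-convergence.
* The MIN index is `(PA + NA) − |PA − NA| = 2 · min(PA, NA)` averaged
  over time points, on a 0–200 scale.
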