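# pvsignal

Disproportionality analysis of spontaneous adverse-event (ICSR) line
listings: reporting odds ratio (ROR) and proportional reporting ratio (PRR)
with Woolf 95% confidence intervals, uncorrected Pearson chi-square tests,
and the EMA signal-of-disproportionate-reporting (SDR) rules — applied to
antiseizure-medication reaction exports stratified by market era (old vs
new), ATC N03A chemical subgroup, system organ class (SOC), seriousness
criteria, outcomes and SUDEP.

## What it does

* **Ingest** (`pvsignal.ingest` / `pvsignal.reference`) — parse delimited
  line listings (one row per case report, packed reaction-list field),
  normalize demographics/outcome/seriousness tokens, resolve substances
  against a bundled ATC N03A catalogue (old/new era, chemical subgroup,
  salt-form folding) and map preferred terms to SOCs. Unparseable rows go
  to an error report, never silently dropped. Gzip input supported.
* **Statistics** (`pvsignal.stats`) — 2x2 `ContingencyTable`, ROR/PRR with
  log-normal CIs, Pearson chi-square (r x c, optional Yates), "not
  countable" zero-cell policy with an opt-in Haldane–Anscombe correction,
  SDR rules (PRR CI lower bound ≥ 1 with ≥ 3 cases; PRR > 2 with χ² > 4),
  optional Benjamini–Hochberg adjustment.
* **Scans** (`pvsignal.scans`) — per-SOC, per-seriousness-criterion
  (multi-label), per-outcome and SUDEP scans under era / subgroup /
  substance groupings with `sex=female,age=18-64,year=2012:2021` strata
  filters; top-PT tables; yearly SOC series; demographic chi-square tests.
* **Synthetic data** (`pvsignal.simulate`) — a seeded generator with
  planted drug–event odds ratios (per-report RNG substreams, order
  independent), and a deterministic `margin_replicator` that emits datasets
  whose PT-level cell counts equal requested margins exactly.
* **CLI** (`pvsignal`) — `ingest`, `analyze`, `simulate`, `signal`
  subcommands; exit codes 0 / 2 (usage, config) / 3 (data validation).

## CLI examples

```sh
# simulate a listing with a planted odds ratio, then analyze it
pvsignal simulate -o sim/ --seed 42 --n-reports 10000
pvsignal analyze sim/simulated.csv -o out/ --by soc --grouping era
pvsignal analyze sim/simulated.csv -o out/ --by seriousness --grouping subgroup \
    --strata sex=female,year=2012:2021 --format tsv
pvsignal analyze sim/simulated.csv -o out/ --by demographics
pvsignal signal out/soc_era.csv -o out/signals.csv
```

Scan tables are delimited text with the columns
`exposure,event,a,b,c,d,ror,ror_l,ror_u,prr,prr_l,prr_u,chi2,dof,p,n_cases,countable,sdr_ci_rule,sdr_chi2_rule`
plus a JSON sidecar carrying the scan spec and a dataset hash.

## Notes

* Reference data bundled under `pvsignal/data/`: the ATC N03A catalogue
  with old/new era labels, a salt/ester synonym table, and a small
  demonstration PT→SOC map (a licensed terminology map can be supplied via
  `--map`).
* Published CI bounds for the per-SOC RORs use an unstated method narrower
  than the Woolf interval and are deliberately not reproduction targets;
  the Woolf implementation is validated by simulation coverage instead.
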