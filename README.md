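# pvsignal

Disproportionality signal detection for FAERS-style spontaneous adverse-event
reports: parse quarterly `$`-delimited DEMO/DRUG/REAC dumps, deduplicate case
versions, standardize drug names, build report×event 2×2 contingency tables at
MedDRA PT and SOC level, and score every drug–event pair with ROR, PRR (with
Yates χ²) and the BCPNN information component (IC, E(IC), V(IC),
IC025 = E(IC) − 2√V(IC)) under the standard signal thresholds:

| method | statistic | signal rule |
|---|---|---|
| ROR | (a·d)/(b·c), lognormal Wald 95% CI | a ≥ 3 and CI lower bound > 1 |
| PRR | (a/(a+b))/(c/(c+d)), Yates χ² | a ≥ 3, CI lower bound > 1, χ² > 4 |
| BCPNN | IC = log₂(aN/((a+b)(a+c))) | IC025 > 0 |

A fully deterministic synthetic-FAERS generator with known ground truth
(injected relative risks, duplicate case versions, demographics) makes the
whole pipeline testable at desk scale without any download.

## Layout

- `pvsignal.faers_io` — readers/writers for the quarterly dialect plus the
  PT→SOC map and drug-synonym dictionary formats
- `pvsignal.case_processing` — case deduplication (latest version per caseid),
  drug-name standardization, target-report selection, age binning
- `pvsignal.contingency` — device-PT merge rule, event building, 2×2 tables
  (overall / stratified / yearly time-scan series)
- `pvsignal.signal_stats` — ROR / PRR / BCPNN estimators, thresholds, IC
  ranking; vectorized over whole signal tables
- `pvsignal.synthetic` — generator, ground truth, and the analytic
  expected-table oracle
- `pvsignal.reporting` — study orchestration and the CSV report surfaces
  (screening flow, quarterly counts, demographics, PT/SOC/subgroup signal
  tables, time-scan)

## CLI

Generate a synthetic study and analyze it:

```bash
pvsignal simulate --outdir sim --seed 4 --n-cases 20000
cat > study.yaml <<EOF
input_dir: sim
output_dir: out
pt_soc_map_path: sim/pt_soc_map.txt
synonym_dict_path: sim/synonyms.txt
targets:
  BUD/GLY/FOR: {start: 2020Q3, end: 2023Q4}
  FF/UMEC/VI:  {start: 2020Q1, end: 2023Q4}
EOF
pvsignal run --config study.yaml
```

Per-drug quarter windows may differ; each drug's 2×2 background is every other
report loaded in its own window. Outputs are deterministic CSVs under
`output_dir` plus `run_log.txt` with all screening counts.

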