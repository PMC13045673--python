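# crseligible

Biologic-indication analysis for chronic rhinosinusitis with nasal polyps
(CRSwNP), built for clinical epidemiologists working with registry-style
per-patient snapshots in which almost any field can be missing.

Two international recommendation sets define when a CRSwNP patient is
indicated for biologic therapy (dupilumab, mepolizumab, omalizumab, ...):

* **EUFOREA 2021** — *uncontrolled severe* disease:

  `(ESS ≥ 1 ∨ SCS ≥ 1/yr) ∧ NPS ≥ 4 ∧ (SNOT-22 ≥ 35 ∨ VAS_TSS ≥ 50 ∨ VAS_NB ≥ 50 ∨ VAS_LoS ≥ 52)`

* **EPOS/EUFOREA 2023** — prior surgery plus 3 of 5 uncontrolled-severe
  criteria:

  `ESS ≥ 1 ∧ |{type-2, SCS ≥ 2/yr, SNOT-22 ≥ 40, VAS_LoS ≥ 52, asthma}| ≥ 3`,
  where `type-2 = (BEC ≥ 150 cells/µL ∨ IgE ≥ 100 IU/mL)`

Real records rarely carry every field, so the engine evaluates these rule
trees in **strong Kleene three-valued logic**: each leaf is TRUE, FALSE or
UNKNOWN, and a composite verdict is determinate whenever the known fields
force it (a failed surgery gate settles the 2023 rule even with missing
labs). A patient is *evaluable* for a rule iff the composite verdict is
determinate — which is why each reported proportion carries its own
denominator.

The package provides:

* `cohort_model` — record schema, validation, CSV I/O (missing = empty cell).
* `criteria_engine` — declarative, JSON-serializable rule trees; Kleene
  connectives and the at-least-k operator; both rule sets bundled.
* `cohort_evaluation` — per-criterion prevalence tables, indication ×
  treatment cross-tabs, treatment-gap percentages, between-rule-set
  concordance (determinate-case denominators throughout).
* `stats` — two-sided Fisher's exact test by hypergeometric enumeration,
  half-up percentage rounding, median/IQR summaries.
* `synthetic_cohort` — a generator whose marginals, category frequencies
  and per-field missingness are calibrated to a published multicentre
  European CRSwNP cohort (n = 206), so the whole pipeline runs without any
  real registry data.
* `crseligible` CLI — `generate`, `evaluate`, `simulate`.

## Worked example

```python
from crseligible import PatientRecord, eval_euforea2021, eval_epos2023

rec = PatientRecord(patient_id="P017", n_ess=1, n_scs_past_year=0, nps=5,
                    snot22=41, vas_los=63.0, bec=420.0, asthma=True)
v = eval_epos2023(rec)
print(v.overall, v.evaluable)
print({k: s.value for k, s in v.components.items()})
```

```
TriState.TRUE True
{'ess': 'true', 'bec': 'true', 'ige': 'unknown', 'type2': 'true',
 'scs': 'false', 'snot22': 'true', 'vas_los': 'true', 'asthma': 'true',
 'uncontrolled_severe': 'true', 'overall': 'true'}
```

The IgE is missing, but BEC ≥ 150 already proves type-2 inflammation, and
type-2 + SNOT-22 + smell VAS + asthma are four criteria — the verdict is
determinate TRUE.

Cohort-level, on a synthetic cohort emulating the published one:

```python
from crseligible import indication_table, euforea_2021
from crseligible.synthetic_cohort import default_config, simulate_cohort

cohort = simulate_cohort(default_config(n=206, seed=1))
for row in indication_table(cohort, euforea_2021()):
    print(f"{row.criterion_id:20s} {row.n_met:>4d}/{row.n_evaluable:<4d} {row.pct}")
```

```
ess                   136/197  69.0
scs                    89/188  47.3
history               171/197  86.8
nps                    67/161  41.6
snot22                 97/184  52.7
vas_tss                82/197  41.6
vas_nb                 78/194  40.2
vas_los               113/201  56.2
uncontrolled          186/198  93.9
uncontrolled_severe    63/160  39.4
overall                56/168  33.3
```

Each row is `n_met / n_evaluable` with the half-up one-decimal percentage;
denominators differ per row because evaluability differs per criterion.
Note how `history` (an OR) is evaluable for 197 patients although its
`scs` component is evaluable for only 188 — Kleene logic at work.

From the shell, the same run is:

```sh
crseligible simulate --out report/ --n 206 --seed 1 --formats csv,json,md
```

which writes `cohort_summary.csv`, one indication table per rule set, the
treatment cross-tab with Fisher's exact comparison and gap percentages,
the concordance summary, `report.json`, and a `manifest.json` capturing
seed and inputs for bit-identical re-runs.

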