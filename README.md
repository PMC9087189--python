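# xenodose

Translate mouse xenograft efficacious doses into predicted human
doses, and measure how well such simple translations work.

`xenodose` is a library (with a thin CLI) for discovery-stage DMPK and
pharmacology work in oncology. It implements:

* **BSA scaling** — mouse mg/kg × 3 → mg/m², ÷ 37 → human mg/kg, the
  standard body-surface-area human-equivalent-dose (HED) conversion.
  A 37 mg/kg mouse dose maps to exactly 3 mg/kg in human.
* **BW carryover** — mg/kg in mouse = mg/kg in human, the preferred
  rule for intravascular proteins above 100 kDa (`select_method`
  picks per molecular weight; `mrsd_from_hed` divides an HED by a
  safety factor, default 10, for a starting-dose estimate).
* **Retrospective evaluation** — per-drug symmetric fold error
  `max(predicted/clinical, clinical/predicted)` and class-level
  "% within 2× / 3×" summary tables, with log-log scatter export and
  optional bootstrap intervals.
* **Curation rules as code** — drug-table CSV schema with validation,
  TGI ≥ 60 % efficacy floor, Day-1 24-h dose totals, clinical-range
  averaging, and exclusion of MTD-only and syngeneic-model records.
* **Calibrated synthetic cohorts** — drug tables whose log10-normal
  prediction error is solved analytically from target within-2×/3×
  fractions, so the whole pipeline is testable with no external data.

See `docs/methods.md` for the model, assumptions and limitations, and
`examples/` for one short script per capability.

## Worked example

```python
from xenodose import (
    ClassErrorModel, Method, ModalityClass,
    bsa_predict_human_dose, calibrate, evaluate, generate, pct_within,
)

# one dose: BSA-scale a 37 mg/kg mouse dose
print(bsa_predict_human_dose(37.0))   # -> 3.0  (mg/kg, x3 then /37)

# a cohort: calibrate an error model to 63.3 % within 2x, 85.6 % within 3x,
# generate 90 small-molecule records, and evaluate them
mu, sigma = calibrate(0.633, 0.856)
print(round(mu, 4), round(sigma, 4))  # -> 0.1858 0.2669  (log10 scale)

rows = evaluate(
    generate(90, ClassErrorModel(ModalityClass.SM_PO, mu=mu, sigma=sigma),
             seed=42),
    Method.BSA,
)
print(f"{pct_within(rows, 2):.1f} {pct_within(rows, 3):.1f}")  # -> 73.3 90.0
```

The first number is the exact BSA conversion. The calibrated
(mu, sigma) are the mean and SD of the log10 fold deviation whose
analytic within-2×/3× probabilities equal the targets; the 90-drug
cohort then lands near those targets, off by binomial sampling noise
(standard error ≈ 4–5 percentage points at n = 90 — at 100,000 drugs
the empirical values agree to a fraction of a point, see
`examples/calibrate_error_model.py`).

The same pipeline runs from the shell:

```bash
xenodose convert --dose 37 --species mouse --method bsa
xenodose simulate --n 90 --modality SM_PO --p2 0.633 --p3 0.856 \
    --seed 42 --out cohort.csv
xenodose report cohort.csv --out report/ --method both
```

`report/` then contains the class summary CSV, the per-drug table, a
log-log scatter (CSV + PNG) with identity and ±3-fold lines, and a run
log with the config fingerprint and exclusion counts.

## Evaluating your own curated table

`read_records` loads CSVs in the documented schema (see the
`xenodose.records` module docstring): one row per drug with modality
class, mouse dose + unit + Day-1 administration count, xenograft model
and response, clinical dose (or range) + unit, indication, curation
flags and reference. Place curated reference tables anywhere and run
`xenodose evaluate table.csv --method bsa` (or `bw`, `auto`, `both`);
if files named `data/reference/small_molecules.csv` and
`data/reference/large_molecules.csv` exist in the repository, the test
suite additionally checks the published class accuracies against them.

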