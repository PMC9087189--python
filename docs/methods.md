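# Methods

## The dose-translation problem

Early oncology discovery teams routinely ask what human dose a mouse
xenograft efficacious dose implies. `xenodose` implements the two
simple, dose-based answers used for that purpose and the retrospective
machinery to measure how well they work:

* **Body-surface-area (BSA) scaling.** A mouse dose in mg/kg is
  multiplied by the mouse surface-area factor 3 to give mg/m², then
  divided by the human factor 37 to give the human equivalent dose
  (HED) in mg/kg. The two factors are species-level constants (body
  weight over body surface area); composing them makes the full
  conversion a single multiplication by 3/37, so a 37 mg/kg mouse dose
  maps to exactly 3 mg/kg in human.
* **Body-weight (BW) carryover.** The mg/kg dose is carried across
  species unchanged. This is the appropriate default for intravascular
  proteins above 100 kDa, whose clearance is dominated by
  target-mediated disposition and FcRn recycling rather than by
  surface-area-scaled physiology.

`select_method` encodes the molecular-weight rule with a strict
inequality: exactly 100 kDa still uses BSA. A bispecific T-cell
engager at 54.1 kDa therefore scales by BSA, while an intact IgG
(~150 kDa) carries over by BW. `mrsd_from_hed` divides an HED by a
safety factor (default 10) to give a maximum recommended starting
dose; it is a labelled helper, not a safety recommendation engine.

## Units and normalization

All internal arithmetic is in mg/kg; conversions happen at the
boundary. Absolute-mg doses divide by the species default body weight
(70 kg human, 25 g mouse) and mg/m² doses divide by the species
surface-area factor. Regulatory tables sometimes pair the human
factor 37 with a 60 kg reference weight; this package pairs it with
70 kg, the convention of the retrospective dataset it models, and a
user who prefers 60 kg can supply a species profile override. Clinical
doses labelled in mg/m² are converted to mg/kg (÷37) before any
fold-error comparison — comparing in mg/kg space is a documented
assumption, since dose-range recommendations do not state the space
they should be compared in.

The comparable nonclinical quantity across intermittent schedules is
the **Day-1 24-hour total**: the sum of all administrations in the
first day, each normalized to mg/kg. A drug dosed once every four days
counts only its Day-1 dose; schedule differences beyond Day 1 are
deliberately not modelled. Clinical dose ranges contribute the
arithmetic mean of their normalized endpoints ("the average dose"),
which makes the result invariant to endpoint order and labelling
units.

## Curation rules

Literature curation is mostly human judgment (study selection,
model/route matching, one indication per drug); those decisions travel
as provenance fields and flags rather than being recomputed. The
computable rules are:

* **Efficacy floor**: tumor stasis or regression always counts as an
  efficacious response; tumor growth inhibition (TGI) counts at
  ≥ 60 % (boundary inclusive). Metrics without a numeric convention
  (T/C, survival) count only when the curator recorded the source
  authors' significance call. TGI above 100 % (regressions reported on
  the TGI scale) draws a warning but is accepted literally.
* **Exclusions**: records flagged as MTD-only (efficacy shown only at
  a maximum tolerated dose, so no dose-response) or from syngeneic
  models (mouse tumors, used for immuno-oncology, with known
  human-vs-mouse disconnects) are removed before evaluation; all
  other flags are annotations. The partition is pure — no record is
  modified.

## Accuracy metric

Per drug, the **fold error** is `max(predicted/clinical,
clinical/predicted)`: symmetric, scale-invariant, ≥ 1, equal to 1 only
for an exact prediction. "Within k×" means fold error ≤ k, boundary
inclusive — "within 3-fold" reads as a closed bound, and the inclusive
convention makes table outputs deterministic. Percentages are kept
unrounded internally and displayed at one decimal (`format_pct`), so
display rounding can never hide a mismatch of more than 0.05 points.
Class summaries follow the standard retrospective layout: small
molecules split IV / PO / pooled / immuno-or-hormone-targeted, large
molecules split mAb+ADC / ADC / mAb / checkpoint; BW columns are
reported only for large-molecule groups. Empty groups are omitted with
a logged warning rather than emitted as zero rows. Bootstrap
percentile intervals for the within-k percentage are an addition
beyond the published point estimates and are labelled as such in
output.

## Synthetic cohorts and calibration

The curated dose tables behind published retrospective analyses are
journal supplements without a machine-readable accession, so the test
surface is a generator that reproduces their statistical structure.
On log-log axes the clinical dose scatters multiplicatively around the
prediction; we model the log10 fold deviation ε as Normal(mu, sigma),
giving the analytic within-k probability

    P(k) = Φ((log10 k − mu)/σ) − Φ((−log10 k − mu)/σ).

`calibrate(p2, p3)` inverts this two-equation system numerically
(Powell hybrid with analytic Jacobian, trust-region polish, and a
nested-bisection fallback near mu = 0, where the residual is even in
mu and Newton steps stall); residuals are verified below 1e-8. P(k) is
even in mu, so the sign is not identified; `calibrate` returns mu ≥ 0
and the caller chooses the direction (positive mu with
`clinical = predicted × 10^ε` means systematic under-prediction).

A genuine property of this model, found during implementation: along
the contour P(2) = p2, P(3) is minimized by the unbiased model, so the
pair (p2, p3) is feasible only when p3 is at or above that envelope.
Published class rows whose within-2× and within-3× values sit close
together — the hallmark of heavier-than-log-normal tails — fall below
it and are rejected with an explicit error rather than approximated
silently. Where a near-envelope target must be emulated (the
large-molecule BW cohort in the reproduction script), sigma is matched
to the within-3× point alone with mu = 0, the package's documented
choice for such targets.

Generator defaults: mouse doses log-uniform over 0.1–100 mg/kg (the
typical xenograft efficacious range); routes follow the modality class
(PO for oral small molecules, IV otherwise); molecular weights sampled
from class-typical ranges (IgG ≈ 140–155 kDa, bispecifics 50–60 kDa);
responses drawn efficacious by construction (TGI 60–98 % or
regression) so generated tables survive curation unchanged. Everything
is deterministic for a fixed seed. What the generator does **not**
emulate: heavy-tailed error distributions, correlation between dose
level and prediction error, multi-indication drugs, non-Day-1 schedule
structure, and PK differences underlying the errors. Passing tests
therefore demonstrate that the pipeline measures what it claims on
data with known structure — not that real drug data are log-normal.

## Numerical and design choices

* Negative doses and nonpositive molecular weights fail fast
  (`DoseDomainError`) rather than being clamped; rows with missing
  doses fail loudly with the drug name rather than being dropped.
* Record containers are frozen dataclasses; CSV errors name the
  1-based row and the column.
* The species registry ships exactly mouse and human; user species are
  YAML extensions and can never shadow the built-ins.
* `evaluate(..., method="auto")` uses the 100 kDa rule when a
  molecular weight is present and falls back to BSA otherwise (only
  large-molecule classes require a molecular weight).
* Report runs are deterministic per (config, seed); every CSV carries
  a schema version and a 12-hex-digit fingerprint of the analysis
  parameters (output paths excluded, so relocating a run does not
  change its identity).
* Scale of the default test runs: property suites use up to 1,000
  random instances; statistical closure checks use cohorts of
  5,000–100,000 generated drugs, with agreement asserted within 3
  binomial standard errors; parameter recovery uses n = 10,000.

## Known limitations

Dose-based translation assumes physiology, PK/PD and efficacy scale
with body surface area (or not at all, for BW carryover); it is a
statistical screen, not a mechanistic prediction, and exposure-based
or PBPK methods should supersede it when available. The evaluation
reproduces whatever its input tables yield; published retrospective
tables can contain internal rounding inconsistencies (e.g. a
percentage printed as 77.7 where 7/9 = 77.8), which this package
neither replicates nor corrects — it simply reports its own computed
values at one-decimal display.
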