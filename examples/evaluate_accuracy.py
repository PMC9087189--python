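"""Score predicted vs clinical doses for a cohort and summarize by class.

Builds a synthetic 90-drug small-molecule cohort whose log-normal
prediction error is calibrated so that 63.3 % of drugs fall within
2-fold and 85.6 % within 3-fold of the clinical dose, then runs the
evaluation and prints the class summary and a bootstrap interval.
"""

from xenodose import (
    ClassErrorModel,
    Method,
    ModalityClass,
    bootstrap_ci,
    calibrate,
    evaluate,
    generate,
    pct_within,
    summarize,
)

mu, sigma = calibrate(0.633, 0.856)
print(f"calibrated error model: mu={mu:.4f}, sigma={sigma:.4f} (log10 scale)")

model = ClassErrorModel(ModalityClass.SM_PO, mu=mu, sigma=sigma)
records = generate(90, model, seed=42)
rows = evaluate(records, Method.BSA)

for k in (2, 3):
    low, high = bootstrap_ci(rows, k, n_boot=1000, seed=42)
    print(f"within {k}x: {pct_within(rows, k):.1f}%  "
          f"(bootstrap 95% CI [{low:.1f}, {high:.1f}])")

for s in summarize(rows):
    print(f"{s.class_label} / {s.subclass_label}: n={s.n}, "
          f"2x={s.pct_within_2x_bsa:.1f}%, 3x={s.pct_within_3x_bsa:.1f}%")

# With 90 drugs the empirical fractions scatter around the calibrated
# 63.3 / 85.6 targets with a binomial standard error of ~4-5 points,
# so deviations of up to ~10 points are unremarkable; the bootstrap
# interval quantifies that uncertainty for the cohort actually drawn.
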