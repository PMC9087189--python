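"""Synthetic drug tables with class-specific multiplicative prediction error.

Retrospective dose-translation datasets are curated by hand from the
literature and are not downloadable, so end-to-end testing needs a
generator that reproduces their statistical structure: on log-log axes
the clinical dose scatters multiplicatively around the predicted dose.
We model the log10 fold deviation ε as Normal(mu, sigma), giving an
analytic within-k probability

    P(k) = Φ((log10 k − mu)/σ) − Φ((−log10 k − mu)/σ)

which can be inverted: ``calibrate(p2, p3)`` finds the (mu, σ) whose
within-2× and within-3× probabilities match two target fractions, so a
generated cohort carries a known ground truth for the whole pipeline.

P(k) is symmetric under mu → −mu; ``calibrate`` returns mu ≥ 0 by
convention and the caller chooses the sign (positive mu with
``clinical = predicted × 10^ε`` means the clinical dose tends to exceed
the prediction, i.e. the method under-predicts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .records import (
    LARGE_MOLECULE_CLASSES,
    DrugRecord,
    ModalityClass,
    Response,
    ResponseMetric,
)
from .scaling import (
    HUMAN,
    MOUSE,
    DoseSpec,
    Method,
    Route,
    UnitBasis,
    bsa_predict_human_dose,
    bw_predict_human_dose,
)

__all__ = [
    "ClassErrorModel",
    "within_k_probability",
    "calibrate",
    "generate",
]


def within_k_probability(k: float, mu: float, sigma: float) -> float:
    """P(fold error ≤ k) under the log10-normal deviation model."""
    if k < 1:
        raise ValueError(f"fold threshold must be ≥ 1, got {k}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    a = math.log10(k)
    return float(stats.norm.cdf((a - mu) / sigma) - stats.norm.cdf((-a - mu) / sigma))


@dataclass(frozen=True)
class ClassErrorModel:
    """Error model for one modality class.

    ``mu`` and ``sigma`` are the mean and SD of the log10 fold deviation
    (mu = 0: unbiased predictions). ``dose_scale_range`` spans the mouse
    doses to sample, log-uniformly, in mg/kg — 0.1–100 covers typical
    xenograft efficacious doses. ``method`` is the prediction rule the
    deviation is defined against.
    """

    modality_class: ModalityClass
    mu: float
    sigma: float
    dose_scale_range: tuple[float, float] = (0.1, 100.0)
    method: Method = Method.BSA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        lo, hi = self.dose_scale_range
        if not (0 < lo < hi):
            raise ValueError(
                f"dose_scale_range must satisfy 0 < low < high, got "
                f"{self.dose_scale_range}"
            )

    def within_k(self, k: float) -> float:
        return within_k_probability(k, self.mu, self.sigma)


def min_p3_given_p2(p2: float) -> float:
    """Smallest within-3× probability the model allows at a given P(2).

    Along the contour P(2) = p2, P(3) is minimized by the unbiased
    model (mu = 0): bias shifts the acceptance window into one tail,
    which inflates P(3) relative to P(2). Real retrospective tables can
    therefore present (p2, p3) pairs — heavy-tailed error patterns —
    that no log-normal deviation model reproduces exactly.
    """
    if not 0.0 < p2 < 1.0:
        raise ValueError(f"need 0 < p2 < 1, got {p2}")
    sigma = math.log10(2) / stats.norm.ppf((1 + p2) / 2)
    return float(2 * stats.norm.cdf(math.log10(3) / sigma) - 1)


def calibrate(p2: float, p3: float, tol: float = 1e-10) -> tuple[float, float]:
    """Solve for (mu, sigma) with analytic P(2) = p2 and P(3) = p3.

    Requires 0 < p2 < p3 < 1 (within-k fractions are strictly
    increasing in k under the model) and p3 ≥ :func:`min_p3_given_p2`
    (the model's feasibility envelope). Solved numerically in
    (mu, log sigma); residuals are verified below 1e-8 and mu ≥ 0 is
    returned (the sign is not identified by the two probabilities).
    """
    if not (0.0 < p2 < p3 < 1.0):
        raise ValueError(
            f"need 0 < p2 < p3 < 1, got p2={p2}, p3={p3} "
            "(within-k fractions must increase strictly with k)"
        )
    p3_floor = min_p3_given_p2(p2)
    if p3 < p3_floor - 1e-12:
        raise ValueError(
            f"(p2={p2}, p3={p3}) is infeasible under the log10-normal "
            f"deviation model: at P(2)={p2} the smallest attainable "
            f"P(3) is {p3_floor:.6f} (unbiased case)"
        )
    if p3 <= p3_floor + 1e-12:
        # on the envelope: exactly the unbiased closed form
        return 0.0, math.log10(2) / float(stats.norm.ppf((1 + p2) / 2))

    def residual(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        return np.array(
            [
                within_k_probability(2, mu, sigma) - p2,
                within_k_probability(3, mu, sigma) - p3,
            ]
        )

    def jacobian(params: np.ndarray) -> np.ndarray:
        # analytic: finite differencing is too noisy in the near-flat
        # mu direction at large sigma
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        rows = []
        for k in (2, 3):
            a = math.log10(k)
            z_hi = (a - mu) / sigma
            z_lo = (-a - mu) / sigma
            phi_hi, phi_lo = stats.norm.pdf(z_hi), stats.norm.pdf(z_lo)
            d_mu = (-phi_hi + phi_lo) / sigma
            d_log_sigma = -(phi_hi * z_hi - phi_lo * z_lo)
            rows.append([d_mu, d_log_sigma])
        return np.array(rows)

    # Two analytic seeds: the unbiased closed form (mu = 0, sigma from p3
    # alone), and a one-sided tail approximation for strongly biased
    # targets, where P(k) ≈ Φ((log10 k − mu)/σ) and the pair of
    # quantiles identifies (mu, σ) linearly.
    seeds: list[tuple[float, float]] = []
    sigma_unbiased = math.log10(3) / stats.norm.ppf((1 + p3) / 2)
    seeds.append((0.0, sigma_unbiased))
    z2, z3 = stats.norm.ppf(p2), stats.norm.ppf(p3)
    if z3 > z2:
        sigma_tail = (math.log10(3) - math.log10(2)) / (z3 - z2)
        mu_tail = math.log10(2) - sigma_tail * z2
        if sigma_tail > 0:
            seeds.append((abs(mu_tail), sigma_tail))
    seeds.extend((m, sigma_unbiased) for m in (0.5, 1.0, 2.0))

    best = None
    for mu0, s0 in seeds:
        sol = optimize.root(residual, x0=[mu0, math.log(s0)], jac=jacobian,
                            tol=tol)
        res = float(np.max(np.abs(residual(sol.x))))
        if best is None or res < best[1]:
            best = (sol.x, res)
        if res < 1e-10:
            break
    # trust-region polish: hybr can stall short of tolerance where the
    # mu-direction is nearly flat
    polished = optimize.least_squares(
        residual, x0=best[0], jac=jacobian, xtol=3e-16, ftol=3e-16, gtol=3e-16
    )
    res_polished = float(np.max(np.abs(residual(polished.x))))
    if res_polished < best[1]:
        best = (polished.x, res_polished)

    if best[1] >= 1e-8:
        # near the envelope mu = 0 is a stationary point of the residual
        # (P is even in mu), defeating Newton steps; solve there by nested
        # bisection instead. For |mu| < log10(2), P(2) is strictly
        # decreasing in sigma, so sigma(mu) on the P(2)=p2 contour is a
        # 1-D root; P(3) along that contour increases with mu.
        a2 = math.log10(2)

        def sigma_on_contour(mu: float) -> float:
            return optimize.brentq(
                lambda s: within_k_probability(2, mu, s) - p2, 1e-9, 1e4,
                xtol=1e-15, rtol=8.9e-16,
            )

        def p3_gap(mu: float) -> float:
            return within_k_probability(3, mu, sigma_on_contour(mu)) - p3

        mu_hi = a2 * (1 - 1e-12)
        if p3_gap(0.0) <= 0.0 <= p3_gap(mu_hi):
            mu_sol = optimize.brentq(p3_gap, 0.0, mu_hi,
                                     xtol=1e-15, rtol=8.9e-16)
            candidate = np.array([mu_sol, math.log(sigma_on_contour(mu_sol))])
            res_candidate = float(np.max(np.abs(residual(candidate))))
            if res_candidate < best[1]:
                best = (candidate, res_candidate)
    params, res = best
    if res >= 1e-8:
        raise RuntimeError(
            f"calibration did not converge for p2={p2}, p3={p3} "
            f"(residual {res:.2e})"
        )
    mu, sigma = float(params[0]), float(math.exp(params[1]))
    return abs(mu), sigma


_ROUTES = {
    ModalityClass.SM_IV: Route.IV,
    ModalityClass.SM_PO: Route.PO,
    ModalityClass.SM_IO_HT: Route.PO,
}

# representative molecular weights (kDa): intact IgG ≈ 150, ADCs slightly
# heavier, bispecific T-cell engagers well below the 100 kDa cutoff
_MW_RANGES = {
    ModalityClass.MAB: (140.0, 155.0),
    ModalityClass.ADC: (148.0, 160.0),
    ModalityClass.CHECKPOINT: (143.0, 150.0),
    ModalityClass.BISPECIFIC: (50.0, 60.0),
}

_MODELS = ("HT-29 xenograft", "A549 xenograft", "MDA-MB-231 xenograft",
           "HCT-116 xenograft", "Raji xenograft")
_INDICATIONS = ("colorectal cancer", "NSCLC", "breast cancer",
                "lymphoma", "AML")


def generate(
    n: int,
    model: ClassErrorModel,
    seed: int,
    name_prefix: str | None = None,
) -> list[DrugRecord]:
    """Sample ``n`` schema-valid drug records under an error model.

    The mouse efficacious dose is log-uniform over the model's dose
    range; the clinical dose is the method's prediction times a
    log10-normal deviation ``10^ε`` with ε ~ Normal(mu, sigma). All
    responses are efficacious by construction (TGI ≥ 60 % or
    regression), so generated tables survive curation unchanged.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be ≥ 1, got {n}")
    rng = np.random.default_rng(seed)
    lo, hi = model.dose_scale_range
    mouse_doses = 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)
    eps = rng.normal(model.mu, model.sigma, size=n)
    predict = (
        bsa_predict_human_dose if model.method is Method.BSA
        else bw_predict_human_dose
    )
    prefix = name_prefix or f"syn-{model.modality_class.value}"
    route = _ROUTES.get(model.modality_class, Route.IV)
    mw_range = _MW_RANGES.get(model.modality_class)

    records: list[DrugRecord] = []
    for i in range(n):
        mouse_dose = float(mouse_doses[i])
        clinical = predict(mouse_dose) * 10 ** float(eps[i])
        mw = float(rng.uniform(*mw_range)) if mw_range else None
        if rng.random() < 0.8:
            response = Response(ResponseMetric.TGI_PERCENT,
                                float(rng.uniform(60.0, 98.0)))
        else:
            response = Response(ResponseMetric.REGRESSION)
        records.append(
            DrugRecord(
                drug_name=f"{prefix}-{i:05d}",
                modality_class=model.modality_class,
                molecular_weight_kda=mw,
                nonclinical_dose=DoseSpec(
                    amount=mouse_dose,
                    unit_basis=UnitBasis.MG_PER_KG,
                    species=MOUSE,
                    route=route if route is not Route.PO else Route.PO,
                ),
                nonclinical_model=_MODELS[i % len(_MODELS)],
                nonclinical_response=response,
                clinical_dose_low=DoseSpec(
                    amount=clinical,
                    unit_basis=UnitBasis.MG_PER_KG,
                    species=HUMAN,
                    route=route,
                ),
                clinical_route=route,
                indication=_INDICATIONS[i % len(_INDICATIONS)],
                reference="synthetic",
            )
        )
    return records
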