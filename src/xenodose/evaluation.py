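"""Fold-error accuracy of dose predictions, class summaries, scatter export.

The accuracy metric is the symmetric fold error
``max(predicted/clinical, clinical/predicted)``; a prediction is
"within k×" when that ratio is ≤ k (inclusive). Class-level summaries
report the percentage of drugs within 2× and 3× for the BSA and BW
methods, in the layout of a retrospective dose-translation table
(small molecules split IV / PO / combined / IO-HT; large molecules
split mAb+ADC / ADC / mAb / checkpoint). Scatter export writes the
(predicted, clinical) pairs with identity and ±3-fold reference lines
on log-log axes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .records import DrugRecord, ModalityClass, recommended_clinical_dose
from .scaling import (
    DoseDomainError,
    Method,
    bsa_predict_human_dose,
    bw_predict_human_dose,
    day1_total,
    select_method,
)

__all__ = [
    "EvaluationRow",
    "ClassSummary",
    "fold_error",
    "pct_within",
    "format_pct",
    "evaluate",
    "summarize",
    "bootstrap_ci",
    "export_scatter",
    "STANDARD_GROUPS",
]

log = logging.getLogger(__name__)


def fold_error(predicted: float, clinical: float) -> float:
    """Symmetric fold error between predicted and clinical dose.

    ``max(predicted/clinical, clinical/predicted)`` — dimensionless,
    ≥ 1, equal to 1 iff the prediction is exact, and invariant to which
    argument over- or under-shoots. Requires strictly positive doses
    (the metric lives on a log scale).
    """
    if not (predicted > 0 and clinical > 0) or not (
        math.isfinite(predicted) and math.isfinite(clinical)
    ):
        raise DoseDomainError(
            f"fold error needs positive finite doses, got "
            f"predicted={predicted!r}, clinical={clinical!r}"
        )
    return max(predicted / clinical, clinical / predicted)


@dataclass(frozen=True)
class EvaluationRow:
    """Per-drug outcome of one prediction method."""

    drug_name: str
    method: Method
    predicted_dose: float  # mg/kg
    clinical_dose: float  # mg/kg
    fold_error: float
    within_2x: bool
    within_3x: bool
    modality_class: ModalityClass


@dataclass(frozen=True)
class ClassSummary:
    """One row of a class-level accuracy table."""

    class_label: str
    subclass_label: str
    n: int
    pct_within_2x_bsa: float | None
    pct_within_3x_bsa: float | None
    pct_within_2x_bw: float | None
    pct_within_3x_bw: float | None


def _fold_of(item) -> float:
    return item.fold_error if hasattr(item, "fold_error") else float(item)


def pct_within(rows: Sequence, k: float) -> float:
    """Percentage of rows whose fold error is ≤ k (boundary inclusive).

    Accepts EvaluationRows or bare fold-error numbers. Returns the
    unrounded percentage; use :func:`format_pct` for one-decimal
    display. Five of 30 rows within k gives 16.666…, displayed 16.7.
    """
    if len(rows) == 0:
        raise ValueError("pct_within is undefined on an empty row set")
    if k < 1:
        raise ValueError(f"fold threshold must be ≥ 1, got {k}")
    hits = sum(1 for r in rows if _fold_of(r) <= k)
    return 100.0 * hits / len(rows)


def format_pct(pct: float, decimals: int = 1) -> str:
    """One-decimal display convention for percentages (e.g. ``'16.7'``)."""
    return f"{pct:.{decimals}f}"


def _predict(record: DrugRecord, method: Method | str) -> tuple[Method, float]:
    mouse_mgkg = day1_total(record.nonclinical_dose)
    if isinstance(method, str) and method.lower() == "auto":
        if record.molecular_weight_kda is not None:
            chosen = select_method(record.molecular_weight_kda)
        else:
            # small molecules may omit MW; they are below any protein cutoff
            chosen = Method.BSA
    else:
        chosen = Method(method)
    if chosen is Method.BSA:
        return chosen, bsa_predict_human_dose(mouse_mgkg)
    return chosen, bw_predict_human_dose(mouse_mgkg)


def evaluate(
    records: Sequence[DrugRecord], method: Method | str = Method.BSA
) -> list[EvaluationRow]:
    """Score each drug's predicted human dose against its clinical dose.

    ``method`` is ``Method.BSA``, ``Method.BW``, or ``"auto"`` (pick BW
    above the 100 kDa protein cutoff, BSA otherwise). The nonclinical
    dose is first reduced to its Day-1 24-h mg/kg total; the clinical
    comparator is the recommended dose (range midpoint) in mg/kg.
    """
    rows: list[EvaluationRow] = []
    for rec in records:
        try:
            chosen, predicted = _predict(rec, method)
            clinical = recommended_clinical_dose(rec)
            fe = fold_error(predicted, clinical)
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"{rec.drug_name}: {exc}") from exc
        rows.append(
            EvaluationRow(
                drug_name=rec.drug_name,
                method=chosen,
                predicted_dose=predicted,
                clinical_dose=clinical,
                fold_error=fe,
                within_2x=fe <= 2.0,
                within_3x=fe <= 3.0,
                modality_class=rec.modality_class,
            )
        )
    return rows


_SM = {ModalityClass.SM_IV, ModalityClass.SM_PO}

#: (class label, subclass label, membership predicate, report BW columns?)
STANDARD_GROUPS: list[tuple[str, str, Callable[[ModalityClass], bool], bool]] = [
    ("Small molecule", "IV", lambda c: c is ModalityClass.SM_IV, False),
    ("Small molecule", "PO", lambda c: c is ModalityClass.SM_PO, False),
    ("Small molecule", "IV + PO", lambda c: c in _SM, False),
    ("Small molecule", "IO/HT", lambda c: c is ModalityClass.SM_IO_HT, False),
    ("Large molecule", "mAb + ADC",
     lambda c: c in {ModalityClass.MAB, ModalityClass.ADC}, True),
    ("Large molecule", "ADC", lambda c: c is ModalityClass.ADC, True),
    ("Large molecule", "mAb", lambda c: c is ModalityClass.MAB, True),
    ("Large molecule", "Checkpoint inhibitor",
     lambda c: c is ModalityClass.CHECKPOINT, True),
]


def summarize(
    rows: Sequence[EvaluationRow],
    grouping: Sequence[tuple[str, str, Callable[[ModalityClass], bool], bool]]
    | None = None,
) -> list[ClassSummary]:
    """Class-level within-2×/3× percentages per prediction method.

    ``rows`` may mix BSA and BW evaluations of the same drugs; each
    group reports whichever methods are present (BW columns are omitted
    for small-molecule groups, where BW carryover is not a candidate
    method). Empty groups are omitted with a logged warning.
    """
    grouping = STANDARD_GROUPS if grouping is None else grouping
    summaries: list[ClassSummary] = []
    for class_label, subclass_label, member, with_bw in grouping:
        in_group = [r for r in rows if member(r.modality_class)]
        if not in_group:
            log.warning(
                "group %s / %s is empty; omitted", class_label, subclass_label
            )
            continue
        by_method = {
            m: [r for r in in_group if r.method is m] for m in Method
        }
        n = max(len(v) for v in by_method.values())

        def _pct(m: Method, k: float) -> float | None:
            subset = by_method[m]
            return pct_within(subset, k) if subset else None

        bw2, bw3 = (_pct(Method.BW, 2), _pct(Method.BW, 3)) if with_bw else (None, None)
        summaries.append(
            ClassSummary(
                class_label=class_label,
                subclass_label=subclass_label,
                n=n,
                pct_within_2x_bsa=_pct(Method.BSA, 2),
                pct_within_3x_bsa=_pct(Method.BSA, 3),
                pct_within_2x_bw=bw2,
                pct_within_3x_bw=bw3,
            )
        )
    return summaries


def bootstrap_ci(
    rows: Sequence,
    k: float,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the within-k percentage.

    An addition beyond the point estimates a retrospective table
    reports; resamples rows with replacement, reproducibly for a fixed
    seed.
    """
    if len(rows) == 0:
        raise ValueError("bootstrap_ci needs at least one row")
    if n_boot < 100:
        raise ValueError(f"n_boot must be ≥ 100, got {n_boot}")
    folds = np.array([_fold_of(r) for r in rows])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(folds), size=(n_boot, len(folds)))
    pcts = 100.0 * (folds[idx] <= k).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(pcts, [alpha, 1.0 - alpha])
    return float(low), float(high)


def export_scatter(
    rows: Sequence[EvaluationRow],
    csv_path: str | Path,
    fig_path: str | Path | None = None,
    header_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """Write (predicted, clinical) pairs and, optionally, a log-log figure.

    The CSV holds one row per drug with both doses and the fold error;
    the figure shows the identity line and ±3-fold reference lines.
    Rows with nonpositive doses cannot be log-plotted and are dropped
    with a warning; an empty result is an error.
    """
    usable = []
    for r in rows:
        if r.predicted_dose > 0 and r.clinical_dose > 0:
            usable.append(r)
        else:
            warnings.warn(
                f"{r.drug_name}: nonpositive dose excluded from scatter",
                stacklevel=2,
            )
    if not usable:
        raise ValueError("no plottable rows (all doses nonpositive)")

    frame = pd.DataFrame(
        {
            "drug_name": [r.drug_name for r in usable],
            "method": [r.method.value for r in usable],
            "modality_class": [r.modality_class.value for r in usable],
            "predicted_dose_mgkg": [r.predicted_dose for r in usable],
            "clinical_dose_mgkg": [r.clinical_dose for r in usable],
            "fold_error": [r.fold_error for r in usable],
        }
    )
    csv_path = Path(csv_path)
    with open(csv_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)

    if fig_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        x = frame["predicted_dose_mgkg"].to_numpy()
        y = frame["clinical_dose_mgkg"].to_numpy()
        lo = min(x.min(), y.min()) / 4
        hi = max(x.max(), y.max()) * 4
        line = np.array([lo, hi])
        ax.plot(line, line, "k--", lw=0.8, label="identity")
        ax.plot(line, 3 * line, "k-", lw=0.8, label="±3-fold")
        ax.plot(line, line / 3, "k-", lw=0.8)
        ax.scatter(x, y, s=18, alpha=0.75)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("Predicted human dose (mg/kg)")
        ax.set_ylabel("Recommended clinical dose (mg/kg)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)

    return frame
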