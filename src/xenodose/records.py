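"""Drug-record schema, curation rules, and CSV I/O.

One record per drug per analysis set: the modality class, the mouse
xenograft efficacious dose (with model and response metadata), and the
recommended human clinical dose (possibly a range). Curation judgments
made during literature review — study selection, model/route matching,
regimen matching, one indication per drug — travel as provenance fields
and flags; only the computable rules (TGI ≥ 60 % efficacy floor, Day-1
totals, range averaging, MTD-only/syngeneic exclusion) are applied here.

CSV schema (header required, comma-separated, UTF-8, plain decimal doses
with the unit in its own column)::

    drug_name, modality_class, molecular_weight_kda,
    nonclin_dose_value, nonclin_dose_unit {mg_per_kg|mg|mg_per_m2},
    nonclin_n_admin_day1, nonclin_species, nonclin_route, nonclin_model,
    nonclin_response_metric, nonclin_response_value,
    clin_dose_low, clin_dose_high, clin_dose_unit, clin_route,
    indication, flags, reference

``nonclin_n_admin_day1`` is the number of administrations on Day 1;
``nonclin_dose_value`` is the per-administration dose, so the Day-1
total is their product. ``flags`` is semicolon-separated. Unknown
columns are preserved round-trip as opaque metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scaling import (
    HUMAN,
    MOUSE,
    DoseSpec,
    DoseValidationError,
    Route,
    SpeciesProfile,
    SpeciesRegistry,
    DEFAULT_REGISTRY,
    UnitBasis,
    normalize_to_mgkg,
)

__all__ = [
    "ModalityClass",
    "ResponseMetric",
    "Response",
    "CurationFlag",
    "DrugRecord",
    "DatasetLoadError",
    "LARGE_MOLECULE_CLASSES",
    "recommended_clinical_dose",
    "is_efficacious_response",
    "apply_exclusions",
    "read_records",
    "write_records",
    "CSV_COLUMNS",
]

log = logging.getLogger(__name__)


class DatasetLoadError(ValueError):
    """CSV content that cannot be turned into valid records."""


class ModalityClass(str, Enum):
    SM_IV = "SM_IV"
    SM_PO = "SM_PO"
    SM_IO_HT = "SM_IO_HT"
    MAB = "mAb"
    ADC = "ADC"
    CHECKPOINT = "checkpoint"
    BISPECIFIC = "bispecific"


#: Classes that are antibody-based large molecules and therefore require
#: a molecular weight (the BW-vs-BSA rule depends on it).
LARGE_MOLECULE_CLASSES = frozenset(
    {ModalityClass.MAB, ModalityClass.ADC, ModalityClass.CHECKPOINT,
     ModalityClass.BISPECIFIC}
)


class ResponseMetric(str, Enum):
    TGI_PERCENT = "TGI_percent"
    T_OVER_C = "T_over_C"
    SURVIVAL = "survival"
    REGRESSION = "regression"
    STASIS = "stasis"


class CurationFlag(str, Enum):
    MTD_ONLY = "mtd_only"
    SYNGENEIC_MODEL = "syngeneic_model"
    COMBINATION_MISMATCH = "combination_mismatch"
    CNS_MISMATCH = "cns_mismatch"
    HEME_TO_SOLID_MISMATCH = "heme_to_solid_mismatch"


#: Flags that remove a record from the analysis set (saturated-response
#: MTD-only data; syngeneic models with human-vs-mouse tumor disconnects).
EXCLUSION_FLAGS = frozenset({CurationFlag.MTD_ONLY, CurationFlag.SYNGENEIC_MODEL})


@dataclass(frozen=True)
class Response:
    """Xenograft efficacy readout as defined by the source authors."""

    metric: ResponseMetric
    value: float | None = None
    #: curator attests the source authors declared the response significant;
    #: needed for metrics without a numeric threshold (T/C, survival).
    author_significant: bool = False


@dataclass(frozen=True)
class DrugRecord:
    drug_name: str
    modality_class: ModalityClass
    nonclinical_dose: DoseSpec
    clinical_dose_low: DoseSpec
    clinical_dose_high: DoseSpec | None = None
    molecular_weight_kda: float | None = None
    nonclinical_model: str = ""
    nonclinical_response: Response | None = None
    clinical_route: Route = Route.IV
    indication: str = ""
    flags: frozenset[CurationFlag] = frozenset()
    reference: str = ""
    #: unknown CSV columns, preserved verbatim on round trip
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality_class in LARGE_MOLECULE_CLASSES:
            if self.molecular_weight_kda is None:
                raise DoseValidationError(
                    f"{self.drug_name}: large-molecule class "
                    f"{self.modality_class.value} requires molecular_weight_kda"
                )
        if self.molecular_weight_kda is not None and self.molecular_weight_kda <= 0:
            raise DoseValidationError(
                f"{self.drug_name}: molecular_weight_kda must be > 0"
            )
        if self.clinical_dose_high is not None:
            lo = normalize_to_mgkg(self.clinical_dose_low)
            hi = normalize_to_mgkg(self.clinical_dose_high)
            if lo > hi:
                raise DoseValidationError(
                    f"{self.drug_name}: clinical dose range inverted "
                    f"({lo:g} > {hi:g} mg/kg after normalization)"
                )


def recommended_clinical_dose(record: DrugRecord) -> float:
    """Recommended clinical dose in mg/kg.

    A single dose normalizes directly; a range contributes the
    arithmetic mean of its normalized endpoints ("the average dose").
    Endpoints in different units are normalized to mg/kg before
    averaging, so the result does not depend on how the range was
    labelled.
    """
    if record.clinical_dose_low is None:
        raise DoseValidationError(f"{record.drug_name}: no clinical dose")
    lo = normalize_to_mgkg(record.clinical_dose_low)
    if record.clinical_dose_high is None:
        return lo
    hi = normalize_to_mgkg(record.clinical_dose_high)
    return (lo + hi) / 2.0


#: Lower bound (%) of tumor growth inhibition considered efficacious.
TGI_EFFICACY_THRESHOLD = 60.0


def is_efficacious_response(response: Response) -> bool:
    """Whether a xenograft readout counts as an efficacious response.

    Stasis or regression always qualifies; TGI qualifies at ≥ 60 %;
    metrics without a numeric convention (T/C, survival) qualify only if
    the curator recorded the source authors' significance call.
    TGI outside [0, 100] draws a warning but is not rejected —
    regressions are sometimes reported as > 100 % TGI.
    """
    if response.metric in (ResponseMetric.REGRESSION, ResponseMetric.STASIS):
        return True
    if response.metric is ResponseMetric.TGI_PERCENT:
        if response.value is None:
            raise DoseValidationError("TGI response requires a value")
        if not 0 <= response.value <= 100:
            warnings.warn(
                f"TGI of {response.value}% outside [0, 100]; "
                "treating literally",
                stacklevel=2,
            )
        return response.value >= TGI_EFFICACY_THRESHOLD
    return response.author_significant


def apply_exclusions(
    records: Sequence[DrugRecord],
) -> tuple[list[DrugRecord], list[tuple[DrugRecord, str]]]:
    """Partition records into (kept, excluded-with-reason).

    Records flagged ``mtd_only`` or ``syngeneic_model`` are excluded;
    all other flags are annotations only. The partition is pure: no
    record is modified.
    """
    kept: list[DrugRecord] = []
    excluded: list[tuple[DrugRecord, str]] = []
    for rec in records:
        triggers = sorted(f.value for f in rec.flags & EXCLUSION_FLAGS)
        if triggers:
            excluded.append((rec, ";".join(triggers)))
        else:
            kept.append(rec)
    return kept, excluded


# ---------------------------------------------------------------------------
# CSV I/O

CSV_COLUMNS = [
    "drug_name",
    "modality_class",
    "molecular_weight_kda",
    "nonclin_dose_value",
    "nonclin_dose_unit",
    "nonclin_n_admin_day1",
    "nonclin_species",
    "nonclin_route",
    "nonclin_model",
    "nonclin_response_metric",
    "nonclin_response_value",
    "clin_dose_low",
    "clin_dose_high",
    "clin_dose_unit",
    "clin_route",
    "indication",
    "flags",
    "reference",
]

_MANDATORY = {
    "drug_name",
    "modality_class",
    "nonclin_dose_value",
    "nonclin_dose_unit",
    "clin_dose_low",
    "clin_dose_unit",
}


def _is_blank(value: object) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def _cell_error(row: int, column: str, message: str) -> DatasetLoadError:
    return DatasetLoadError(f"row {row}, column {column!r}: {message}")


def _parse_float(raw: object, row: int, column: str) -> float:
    try:
        return float(str(raw).strip())
    except (TypeError, ValueError):
        raise _cell_error(row, column, f"unparseable number {raw!r}") from None


def _parse_enum(enum_cls, raw: object, row: int, column: str):
    token = str(raw).strip()
    for member in enum_cls:
        if member.value == token:
            return member
    raise _cell_error(
        row, column,
        f"unknown value {token!r}; expected one of "
        f"{[m.value for m in enum_cls]}",
    )


def _row_to_record(
    row: Mapping[str, object], row_no: int, registry: SpeciesRegistry
) -> DrugRecord:
    for col in _MANDATORY:
        if _is_blank(row.get(col)):
            raise _cell_error(row_no, col, "mandatory value missing")

    modality = _parse_enum(ModalityClass, row["modality_class"], row_no,
                           "modality_class")
    mw = None
    if not _is_blank(row.get("molecular_weight_kda")):
        mw = _parse_float(row["molecular_weight_kda"], row_no,
                          "molecular_weight_kda")

    species_name = str(row.get("nonclin_species") or "mouse").strip()
    try:
        species = registry.get(species_name)
    except LookupError:
        raise _cell_error(row_no, "nonclin_species",
                          f"unknown species {species_name!r}") from None

    nonclin_unit = _parse_enum(UnitBasis, row["nonclin_dose_unit"], row_no,
                               "nonclin_dose_unit")
    nonclin_value = _parse_float(row["nonclin_dose_value"], row_no,
                                 "nonclin_dose_value")
    n_admin = 1
    if not _is_blank(row.get("nonclin_n_admin_day1")):
        n_admin = int(_parse_float(row["nonclin_n_admin_day1"], row_no,
                                   "nonclin_n_admin_day1"))
        if n_admin < 1:
            raise _cell_error(row_no, "nonclin_n_admin_day1", "must be ≥ 1")
    nonclin_route = Route.OTHER
    if not _is_blank(row.get("nonclin_route")):
        nonclin_route = _parse_enum(Route, row["nonclin_route"], row_no,
                                    "nonclin_route")
    try:
        nonclinical = DoseSpec(
            amount=nonclin_value,
            unit_basis=nonclin_unit,
            species=species,
            route=nonclin_route,
            administrations_day1=(nonclin_value,) * n_admin,
        )
    except ValueError as exc:
        raise _cell_error(row_no, "nonclin_dose_value", str(exc)) from None

    response = None
    if not _is_blank(row.get("nonclin_response_metric")):
        metric = _parse_enum(ResponseMetric, row["nonclin_response_metric"],
                             row_no, "nonclin_response_metric")
        value = None
        if not _is_blank(row.get("nonclin_response_value")):
            value = _parse_float(row["nonclin_response_value"], row_no,
                                 "nonclin_response_value")
        response = Response(metric=metric, value=value)

    clin_unit = _parse_enum(UnitBasis, row["clin_dose_unit"], row_no,
                            "clin_dose_unit")
    clin_route = Route.IV
    if not _is_blank(row.get("clin_route")):
        clin_route = _parse_enum(Route, row["clin_route"], row_no,
                                 "clin_route")
    try:
        clin_low = DoseSpec(
            amount=_parse_float(row["clin_dose_low"], row_no, "clin_dose_low"),
            unit_basis=clin_unit,
            species=HUMAN,
            route=clin_route,
        )
        clin_high = None
        if not _is_blank(row.get("clin_dose_high")):
            clin_high = DoseSpec(
                amount=_parse_float(row["clin_dose_high"], row_no,
                                    "clin_dose_high"),
                unit_basis=clin_unit,
                species=HUMAN,
                route=clin_route,
            )
    except ValueError as exc:
        raise _cell_error(row_no, "clin_dose_low", str(exc)) from None

    flags: set[CurationFlag] = set()
    if not _is_blank(row.get("flags")):
        for token in str(row["flags"]).split(";"):
            token = token.strip()
            if token:
                flags.add(_parse_enum(CurationFlag, token, row_no, "flags"))

    extra = {
        k: str(v)
        for k, v in row.items()
        if k not in CSV_COLUMNS and not _is_blank(v)
    }

    try:
        return DrugRecord(
            drug_name=str(row["drug_name"]).strip(),
            modality_class=modality,
            molecular_weight_kda=mw,
            nonclinical_dose=nonclinical,
            nonclinical_model=str(row.get("nonclin_model") or "").strip(),
            nonclinical_response=response,
            clinical_dose_low=clin_low,
            clinical_dose_high=clin_high,
            clinical_route=clin_route,
            indication=str(row.get("indication") or "").strip(),
            flags=frozenset(flags),
            reference=str(row.get("reference") or "").strip(),
            extra=extra,
        )
    except DoseValidationError as exc:
        raise DatasetLoadError(f"row {row_no}: {exc}") from None


def read_records(
    path: str | Path, registry: SpeciesRegistry | None = None
) -> list[DrugRecord]:
    """Load and validate drug records from the documented CSV schema.

    Lines starting with ``#`` are treated as comments. Errors name the
    offending row (1-based, excluding header) and column.
    """
    registry = registry or DEFAULT_REGISTRY
    frame = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = _MANDATORY - set(frame.columns)
    if missing:
        raise DatasetLoadError(
            f"missing mandatory columns: {sorted(missing)}"
        )
    records = []
    for idx, row in enumerate(frame.to_dict(orient="records"), start=1):
        records.append(_row_to_record(row, idx, registry))
    return records


def _record_to_row(rec: DrugRecord) -> dict[str, object]:
    admins = rec.nonclinical_dose.administrations_day1
    response = rec.nonclinical_response
    return {
        "drug_name": rec.drug_name,
        "modality_class": rec.modality_class.value,
        "molecular_weight_kda": rec.molecular_weight_kda,
        "nonclin_dose_value": rec.nonclinical_dose.amount,
        "nonclin_dose_unit": rec.nonclinical_dose.unit_basis.value,
        "nonclin_n_admin_day1": len(admins),
        "nonclin_species": rec.nonclinical_dose.species.species_name,
        "nonclin_route": rec.nonclinical_dose.route.value,
        "nonclin_model": rec.nonclinical_model,
        "nonclin_response_metric": response.metric.value if response else None,
        "nonclin_response_value": response.value if response else None,
        "clin_dose_low": rec.clinical_dose_low.amount,
        "clin_dose_high": (
            rec.clinical_dose_high.amount if rec.clinical_dose_high else None
        ),
        "clin_dose_unit": rec.clinical_dose_low.unit_basis.value,
        "clin_route": rec.clinical_route.value,
        "indication": rec.indication,
        "flags": ";".join(sorted(f.value for f in rec.flags)) or None,
        "reference": rec.reference,
        **dict(rec.extra),
    }


def write_records(records: Sequence[DrugRecord], path: str | Path) -> None:
    """Write records back to the CSV schema (round-trip stable)."""
    rows = [_record_to_row(rec) for rec in records]
    extra_cols = sorted({k for r in rows for k in r} - set(CSV_COLUMNS))
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS + extra_cols)
    frame.to_csv(path, index=False)
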