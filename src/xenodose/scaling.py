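"""Unit-safe interspecies dose conversion.

Implements the two dose-translation rules used in early oncology discovery:

* **BSA scaling** — a mouse dose in mg/kg is multiplied by the mouse
  surface-area factor (3) to give mg/m², then divided by the human factor
  (37) to give the human equivalent dose (HED) in mg/kg.
* **Body-weight (BW) carryover** — the mg/kg dose is carried over
  unchanged (2 mg/kg in mouse = 2 mg/kg in human), the FDA-recommended
  route for intravascular proteins above 100 kDa.

All internal arithmetic uses mg/kg as the canonical unit; absolute-mg and
mg/m² doses are normalized at the boundary using species default body
weights (70 kg human, 25 g mouse) and surface-area factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Method",
    "Route",
    "UnitBasis",
    "SpeciesProfile",
    "SpeciesRegistry",
    "DoseSpec",
    "MOUSE",
    "HUMAN",
    "DoseDomainError",
    "SpeciesLookupError",
    "DoseValidationError",
    "mgkg_to_mgm2",
    "mgm2_to_mgkg",
    "bsa_predict_human_dose",
    "bw_predict_human_dose",
    "normalize_to_mgkg",
    "day1_total",
    "select_method",
    "mrsd_from_hed",
    "load_species_config",
]


class DoseDomainError(ValueError):
    """A dose or parameter outside the mathematically valid domain."""


class SpeciesLookupError(LookupError):
    """Species name not present in the registry."""


class DoseValidationError(ValueError):
    """A structurally invalid dose specification."""


class Method(str, Enum):
    """Human-dose prediction method."""

    BSA = "bsa"
    BW = "bw"


class Route(str, Enum):
    IV = "IV"
    PO = "PO"
    SC = "SC"
    IP = "IP"
    OTHER = "other"


class UnitBasis(str, Enum):
    MG_PER_KG = "mg_per_kg"
    MG_PER_M2 = "mg_per_m2"
    MG_ABSOLUTE = "mg"


@dataclass(frozen=True)
class SpeciesProfile:
    """Fixed species-level scaling constants.

    Parameters
    ----------
    species_name:
        Lower-case species identifier, e.g. ``"mouse"``.
    bsa_factor:
        Dimensionless mg/kg → mg/m² multiplier (body weight divided by
        body surface area; the Km-like factor). Mouse 3, human 37.
    default_body_weight_kg:
        Reference body weight used to normalize absolute-mg doses.
        Mouse 0.025 kg, human 70 kg.
    """

    species_name: str
    bsa_factor: float
    default_body_weight_kg: float

    def __post_init__(self) -> None:
        if self.bsa_factor <= 0:
            raise DoseValidationError(
                f"bsa_factor must be > 0, got {self.bsa_factor}"
            )
        if self.default_body_weight_kg <= 0:
            raise DoseValidationError(
                f"default_body_weight_kg must be > 0, got "
                f"{self.default_body_weight_kg}"
            )


MOUSE = SpeciesProfile("mouse", bsa_factor=3.0, default_body_weight_kg=0.025)
HUMAN = SpeciesProfile("human", bsa_factor=37.0, default_body_weight_kg=70.0)

_BUILTINS: Mapping[str, SpeciesProfile] = {"mouse": MOUSE, "human": HUMAN}


class SpeciesRegistry:
    """Species lookup: the two built-ins plus user-supplied profiles.

    User profiles may never override the built-in mouse and human
    constants — those are the fixed points of the method.
    """

    def __init__(self, extra: Iterable[SpeciesProfile] = ()) -> None:
        self._extra: dict[str, SpeciesProfile] = {}
        for profile in extra:
            self.register(profile)

    def register(self, profile: SpeciesProfile) -> None:
        name = profile.species_name.lower()
        if name in _BUILTINS:
            raise DoseValidationError(
                f"species {name!r} is built in and cannot be overridden"
            )
        self._extra[name] = profile

    def get(self, name: str) -> SpeciesProfile:
        key = name.lower()
        if key in _BUILTINS:
            return _BUILTINS[key]
        try:
            return self._extra[key]
        except KeyError:
            raise SpeciesLookupError(
                f"unknown species {name!r}; known: "
                f"{sorted([*_BUILTINS, *self._extra])}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name.lower() in _BUILTINS or name.lower() in self._extra

    def names(self) -> list[str]:
        return sorted([*_BUILTINS, *self._extra])


DEFAULT_REGISTRY = SpeciesRegistry()


def load_species_config(path: str | Path) -> SpeciesRegistry:
    """Build a registry from a YAML file of user species profiles.

    The file maps species names to ``{bsa_factor, default_body_weight_kg}``::

        rat:
          bsa_factor: 6
          default_body_weight_kg: 0.25
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise DoseValidationError(f"species config {path} must be a mapping")
    profiles = []
    for name, entry in raw.items():
        try:
            profiles.append(
                SpeciesProfile(
                    species_name=str(name),
                    bsa_factor=float(entry["bsa_factor"]),
                    default_body_weight_kg=float(entry["default_body_weight_kg"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise DoseValidationError(
                f"species config entry {name!r} needs bsa_factor and "
                f"default_body_weight_kg"
            ) from exc
    return SpeciesRegistry(profiles)


@dataclass(frozen=True)
class DoseSpec:
    """A dose as reported, before normalization to mg/kg.

    ``administrations_day1`` lists the per-administration amounts given
    within the first 24 h of dosing (same unit basis as ``amount``); it
    defaults to a single administration of ``amount``. Day-1 totals are
    the comparable quantity across intermittent schedules: a drug given
    once every 4 days still counts only its Day-1 dose.
    """

    amount: float
    unit_basis: UnitBasis = UnitBasis.MG_PER_KG
    species: SpeciesProfile = MOUSE
    route: Route = Route.IV
    administrations_day1: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise DoseDomainError(f"dose amount must be ≥ 0, got {self.amount}")
        if self.administrations_day1 is None:
            object.__setattr__(self, "administrations_day1", (self.amount,))
        else:
            admins = tuple(float(a) for a in self.administrations_day1)
            if any(a < 0 for a in admins):
                raise DoseDomainError(
                    f"Day-1 administrations must be ≥ 0, got {admins}"
                )
            object.__setattr__(self, "administrations_day1", admins)


def _check_nonnegative(dose: float, what: str = "dose") -> None:
    if not math.isfinite(dose):
        raise DoseDomainError(f"{what} must be finite, got {dose}")
    if dose < 0:
        raise DoseDomainError(f"{what} must be ≥ 0, got {dose}")


def mgkg_to_mgm2(dose_mgkg: float, species: SpeciesProfile) -> float:
    """Convert mg/kg to mg/m² by the species surface-area factor.

    Mouse dose in mg/kg × 3 = mouse dose in mg/m².
    """
    _check_nonnegative(dose_mgkg)
    return dose_mgkg * species.bsa_factor


def mgm2_to_mgkg(dose_mgm2: float, species: SpeciesProfile) -> float:
    """Convert mg/m² to mg/kg by the species surface-area factor.

    Dose in mg/m² ÷ 37 = human dose in mg/kg.
    """
    _check_nonnegative(dose_mgm2)
    return dose_mgm2 / species.bsa_factor


def bsa_predict_human_dose(mouse_dose_mgkg: float) -> float:
    """Human equivalent dose (mg/kg) from a mouse mg/kg dose by BSA scaling.

    Composition of the two conversions: ×3 into mg/m², then ÷37 into
    human mg/kg. A 37 mg/kg mouse dose maps to exactly 3 mg/kg.
    """
    return mgm2_to_mgkg(mgkg_to_mgm2(mouse_dose_mgkg, MOUSE), HUMAN)


def bw_predict_human_dose(animal_dose_mgkg: float) -> float:
    """Body-weight carryover: the mg/kg dose is species-invariant."""
    _check_nonnegative(animal_dose_mgkg)
    return animal_dose_mgkg


def normalize_to_mgkg(dose: DoseSpec) -> float:
    """Express a dose in mg/kg using its species profile.

    mg/kg passes through; absolute mg divides by the species default body
    weight; mg/m² divides by the species surface-area factor.
    """
    if dose.unit_basis is UnitBasis.MG_PER_KG:
        return dose.amount
    if dose.unit_basis is UnitBasis.MG_ABSOLUTE:
        return dose.amount / dose.species.default_body_weight_kg
    if dose.unit_basis is UnitBasis.MG_PER_M2:
        return dose.amount / dose.species.bsa_factor
    raise DoseValidationError(f"unhandled unit basis {dose.unit_basis!r}")


def day1_total(dose: DoseSpec) -> float:
    """Total Day-1 (24 h) dose in mg/kg.

    Sums every administration given within the first 24 h, each
    normalized to mg/kg. Intermittent schedules beyond Day 1 are
    deliberately not factored in.
    """
    if not dose.administrations_day1:
        raise DoseValidationError("administrations_day1 must be non-empty")
    per_admin = [
        normalize_to_mgkg(
            DoseSpec(a, dose.unit_basis, dose.species, dose.route)
        )
        for a in dose.administrations_day1
    ]
    return float(sum(per_admin))


#: Molecular-weight cutoff (kDa) above which BW carryover is preferred
#: for intravascular proteins.
MW_CUTOFF_KDA = 100.0


def select_method(molecular_weight_kda: float) -> Method:
    """Pick the prediction method from molecular weight.

    BW for proteins strictly above 100 kDa, BSA otherwise. The cutoff is
    read strictly: exactly 100 kDa uses BSA (blinatumomab, 54.1 kDa, is
    the canonical below-cutoff antibody that predicts well by BSA).
    """
    if not math.isfinite(molecular_weight_kda) or molecular_weight_kda <= 0:
        raise DoseDomainError(
            f"molecular weight must be > 0 kDa, got {molecular_weight_kda}"
        )
    return Method.BW if molecular_weight_kda > MW_CUTOFF_KDA else Method.BSA


def mrsd_from_hed(hed_mgkg: float, safety_factor: float = 10.0) -> float:
    """Maximum recommended starting dose: HED divided by a safety factor.

    The default 10× factor is the conventional margin applied to a human
    equivalent dose to reach a likely-safe first-in-human starting dose.
    """
    _check_nonnegative(hed_mgkg, "HED")
    if safety_factor < 1:
        raise DoseDomainError(
            f"safety factor must be ≥ 1, got {safety_factor}"
        )
    return hed_mgkg / safety_factor
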