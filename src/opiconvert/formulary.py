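"""Data-driven equianalgesic conversion formulary.

A :class:`Formulary` is the single source of clinical numbers in this
package: which opioid/route preparations exist, the oral-morphine-equivalent
(OME) conversion factor for each continuous preparation, the patch-band
tables for transdermal preparations, and prescribing defaults (breakthrough
divisor, eGFR warning threshold, practical rounding increments).

Conversion ratios are *data*, never code: guidelines revise their tables and
a deployment encodes the current guideline in a formulary file.  The fixture
formulary shipped with the test suite uses deliberately round, non-clinical
values (see :mod:`opiconvert.fixtures`).

All numeric fields are held as :class:`decimal.Decimal` so that dose
arithmetic and patch-band border comparisons are exact on the decimal
representation, never subject to binary floating-point representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

ORAL = "oral"
SUBCUTANEOUS = "subcutaneous"
TRANSDERMAL = "transdermal"
ROUTES = frozenset({ORAL, SUBCUTANEOUS, TRANSDERMAL})

#: Dose unit implied by the route.  Continuous preparations are dosed as a
#: 24-hour total in milligrams; patches are dosed as a delivery rate in
#: micrograms per hour.  Units are fixed by route precisely so that a unit
#: mix-up cannot be expressed in a request.
UNIT_BY_ROUTE: Mapping[str, str] = {
    ORAL: "mg/24h",
    SUBCUTANEOUS: "mg/24h",
    TRANSDERMAL: "microgram/h",
}

HUB_DRUG = "morphine"
HUB_ROUTE = ORAL

Number = Union[int, float, str, Decimal]


class FormularyError(Exception):
    """Base class for formulary problems."""


class FormularySchemaError(FormularyError):
    """The file does not follow the documented schema.

    ``field_path`` names the offending field.
    """

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


class FormularyValidationError(FormularyError):
    """The file parsed but violates one or more formulary invariants.

    Every violation is collected and reported, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "formulary invariants violated:\n  - " + "\n  - ".join(self.violations)
        )


def _as_decimal(value: Number, field_path: str) -> Decimal:
    """Parse a number into an exact Decimal via its decimal string form."""
    if isinstance(value, bool) or value is None:
        raise FormularySchemaError(field_path, f"expected a number, got {value!r}")
    try:
        return Decimal(str(value))
    except InvalidOperation:
        raise FormularySchemaError(field_path, f"not a decimal number: {value!r}") from None


@dataclass(frozen=True)
class DrugRoute:
    """One opioid preparation: a (drug, route) pair.

    ``supported=False`` marks a drug the formulary deliberately refuses to
    convert (methadone, whose pharmacodynamics make table-based equivalence
    unsafe).  ``renal_risk`` flags drugs needing caution in renal impairment.
    """

    drug_name: str
    route: str
    supported: bool = True
    renal_risk: bool = False

    @property
    def dose_unit(self) -> str:
        return UNIT_BY_ROUTE[self.route]

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_name, self.route)


@dataclass(frozen=True)
class ConversionFactor:
    """Milligrams of oral morphine equivalent per unit dose of a preparation."""

    drug_name: str
    route: str
    ome_per_unit: Decimal

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_name, self.route)


@dataclass(frozen=True)
class PatchBand:
    """One discrete patch strength and its 24-hour OME range.

    The range is inclusive on both ends; adjacent bands may share a border
    (one band's ``ome_high`` equal to the next band's ``ome_low``).  Border
    resolution is the conversion engine's responsibility.
    """

    strength: Decimal  # microgram/h
    ome_low: Decimal  # mg/24h, inclusive
    ome_high: Decimal  # mg/24h, inclusive


@dataclass
class Formulary:
    """A versioned collection of preparations, factors and patch tables."""

    version_id: str
    drug_routes: dict[tuple[str, str], DrugRoute] = field(default_factory=dict)
    factors: dict[tuple[str, str], ConversionFactor] = field(default_factory=dict)
    patch_tables: dict[str, tuple[PatchBand, ...]] = field(default_factory=dict)
    breakthrough_divisor: Decimal = Decimal(6)
    egfr_warning_threshold: Decimal = Decimal(30)  # mL/min
    #: 24h OME above which a large_dose warning is attached to conversions.
    large_dose_ome_threshold: Optional[Decimal] = None
    #: Practical rounding increment (mg) keyed by route.
    practical_increments: dict[str, Decimal] = field(default_factory=dict)

    # -- queries ---------------------------------------------------------

    def drug_route(self, drug: str, route: str) -> Optional[DrugRoute]:
        return self.drug_routes.get((_canon(drug), _canon(route)))

    def factor(self, drug: str, route: str) -> Optional[ConversionFactor]:
        return self.factors.get((_canon(drug), _canon(route)))

    def patch_table(self, drug: str) -> Optional[tuple[PatchBand, ...]]:
        return self.patch_tables.get(_canon(drug))

    def increment_for(self, route: str) -> Optional[Decimal]:
        return self.practical_increments.get(_canon(route))

    def renal_risk(self, drug: str) -> bool:
        """True when any preparation of this drug is flagged renal-risk."""
        drug = _canon(drug)
        return any(dr.renal_risk for dr in self.drug_routes.values() if dr.drug_name == drug)

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Return every invariant violation (empty list when valid)."""
        violations: list[str] = []

        for key, dr in self.drug_routes.items():
            if dr.route not in ROUTES:
                violations.append(f"unknown route {dr.route!r} for drug {dr.drug_name!r}")
            if key != (dr.drug_name, dr.route):
                violations.append(f"drug_routes key {key} does not match entry {dr.key}")

        methadone_entries = [dr for dr in self.drug_routes.values() if dr.drug_name == "methadone"]
        for dr in methadone_entries:
            if dr.supported:
                violations.append("methadone must be marked unsupported")

        hub = self.factors.get((HUB_DRUG, HUB_ROUTE))
        if hub is None:
            violations.append("missing hub factor: no (morphine, oral) conversion factor")
        elif hub.ome_per_unit != Decimal(1):
            violations.append(
                f"hub factor (morphine, oral) must be exactly 1, got {hub.ome_per_unit}"
            )

        for key, factor in self.factors.items():
            if factor.ome_per_unit <= 0:
                violations.append(f"factor {key} has non-positive ome_per_unit")
            if key not in self.drug_routes:
                violations.append(f"factor {key} references an unknown drug/route")

        for key, dr in self.drug_routes.items():
            if not dr.supported:
                continue
            if dr.route == TRANSDERMAL:
                table = self.patch_tables.get(dr.drug_name)
                if not table:
                    violations.append(f"supported transdermal drug {dr.drug_name!r} has no patch table")
            else:
                if key not in self.factors:
                    violations.append(f"supported drug/route {key} has no conversion factor")

        for drug, table in self.patch_tables.items():
            key = (drug, TRANSDERMAL)
            if key not in self.drug_routes:
                violations.append(f"patch table for {drug!r} without a transdermal drug entry")
            violations.extend(_validate_patch_table(drug, table))

        if self.breakthrough_divisor <= 0:
            violations.append("breakthrough_divisor must be positive")
        if self.egfr_warning_threshold <= 0:
            violations.append("egfr_warning_threshold must be positive")
        for route, inc in self.practical_increments.items():
            if inc <= 0:
                violations.append(f"practical increment for route {route!r} must be positive")

        return violations

    def raise_for_violations(self) -> "Formulary":
        violations = self.validate()
        if violations:
            raise FormularyValidationError(violations)
        return self


def _validate_patch_table(drug: str, table: Iterable[PatchBand]) -> list[str]:
    violations: list[str] = []
    bands = list(table)
    for band in bands:
        if band.ome_low >= band.ome_high:
            violations.append(
                f"{drug} patch band {band.strength}: ome_low {band.ome_low} "
                f"not below ome_high {band.ome_high}"
            )
    for prev, nxt in zip(bands, bands[1:]):
        if nxt.strength <= prev.strength:
            violations.append(
                f"{drug} patch bands not sorted by strength "
                f"({prev.strength} then {nxt.strength})"
            )
        if nxt.ome_low < prev.ome_high:
            violations.append(
                f"{drug} patch bands overlap: band {prev.strength} range ends at "
                f"{prev.ome_high} but band {nxt.strength} starts at {nxt.ome_low}"
            )
        if nxt.ome_low <= prev.ome_low:
            violations.append(
                f"{drug} patch band strength does not increase with ome_low "
                f"({prev.strength}@{prev.ome_low} then {nxt.strength}@{nxt.ome_low})"
            )
    return violations


def _canon(name: str) -> str:
    return str(name).strip().lower()


def lookup_factor(formulary: Formulary, drug: str, route: str) -> Optional[ConversionFactor]:
    """Return the OME factor for a preparation, or ``None``.

    Absence is a value, not an error: it means the guideline encoded by this
    formulary offers no equianalgesic equivalence for that preparation, and
    callers must surface that — never fabricate a number.
    """
    return formulary.factor(drug, route)


# ---------------------------------------------------------------------------
# loading / serialising
# ---------------------------------------------------------------------------

_TOP_LEVEL_KEYS = {"version", "drugs", "factors", "patch_tables", "defaults"}


def load_formulary(path: Union[str, Path]) -> Formulary:
    """Load and validate a formulary file (YAML or its JSON subset).

    Raises :class:`FormularySchemaError` on malformed structure and
    :class:`FormularyValidationError` (listing every violation) on invariant
    failure.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormularySchemaError(str(path), f"cannot parse: {exc}") from exc
    return parse_formulary(raw)


def parse_formulary(raw: object) -> Formulary:
    """Build a validated :class:`Formulary` from parsed file content."""
    if not isinstance(raw, Mapping):
        raise FormularySchemaError("<root>", "top level must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise FormularySchemaError(sorted(unknown)[0], "unknown top-level key")
    if "version" not in raw:
        raise FormularySchemaError("version", "required key missing")

    form = Formulary(version_id=str(raw["version"]))

    for i, entry in enumerate(raw.get("drugs") or []):
        where = f"drugs[{i}]"
        if not isinstance(entry, Mapping) or "name" not in entry or "route" not in entry:
            raise FormularySchemaError(where, "each drug entry needs 'name' and 'route'")
        route = _canon(entry["route"])
        if route not in ROUTES:
            raise FormularySchemaError(f"{where}.route", f"unknown route {entry['route']!r}")
        dr = DrugRoute(
            drug_name=_canon(entry["name"]),
            route=route,
            supported=bool(entry.get("supported", True)),
            renal_risk=bool(entry.get("renal_risk", False)),
        )
        if dr.key in form.drug_routes:
            raise FormularySchemaError(where, f"duplicate drug/route {dr.key}")
        form.drug_routes[dr.key] = dr

    for i, entry in enumerate(raw.get("factors") or []):
        where = f"factors[{i}]"
        if not isinstance(entry, Mapping) or not {"drug", "route", "ome_per_unit"} <= set(entry):
            raise FormularySchemaError(where, "each factor needs 'drug', 'route', 'ome_per_unit'")
        factor = ConversionFactor(
            drug_name=_canon(entry["drug"]),
            route=_canon(entry["route"]),
            ome_per_unit=_as_decimal(entry["ome_per_unit"], f"{where}.ome_per_unit"),
        )
        if factor.key in form.factors:
            raise FormularySchemaError(where, f"duplicate factor for {factor.key}")
        form.factors[factor.key] = factor

    for drug, bands in (raw.get("patch_tables") or {}).items():
        parsed = []
        for i, band in enumerate(bands or []):
            where = f"patch_tables.{drug}[{i}]"
            if not isinstance(band, Mapping) or not {"strength", "ome_low", "ome_high"} <= set(band):
                raise FormularySchemaError(where, "each band needs 'strength', 'ome_low', 'ome_high'")
            parsed.append(
                PatchBand(
                    strength=_as_decimal(band["strength"], f"{where}.strength"),
                    ome_low=_as_decimal(band["ome_low"], f"{where}.ome_low"),
                    ome_high=_as_decimal(band["ome_high"], f"{where}.ome_high"),
                )
            )
        form.patch_tables[_canon(drug)] = tuple(parsed)

    defaults = raw.get("defaults") or {}
    if not isinstance(defaults, Mapping):
        raise FormularySchemaError("defaults", "must be a mapping")
    if "breakthrough_divisor" in defaults:
        form.breakthrough_divisor = _as_decimal(
            defaults["breakthrough_divisor"], "defaults.breakthrough_divisor"
        )
    if "egfr_warning_threshold" in defaults:
        form.egfr_warning_threshold = _as_decimal(
            defaults["egfr_warning_threshold"], "defaults.egfr_warning_threshold"
        )
    if "large_dose_ome_threshold" in defaults:
        form.large_dose_ome_threshold = _as_decimal(
            defaults["large_dose_ome_threshold"], "defaults.large_dose_ome_threshold"
        )
    for route, inc in (defaults.get("practical_increments") or {}).items():
        form.practical_increments[_canon(route)] = _as_decimal(
            inc, f"defaults.practical_increments.{route}"
        )

    return form.raise_for_violations()


def formulary_to_dict(form: Formulary) -> dict:
    """Serialise a formulary back to the file schema (plain types only)."""

    def num(d: Decimal) -> Union[int, float]:
        return int(d) if d == d.to_integral_value() else float(d)

    out: dict = {
        "version": form.version_id,
        "drugs": [
            {
                "name": dr.drug_name,
                "route": dr.route,
                "supported": dr.supported,
                "renal_risk": dr.renal_risk,
            }
            for dr in form.drug_routes.values()
        ],
        "factors": [
            {"drug": f.drug_name, "route": f.route, "ome_per_unit": num(f.ome_per_unit)}
            for f in form.factors.values()
        ],
        "patch_tables": {
            drug: [
                {"strength": num(b.strength), "ome_low": num(b.ome_low), "ome_high": num(b.ome_high)}
                for b in bands
            ]
            for drug, bands in form.patch_tables.items()
        },
        "defaults": {
            "breakthrough_divisor": num(form.breakthrough_divisor),
            "egfr_warning_threshold": num(form.egfr_warning_threshold),
            "practical_increments": {
                route: num(inc) for route, inc in form.practical_increments.items()
            },
        },
    }
    if form.large_dose_ome_threshold is not None:
        out["defaults"]["large_dose_ome_threshold"] = num(form.large_dose_ome_threshold)
    return out


def dump_formulary(form: Formulary, path: Union[str, Path]) -> None:
    """Write a formulary to a YAML file (round-trips through load_formulary)."""
    Path(path).write_text(yaml.safe_dump(formulary_to_dict(form), sort_keys=False))
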