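"""Equianalgesic conversion engine.

Every conversion runs through the oral-morphine-equivalent (OME) hub:

    index dose  --x factor-->  24h OME (mg)  --/ factor or patch table-->  target dose

The hub model guarantees transitive consistency between any pair of
preparations (a dense pairwise ratio matrix cannot, once edited by hand);
the pairwise matrix survives only as an independent test oracle.

Safety direction of all rounding is DOWN.  In particular, when a computed
OME falls exactly on the shared border of two adjacent patch bands the
*lower*-strength patch is chosen: rounding up at borders is a known defect
class in deployed dose-conversion tools, and the band comparison here is
exact decimal arithmetic so the border case never depends on binary float
representation.

The one deliberate exception is :func:`round_practical`'s never-zero rule:
rounding a small positive dose down to zero would silently delete the
prescription, so the minimum increment is returned instead together with a
``large_dose`` warning flagging the upward relative change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from enum import Enum
from typing import Optional, Sequence, Union

from .formulary import (
    TRANSDERMAL,
    UNIT_BY_ROUTE,
    Formulary,
    PatchBand,
    _canon,
    lookup_factor,
)

Number = Union[int, float, str, Decimal]


def _dose(value: Number, what: str = "dose") -> Decimal:
    d = Decimal(str(value))
    if d <= 0:
        raise ValueError(f"{what} must be positive, got {value}")
    return d


class Status(str, Enum):
    OK = "ok"
    NO_GUIDELINE_EQUIVALENCE = "no_guideline_equivalence"
    UNSUPPORTED_DRUG = "unsupported_drug"


class WarningCode(str, Enum):
    RENAL_CAUTION = "renal_caution"
    BELOW_SMALLEST_PATCH = "below_smallest_patch"
    ABOVE_LARGEST_PATCH = "above_largest_patch"
    LARGE_DOSE = "large_dose"


@dataclass(frozen=True)
class DoseWarning:
    code: WarningCode
    message: str


class TieBreak(str, Enum):
    """Border resolution when an OME equals a shared patch-band border.

    DOWN is the correct, safety-first behaviour.  UP reproduces the known
    round-up defect and exists only so tests can demonstrate that the defect
    produces mismatches exactly at band borders; it must never be used in a
    clinical configuration.
    """

    DOWN = "down"
    UP = "up"


@dataclass(frozen=True)
class ConversionRequest:
    index_drug: str
    index_route: str
    index_dose: Decimal
    target_drug: str
    target_route: str
    egfr: Optional[Decimal] = None  # mL/min
    indication: Optional[str] = None
    rounding: str = "off"  # "off" | "practical"

    def __post_init__(self):
        object.__setattr__(self, "index_dose", _dose(self.index_dose, "index_dose"))
        if self.egfr is not None:
            egfr = Decimal(str(self.egfr))
            if egfr < 0:
                raise ValueError(f"egfr must be non-negative, got {self.egfr}")
            object.__setattr__(self, "egfr", egfr)
        if self.rounding not in ("off", "practical"):
            raise ValueError(f"rounding must be 'off' or 'practical', got {self.rounding!r}")


@dataclass(frozen=True)
class ConversionResult:
    status: Status
    formulary_version: str
    ome: Optional[Decimal] = None  # mg/24h
    exact_target_dose: Optional[Decimal] = None
    practical_target_dose: Optional[Decimal] = None
    target_unit: Optional[str] = None
    warnings: tuple[DoseWarning, ...] = ()

    @property
    def ok(self) -> bool:
        return self.status is Status.OK

    def warning_codes(self) -> tuple[str, ...]:
        return tuple(w.code.value for w in self.warnings)


# ---------------------------------------------------------------------------
# hub arithmetic
# ---------------------------------------------------------------------------

def to_ome(formulary: Formulary, drug: str, route: str, dose: Number) -> Optional[Decimal]:
    """24h oral morphine equivalent of a dose, or None without a factor."""
    d = _dose(dose)
    factor = lookup_factor(formulary, drug, route)
    if factor is None:
        return None
    return d * factor.ome_per_unit


def from_ome(formulary: Formulary, drug: str, route: str, ome: Number) -> Optional[Decimal]:
    """Target dose delivering the given OME; exact inverse of :func:`to_ome`."""
    o = _dose(ome, "ome")
    if _canon(route) == TRANSDERMAL:
        raise ValueError(
            "transdermal targets are discrete patch strengths; use select_patch"
        )
    factor = lookup_factor(formulary, drug, route)
    if factor is None:
        return None
    return o / factor.ome_per_unit


def select_patch(
    table: Sequence[PatchBand],
    ome: Number,
    tie_break: TieBreak = TieBreak.DOWN,
) -> tuple[Optional[PatchBand], Optional[DoseWarning]]:
    """Pick the patch band whose inclusive OME range contains ``ome``.

    Shared borders resolve to the lower-strength band under the default
    DOWN rule (UP reproduces the historical defect).  Below the first band
    returns ``(None, below_smallest_patch)``; above the last band returns
    the highest band plus an ``above_largest_patch`` warning rather than
    failing, since combination patches are real practice.
    """
    if not table:
        raise ValueError("empty patch table")
    o = _dose(ome, "ome")
    bands = list(table)
    if o < bands[0].ome_low:
        return None, DoseWarning(
            WarningCode.BELOW_SMALLEST_PATCH,
            f"24h OME {o} mg is below the smallest patch range "
            f"(starts at {bands[0].ome_low} mg)",
        )
    if o > bands[-1].ome_high:
        return bands[-1], DoseWarning(
            WarningCode.ABOVE_LARGEST_PATCH,
            f"24h OME {o} mg exceeds the largest patch range "
            f"(ends at {bands[-1].ome_high} mg); consider combination patches",
        )
    ordered = bands if tie_break is TieBreak.DOWN else list(reversed(bands))
    for band in ordered:
        if band.ome_low <= o <= band.ome_high:
            return band, None
    # Unreachable for gap-free tables; a gap between bands is a data defect.
    raise ValueError(f"OME {o} mg falls in a gap of the patch table")


@dataclass(frozen=True)
class RoundedDose:
    dose: Decimal
    forced_minimum: bool  # rounding down would have yielded zero


def round_practical(dose: Number, increment: Number) -> RoundedDose:
    """Round DOWN to the nearest multiple of ``increment`` (never to zero).

    If flooring would give 0 for a positive input, the increment itself is
    returned with ``forced_minimum=True`` so callers can warn about the
    large upward relative change.
    """
    d = _dose(dose)
    inc = _dose(increment, "increment")
    floored = (d // inc) * inc
    if floored == 0:
        return RoundedDose(inc, True)
    return RoundedDose(floored, False)


# ---------------------------------------------------------------------------
# warnings
# ---------------------------------------------------------------------------

def renal_warning(
    formulary: Formulary, drug: str, egfr: Optional[Number]
) -> Optional[DoseWarning]:
    """renal_caution iff eGFR is known, below threshold, and the drug is flagged.

    An absent eGFR yields no warning: the tool reports what the data shows
    and never silently assumes either normal or impaired renal function.
    """
    if egfr is None:
        return None
    e = Decimal(str(egfr))
    if e < 0:
        raise ValueError(f"egfr must be non-negative, got {egfr}")
    if e < formulary.egfr_warning_threshold and formulary.renal_risk(drug):
        return DoseWarning(
            WarningCode.RENAL_CAUTION,
            f"eGFR {e} mL/min is below {formulary.egfr_warning_threshold} mL/min: "
            f"consider dose adjustment for {_canon(drug)} in renal impairment",
        )
    return None


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def convert(
    formulary: Formulary,
    request: ConversionRequest,
    tie_break: TieBreak = TieBreak.DOWN,
) -> ConversionResult:
    """Full conversion pipeline.

    check supported -> to_ome -> (select_patch | from_ome) -> practical
    rounding on request -> attach warnings.  Endpoints the guideline does
    not cover yield ``no_guideline_equivalence``; an explicitly unsupported
    drug (methadone) yields ``unsupported_drug``.  A dose is never silently
    substituted.
    """
    version = formulary.version_id
    idx_drug, idx_route = _canon(request.index_drug), _canon(request.index_route)
    tgt_drug, tgt_route = _canon(request.target_drug), _canon(request.target_route)

    for drug, route in ((idx_drug, idx_route), (tgt_drug, tgt_route)):
        dr = formulary.drug_route(drug, route)
        if dr is not None and not dr.supported:
            return ConversionResult(Status.UNSUPPORTED_DRUG, version)
        # Unsupported drug under any route blocks the conversion outright.
        if any(
            d.drug_name == drug and not d.supported for d in formulary.drug_routes.values()
        ):
            return ConversionResult(Status.UNSUPPORTED_DRUG, version)

    ome = to_ome(formulary, idx_drug, idx_route, request.index_dose)
    if ome is None:
        return ConversionResult(Status.NO_GUIDELINE_EQUIVALENCE, version)

    warnings: list[DoseWarning] = []

    rw = renal_warning(formulary, tgt_drug, request.egfr)
    if rw is not None:
        warnings.append(rw)
    if (
        formulary.large_dose_ome_threshold is not None
        and ome > formulary.large_dose_ome_threshold
    ):
        warnings.append(
            DoseWarning(
                WarningCode.LARGE_DOSE,
                f"24h OME {ome} mg exceeds {formulary.large_dose_ome_threshold} mg; "
                "verify the index dose and seek specialist advice",
            )
        )

    if tgt_route == TRANSDERMAL:
        table = formulary.patch_table(tgt_drug)
        if not table or formulary.drug_route(tgt_drug, tgt_route) is None:
            return ConversionResult(Status.NO_GUIDELINE_EQUIVALENCE, version)
        band, warning = select_patch(table, ome, tie_break=tie_break)
        if warning is not None:
            warnings.append(warning)
        if band is None:
            # Below the smallest patch: no patch can be recommended.
            return ConversionResult(
                Status.OK,
                version,
                ome=ome,
                target_unit=UNIT_BY_ROUTE[TRANSDERMAL],
                warnings=tuple(warnings),
            )
        return ConversionResult(
            Status.OK,
            version,
            ome=ome,
            practical_target_dose=band.strength,
            target_unit=UNIT_BY_ROUTE[TRANSDERMAL],
            warnings=tuple(warnings),
        )

    exact = from_ome(formulary, tgt_drug, tgt_route, ome)
    if exact is None:
        return ConversionResult(Status.NO_GUIDELINE_EQUIVALENCE, version)

    practical = exact
    if request.rounding == "practical":
        inc = formulary.increment_for(tgt_route)
        if inc is not None:
            rounded = round_practical(exact, inc)
            practical = rounded.dose
            if rounded.forced_minimum:
                warnings.append(
                    DoseWarning(
                        WarningCode.LARGE_DOSE,
                        f"exact dose {exact} {UNIT_BY_ROUTE[tgt_route]} rounds up to the "
                        f"minimum practical increment {inc}: large relative increase",
                    )
                )

    return ConversionResult(
        Status.OK,
        version,
        ome=ome,
        exact_target_dose=exact,
        practical_target_dose=practical,
        target_unit=UNIT_BY_ROUTE[tgt_route],
        warnings=tuple(warnings),
    )


def breakthrough_dose(
    formulary: Formulary,
    drug: str,
    route: str,
    daily_dose: Number,
    rounding: str = "off",
) -> Decimal:
    """Rescue dose for pain flares: the regular 24h dose / breakthrough divisor.

    Transdermal routes are refused: breakthrough is computed on the 24h OME,
    so convert the patch to an oral equivalent first.
    """
    d = _dose(daily_dose, "daily_dose")
    if _canon(route) == TRANSDERMAL:
        raise ValueError(
            "breakthrough dosing is not defined for a patch: convert the patch "
            "to its 24h oral equivalent first, then compute breakthrough"
        )
    dose = d / formulary.breakthrough_divisor
    if rounding == "practical":
        inc = formulary.increment_for(route)
        if inc is not None:
            dose = round_practical(dose, inc).dose
    return dose
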