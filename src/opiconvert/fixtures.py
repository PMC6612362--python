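"""Deterministic test fixtures and independent oracles.

This module is first-class, tested code.  It ships:

* the fixture formulary **F1** — deliberately round, non-clinical values so
  every hand example is mental arithmetic and nobody mistakes the test
  tables for prescribing guidance;
* a seeded request generator (Mersenne Twister via :mod:`random`, a named
  portable PRNG, so sequences are stable across platforms);
* the **pairwise-ratio conversion oracle**: an independent re-derivation of
  every conversion as dose x factor_index / factor_target in a single step,
  with patch selection re-implemented as a linear scan on upper bounds —
  no code shared with the engine's hub pipeline;
* the **permutation oracle** for the Cochran–Armitage trend test:
  a Monte-Carlo conditional-on-margins null;
* builders that replay a pilot prescribing audit at the scale of the
  five-month single-centre study this package's analytics are designed to
  summarise (210 drug-to-drug conversions, 76 breakthrough calculations,
  18 conversions without guideline equivalence, and 10 patch-border cases
  that expose the historical round-up defect).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .audit import AuditLog, AuditRecord, TrendTable
from .engine import (
    ConversionRequest,
    ConversionResult,
    Status,
    TieBreak,
    WarningCode,
    DoseWarning,
    breakthrough_dose,
    convert,
)
from .formulary import (
    ORAL,
    SUBCUTANEOUS,
    TRANSDERMAL,
    UNIT_BY_ROUTE,
    Formulary,
    parse_formulary,
)

# ---------------------------------------------------------------------------
# F1, the fixture formulary
# ---------------------------------------------------------------------------

#: F1 as plain file-schema data.  Ten drug/route entries; values are round
#: numbers chosen for arithmetic transparency, NOT clinical content.
F1_DATA: dict = {
    "version": "F1",
    "drugs": [
        {"name": "morphine", "route": "oral", "renal_risk": True},
        {"name": "morphine", "route": "subcutaneous", "renal_risk": True},
        {"name": "oxycodone", "route": "oral"},
        {"name": "oxycodone", "route": "subcutaneous"},
        {"name": "codeine", "route": "oral", "renal_risk": True},
        {"name": "alfentanil", "route": "subcutaneous", "renal_risk": False},
        {"name": "diamorphine", "route": "subcutaneous", "renal_risk": True},
        {"name": "hydromorphone", "route": "oral"},
        {"name": "methadone", "route": "oral", "supported": False},
        {"name": "fentanyl", "route": "transdermal"},
    ],
    "factors": [
        {"drug": "morphine", "route": "oral", "ome_per_unit": 1},
        {"drug": "morphine", "route": "subcutaneous", "ome_per_unit": 2},
        {"drug": "oxycodone", "route": "oral", "ome_per_unit": 2},
        {"drug": "oxycodone", "route": "subcutaneous", "ome_per_unit": 4},
        {"drug": "codeine", "route": "oral", "ome_per_unit": 0.1},
        {"drug": "alfentanil", "route": "subcutaneous", "ome_per_unit": 30},
        {"drug": "diamorphine", "route": "subcutaneous", "ome_per_unit": 3},
        {"drug": "hydromorphone", "route": "oral", "ome_per_unit": 5},
    ],
    "patch_tables": {
        "fentanyl": [
            {"strength": 12, "ome_low": 30, "ome_high": 60},
            {"strength": 25, "ome_low": 60, "ome_high": 90},
            {"strength": 50, "ome_low": 90, "ome_high": 150},
            {"strength": 75, "ome_low": 150, "ome_high": 210},
            {"strength": 100, "ome_low": 210, "ome_high": 270},
        ]
    },
    "defaults": {
        "breakthrough_divisor": 6,
        "egfr_warning_threshold": 30,
        "practical_increments": {"oral": 2.5},
    },
}

#: The four shared band borders of the F1 fentanyl table, in mg OME/24h.
F1_PATCH_BORDERS = (Decimal(60), Decimal(90), Decimal(150), Decimal(210))


def fixture_formulary_F1() -> Formulary:
    """Build F1 from the in-code constant (validated on construction)."""
    return parse_formulary(F1_DATA)


def fixture_formulary_path() -> Path:
    """Path of the shipped F1 formulary file (exercises the loader)."""
    return Path(resources.files("opiconvert").joinpath("data/f1.yaml"))


# ---------------------------------------------------------------------------
# seeded request generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakthroughRequest:
    drug: str
    route: str
    daily_dose: Decimal


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the seeded request stream.

    Fractions are applied as exact rounded counts over ``n_requests``.
    """

    seed: int
    n_requests: int
    frac_no_equivalence: float = 0.1
    frac_breakthrough: float = 0.0
    frac_border: float = 0.05
    frac_methadone: float = 0.02


#: Continuous (non-patch) preparations of F1 with dose grids per route.
_DOSE_GRID = {
    ORAL: [Decimal(5) * i for i in range(2, 49)],  # 10 .. 240 mg/24h
    SUBCUTANEOUS: [Decimal("2.5") * i for i in range(2, 49)],  # 5 .. 120 mg/24h
}

#: Drug/route pairs absent from F1, used to build no-equivalence requests.
_MISSING_PAIRS = (
    ("buprenorphine", ORAL),
    ("tramadol", ORAL),
    ("dihydrocodeine", ORAL),
    ("hydromorphone", SUBCUTANEOUS),
)


def _continuous_pairs(formulary: Formulary) -> list[tuple[str, str]]:
    return sorted(
        key
        for key, dr in formulary.drug_routes.items()
        if dr.supported and dr.route != TRANSDERMAL and key in formulary.factors
    )


def generate_requests(
    spec: FixtureSpec, formulary: Optional[Formulary] = None
) -> list[Union[ConversionRequest, BreakthroughRequest]]:
    """Deterministic stream of requests over F1 (or a supplied formulary).

    The stream contains, in exactly the rounded counts implied by the
    fractions: no-equivalence pairs, patch-border-exact conversions,
    methadone requests and breakthrough calculations; the remainder are
    random conversions between supported preparations (including interior
    fentanyl patch targets).
    """
    formulary = formulary or fixture_formulary_F1()
    rng = random.Random(spec.seed)
    n = spec.n_requests
    n_ne = round(spec.frac_no_equivalence * n)
    n_bt = round(spec.frac_breakthrough * n)
    n_border = round(spec.frac_border * n)
    n_meth = round(spec.frac_methadone * n)
    n_plain = n - n_ne - n_bt - n_border - n_meth
    if n_plain < 0:
        raise ValueError("fractions exceed 1")

    continuous = _continuous_pairs(formulary)
    out: list[Union[ConversionRequest, BreakthroughRequest]] = []

    for _ in range(n_plain):
        idx = rng.choice(continuous)
        if rng.random() < 0.2 and formulary.patch_table("fentanyl"):
            # interior (non-border) fentanyl patch target: morphine oral dose
            # strictly inside a band
            interior = [Decimal(v) for v in (45, 70, 120, 180, 240)]
            out.append(
                ConversionRequest("morphine", ORAL, rng.choice(interior), "fentanyl", TRANSDERMAL)
            )
            continue
        tgt = rng.choice([p for p in continuous if p != idx])
        dose = rng.choice(_DOSE_GRID[idx[1]])
        out.append(ConversionRequest(idx[0], idx[1], dose, tgt[0], tgt[1]))

    for _ in range(n_border):
        border = rng.choice(F1_PATCH_BORDERS)
        # morphine oral (factor 1) or oxycodone oral (factor 2) hit the
        # border exactly
        if rng.random() < 0.5:
            out.append(ConversionRequest("morphine", ORAL, border, "fentanyl", TRANSDERMAL))
        else:
            out.append(ConversionRequest("oxycodone", ORAL, border / 2, "fentanyl", TRANSDERMAL))

    for _ in range(n_ne):
        drug, route = rng.choice(_MISSING_PAIRS)
        if rng.random() < 0.5:
            idx = rng.choice(continuous)
            out.append(
                ConversionRequest(idx[0], idx[1], rng.choice(_DOSE_GRID[idx[1]]), drug, route)
            )
        else:
            tgt = rng.choice(continuous)
            out.append(
                ConversionRequest(drug, route, rng.choice(_DOSE_GRID[route]), tgt[0], tgt[1])
            )

    for _ in range(n_meth):
        idx = rng.choice(continuous)
        out.append(
            ConversionRequest(idx[0], idx[1], rng.choice(_DOSE_GRID[idx[1]]), "methadone", ORAL)
        )

    for _ in range(n_bt):
        drug, route = rng.choice(continuous)
        out.append(BreakthroughRequest(drug, route, rng.choice(_DOSE_GRID[route])))

    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# pairwise-ratio conversion oracle
# ---------------------------------------------------------------------------

def pairwise_oracle(
    formulary: Formulary, request: ConversionRequest
) -> ConversionResult:
    """Independent conversion oracle: direct pairwise ratio, no hub pipeline.

    target dose = index dose x factor_index / factor_target in one Decimal
    expression; patch selection is a linear scan on band upper bounds with
    an explicit border-down comparison.  Shares data (the formulary) but no
    conversion code with :func:`opiconvert.engine.convert`.
    """
    version = formulary.version_id
    idx = (request.index_drug.strip().lower(), request.index_route.strip().lower())
    tgt = (request.target_drug.strip().lower(), request.target_route.strip().lower())

    for drug, _route in (idx, tgt):
        if any(
            dr.drug_name == drug and not dr.supported
            for dr in formulary.drug_routes.values()
        ):
            return ConversionResult(Status.UNSUPPORTED_DRUG, version)

    fa = formulary.factors.get(idx)
    if fa is None:
        return ConversionResult(Status.NO_GUIDELINE_EQUIVALENCE, version)
    dose = request.index_dose
    ome = dose * fa.ome_per_unit

    if tgt[1] == TRANSDERMAL:
        table = formulary.patch_tables.get(tgt[0])
        if not table or (tgt[0], TRANSDERMAL) not in formulary.drug_routes:
            return ConversionResult(Status.NO_GUIDELINE_EQUIVALENCE, version)
        if ome < table[0].ome_low:
            return ConversionResult(
                Status.OK,
                version,
                ome=ome,
                target_unit=UNIT_BY_ROUTE[TRANSDERMAL],
                warnings=(
                    DoseWarning(WarningCode.BELOW_SMALLEST_PATCH, "below smallest patch"),
                ),
            )
        if ome > table[-1].ome_high:
            return ConversionResult(
                Status.OK,
                version,
                ome=ome,
                practical_target_dose=table[-1].strength,
                target_unit=UNIT_BY_ROUTE[TRANSDERMAL],
                warnings=(
                    DoseWarning(WarningCode.ABOVE_LARGEST_PATCH, "above largest patch"),
                ),
            )
        # border-down: the FIRST band whose upper bound reaches the OME wins,
        # so an OME equal to a shared border resolves to the lower strength.
        chosen = next(band for band in table if ome <= band.ome_high)
        assert chosen.ome_low <= ome
        return ConversionResult(
            Status.OK,
            version,
            ome=ome,
            practical_target_dose=chosen.strength,
            target_unit=UNIT_BY_ROUTE[TRANSDERMAL],
        )

    fb = formulary.factors.get(tgt)
    if fb is None:
        return ConversionResult(Status.NO_GUIDELINE_EQUIVALENCE, version)
    exact = dose * fa.ome_per_unit / fb.ome_per_unit
    practical = exact
    if request.rounding == "practical":
        inc = formulary.practical_increments.get(tgt[1])
        if inc is not None:
            practical = exact - (exact % inc)
            if practical == 0:
                practical = inc
    return ConversionResult(
        Status.OK,
        version,
        ome=ome,
        exact_target_dose=exact,
        practical_target_dose=practical,
        target_unit=UNIT_BY_ROUTE[tgt[1]],
    )


class GoldStandard:
    """Gold-standard lookup for audit match-rate analysis.

    Recomputes each record's answer from its request fields through the
    pairwise oracle (never from the stored result), mirroring a manual
    re-derivation of every logged calculation from the guideline tables.
    """

    def __init__(self, formulary: Formulary):
        self.formulary = formulary
        self.formulary_version = formulary.version_id

    def gold_practical(self, record: AuditRecord) -> Optional[Decimal]:
        if record.kind == "breakthrough":
            return Decimal(record.index_dose) / self.formulary.breakthrough_divisor
        request = ConversionRequest(
            record.index_drug,
            record.index_route,
            Decimal(record.index_dose),
            record.target_drug or "",
            record.target_route or "",
        )
        result = pairwise_oracle(self.formulary, request)
        return result.practical_target_dose


# ---------------------------------------------------------------------------
# permutation oracle for the trend test
# ---------------------------------------------------------------------------

def permutation_trend_pvalue(
    table: TrendTable, n_resamples: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo permutation two-sided p for the linear trend statistic.

    Conditions on both margins: ``sum(post)`` subjects are drawn without
    replacement from the pooled column totals (multivariate hypergeometric)
    and the trend statistic T = sum(score x post count) recomputed.  The
    two-sided mid-p — P(|T - E| > |t| ) + 0.5 P(|T - E| = |t|) — is
    returned with its Monte-Carlo standard error; the mid-p convention is
    the discrete quantity the uncorrected normal approximation estimates.
    All comparisons are exact integer arithmetic (scaled by N).
    """
    rng = np.random.default_rng(seed)
    n_i = np.array([a + b for a, b in zip(table.pre, table.post)], dtype=np.int64)
    s = np.array(table.scores, dtype=np.int64)
    N = int(n_i.sum())
    R2 = int(sum(table.post))
    draws = rng.multivariate_hypergeometric(n_i, R2, size=n_resamples)
    T = draws @ s
    scaled_mean = R2 * int((s * n_i).sum())  # = N x E[T], an integer
    d = np.abs(N * T - scaled_mean)
    t_obs = int(sum(si * bi for si, bi in zip(table.scores, table.post)))
    d_obs = abs(N * t_obs - scaled_mean)
    p = float((np.sum(d > d_obs) + 0.5 * np.sum(d == d_obs)) / n_resamples)
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_resamples) / n_resamples))
    return p, se


def permutation_trend_zscore(
    table: TrendTable, n_resamples: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo standardisation of the trend statistic.

    Estimates the permutation-null mean and standard deviation of
    T = sum(score x post count) by brute-force resampling and standardises
    the observed T against them — an independent check of the analytic
    hypergeometric moments.  Returns ``(z_mc, se)`` where ``se`` is the
    Monte-Carlo standard error of ``z_mc`` (delta method, near-normal null).
    """
    rng = np.random.default_rng(seed)
    n_i = np.array([a + b for a, b in zip(table.pre, table.post)], dtype=np.int64)
    s = np.array(table.scores, dtype=np.int64)
    R2 = int(sum(table.post))
    draws = rng.multivariate_hypergeometric(n_i, R2, size=n_resamples)
    T = draws @ s
    t_obs = int(sum(si * bi for si, bi in zip(table.scores, table.post)))
    sd = float(T.std(ddof=1))
    z_mc = (t_obs - float(T.mean())) / sd
    se = float(np.sqrt((1.0 + z_mc * z_mc / 2.0) / n_resamples))
    return z_mc, se


# ---------------------------------------------------------------------------
# pilot-study-scale audit replay
# ---------------------------------------------------------------------------

#: Observed opioid-switch tallies from the five-month pilot audit the
#: analytics layer is sized for: counts of each opioid as the starting
#: (index) and resulting (target) drug of a switch.  These are inputs to
#: the usage analytics, not conversion data.
PILOT_INDEX_TALLY = {
    "alfentanil": 26,
    "buprenorphine": 2,
    "codeine": 16,
    "diamorphine": 6,
    "dihydrocodeine": 1,
    "hydromorphone": 10,
    "fentanyl": 0,
    "morphine": 81,
    "oxycodone": 68,
}
PILOT_TARGET_TALLY = {
    "alfentanil": 41,
    "buprenorphine": 4,
    "codeine": 3,
    "diamorphine": 7,
    "dihydrocodeine": 1,
    "hydromorphone": 9,
    "fentanyl": 29,
    "morphine": 53,
    "oxycodone": 63,
}
PILOT_N_CONVERSIONS = 210
PILOT_N_BREAKTHROUGH = 76
PILOT_N_NO_EQUIVALENCE = 18
PILOT_N_BORDER_CASES = 10

_EPOCH = "1970-01-01T00:00:00Z"


def _record_dict(
    log: AuditLog,
    *,
    kind: str,
    index_drug: str,
    index_route: str,
    index_dose: Decimal,
    target_drug: Optional[str] = None,
    target_route: Optional[str] = None,
    result: Optional[ConversionResult] = None,
    practical: Optional[Decimal] = None,
    status: str = Status.OK.value,
    indication: str = "unspecified",
    formulary_version: str = "F1",
    timestamp: str = _EPOCH,
) -> dict:
    if result is not None:
        status = result.status.value
        formulary_version = result.formulary_version
    return {
        "record_id": log.next_record_id,
        "timestamp": timestamp,
        "kind": kind,
        "index_drug": index_drug,
        "index_route": index_route,
        "index_dose": str(index_dose),
        "target_drug": target_drug,
        "target_route": target_route,
        "status": status,
        "ome": None if result is None or result.ome is None else str(result.ome),
        "exact_dose": (
            None
            if result is None or result.exact_target_dose is None
            else str(result.exact_target_dose)
        ),
        "practical_dose": (
            str(practical)
            if practical is not None
            else (
                None
                if result is None or result.practical_target_dose is None
                else str(result.practical_target_dose)
            )
        ),
        "warnings": [] if result is None else list(result.warning_codes()),
        "indication": indication,
        "formulary_version": formulary_version,
    }


def log_request(
    log: AuditLog,
    formulary: Formulary,
    request: Union[ConversionRequest, BreakthroughRequest],
    tie_break: TieBreak = TieBreak.DOWN,
    indication: str = "unspecified",
    timestamp: str = _EPOCH,
) -> AuditRecord:
    """Execute one request against the engine and append the audit record.

    ``timestamp`` defaults to the epoch so fixture logs are byte-stable;
    interactive callers pass the current UTC time.
    """
    if isinstance(request, BreakthroughRequest):
        dose = breakthrough_dose(formulary, request.drug, request.route, request.daily_dose)
        return log.append(
            _record_dict(
                log,
                kind="breakthrough",
                index_drug=request.drug,
                index_route=request.route,
                index_dose=request.daily_dose,
                practical=dose,
                indication=indication,
                formulary_version=formulary.version_id,
                timestamp=timestamp,
            )
        )
    result = convert(formulary, request, tie_break=tie_break)
    return log.append(
        _record_dict(
            log,
            kind="conversion",
            index_drug=request.index_drug.strip().lower(),
            index_route=request.index_route.strip().lower(),
            index_dose=request.index_dose,
            target_drug=request.target_drug.strip().lower(),
            target_route=request.target_route.strip().lower(),
            result=result,
            indication=indication,
            timestamp=timestamp,
        )
    )


def generate_pilot_usage_log(seed: int = 0) -> AuditLog:
    """A log whose per-drug index and target tallies equal the pilot audit's.

    Index and target drug lists realise the two tally columns exactly; the
    pairing of index with target within a record is a seeded shuffle (the
    tallies are marginal counts and carry no pairing information).  Doses
    are nominal: this log exercises the usage tallies, not the engine.
    """
    rng = random.Random(seed)
    index_drugs = [d for d, n in sorted(PILOT_INDEX_TALLY.items()) for _ in range(n)]
    target_drugs = [d for d, n in sorted(PILOT_TARGET_TALLY.items()) for _ in range(n)]
    rng.shuffle(index_drugs)
    rng.shuffle(target_drugs)
    log = AuditLog()
    for idx, tgt in zip(index_drugs, target_drugs):
        log.append(
            _record_dict(
                log,
                kind="conversion",
                index_drug=idx,
                index_route=ORAL,
                index_dose=Decimal(60),
                target_drug=tgt,
                target_route=ORAL,
                status=Status.OK.value,
            )
        )
    for _ in range(PILOT_N_BREAKTHROUGH):
        log.append(
            _record_dict(
                log,
                kind="breakthrough",
                index_drug="morphine",
                index_route=ORAL,
                index_dose=Decimal(60),
                practical=Decimal(10),
            )
        )
    return log


def generate_pilot_accuracy_log(
    seed: int,
    formulary: Optional[Formulary] = None,
    tie_break: TieBreak = TieBreak.UP,
) -> AuditLog:
    """Replay the pilot's accuracy audit at its exact scale.

    286 calculations: 210 drug-to-drug (18 of which lack a guideline
    equivalence and are destined for exclusion; 10 of which are patch
    conversions whose OME lands exactly on a band border) plus 76
    breakthrough calculations.  ``tie_break=UP`` reproduces the historical
    deployed defect, so comparing this log against the round-down gold
    standard yields mismatches at exactly the border cases;
    ``tie_break=DOWN`` replays the corrected release.
    """
    formulary = formulary or fixture_formulary_F1()
    rng = random.Random(seed)
    continuous = _continuous_pairs(formulary)

    requests: list[Union[ConversionRequest, BreakthroughRequest]] = []

    n_plain = PILOT_N_CONVERSIONS - PILOT_N_NO_EQUIVALENCE - PILOT_N_BORDER_CASES
    for _ in range(n_plain):
        if rng.random() < 0.12:
            interior = [Decimal(v) for v in (45, 70, 120, 180, 240, 300)]
            requests.append(
                ConversionRequest("morphine", ORAL, rng.choice(interior), "fentanyl", TRANSDERMAL)
            )
            continue
        idx = rng.choice(continuous)
        tgt = rng.choice([p for p in continuous if p != idx])
        requests.append(
            ConversionRequest(idx[0], idx[1], rng.choice(_DOSE_GRID[idx[1]]), tgt[0], tgt[1])
        )

    for i in range(PILOT_N_BORDER_CASES):
        border = F1_PATCH_BORDERS[i % len(F1_PATCH_BORDERS)]
        requests.append(ConversionRequest("morphine", ORAL, border, "fentanyl", TRANSDERMAL))

    for _ in range(PILOT_N_NO_EQUIVALENCE):
        drug, route = rng.choice(_MISSING_PAIRS)
        idx = rng.choice(continuous)
        requests.append(
            ConversionRequest(idx[0], idx[1], rng.choice(_DOSE_GRID[idx[1]]), drug, route)
        )

    for _ in range(PILOT_N_BREAKTHROUGH):
        drug, route = rng.choice(continuous)
        requests.append(BreakthroughRequest(drug, route, rng.choice(_DOSE_GRID[route])))

    rng.shuffle(requests)
    log = AuditLog()
    for request in requests:
        log_request(log, formulary, request, tie_break=tie_break, indication="cancer pain")
    return log
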