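"""Append-only prescribing audit log and its analytics.

Every conversion or breakthrough calculation is captured as one
:class:`AuditRecord` in a local append-only JSON-lines log — the same data
contract as a cloud capture database, with no infrastructure dependency.
Records carry no patient-identifiable information by construction: the
schema is closed (unknown fields are rejected, not ignored) and the only
categorical context field, ``indication``, is drawn from a fixed list.

Analytics reproduce the standard audit summaries of a conversion service:

* usage tallies by index (starting) and target (resulting) opioid, with
  the conservation law that both tallies sum to the drug-to-drug record
  count;
* exclusion arithmetic — calculations whose endpoints have no guideline
  equivalence are removed before accuracy analysis;
* gold-standard match rate: the fraction of analysed calculations whose
  final practical dose equals an independent oracle's, reported half-up to
  one decimal;
* a Cochran–Armitage test for trend over ordered confidence categories
  (pre- vs post-intervention survey counts).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from math import comb, sqrt
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence, Union

from scipy.stats import norm

from .engine import Status

#: Closed list of indication categories.  Free text is forbidden so the log
#: can never carry identifiable information through this field.
INDICATIONS = (
    "cancer pain",
    "non-cancer pain",
    "end of life",
    "opioid toxicity",
    "renal impairment",
    "unspecified",
)

RECORD_KINDS = ("conversion", "breakthrough")

#: Fixed field order, shared by the JSON-lines schema and the CSV export.
RECORD_FIELDS = (
    "record_id",
    "timestamp",
    "kind",
    "index_drug",
    "index_route",
    "index_dose",
    "target_drug",
    "target_route",
    "status",
    "ome",
    "exact_dose",
    "practical_dose",
    "warnings",
    "indication",
    "formulary_version",
)

_STATUS_VALUES = tuple(s.value for s in Status)


class AuditError(Exception):
    pass


class AuditSchemaError(AuditError):
    """A record violates the closed schema; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class AuditRecord:
    """One logged calculation.  Dose fields are decimal strings (exact)."""

    record_id: int
    timestamp: str  # ISO-8601 UTC
    kind: str  # conversion | breakthrough
    index_drug: str
    index_route: str
    index_dose: str
    target_drug: Optional[str]
    target_route: Optional[str]
    status: str
    ome: Optional[str]
    exact_dose: Optional[str]
    practical_dose: Optional[str]
    warnings: tuple[str, ...]
    indication: str
    formulary_version: str

    def to_json(self) -> str:
        d = asdict(self)
        d["warnings"] = list(self.warnings)
        return json.dumps(d, sort_keys=False)


def validate_record(raw: Mapping, expected_id: Optional[int] = None) -> AuditRecord:
    """Validate a mapping against the closed record schema.

    Unknown keys are rejected by name — this is what enforces the
    no-identifiable-fields invariant.  ``expected_id`` enforces the gapless
    monotone record_id rule on append.
    """
    unknown = set(raw) - set(RECORD_FIELDS)
    if unknown:
        name = sorted(unknown)[0]
        raise AuditSchemaError(name, "field not in the closed audit schema (rejected)")
    missing = set(RECORD_FIELDS) - set(raw)
    if missing:
        raise AuditSchemaError(sorted(missing)[0], "required field missing")

    rid = raw["record_id"]
    if not isinstance(rid, int) or isinstance(rid, bool) or rid < 1:
        raise AuditSchemaError("record_id", f"must be a positive integer, got {rid!r}")
    if expected_id is not None and rid != expected_id:
        raise AuditSchemaError(
            "record_id", f"must be gapless: expected {expected_id}, got {rid}"
        )
    if raw["kind"] not in RECORD_KINDS:
        raise AuditSchemaError("kind", f"must be one of {RECORD_KINDS}, got {raw['kind']!r}")
    if raw["status"] not in _STATUS_VALUES:
        raise AuditSchemaError("status", f"unknown status {raw['status']!r}")
    if raw["indication"] not in INDICATIONS:
        raise AuditSchemaError(
            "indication",
            f"{raw['indication']!r} is not in the closed category list {INDICATIONS}",
        )
    warnings = raw["warnings"]
    if not isinstance(warnings, (list, tuple)) or not all(isinstance(w, str) for w in warnings):
        raise AuditSchemaError("warnings", "must be a list of warning code strings")
    for key in ("index_dose", "ome", "exact_dose", "practical_dose"):
        value = raw[key]
        if value is None:
            continue
        try:
            Decimal(str(value))
        except Exception:
            raise AuditSchemaError(key, f"not a decimal number: {value!r}") from None

    return AuditRecord(
        record_id=rid,
        timestamp=str(raw["timestamp"]),
        kind=raw["kind"],
        index_drug=str(raw["index_drug"]),
        index_route=str(raw["index_route"]),
        index_dose=str(raw["index_dose"]),
        target_drug=None if raw["target_drug"] is None else str(raw["target_drug"]),
        target_route=None if raw["target_route"] is None else str(raw["target_route"]),
        status=raw["status"],
        ome=None if raw["ome"] is None else str(raw["ome"]),
        exact_dose=None if raw["exact_dose"] is None else str(raw["exact_dose"]),
        practical_dose=None if raw["practical_dose"] is None else str(raw["practical_dose"]),
        warnings=tuple(warnings),
        indication=raw["indication"],
        formulary_version=str(raw["formulary_version"]),
    )


class AuditLog:
    """Append-only log of audit records, optionally backed by a JSONL file.

    There is deliberately no update or delete operation: the audit trail is
    immutable once written.
    """

    def __init__(self, path: Optional[Union[str, Path]] = None):
        self.path = Path(path) if path is not None else None
        self._records: list[AuditRecord] = []
        self.quarantined: list[tuple[Optional[int], str]] = []  # (record_id?, reason)
        if self.path is not None and self.path.exists():
            self._load()

    def _load(self) -> None:
        assert self.path is not None
        for lineno, line in enumerate(self.path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
                record = validate_record(raw)
            except (json.JSONDecodeError, AuditSchemaError) as exc:
                rid = None
                try:
                    rid = json.loads(line).get("record_id")
                except Exception:
                    pass
                self.quarantined.append((rid, f"line {lineno}: {exc}"))
                continue
            self._records.append(record)

    # -- append-only interface ------------------------------------------

    @property
    def next_record_id(self) -> int:
        return (self._records[-1].record_id + 1) if self._records else 1

    def append(self, record: Union[AuditRecord, Mapping]) -> AuditRecord:
        raw = asdict(record) if isinstance(record, AuditRecord) else dict(record)
        validated = validate_record(raw, expected_id=self.next_record_id)
        self._records.append(validated)
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(validated.to_json() + "\n")
        return validated

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def records(self) -> tuple[AuditRecord, ...]:
        return tuple(self._records)


def append_record(log: AuditLog, record: Union[AuditRecord, Mapping]) -> AuditLog:
    """Append exactly one validated record; returns the (mutated) log."""
    log.append(record)
    return log


# ---------------------------------------------------------------------------
# usage summaries
# ---------------------------------------------------------------------------

@dataclass
class UsageSummary:
    index_counts: dict[str, int] = field(default_factory=dict)
    target_counts: dict[str, int] = field(default_factory=dict)
    total_conversions: int = 0
    total_breakthrough: int = 0
    quarantined: int = 0
    excluded_no_equivalence: Optional[int] = None
    analyzed: Optional[int] = None
    matched: Optional[int] = None
    match_rate: Optional[float] = None  # percent, half-up to one decimal

    @property
    def total_recorded(self) -> int:
        return self.total_conversions + self.total_breakthrough


def summarize_usage(log: AuditLog) -> UsageSummary:
    """Tally index/target opioid usage over drug-to-drug records.

    Breakthrough calculations are tallied separately.  Records quarantined
    at load time are excluded from all tallies but counted.
    """
    index_counts: Counter[str] = Counter()
    target_counts: Counter[str] = Counter()
    n_conv = n_bt = 0
    for record in log:
        if record.kind == "breakthrough":
            n_bt += 1
            continue
        n_conv += 1
        index_counts[record.index_drug] += 1
        target_counts[record.target_drug or ""] += 1
    return UsageSummary(
        index_counts=dict(sorted(index_counts.items())),
        target_counts=dict(sorted(target_counts.items())),
        total_conversions=n_conv,
        total_breakthrough=n_bt,
        quarantined=len(log.quarantined),
    )


def _round_half_up_1dp(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class GoldStandardOracle(Protocol):
    """Independent lookup producing the guideline's own answer for a record."""

    formulary_version: str

    def gold_practical(self, record: AuditRecord) -> Optional[Decimal]:
        ...


def match_rate(log: AuditLog, oracle: GoldStandardOracle) -> UsageSummary:
    """Compare each analysed record's practical dose with the gold standard.

    Records without a guideline equivalence (non-ok status) are removed
    before analysis, exactly as a prospective accuracy audit removes
    calculations the guideline cannot answer.  The match rate is
    100 x matched / analysed, half-up to one decimal; with nothing analysed
    it is reported as absent, never as zero.
    """
    summary = summarize_usage(log)
    for record in log:
        if record.formulary_version != oracle.formulary_version:
            raise AuditError(
                f"formulary version mismatch: log record {record.record_id} used "
                f"{record.formulary_version!r} but oracle covers "
                f"{oracle.formulary_version!r}"
            )

    excluded = analyzed = matched = 0
    for record in log:
        if record.status != Status.OK.value:
            excluded += 1
            continue
        analyzed += 1
        gold = oracle.gold_practical(record)
        mine = None if record.practical_dose is None else Decimal(record.practical_dose)
        if (gold is None) == (mine is None) and (gold is None or gold == mine):
            matched += 1

    summary.excluded_no_equivalence = excluded
    summary.analyzed = analyzed
    summary.matched = matched
    summary.match_rate = (
        _round_half_up_1dp(Decimal(100) * Decimal(matched) / Decimal(analyzed))
        if analyzed > 0
        else None
    )
    return summary


def usage_summary_csv(summary: UsageSummary) -> str:
    """CSV export: Opioid / As Index Opioid (n) / As Target Opioid (n)."""
    lines = ["Opioid,As Index Opioid (n),As Target Opioid (n)"]
    for drug in sorted(set(summary.index_counts) | set(summary.target_counts)):
        lines.append(
            f"{drug},{summary.index_counts.get(drug, 0)},{summary.target_counts.get(drug, 0)}"
        )
    lines.append("")
    lines.append(f"# total_conversions,{summary.total_conversions}")
    lines.append(f"# total_breakthrough,{summary.total_breakthrough}")
    lines.append(f"# quarantined,{summary.quarantined}")
    if summary.analyzed is not None:
        lines.append(f"# excluded_no_equivalence,{summary.excluded_no_equivalence}")
        lines.append(f"# analyzed,{summary.analyzed}")
        lines.append(f"# matched,{summary.matched}")
        rate = "" if summary.match_rate is None else summary.match_rate
        lines.append(f"# match_rate_percent,{rate}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# trend test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendTable:
    """2 x k table of ordered category counts (e.g. confidence ratings).

    ``scores`` are the integer scores attached to the ordered categories;
    ``pre`` and ``post`` are the per-category counts for the two groups.
    """

    scores: tuple[int, ...]
    pre: tuple[int, ...]
    post: tuple[int, ...]

    def __post_init__(self):
        k = len(self.scores)
        if k < 2:
            raise ValueError("trend is undefined for fewer than 2 categories")
        if len(self.pre) != k or len(self.post) != k:
            raise ValueError("scores, pre and post must have equal length")
        if any(c < 0 for c in self.pre + self.post):
            raise ValueError("counts must be non-negative")
        if sum(self.pre) + sum(self.post) == 0:
            raise ValueError("total count must be positive")


def cochran_armitage_trend(table: TrendTable, p_method: str = "normal") -> tuple[float, float]:
    """Cochran–Armitage linear trend statistic for a 2 x k ordered table.

    Returns ``(Z, p)``.  Sign convention: positive Z means the post row is
    shifted toward higher-score categories relative to the pre row.  The
    variance uses the exact permutation (hypergeometric) form with the N-1
    denominator, so Z is standardized against the conditional-on-margins
    null.

    ``p_method="normal"`` (default) gives the conventional two-sided p from
    the normal approximation with no continuity correction — the form whose
    Z/p pairs survey reports print.  ``p_method="exact"`` enumerates the
    conditional permutation distribution of the trend statistic and returns
    the two-sided mid-p, P(|T - E| > |t|) + 0.5 P(|T - E| = |t|): the exact
    discrete quantity the uncorrected normal approximation estimates.  On
    the table sizes of prescriber surveys the enumeration is instant.
    """
    s = table.scores
    n_i = [a + b for a, b in zip(table.pre, table.post)]
    N = sum(n_i)
    R2 = sum(table.post)
    if R2 == 0 or R2 == N or N < 2:
        raise ValueError("both rows need at least one observation")

    T = sum(si * bi for si, bi in zip(s, table.post))
    sum_sn = sum(si * ni for si, ni in zip(s, n_i))
    sum_s2n = sum(si * si * ni for si, ni in zip(s, n_i))
    mean = R2 * sum_sn / N
    var = (R2 * (N - R2) / (N * (N - 1))) * (sum_s2n - sum_sn * sum_sn / N)
    if var == 0:
        raise ValueError("trend statistic has zero variance (degenerate scores)")
    z = (T - mean) / sqrt(var)

    if p_method == "normal":
        p = float(2 * norm.sf(abs(z)))
    elif p_method == "exact":
        p = _exact_trend_midp(s, n_i, N, R2, T, sum_sn)
    else:
        raise ValueError(f"p_method must be 'normal' or 'exact', got {p_method!r}")
    return float(z), min(p, 1.0)


def _exact_trend_midp(
    scores: Sequence[int], n_i: Sequence[int], N: int, R2: int, t_obs: int, sum_sn: int
) -> float:
    """Exhaustive conditional null of the trend statistic, two-sided mid-p.

    Enumerates every allocation of the R2 post-row subjects across the
    column totals, weighting by the multivariate hypergeometric count
    prod C(n_i, x_i).  All comparisons are exact integers scaled by N
    (|N*T - R2*sum(s n)| vs the observed value).
    """
    d_obs = abs(N * t_obs - R2 * sum_sn)
    greater = equal = 0
    k = len(scores)

    def walk(i: int, remaining: int, weight: int, t: int) -> None:
        nonlocal greater, equal
        if i == k - 1:
            if remaining > n_i[i]:
                return
            w = weight * comb(n_i[i], remaining)
            d = abs(N * (t + scores[i] * remaining) - R2 * sum_sn)
            if d > d_obs:
                greater += w
            elif d == d_obs:
                equal += w
            return
        tail_capacity = sum(n_i[i + 1:])
        lo = max(0, remaining - tail_capacity)
        hi = min(n_i[i], remaining)
        for x in range(lo, hi + 1):
            walk(i + 1, remaining - x, weight * comb(n_i[i], x), t + scores[i] * x)

    walk(0, R2, 1, 0)
    total = comb(N, R2)
    return (greater + 0.5 * equal) / total
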