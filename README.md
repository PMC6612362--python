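# opiconvert

Equianalgesic opioid dose conversion for palliative-care decision support,
with an append-only prescribing audit log and its analytics.

Opioid switching ("rotation") requires translating a dose of one opioid by
one route into an approximately equianalgesic dose of another, using
guideline tables of relative potency. Manual conversion is a known source
of prescribing error — over- and under-dosing both reach patients — and
deployed calculator apps have themselves shipped rounding defects.
`opiconvert` is the core of such a calculator, built so every clinical
number is auditable data and every rounding decision errs in the safe
direction.

**This is a decision-support library: it double-checks a prescriber's
arithmetic against a formulary; it does not prescribe.** The shipped
fixture formulary (`F1`) contains deliberately round, non-clinical numbers
for testing; a real deployment supplies its own guideline formulary file.

## The model

Every conversion passes through the **oral morphine equivalent (OME)** hub.
For a preparation *i* (drug + route) with guideline factor *f_i* (mg OME
per unit dose), a dose *d* of the index preparation converts to the target
preparation *j* as

    OME = d · f_i          (mg/24 h)
    d_j = OME / f_j        (continuous routes, mg/24 h)

so any two conversion paths between the same endpoints agree (hub
transitivity) — a property a hand-edited pairwise ratio matrix cannot
guarantee. Transdermal targets are discrete: a patch table maps inclusive
OME ranges `[ome_low, ome_high]` to patch strengths (µg/h). When an OME
falls **exactly on the shared border of two bands, the lower strength is
chosen** — round-up at borders is a documented defect class in deployed
converters, and this package carries that defect behind an explicit
`TieBreak.UP` flag solely so tests can demonstrate that it breaks exactly
the border cases. Breakthrough (rescue) dosing is the regular 24-hour dose
divided by the formulary's divisor (default 6). Drugs without a guideline
equivalence return a `no_guideline_equivalence` status — never a fabricated
number — and methadone is refused outright (`unsupported_drug`) because its
pharmacodynamics defeat table-based equivalence.

The audit layer logs every calculation to an append-only JSON-lines file
with a closed schema (no free-text fields, so nothing patient-identifiable
can enter), and reproduces the standard audit summaries: per-opioid
index/target tallies, exclusion arithmetic, gold-standard match rate, and a
Cochran–Armitage test for trend over ordered survey categories (with both
the conventional normal-approximation p and an exact conditional mid-p).

## Worked example

```bash
$ opiconvert convert --formulary src/opiconvert/data/f1.yaml \
    --from morphine:oral --to oxycodone:oral --dose 60
practical dose: 30 mg/24h
exact dose: 30 mg/24h
24h oral morphine equivalent: 60 mg
formulary: F1
```

60 mg/24 h oral morphine is 60 mg OME (hub factor 1); oxycodone oral has
factor 2 in F1, so the equianalgesic dose is 30 mg/24 h. A patch target
lands on a band instead:

```bash
$ opiconvert convert --formulary src/opiconvert/data/f1.yaml \
    --from morphine:oral --to fentanyl:transdermal --dose 60
practical dose: 12 microgram/h
24h oral morphine equivalent: 60 mg
formulary: F1
```

60 mg OME is exactly the border between the 12 µg/h band (30–60) and the
25 µg/h band (60–90); the safety rule rounds down to 12 µg/h.

```bash
$ opiconvert breakthrough --formulary src/opiconvert/data/f1.yaml \
    --drug morphine --route oral --daily-dose 60
breakthrough dose: 10 mg
```

Exit codes are stable for batch callers: 0 ok, 2 usage error, 3 no
guideline equivalence, 4 unsupported drug (methadone), 5 validation
failure. `--json` emits machine-readable output (schema in
`src/opiconvert/data/`), `--log` appends to an audit log, and
`opiconvert audit --log FILE [--oracle FORMULARY]` prints the usage tally
and match statistics.

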