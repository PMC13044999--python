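# Methods

`pdms_etl` implements a governance-first ETL pipeline for intensive-care
patient-data-management-system (PDMS) data: read-only extraction from a
relational source, domain-specific harmonization, schema-contract validation,
salted irreversible pseudonymization, structured audit logging, and
analysis-ready export.  Because operational hospital databases cannot be
shared, the package ships a seeded synthetic source generator with retained
ground truth; every transformation is tested by recovering that truth.

## Pipeline model and assumptions

The pipeline treats the source as an append-only, transaction-oriented
relational database that is never mutated (enforced by opening SQLite in
`mode=ro`; any write raises).  Extractions are tied to case numbers.  For
each resource of a template the stages are:

    fetch (chunked by case-id batches) → transform → validate against the
    domain's schema contract → pseudonymize case identifiers → export →
    append one audit record

Stage order matters for governance: validation sees raw case identifiers
(so failure locators are actionable), pseudonymization happens before
anything is written, and the audit sink is verified writable before export,
so no artifact can exist without a provenance entry.

### Timestamps

The source stores UTC ISO-8601 strings at second resolution.  All outputs
render Europe/Berlin local time (CET/CEST) with an explicit offset.  The
conversion is one-way (UTC → local), so ambiguous local times during the
autumn DST transition cannot arise.  Cross-field timestamp comparisons parse
strings back to instants rather than comparing lexically, because mixed
+01:00/+02:00 offsets break lexical ordering.

### Units

A flat curated registry (`data/units.csv`) covers mass (µg/mg/g), volume
(mL/L), biological activity (U, with IU as a synonym — the source system's
usage does not distinguish them), and time (s/min/h).  Compound rate units
(`mg/h`) convert numerator and denominator independently.  Cross-dimension
conversion without a concentration is a hard error, never a guess.

## Therapy-episode reconstruction

Device support (ECMO, dialysis, microaxial pump, IABP) is documented as
interval records with two pathologies: missing end times, and reverification
entries that re-document one continuous intervention as multiple rows.
Reconstruction per (case, device) group:

1. **Merge** (gap-tolerant sweep in chronological order).  A record joins the
   growing episode iff it overlaps, abuts, or follows within `gap_tolerance`
   of the episode's maximum documented end — or the episode's
   latest-starting contributor is open (null end), in which case the next
   record is read as the reverification that supersedes it.  An episode whose
   latest-starting contributor is open remains unterminated.  The absorption
   rule is *resolved-once*: after a later record closes the open one,
   subsequent records again face the plain gap rule.  The unconditional
   alternative (an open record absorbing arbitrarily distant later records)
   would contradict episode disjointness and was rejected.
2. **Infer ends from bed occupancy.**  A merged episode with no end takes the
   end of the bed-occupancy interval containing its start: a therapy cannot
   outlive the stay.  Documented contributor ends are authoritative — the
   inferred end is never allowed to fall below the maximum documented end.
   If the bed is still occupied the episode is flagged `ongoing`; an episode
   starting outside every occupancy interval is retained but flagged orphan
   with a warning.

All intervals are half-open `[start, end)`, which makes "abutting ≠
overlapping" unambiguous.  `gap_tolerance` defaults to 60 minutes and is a
configuration surface, not a constant — the clinically right value depends
on local documentation habits and may differ per device type.

The sweep is verified against an independent naive oracle (clustering that
recomputes its decision from full cluster contents at every step) on random
instances, and by exact ground-truth recovery on synthetic cohorts.

## Medication standardization

Medication rows document a pump **rate** (mL/h), a **volume** over an
interval (mL), or a discrete **dose**, and never carry a concentration.  The
concentration is reconstructed from the internal drug catalog — ingredient
amount per diluent volume of the standard mixture — as
`c = amount / volume` (mg/mL or U/mL).  Standardization:

* rate format → infusion, `rate = value × c` (mg/h or U/h);
* volume format → infusion spread evenly over its documented interval,
  `rate = value × c / duration`;  the even-spread reading is an assumption:
  the source documents the total volume but not its temporal profile;
* dose format → bolus, amount unit-converted to mg or U.

A volume record without a positive-length interval is unresolvable; it is
routed to a failure list, never silently dropped.  Catalog resolution is a
transparent lookup by drug id with an ingredient-name fallback; anything
else is an explicit catalog error.  Windowed aggregation sums bolus amounts
with timestamps inside the half-open window plus rate × overlap for
infusions, keyed by (ingredient, unit) so mass and activity never mix.

## Schema contracts and validation

Each export domain has a JSON contract: typed fields, closed plausibility
intervals or enumerated sets (optionally conditional on another field, used
for per-variable bounds in the long observation table), and cross-field
predicates.  Validation reports the *first* violated rule per record; failed
records are excluded from export and fully listed in the report, and
`n_valid + n_failed = n_input` holds by construction.  Default bounds —
heart rate [0, 300] /min, MAP [0, 250] mmHg, SpO₂ [0, 100] %, temperature
[20, 45] °C, medication rate [0, 10000] mg/h, age [0, 120] years — are
deliberately permissive sanity bounds, editable per site; they reject the
impossible, not the unusual.

## Pseudonymization and audit

Identifiers are replaced by HMAC digests (salt as key, SHA-256 by default,
64 hex characters).  The keyed construction gives a cleaner irreversibility
argument than hash-of-concatenation for the same interface.  The salt
(≥ 16 bytes) comes from the environment or in-memory config, is never
persisted, and never appears in `repr`.  One salt per project: pseudonyms
are stable within a project (enabling cross-domain joins) and unlinkable
across projects.

Audit records are JSON lines — actor, purpose, resource, redacted
parameters, requested-case and exported-row counts, start/finish local
timestamps, runtime seconds, a hashed id sample, outcome — with size-based
rotation.  Sensitive parameter values (case-id lists) are hashed
elementwise, order preserved.  Authorization is a static actor → template
map checked before any source access; a denied run leaves exactly one
`error` audit entry and no artifact.

## Synthetic cohort generator

The generator emulates the documented source characteristics: denormalized
case/patient tables, UTC second-resolution timestamps, ~266.5 medication
events per case split uniformly across the three documentation formats,
concentrations present only in the catalog, four device types, one
case→multiple-patient identifier conflict per 1838 cases (injected as a
duplicate case row pointing at a phantom patient, so per-patient admission
windows stay non-overlapping by construction), and ~8% of cases still
admitted at extraction time (open admission window, open occupancy, possibly
truly ongoing therapy).  Operating-room start/end live as nullable columns
on the denormalized case row.  About 10% of patients are readmitted, always
after their previous discharge.

Missing-end placement is recoverability-aware: an end timestamp is dropped
only on non-terminal reverification fragments (a later entry supersedes
them) or on terminal records of therapies that ran to the end of bed
occupancy.  The rationale is clinical: a charted mid-stay stop implies the
stop was documented; termination markers go missing at discharge or
handover.  This makes "exact recovery whenever ends are recoverable in
principle" a well-defined, 100%-achievable target, which the tests assert.
Reverification fragments overlap or abut (never gap), and distinct true
episodes of one (case, device) are separated by ≥ 4 h, safely above the
60-minute merge tolerance.  The distributions of reverification counts
(geometric, capped at 3) and fragment overlaps (uniform ≤ 30 min) are stated
assumptions — real fragmentation statistics are not documented anywhere.

What the generator does **not** emulate: realistic physiological waveforms
or autocorrelated vitals (values are uniform draws inside clinical ranges),
vendor schema layouts, free-text notes, cross-case transfers, or
out-of-bounds artifact values.  Consequently, the 0% validation-failure
result on synthetic cohorts demonstrates contract conformance of the
pipeline's own output model — it does not predict the failure rate on any
operational system, and plausibility bounds will flag real artifacts
(e.g. sensor spikes) that this generator never produces.

Determinism: one `random.Random(seed)` drives everything; identical config
and seed reproduce the SQLite file and ground-truth JSON byte for byte.
Medication event counts per case use a normal approximation to Poisson
(mean ≈ 266.5), which is accurate at that mean.

## Problem sizes and numerical choices

Tests run on generated cohorts of 15–100 cases (full medication intensity
where medication processing is under test, reduced intensity where only
demographics or therapy logic is exercised); cardinality and chunk-size
invariance checks use cohorts up to 1000 cases at full intensity.  Episode
logic is additionally cross-checked against the naive oracle on 1000 random
instances of ≤ 12 records.  Rate-recovery assertions use 1e-9 relative
tolerance (pure float round-trips); unit-conversion group properties use
1e-9 relative, inversion 1e-12 absolute.  Identifier chunking defaults to
500 ids per batch, safely below common database parameter limits; fetch
results are multiset-equal across chunk sizes, and exports are byte-identical
because rows are sorted by (case pseudonym, domain timestamp, remaining
columns) before writing.

## Known limitations

* Only occupancy-based end inference is implemented; signals from related
  device tables could refine it and the hook is left extensible.
* Boluses documented inside a running infusion are kept as separate events,
  not merged.
* Weight-indexed rates (µg/kg/min) are out of scope — weight linkage is not
  modeled.
* The access policy is an enforcement hook, not identity management.
* Sample-based auditing against a clinical front end is inherently manual;
  its programmatic analogue here is recovery testing against ground truth.
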