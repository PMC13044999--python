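# pdms_etl

Governance-first ETL for intensive-care PDMS data.

Patient Data Management Systems (PDMS) at ICU and perioperative bedsides
produce high-frequency, multimodal clinical data in transaction-oriented,
denormalized relational schemas that are excellent for documentation and
hopeless for research: therapy intervals lack end times, reverification
duplicates records of one continuous intervention, medications are charted
as volume / dose / rate without concentrations, and direct identifiers are
everywhere.  `pdms_etl` is a tested pipeline that turns such a source into
analysis-ready, pseudonymized tables while keeping every access auditable:

* **read-only source adapter** with bounded identifier batching (chunked
  `IN (…)` queries, multiset-invariant across chunk sizes);
* **harmonization** — UTC → CET/CEST timestamp normalization and a curated
  unit registry (µg/mg/g, mL/L, U, s/min/h, compound rates);
* **therapy-episode reconstruction** — gap-tolerant merging of fragmented
  interval records; missing end times inferred from bed occupancy
  (an episode cannot outlive the stay), with `ongoing` / `end_inferred`
  flags and full source-record provenance;
* **medication standardization** — concentration reconstructed from the drug
  catalog (`c = ingredient amount / diluent volume`), then every record
  harmonized to an infusion rate in mg/h or U/h (`rate = mL/h × c`, or
  volume spread evenly over its interval) or a bolus in mg/U, plus windowed
  per-ingredient totals;
* **schema contracts** — per-domain typed fields, clinical plausibility
  bounds and cross-field rules, with first-violation failure accounting
  (`n_valid + n_failed = n_input`, failed rows reported, never silently
  dropped);
* **governance** — salted irreversible pseudonyms (HMAC-SHA256, salt from
  the environment, never persisted), redacted parameters, and a JSON-lines
  audit log recording actor, purpose, row counts and runtime for every
  export;
* **synthetic PDMS fixture** — a seeded SQLite cohort generator that injects
  the documentation pathologies above and retains the hidden ground truth
  (true episodes, true rates, identity map), so the whole pipeline is
  testable without access to any hospital system.

## Worked example

Generate a 10-case synthetic source, then extract demographics for two
cases as the pseudonymized, audited template run:

```bash
$ pdms-etl synth --n-cases 10 --seed 3 --out cli.db --mean-drug-events 20
fixture written to cli.db: 10 cases, 8 therapy episodes, 197 medication events, 0 identifier conflicts

$ printf 'C000001\nC000002\n' > ids.txt
$ export PDMS_ETL_SALT="cli-demo-salt-0123456789"
$ pdms-etl run --db cli.db --template demographics --case-ids-file ids.txt \
      --actor alice --purpose "worked example" --out out/
demographics: 2 rows -> out/demographics.csv
outcome: success (1 audit entries, salt from $PDMS_ETL_SALT)

$ head -3 out/demographics.csv
case_pseudonym,admission_ts,discharge_ts,age_at_admission,sex,ward
685fef1ec10e7eb2b8e28d232d582a1a3a3f5c95e60bb37254d9148da576a69e,2024-04-06T21:43:31+02:00,2024-04-10T23:58:13+02:00,46,m,ICU1
b5100a4e0d6b5301429ea863fd2c2e9194d1ee0467bd6495715e5738bfb56111,2024-03-03T07:38:08+01:00,2024-03-12T17:28:21+01:00,32,f,PACU
```

Each exported row carries a 64-hex-character salted pseudonym instead of the
case number, local-time admission/discharge timestamps, and the age derived
at admission — the date of birth never leaves the adapter layer.  The run
appended one audit entry (`out/audit.jsonl`) with the actor, purpose,
hashed case-id sample, exported row count and runtime; `pdms-etl audit-show
--log out/audit.jsonl` pretty-prints it.

The `periop_study` template runs four resources in one governed pass —
demographics, standardized drugs, operating-room timestamps, and
per-ingredient drug totals within each case's OR window — producing four
artifacts and four audit entries.

Library use mirrors the CLI:

```python
from pdms_etl import (SyntheticConfig, generate_fixture, SaltConfig,
                      PipelineConfig, run_template)

handle, truth = generate_fixture(SyntheticConfig(n_cases=100, seed=42), "fix.db")
cfg = PipelineConfig(source=handle, salt=SaltConfig(salt=b"0123456789abcdef"),
                     out_dir="out", audit_log="out/audit.jsonl")
artifacts, audit = run_template("periop_study",
                                [f"C{i:06d}" for i in range(1, 101)],
                                actor="alice", purpose="periop cohort", cfg=cfg)
```

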