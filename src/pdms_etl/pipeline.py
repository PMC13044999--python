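"""Resource registry, extraction templates, orchestration, and export.

A *resource* couples an extractor (source query + domain transformation) with
the schema contract its output must satisfy and the file stem it exports to.
A *template* is an ordered list of resources run as one governed extraction:
for each resource the pipeline fetches (chunked), transforms, validates,
pseudonymizes, exports, and appends exactly one audit entry.  Failure of one
resource marks the run ``partial`` but does not stop independent resources.

Built-in templates:

* ``demographics`` — the simple one-row-per-case extraction;
* ``drugs`` — standardized medication events;
* ``periop_study`` — demographics + drugs + operating-room timestamps +
  per-ingredient drug totals aggregated over each case's OR window.

Exports are CSV (RFC-4180-style, UTF-8, ISO-8601 timestamps) or Parquet,
with snake_case column names and rows sorted by (case pseudonym, domain
timestamp) for reproducible diffs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

from . import extract_core, medications
from .contracts import load_contract, validate_batch
from .errors import (
    AuthorizationError,
    ConfigurationError,
    ExportError,
    RegistrationError,
    ResourceLookupError,
)
from .governance import (
    AuditLog,
    AuditRecord,
    SaltConfig,
    pseudonymize,
    redact_parameters,
    sample_ids,
    write_audit,
)
from .harmonize import format_local, parse_utc
from .medications import RawMedicationRecord, aggregate_window, standardize_batch
from .source_adapter import (
    DEFAULT_CHUNK_SIZE,
    SourceHandle,
    connect_readonly,
    fetch_by_case_ids,
)

__all__ = [
    "RunContext",
    "ResourceDefinition",
    "ResourceRegistry",
    "ExtractionTemplate",
    "AccessPolicy",
    "PipelineConfig",
    "ExportArtifact",
    "build_default_registry",
    "builtin_templates",
    "register_resource",
    "run_template",
    "run_outcome",
    "export_table",
]


@dataclass
class RunContext:
    """Per-run state shared between resources of one template execution."""

    handle: SourceHandle
    chunk_size: int = DEFAULT_CHUNK_SIZE
    cache: dict = field(default_factory=dict)


Extractor = Callable[[SourceHandle, Sequence[str], RunContext], "list[dict]"]


@dataclass(frozen=True)
class ResourceDefinition:
    name: str
    extractor: Extractor
    contract_name: str
    export_name: str
    sort_timestamp: Optional[str] = None  # domain timestamp for row ordering


class ResourceRegistry:
    """Name → resource definition; duplicate registration is an error."""

    def __init__(self) -> None:
        self._resources: dict[str, ResourceDefinition] = {}

    def register(self, defn: ResourceDefinition) -> "ResourceRegistry":
        if defn.name in self._resources:
            raise RegistrationError(f"resource already registered: {defn.name!r}")
        self._resources[defn.name] = defn
        return self

    def resolve(self, name: str) -> ResourceDefinition:
        try:
            return self._resources[name]
        except KeyError:
            raise ResourceLookupError(f"unknown resource: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._resources

    def names(self) -> "list[str]":
        return list(self._resources)


def register_resource(defn: ResourceDefinition, registry: ResourceRegistry) -> ResourceRegistry:
    """Functional alias for :meth:`ResourceRegistry.register`."""
    return registry.register(defn)


@dataclass(frozen=True)
class ExtractionTemplate:
    """Ordered multi-resource extraction for one research domain."""

    name: str
    resources: "tuple[str, ...]"


@dataclass(frozen=True)
class AccessPolicy:
    """Static actor → permitted-template map (CLI-level enforcement hook).

    ``None`` rules mean an open policy (every actor may run every template);
    institutional user management stays out of scope.
    """

    rules: "Optional[Mapping[str, frozenset]]" = None

    def allows(self, actor: str, template: str) -> bool:
        if self.rules is None:
            return True
        return template in self.rules.get(actor, frozenset())


@dataclass
class PipelineConfig:
    """Layered run configuration (defaults < project file < CLI flags)."""

    source: "str | Path | SourceHandle"
    salt: Optional[SaltConfig]
    out_dir: "str | Path"
    audit_log: "str | Path"
    export_format: str = "csv"          # 'csv' | 'parquet'
    chunk_size: int = DEFAULT_CHUNK_SIZE
    access_policy: AccessPolicy = field(default_factory=AccessPolicy)


@dataclass(frozen=True)
class ExportArtifact:
    path: Path
    format: str
    n_rows: int
    columns: "tuple[str, ...]"
    resource: str


# ---------------------------------------------------------------------------
# Built-in extractors
# ---------------------------------------------------------------------------

def _demographics_extractor(
    handle: SourceHandle, case_ids: Sequence[str], ctx: RunContext
) -> "list[dict]":
    return extract_core.extract_demographics(handle, case_ids, ctx.chunk_size)


def _load_db_catalog(handle: SourceHandle) -> medications.DrugCatalog:
    rows = handle.execute("SELECT * FROM drug_catalog")
    return medications.DrugCatalog(
        medications.MixtureDefinition(
            drug_id=r["drug_id"],
            ingredient=r["ingredient"],
            ingredient_amount=r["amount"],
            amount_unit=r["amount_unit"],
            diluent_volume=r["volume_ml"],
            standard_unit=r["standard_unit"],
        )
        for r in rows
    )


def _drugs_extractor(
    handle: SourceHandle, case_ids: Sequence[str], ctx: RunContext
) -> "list[dict]":
    raw_rows = fetch_by_case_ids(handle, "medication_records", case_ids, ctx.chunk_size)
    records = [
        RawMedicationRecord(
            record_id=r["record_id"],
            case_id=r["case_id"],
            drug_id=r["drug_id"],
            doc_format=r["doc_format"],
            value=r["value"],
            unit=r["unit"],
            start_ts=r["start_ts"],
            end_ts=r["end_ts"],
        )
        for r in raw_rows
    ]
    catalog = _load_db_catalog(handle)
    events, failures = standardize_batch(records, catalog)
    ctx.cache["drug_events"] = events
    ctx.cache["drug_failures"] = failures
    return [
        {
            "case_id": ev.case_id,
            "ingredient": ev.ingredient,
            "kind": ev.kind,
            "amount": ev.amount,
            "rate": ev.rate,
            "unit": ev.unit,
            "start_ts": format_local(ev.start_ts),
            "end_ts": format_local(ev.end_ts),
        }
        for ev in events
    ]


def _or_times_extractor(
    handle: SourceHandle, case_ids: Sequence[str], ctx: RunContext
) -> "list[dict]":
    case_rows = fetch_by_case_ids(handle, "cases", case_ids, ctx.chunk_size)
    chosen: dict[str, dict] = {}
    for row in sorted(case_rows, key=lambda r: (r["case_id"], r["patient_id"])):
        chosen.setdefault(row["case_id"], row)
    windows = {
        c: (parse_utc(r["or_start_ts"]), parse_utc(r["or_end_ts"]))
        for c, r in chosen.items()
        if r["or_start_ts"] is not None and r["or_end_ts"] is not None
    }
    ctx.cache["or_windows"] = windows
    return [
        {
            "case_id": case_id,
            "or_start_ts": format_local(w[0]),
            "or_end_ts": format_local(w[1]),
        }
        for case_id, w in sorted(windows.items())
    ]


def _drug_windows_extractor(
    handle: SourceHandle, case_ids: Sequence[str], ctx: RunContext
) -> "list[dict]":
    """Per-ingredient totals within each case's operating-room interval."""
    if "drug_events" not in ctx.cache:
        _drugs_extractor(handle, case_ids, ctx)
    if "or_windows" not in ctx.cache:
        _or_times_extractor(handle, case_ids, ctx)
    events_by_case: dict[str, list] = {}
    for ev in ctx.cache["drug_events"]:
        events_by_case.setdefault(ev.case_id, []).append(ev)
    rows: list[dict] = []
    for case_id, window in sorted(ctx.cache["or_windows"].items()):
        totals = aggregate_window(events_by_case.get(case_id, []), window)
        for (ingredient, unit), total in sorted(totals.items()):
            rows.append(
                {
                    "case_id": case_id,
                    "ingredient": ingredient,
                    "unit": unit,
                    "total": total,
                    "window_start_ts": format_local(window[0]),
                    "window_end_ts": format_local(window[1]),
                }
            )
    return rows


def build_default_registry() -> ResourceRegistry:
    registry = ResourceRegistry()
    registry.register(
        ResourceDefinition("demographics", _demographics_extractor, "demographics",
                           "demographics", "admission_ts")
    )
    registry.register(
        ResourceDefinition("drugs", _drugs_extractor, "drugs", "drugs", "start_ts")
    )
    registry.register(
        ResourceDefinition("or_times", _or_times_extractor, "or_times", "or_times",
                           "or_start_ts")
    )
    registry.register(
        ResourceDefinition("drug_windows", _drug_windows_extractor, "drug_windows",
                           "drug_windows", "window_start_ts")
    )
    return registry


def builtin_templates() -> "dict[str, ExtractionTemplate]":
    return {
        "demographics": ExtractionTemplate("demographics", ("demographics",)),
        "drugs": ExtractionTemplate("drugs", ("drugs",)),
        "periop_study": ExtractionTemplate(
            "periop_study", ("demographics", "drugs", "or_times", "drug_windows")
        ),
    }


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_table(
    rows: Sequence[Mapping],
    export_format: str,
    path: "str | Path",
    columns: "Optional[Sequence[str]]" = None,
    resource: str = "",
) -> ExportArtifact:
    """Write validated rows as CSV or Parquet; re-reading reproduces values.

    An empty batch still produces a header-only artifact so downstream
    tooling sees a stable schema.
    """
    path = Path(path)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    frame = pd.DataFrame(list(rows), columns=list(columns))
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        if export_format == "csv":
            frame.to_csv(path, index=False)
        elif export_format == "parquet":
            frame.to_parquet(path, index=False)
        else:
            raise ConfigurationError(f"unknown export format: {export_format!r}")
    except OSError as exc:
        raise ExportError(f"cannot write export artifact {path}: {exc}") from exc
    return ExportArtifact(
        path=path,
        format=export_format,
        n_rows=len(frame),
        columns=tuple(frame.columns),
        resource=resource,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _pseudonymize_rows(
    rows: Sequence[Mapping], salt: SaltConfig
) -> "list[dict]":
    out = []
    for row in rows:
        new = dict(row)
        case_id = new.pop("case_id")
        out.append({"case_pseudonym": pseudonymize(str(case_id), salt).value, **new})
    return out


def _now_local() -> str:
    return format_local(datetime.now(timezone.utc).replace(microsecond=0))


def run_template(
    template: "ExtractionTemplate | str",
    case_ids: Sequence[str],
    actor: str,
    purpose: str,
    cfg: PipelineConfig,
    registry: Optional[ResourceRegistry] = None,
) -> "tuple[list[ExportArtifact], list[AuditRecord]]":
    """Run one governed multi-resource extraction.

    Per resource: fetch (chunked) → transform → validate → pseudonymize →
    export, plus exactly one audit entry whose ``n_rows_exported`` equals the
    artifact's row count.  Missing salt and failed authorization abort before
    any source access (the latter still leaves an ``error`` audit entry).
    """
    registry = registry or build_default_registry()
    if isinstance(template, str):
        try:
            template = builtin_templates()[template]
        except KeyError:
            raise ResourceLookupError(f"unknown template: {template!r}") from None
    if cfg.salt is None:
        raise ConfigurationError("no salt configured; refusing to run unpseudonymized")
    log = AuditLog(cfg.audit_log)

    if not cfg.access_policy.allows(actor, template.name):
        write_audit(
            AuditRecord(
                actor=actor,
                purpose=purpose,
                resource=template.name,
                parameters={"template": template.name},
                n_cases_requested=len(set(case_ids)),
                started_at=_now_local(),
                finished_at=_now_local(),
                outcome="error",
            ),
            log,
        )
        raise AuthorizationError(
            f"actor {actor!r} is not authorized for template {template.name!r}"
        )

    own_handle = not isinstance(cfg.source, SourceHandle)
    handle = connect_readonly(cfg.source) if own_handle else cfg.source
    ctx = RunContext(handle=handle, chunk_size=cfg.chunk_size)
    out_dir = Path(cfg.out_dir)
    ext = "csv" if cfg.export_format == "csv" else "parquet"

    artifacts: list[ExportArtifact] = []
    audit_records: list[AuditRecord] = []
    try:
        for resource_name in template.resources:
            defn = registry.resolve(resource_name)
            started = _now_local()
            t0 = time.perf_counter()
            try:
                raw_rows = defn.extractor(handle, case_ids, ctx)
                contract = load_contract(defn.contract_name)
                valid_rows, report = validate_batch(raw_rows, contract)
                pseudo_rows = _pseudonymize_rows(valid_rows, cfg.salt)
                sort_cols = ["case_pseudonym"] + (
                    [defn.sort_timestamp] if defn.sort_timestamp else []
                )
                pseudo_rows.sort(
                    key=lambda r: tuple(str(r.get(c)) for c in sort_cols)
                    + tuple(str(v) for v in r.values())
                )
                columns = ["case_pseudonym"] + [
                    c for c in contract.column_names if c != "case_id"
                ]
                artifact = export_table(
                    pseudo_rows,
                    cfg.export_format,
                    out_dir / f"{defn.export_name}.{ext}",
                    columns=columns,
                    resource=resource_name,
                )
                artifacts.append(artifact)
                record = AuditRecord(
                    actor=actor,
                    purpose=purpose,
                    resource=resource_name,
                    parameters=redact_parameters(
                        {
                            "template": template.name,
                            "case_ids": list(dict.fromkeys(case_ids)),
                            "chunk_size": cfg.chunk_size,
                            "export_format": cfg.export_format,
                            "n_validation_input": report.n_input,
                            "n_validation_failed": report.n_failed,
                            "validation_failure_rate": report.failure_rate,
                        },
                        cfg.salt,
                    ),
                    n_cases_requested=len(set(case_ids)),
                    n_rows_exported=artifact.n_rows,
                    started_at=started,
                    finished_at=_now_local(),
                    runtime_s=round(time.perf_counter() - t0, 6),
                    id_sample=sample_ids(list(case_ids), cfg.salt),
                    outcome="success",
                )
            except Exception as exc:  # resource-level isolation
                record = AuditRecord(
                    actor=actor,
                    purpose=purpose,
                    resource=resource_name,
                    parameters={"template": template.name, "error": str(exc)},
                    n_cases_requested=len(set(case_ids)),
                    n_rows_exported=0,
                    started_at=started,
                    finished_at=_now_local(),
                    runtime_s=round(time.perf_counter() - t0, 6),
                    id_sample=sample_ids(list(case_ids), cfg.salt),
                    outcome="error",
                )
            write_audit(record, log)
            audit_records.append(record)
    finally:
        if own_handle:
            handle.close()
    return artifacts, audit_records


def run_outcome(audit_records: Sequence[AuditRecord]) -> str:
    """Overall outcome of a run: success, partial (some resources failed), or error."""
    outcomes = {r.outcome for r in audit_records}
    if outcomes <= {"success"}:
        return "success"
    if "success" in outcomes:
        return "partial"
    return "error"
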