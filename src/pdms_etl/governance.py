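"""Pseudonymization and audit logging.

Direct identifiers (case numbers, patient numbers) are replaced at extraction
time by salted, irreversible pseudonyms computed with a keyed hash
(HMAC, salt as key).  The same identifier maps to the same pseudonym within a
project salt, so cross-domain joins remain possible in pseudonymized space,
while different project salts produce unlinkable pseudonym spaces.

Every pipeline execution appends one structured JSON record per exported
resource to an append-only JSON-lines audit log, documenting actor, purpose,
parameters (with sensitive values redacted), row counts, and runtime.  The
salt itself is supplied via environment variable or in-memory configuration
and is never written to any log or export.
"""

from __future__ import annotations

import hashlib
import hmac
import json
import os
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Literal, Mapping, Sequence

from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError, ExportError

SALT_ENV_VAR = "PDMS_ETL_SALT"

#: parameter keys whose values are replaced by pseudonyms in audit records
DEFAULT_SENSITIVE_KEYS = frozenset(
    {"case_id", "case_ids", "patient_id", "patient_ids", "id_sample"}
)

__all__ = [
    "SALT_ENV_VAR",
    "SaltConfig",
    "Pseudonym",
    "AuditRecord",
    "AuditLog",
    "pseudonymize",
    "redact_parameters",
    "write_audit",
    "read_audit_log",
]


class SaltConfig(BaseModel):
    """Keyed-hash configuration for irreversible pseudonymization."""

    salt: bytes = Field(min_length=16)
    digest_algorithm: str = "sha256"
    output_length: int = Field(default=64, ge=8)

    @field_validator("salt", mode="before")
    @classmethod
    def _coerce_salt(cls, v: Any) -> bytes:
        if isinstance(v, str):
            return v.encode("utf-8")
        return v

    @field_validator("digest_algorithm")
    @classmethod
    def _known_algorithm(cls, v: str) -> str:
        if v not in hashlib.algorithms_available:
            raise ValueError(f"unknown digest algorithm: {v!r}")
        return v

    @classmethod
    def from_env(cls, var: str = SALT_ENV_VAR) -> "SaltConfig":
        """Build a config from an environment secret; absence is a hard error."""
        raw = os.environ.get(var)
        if not raw:
            raise ConfigurationError(
                f"no salt configured: set the {var} environment variable"
            )
        return cls(salt=raw)

    def __repr__(self) -> str:  # never leak the salt via repr
        return (
            f"SaltConfig(salt=<{len(self.salt)} bytes>, "
            f"digest_algorithm={self.digest_algorithm!r}, "
            f"output_length={self.output_length})"
        )


@dataclass(frozen=True)
class Pseudonym:
    """A lowercase hex digest standing in for a direct identifier."""

    value: str

    def __str__(self) -> str:
        return self.value


def pseudonymize(identifier: str, cfg: SaltConfig) -> Pseudonym:
    """Keyed, salted, irreversible digest of an identifier.

    Deterministic for a given (identifier, salt); different salts yield
    unrelated digests, so pseudonyms are not linkable across projects.
    """
    if cfg is None:
        raise ConfigurationError("pseudonymization requires a SaltConfig")
    if not isinstance(identifier, str) or identifier == "":
        raise ValueError("identifier must be a non-empty string")
    digest = hmac.new(cfg.salt, identifier.encode("utf-8"), cfg.digest_algorithm)
    return Pseudonym(digest.hexdigest()[: cfg.output_length])


def redact_parameters(
    params: Mapping[str, Any],
    cfg: SaltConfig,
    sensitive_keys: "frozenset[str] | set[str]" = DEFAULT_SENSITIVE_KEYS,
) -> "dict[str, Any]":
    """Replace sensitive parameter values by pseudonyms, pass the rest through.

    The key set is unchanged; list values under a sensitive key are hashed
    elementwise with order preserved.
    """
    redacted: dict[str, Any] = {}
    for key, value in params.items():
        if key in sensitive_keys:
            if isinstance(value, (list, tuple)):
                redacted[key] = [pseudonymize(str(v), cfg).value for v in value]
            elif value is None:
                redacted[key] = None
            else:
                redacted[key] = pseudonymize(str(value), cfg).value
        else:
            redacted[key] = value
    return redacted


class AuditRecord(BaseModel):
    """One provenance entry per extraction step (JSON-lines serializable)."""

    event_id: str = Field(default_factory=lambda: uuid.uuid4().hex)
    actor: str
    purpose: str
    resource: str
    parameters: dict = Field(default_factory=dict)
    n_cases_requested: int = 0
    n_rows_exported: int = 0
    started_at: "str | None" = None       # local ISO-8601
    finished_at: "str | None" = None      # local ISO-8601
    runtime_s: float = 0.0
    id_sample: list = Field(default_factory=list)   # hashed case identifiers
    outcome: Literal["success", "partial", "error"] = "success"


class AuditLog:
    """Append-only JSON-lines sink with size-based rotation.

    Rotation (``<name>.1``, ``<name>.2`` …) is a site adaptation point; the
    default 10 MiB keeps individual files greppable.
    """

    def __init__(self, path: "str | Path", max_bytes: int = 10 * 1024 * 1024):
        self.path = Path(path)
        self.max_bytes = max_bytes

    def append(self, record: AuditRecord) -> str:
        line = json.dumps(record.model_dump(), ensure_ascii=False, sort_keys=True)
        try:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            if self.path.exists() and self.path.stat().st_size + len(line) > self.max_bytes:
                self._rotate()
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")
        except OSError as exc:
            raise ExportError(f"audit sink not writable: {self.path}") from exc
        return line

    def _rotate(self) -> None:
        n = 1
        while self.path.with_name(f"{self.path.name}.{n}").exists():
            n += 1
        self.path.rename(self.path.with_name(f"{self.path.name}.{n}"))

    def __iter__(self) -> Iterator[AuditRecord]:
        return read_audit_log(self.path)


def write_audit(record: AuditRecord, sink: "AuditLog | str | Path") -> str:
    """Append one audit record to the log; returns the serialized line.

    Raises before any data export proceeds if the sink is unwritable, so no
    export can exist without its provenance entry.
    """
    log = sink if isinstance(sink, AuditLog) else AuditLog(sink)
    return log.append(record)


def read_audit_log(path: "str | Path") -> Iterator[AuditRecord]:
    """Parse a JSON-lines audit log back into records (round-trip safe)."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield AuditRecord.model_validate(json.loads(line))


def sample_ids(case_ids: Sequence[str], cfg: SaltConfig, k: int = 5) -> "list[str]":
    """Hashed sample of the first ``k`` requested identifiers for the audit trail."""
    return [pseudonymize(str(c), cfg).value for c in list(case_ids)[:k]]
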