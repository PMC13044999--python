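"""Per-domain output schema contracts with plausibility bounds.

Each exported domain (demographics, drugs, observations, …) carries an
explicit contract: typed fields, closed numeric plausibility intervals or
enumerated value sets, and cross-field consistency predicates (e.g.
``start ≤ end``).  Validation reports the *first* violated rule per record —
failure accounting stays stable and cheap — and failed records are excluded
from export but fully listed in the report, so nothing is dropped silently.

Plausibility bounds are clinical configuration, not code: the packaged
contracts under ``data/contracts/`` are human-editable JSON and can be
overridden per site.  Default bounds: heart rate [0, 300] /min, MAP
[0, 250] mmHg, SpO2 [0, 100] %, temperature [20, 45] °C, medication rate
[0, 10000] mg/h, age [0, 120] years.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

from .errors import ConfigurationError

__all__ = [
    "FieldSpec",
    "PlausibilityRule",
    "CrossFieldRule",
    "SchemaContract",
    "ValidationFailure",
    "ValidationReport",
    "validate_record",
    "validate_batch",
    "load_contract",
    "packaged_contract_names",
]

_TYPES = {"str", "int", "float", "bool", "datetime"}


def _coerce(value: Any, semantic_type: str) -> Any:
    if semantic_type == "str":
        return value if isinstance(value, str) else str(value)
    if semantic_type == "int":
        if isinstance(value, bool):
            raise ValueError("bool is not an int")
        out = int(value)
        if isinstance(value, float) and value != out:
            raise ValueError(f"not an integer: {value}")
        return out
    if semantic_type == "float":
        out = float(value)
        if math.isnan(out):
            raise ValueError("NaN")
        return out
    if semantic_type == "bool":
        if isinstance(value, bool):
            return value
        if value in (0, 1):
            return bool(value)
        if isinstance(value, str) and value.lower() in ("true", "false"):
            return value.lower() == "true"
        raise ValueError(f"not a bool: {value!r}")
    if semantic_type == "datetime":
        # kept as ISO-8601 text in exports; must parse
        if isinstance(value, datetime):
            return value.isoformat()
        datetime.fromisoformat(str(value).replace("Z", "+00:00"))
        return str(value)
    raise ConfigurationError(f"unknown semantic type: {semantic_type!r}")


@dataclass(frozen=True)
class FieldSpec:
    name: str
    semantic_type: str
    required: bool = True


@dataclass(frozen=True)
class PlausibilityRule:
    """Closed interval or enumerated set on one field, optionally conditional.

    ``when`` restricts the rule to records where another field equals a given
    value (used for per-variable bounds on long-format observation tables).
    """

    field: str
    min: Optional[float] = None
    max: Optional[float] = None
    allowed: Optional[frozenset] = None
    when: Optional[tuple] = None  # (field, value)

    def applies(self, record: Mapping[str, Any]) -> bool:
        if self.when is None:
            return True
        key, expected = self.when
        return record.get(key) == expected

    def check(self, value: Any) -> bool:
        if value is None:
            return True  # absence is the required-flag's concern
        if self.allowed is not None:
            return value in self.allowed
        v = float(value)
        if self.min is not None and v < self.min:
            return False
        if self.max is not None and v > self.max:
            return False
        return True

    def label(self) -> str:
        return f"plausibility: {self.field}"


@dataclass(frozen=True)
class CrossFieldRule:
    """Two-field predicate; records with a null operand are not checked."""

    name: str
    op: str            # 'le' | 'lt' | 'required_if'
    left: str
    right: Optional[str] = None
    when: Optional[tuple] = None

    def check(self, record: Mapping[str, Any]) -> bool:
        if self.op == "required_if":
            key, expected = self.when  # type: ignore[misc]
            if record.get(key) == expected:
                return record.get(self.left) is not None
            return True
        a, b = record.get(self.left), record.get(self.right)
        if a is None or b is None:
            return True
        if isinstance(a, str) and isinstance(b, str):
            # timestamps compare as instants, not lexically
            try:
                a = datetime.fromisoformat(a.replace("Z", "+00:00"))
                b = datetime.fromisoformat(b.replace("Z", "+00:00"))
            except ValueError:
                pass
        return a <= b if self.op == "le" else a < b

    def label(self) -> str:
        return f"cross_field: {self.name}"


@dataclass
class SchemaContract:
    """Output contract for one clinical domain."""

    name: str
    fields: Sequence[FieldSpec]
    plausibility_rules: Sequence[PlausibilityRule] = field(default_factory=list)
    cross_field_rules: Sequence[CrossFieldRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate field names in contract {self.name!r}")
        declared = set(names)
        for f in self.fields:
            if f.semantic_type not in _TYPES:
                raise ConfigurationError(
                    f"contract {self.name!r}: unknown type {f.semantic_type!r}"
                )
        for rule in self.plausibility_rules:
            if rule.field not in declared:
                raise ConfigurationError(
                    f"contract {self.name!r}: plausibility rule targets "
                    f"undeclared field {rule.field!r}"
                )
            if rule.when is not None and rule.when[0] not in declared:
                raise ConfigurationError(
                    f"contract {self.name!r}: rule condition on undeclared field"
                )
        for rule in self.cross_field_rules:
            operands = {rule.left} | ({rule.right} if rule.right else set())
            if not operands <= declared:
                raise ConfigurationError(
                    f"contract {self.name!r}: cross-field rule {rule.name!r} "
                    f"targets undeclared fields"
                )

    @property
    def column_names(self) -> "list[str]":
        return [f.name for f in self.fields]

    def with_bounds(self, field_name: str, lo: float, hi: float) -> "SchemaContract":
        """Copy of this contract with one field's interval replaced."""
        rules = [r for r in self.plausibility_rules if r.field != field_name]
        rules.append(PlausibilityRule(field=field_name, min=lo, max=hi))
        return SchemaContract(self.name, list(self.fields), rules,
                              list(self.cross_field_rules))

    @classmethod
    def from_dict(cls, spec: Mapping[str, Any]) -> "SchemaContract":
        try:
            fields = [
                FieldSpec(f["name"], f["type"], bool(f.get("required", True)))
                for f in spec["fields"]
            ]
            plaus = [
                PlausibilityRule(
                    field=r["field"],
                    min=r.get("min"),
                    max=r.get("max"),
                    allowed=frozenset(r["allowed"]) if "allowed" in r else None,
                    when=tuple(next(iter(r["when"].items()))) if "when" in r else None,
                )
                for r in spec.get("plausibility", [])
            ]
            cross = [
                CrossFieldRule(
                    name=r["name"],
                    op=r["op"],
                    left=r["left"],
                    right=r.get("right"),
                    when=tuple(next(iter(r["when"].items()))) if "when" in r else None,
                )
                for r in spec.get("cross_field", [])
            ]
            return cls(spec["name"], fields, plaus, cross)
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed contract spec: {exc}") from exc


@dataclass(frozen=True)
class ValidationFailure:
    locator: Any          # record index or identifier
    rule: str             # label of the first violated rule


@dataclass(frozen=True)
class ValidationReport:
    n_input: int
    n_valid: int
    n_failed: int
    failure_rate: float
    failures: "tuple[ValidationFailure, ...]" = ()

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_valid": self.n_valid,
            "n_failed": self.n_failed,
            "failure_rate": self.failure_rate,
            "failures": [{"locator": f.locator, "rule": f.rule} for f in self.failures],
        }


def validate_record(
    record: Mapping[str, Any], contract: SchemaContract, locator: Any = None
) -> "tuple[Optional[dict], Optional[ValidationFailure]]":
    """Validate and type-coerce one candidate row.

    Returns ``(coerced_row, None)`` on success or ``(None, failure)`` naming
    the first violated rule.  Checks run in contract order: required flags and
    types field by field, then plausibility rules, then cross-field rules.
    """
    if not isinstance(contract, SchemaContract):
        raise ConfigurationError("contract must be a SchemaContract")
    coerced: dict[str, Any] = {}
    for f in contract.fields:
        value = record.get(f.name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            if f.required:
                return None, ValidationFailure(locator, f"required: {f.name}")
            coerced[f.name] = None
            continue
        try:
            coerced[f.name] = _coerce(value, f.semantic_type)
        except (ValueError, TypeError):
            return None, ValidationFailure(locator, f"type: {f.name}")
    for rule in contract.plausibility_rules:
        if rule.applies(coerced) and not rule.check(coerced.get(rule.field)):
            return None, ValidationFailure(locator, rule.label())
    for xrule in contract.cross_field_rules:
        if not xrule.check(coerced):
            return None, ValidationFailure(locator, xrule.label())
    return coerced, None


def validate_batch(
    records: Iterable[Mapping[str, Any]], contract: SchemaContract
) -> "tuple[list[dict], ValidationReport]":
    """Validate a batch, preserving the order of valid rows.

    The report satisfies ``n_valid + n_failed = n_input`` and
    ``failure_rate = n_failed / max(n_input, 1)`` by construction.
    """
    valid: list[dict] = []
    failures: list[ValidationFailure] = []
    n_input = 0
    for i, record in enumerate(records):
        n_input += 1
        row, failure = validate_record(record, contract, locator=i)
        if failure is None:
            valid.append(row)  # type: ignore[arg-type]
        else:
            failures.append(failure)
    report = ValidationReport(
        n_input=n_input,
        n_valid=len(valid),
        n_failed=len(failures),
        failure_rate=len(failures) / max(n_input, 1),
        failures=tuple(failures),
    )
    return valid, report


def load_contract(name_or_path: "str | Path") -> SchemaContract:
    """Load a contract from a packaged domain name or a JSON file path."""
    path = Path(str(name_or_path))
    if path.suffix == ".json" and path.exists():
        spec = json.loads(path.read_text(encoding="utf-8"))
    else:
        ref = resources.files("pdms_etl.data.contracts").joinpath(f"{name_or_path}.json")
        try:
            spec = json.loads(ref.read_text(encoding="utf-8"))
        except FileNotFoundError:
            raise ConfigurationError(f"no packaged contract named {name_or_path!r}") from None
    return SchemaContract.from_dict(spec)


def packaged_contract_names() -> "list[str]":
    files = resources.files("pdms_etl.data.contracts")
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".json"))
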