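"""Evidence data model, schema validation, and deduplication.

An evidence record is the atomic unit of support linking a target gene to a
disease term.  Records arrive as JSON objects (typically one per line of a
JSON Lines file), are checked against the schema shipped in
``targetrank/schema/evidence.schema.json``, and are represented downstream by
:class:`EvidenceString`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Iterator

from pydantic import BaseModel, ConfigDict, Field, field_validator

logger = logging.getLogger(__name__)

DATATYPES = (
    "genetic_association",
    "somatic_mutation",
    "known_drug",
    "affected_pathway",
    "rna_expression",
    "literature",
    "animal_model",
)

TARGET_ID_RE = re.compile(r"^ENSG[0-9]{11}$")
DISEASE_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*_[0-9]+$")


class EvidenceString(BaseModel):
    """One validated unit of target-disease evidence."""

    model_config = ConfigDict(frozen=True)

    target_id: str
    disease_id: str
    datasource_id: str
    datatype_id: str
    score_payload: dict[str, Any] = Field(default_factory=dict)
    provenance: dict[str, Any] | None = None

    @field_validator("target_id")
    @classmethod
    def _target_pattern(cls, v: str) -> str:
        if not TARGET_ID_RE.match(v):
            raise ValueError(f"target_id {v!r} does not match ENSG + 11 digits")
        return v

    @field_validator("disease_id")
    @classmethod
    def _disease_pattern(cls, v: str) -> str:
        if not DISEASE_ID_RE.match(v):
            raise ValueError(f"disease_id {v!r} is not CURIE-style")
        return v

    @field_validator("datatype_id")
    @classmethod
    def _known_datatype(cls, v: str) -> str:
        if v not in DATATYPES:
            raise ValueError(f"unknown datatype_id {v!r}")
        return v

    def payload_hash(self) -> str:
        """Canonical (key-sorted) hash of the score payload."""
        blob = json.dumps(self.score_payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()

    def dedup_key(self) -> tuple[str, str, str, str]:
        return (self.target_id, self.disease_id, self.datasource_id, self.payload_hash())

    def to_json(self) -> str:
        return self.model_dump_json(exclude_none=True)


@dataclass
class ValidationReport:
    """Outcome of a validation pass over a stream of raw records."""

    n_input: int = 0
    n_valid: int = 0
    n_invalid: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_input": self.n_input,
            "n_valid": self.n_valid,
            "n_invalid": self.n_invalid,
            "failures": [{"index": i, "rule": r} for i, r in self.failures],
        }


def load_schema() -> dict[str, Any]:
    """Load the evidence schema document shipped with the package."""
    text = resources.files("targetrank").joinpath("schema/evidence.schema.json").read_text()
    return json.loads(text)


def _check_value(value: Any, schema: dict[str, Any], path: str) -> list[str]:
    """Check ``value`` against a subset of JSON-schema keywords.

    Supported keywords: type, enum, pattern, minLength, minimum, maximum,
    exclusiveMinimum, required, properties.  Returns a list of human-readable
    violations (empty when valid).
    """
    errors: list[str] = []
    typ = schema.get("type")
    if typ is not None:
        ok = {
            "object": lambda v: isinstance(v, dict),
            "string": lambda v: isinstance(v, str),
            "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
            "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
            "array": lambda v: isinstance(v, list),
            "boolean": lambda v: isinstance(v, bool),
        }[typ](value)
        if not ok:
            return [f"{path}: expected {typ}"]
    if "enum" in schema and value not in schema["enum"]:
        errors.append(f"{path}: value {value!r} not in enum")
    if "pattern" in schema and isinstance(value, str):
        if not re.search(schema["pattern"], value):
            errors.append(f"{path}: {value!r} does not match pattern {schema['pattern']}")
    if "minLength" in schema and isinstance(value, str) and len(value) < schema["minLength"]:
        errors.append(f"{path}: shorter than minLength {schema['minLength']}")
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if "minimum" in schema and value < schema["minimum"]:
            errors.append(f"{path}: {value} below minimum {schema['minimum']}")
        if "maximum" in schema and value > schema["maximum"]:
            errors.append(f"{path}: {value} above maximum {schema['maximum']}")
        if "exclusiveMinimum" in schema and value <= schema["exclusiveMinimum"]:
            errors.append(f"{path}: {value} not above {schema['exclusiveMinimum']}")
    if isinstance(value, dict):
        for req in schema.get("required", []):
            if req not in value:
                errors.append(f"{path}.{req}: required field absent")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                errors.extend(_check_value(value[key], sub, f"{path}.{key}"))
    return errors


def check_record(record: Any, schema: dict[str, Any]) -> list[str]:
    """Return all schema violations for one raw record (empty list = valid)."""
    if not isinstance(record, dict):
        return ["$: not a JSON object"]
    return _check_value(record, schema, "$")


def validate_evidence(
    records: Iterable[Any],
    schema: dict[str, Any] | None = None,
) -> tuple[list[EvidenceString], ValidationReport]:
    """Validate a stream of raw records against the evidence schema.

    ``records`` may contain JSON text lines or already-parsed dicts.  Invalid
    records are excluded and itemised in the report; order is preserved among
    the survivors.
    """
    if schema is None:
        schema = load_schema()
    report = ValidationReport()
    valid: list[EvidenceString] = []
    for idx, raw in enumerate(records):
        report.n_input += 1
        if isinstance(raw, (str, bytes)):
            try:
                raw = json.loads(raw)
            except json.JSONDecodeError as exc:
                report.n_invalid += 1
                report.failures.append((idx, f"malformed JSON: {exc.msg}"))
                continue
        violations = check_record(raw, schema)
        if violations:
            report.n_invalid += 1
            report.failures.append((idx, "; ".join(violations)))
            logger.debug("record %d rejected: %s", idx, violations)
            continue
        valid.append(EvidenceString(**raw))
        report.n_valid += 1
    return valid, report


def deduplicate_evidence(records: Iterable[EvidenceString]) -> Iterator[EvidenceString]:
    """Drop repeats of (target, disease, datasource, payload-hash); first wins."""
    seen: set[tuple[str, str, str, str]] = set()
    for rec in records:
        key = rec.dedup_key()
        if key in seen:
            continue
        seen.add(key)
        yield rec
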