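"""Reading and writing per-source variant files, and vocabulary normalisation.

Sources deliver their statements in a versioned JSON dialect: a top-level
object with ``dialect_version``, ``source``, ``disorder`` and ``records``,
where each record mirrors :class:`~variantdq.model.VariationRecord` field
for field.  Schema profiles and disorder specifications use small
declarative YAML files.

Raw pathogenicity terms are folded case- and whitespace-insensitively into
the canonical class vocabulary; anything unrecognised becomes ``other``
(and is logged), so normalisation is total and never raises.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .model import (
    DEFAULT_CLASS_VOCABULARY,
    AssemblyPlacement,
    CSHGEntity,
    DisorderSpec,
    HGVSExpression,
    SchemaProfile,
    SignificanceAssertion,
    StatisticalAssociationRecord,
    VariationRecord,
    validate_record,
)

logger = logging.getLogger(__name__)

DIALECT_VERSION = "1.0"


class IngestError(ValueError):
    """Base class for ingest failures."""


class ParseError(IngestError):
    """The file is structurally broken or a record violates an invariant."""


class DialectVersionError(IngestError):
    """The file declares an unsupported dialect version."""


class SourceMismatchError(IngestError):
    """The file's declared source differs from the expected one."""


class UnknownEntityError(IngestError):
    """A schema profile names an entity outside the eleven-member universe."""


@dataclass(frozen=True)
class SignificanceMapping:
    """Mapping from raw source terms to canonical pathogenicity classes."""

    raw_to_class: Mapping[str, str]
    vocabulary: tuple[str, ...] = DEFAULT_CLASS_VOCABULARY

    def __post_init__(self) -> None:
        bad = set(self.raw_to_class.values()) - set(self.vocabulary)
        if bad:
            raise ValueError(f"mapped classes {sorted(bad)} not in the vocabulary")


def _fold(term: str) -> str:
    return re.sub(r"\s+", " ", term.strip().lower())


#: Default mapping covering the terms the six public sources print.
DEFAULT_SIGNIFICANCE_MAPPING = SignificanceMapping(
    raw_to_class={
        "pathogenic": "pathogenic",
        "likely pathogenic": "likely_pathogenic",
        "uncertain significance": "uncertain_significance",
        "variant of uncertain significance": "uncertain_significance",
        "vus": "uncertain_significance",
        "likely benign": "likely_benign",
        "benign": "benign",
        "risk factor": "risk_factor",
    }
)


def normalize_significance(term_raw: str,
                           mapping: SignificanceMapping = DEFAULT_SIGNIFICANCE_MAPPING
                           ) -> str:
    """Fold a raw significance term into its canonical class.

    Case- and whitespace-insensitive; unknown terms map to ``"other"``.
    Total: always returns a vocabulary member, never raises.
    """
    folded = _fold(term_raw)
    try:
        return mapping.raw_to_class[folded]
    except KeyError:
        logger.info("unmapped significance term %r -> 'other'", term_raw)
        return "other"


# --- JSON (de)serialisation of the dialect -------------------------------

def _disorder_to_json(d: DisorderSpec) -> dict:
    return {
        "name": d.name,
        "ontology_ids": [list(pair) for pair in d.ontology_ids],
        "synonyms": list(d.synonyms),
    }


def _disorder_from_json(obj: dict) -> DisorderSpec:
    return DisorderSpec(
        name=obj.get("name", ""),
        ontology_ids=tuple((o, i) for o, i in obj.get("ontology_ids", [])),
        synonyms=tuple(obj.get("synonyms", [])),
    )


def record_to_json(record: VariationRecord) -> dict:
    return {
        "source_local_id": record.source_local_id,
        "gene_symbol": record.gene_symbol,
        "hgvs": [{"expression": h.expression, "level": h.level}
                 for h in record.hgvs],
        "placements": [
            {
                "assembly": p.assembly,
                "chromosome": p.chromosome,
                "start": p.start,
                "end": p.end,
                "reference_allele": p.reference_allele,
                "alternate_allele": p.alternate_allele,
            }
            for p in record.placements
        ],
        "assertions": [
            {
                "term_raw": a.term_raw,
                "term_class": a.term_class,
                "assertion_id": a.assertion_id,
                "disorder": _disorder_to_json(a.disorder),
            }
            for a in record.assertions
        ],
        "statistics": [
            {
                "p_value": s.p_value,
                "ci_lower": s.ci_lower,
                "ci_upper": s.ci_upper,
                "effect_scale": s.effect_scale,
                "study_id": s.study_id,
                "disorder": _disorder_to_json(s.disorder),
            }
            for s in record.statistics
        ],
        "bibliography": list(record.bibliography),
        "external_refs": [list(pair) for pair in record.external_refs],
    }


def record_from_json(obj: dict, source_name: str,
                     file_disorder: Optional[DisorderSpec] = None) -> VariationRecord:
    def assertion_disorder(a: dict) -> DisorderSpec:
        if "disorder" in a and a["disorder"] is not None:
            return _disorder_from_json(a["disorder"])
        if file_disorder is None:
            raise ParseError("assertion without a disorder in a file without one")
        return file_disorder

    return VariationRecord(
        source_name=source_name,
        source_local_id=obj.get("source_local_id", ""),
        gene_symbol=obj.get("gene_symbol"),
        hgvs=[HGVSExpression(h["expression"], h["level"])
              for h in obj.get("hgvs", [])],
        placements=[
            AssemblyPlacement(
                assembly=p["assembly"],
                chromosome=p["chromosome"],
                start=int(p["start"]),
                end=int(p["end"]),
                reference_allele=p["reference_allele"],
                alternate_allele=p["alternate_allele"],
            )
            for p in obj.get("placements", [])
        ],
        assertions=[
            SignificanceAssertion(
                term_raw=a["term_raw"],
                term_class=a["term_class"],
                disorder=assertion_disorder(a),
                source_name=source_name,
                assertion_id=a.get("assertion_id", ""),
            )
            for a in obj.get("assertions", [])
        ],
        statistics=[
            StatisticalAssociationRecord(
                p_value=float(s["p_value"]),
                ci_lower=float(s["ci_lower"]),
                ci_upper=float(s["ci_upper"]),
                effect_scale=s["effect_scale"],
                disorder=assertion_disorder(s),
                study_id=s.get("study_id", ""),
                source_name=source_name,
            )
            for s in obj.get("statistics", [])
        ],
        bibliography=list(obj.get("bibliography", [])),
        external_refs=[tuple(pair) for pair in obj.get("external_refs", [])],
    )


def read_source_file(path: Union[str, Path], expected_source: str
                     ) -> list[VariationRecord]:
    """Read one per-source, per-disorder JSON file into validated records.

    Raises :class:`ParseError` on malformed JSON or invariant-violating
    records, :class:`DialectVersionError` on an unsupported version, and
    :class:`SourceMismatchError` if the declared source is not
    ``expected_source``.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}, "
                         f"column {exc.colno}: {exc.msg}") from exc
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: top level must be an object")
    version = payload.get("dialect_version")
    if version != DIALECT_VERSION:
        raise DialectVersionError(
            f"{path}: dialect version {version!r} not supported "
            f"(expected {DIALECT_VERSION!r})")
    declared = payload.get("source")
    if declared != expected_source:
        raise SourceMismatchError(
            f"{path}: file declares source {declared!r}, expected "
            f"{expected_source!r}")
    file_disorder = (_disorder_from_json(payload["disorder"])
                     if payload.get("disorder") else None)
    records: list[VariationRecord] = []
    for index, obj in enumerate(payload.get("records", [])):
        try:
            record = record_from_json(obj, declared, file_disorder)
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: records[{index}]: {exc}") from exc
        violations = validate_record(record)
        if violations:
            detail = "; ".join(f"{v.field}: {v.rule}" for v in violations)
            raise ParseError(f"{path}: records[{index}] invalid: {detail}")
        records.append(record)
    return records


def write_source_file(path: Union[str, Path], source_name: str,
                      disorder: DisorderSpec,
                      records: Iterable[VariationRecord]) -> Path:
    """Write records to one per-source file in the dialect (round-trippable)."""
    path = Path(path)
    records = list(records)
    for record in records:
        if record.source_name != source_name:
            raise ValueError(f"record from {record.source_name!r} cannot be "
                             f"written into a {source_name!r} file")
    payload = {
        "dialect_version": DIALECT_VERSION,
        "source": source_name,
        "disorder": _disorder_to_json(disorder),
        "records": [record_to_json(r) for r in records],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path


def filter_by_disorder(records: Sequence[VariationRecord],
                       disorder: DisorderSpec) -> list[VariationRecord]:
    """Keep records with at least one assertion or statistic for the disorder.

    Matching prefers ontology IDs (exact) and falls back to
    case-insensitive name/synonym equality.  Order-preserving and
    idempotent.
    """
    kept = []
    for record in records:
        referenced = [a.disorder for a in record.assertions]
        referenced += [s.disorder for s in record.statistics]
        if any(disorder.matches(d) for d in referenced):
            kept.append(record)
    return kept


# --- declarative config files --------------------------------------------

def load_schema_profiles(path: Union[str, Path]) -> list[SchemaProfile]:
    """Load schema profiles from a YAML mapping of source -> entity names.

    Entity names are validated against the eleven-member universe;
    an unknown name raises :class:`UnknownEntityError`.
    """
    path = Path(path)
    payload = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: expected a mapping of source -> entity list")
    payload = {k: v for k, v in payload.items() if k != "dialect_version"}
    profiles = []
    for source_name, entity_names in payload.items():
        if isinstance(entity_names, str):
            entity_names = [e.strip() for e in entity_names.split(",")]
        entities = set()
        for name in entity_names or []:
            try:
                entities.add(CSHGEntity(name))
            except ValueError:
                raise UnknownEntityError(
                    f"{path}: source {source_name!r} lists unknown entity "
                    f"{name!r}") from None
        profiles.append(SchemaProfile(source_name=str(source_name),
                                      entities=frozenset(entities)))
    return profiles


def load_disorder_spec(path: Union[str, Path]) -> DisorderSpec:
    """Load a disorder specification from a YAML file."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return disorder_spec_from_config(payload)


def disorder_spec_from_config(payload: dict) -> DisorderSpec:
    return DisorderSpec(
        name=payload.get("name", ""),
        ontology_ids=tuple((str(o), str(i))
                           for o, i in payload.get("ontology_ids", [])),
        synonyms=tuple(payload.get("synonyms", [])),
    )
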