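"""Domain model for cross-database variant knowledge.

The types here instantiate an eleven-entity subschema of a conceptual
schema of the human genome, organised in four views:

* **Structural view** — ``Gene``: the gene a variation falls in.
* **Variation view** — ``Variation``, ``HGVSExpression``, ``AssemblyInfo``:
  the change itself, its HGVS notations, and its position/alleles on a
  reference assembly.
* **Evidence view** — ``GroupOfIndividuals``, ``ExternalItem``,
  ``StatisticalAssociation``, ``Study``, ``Bibliography``: statistical
  (GWAS-style) evidence, literature and cross-references.
* **Phenotype view** — ``Phenotype``, ``Significance``: the disorder and
  the curated interpretation of the variation's role in it.

A :class:`VariationRecord` is one source database's statement about one
variation for one disorder.  Identity across sources is resolved through
:func:`canonical_key`: exact match on (assembly, chromosome, start, end,
reference allele, alternate allele) after normalisation.  Coordinates are
1-based, fully closed; insertions/deletions use ``"-"`` for the absent
allele.  No liftover or indel left-alignment is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence


class CSHGEntity(str, Enum):
    """The eleven entities of the reference subschema.

    Membership is case-sensitive on the canonical names: ``CSHGEntity("Gene")``
    resolves, ``CSHGEntity("gene")`` raises ``ValueError``.
    """

    GENE = "Gene"
    VARIATION = "Variation"
    HGVS_EXPRESSION = "HGVSExpression"
    ASSEMBLY_INFO = "AssemblyInfo"
    GROUP_OF_INDIVIDUALS = "GroupOfIndividuals"
    EXTERNAL_ITEM = "ExternalItem"
    STATISTICAL_ASSOCIATION = "StatisticalAssociation"
    STUDY = "Study"
    BIBLIOGRAPHY = "Bibliography"
    PHENOTYPE = "Phenotype"
    SIGNIFICANCE = "Significance"


#: Total number of entities in the reference subschema (the denominator of
#: schema-level completeness).
ENTITY_UNIVERSE_SIZE = len(CSHGEntity)

#: Canonical pathogenicity class vocabulary.  Raw source terms are folded
#: into these classes by the ingest layer; anything unrecognised becomes
#: ``"other"``.
DEFAULT_CLASS_VOCABULARY: tuple[str, ...] = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain_significance",
    "likely_benign",
    "benign",
    "risk_factor",
    "other",
)

_ALLELE_RE = re.compile(r"^[ACGTN-]+$")
_LEVELS = ("genomic", "coding", "protein")
_LEVEL_PREFIX = {"g.": "genomic", "c.": "coding", "p.": "protein"}


def normalize_chromosome(chromosome: str) -> str:
    """Strip a leading ``chr``/``Chr`` dialect prefix from a chromosome label."""
    return re.sub(r"^chr", "", chromosome.strip(), flags=re.IGNORECASE)


def normalize_allele(allele: str) -> str:
    """Uppercase an allele; an empty/placeholder allele becomes ``"-"``."""
    allele = allele.strip().upper()
    return allele if allele else "-"


@dataclass(frozen=True)
class SchemaProfile:
    """The set of subschema entities a source represents internally."""

    source_name: str
    entities: frozenset[CSHGEntity]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", frozenset(self.entities))


@dataclass(frozen=True)
class DisorderSpec:
    """A disorder identified by name, ontology IDs (HPO/OMIM/ORPHA) and synonyms."""

    name: str
    ontology_ids: tuple[tuple[str, str], ...] = ()
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ontology_ids", tuple(tuple(p) for p in self.ontology_ids))
        object.__setattr__(self, "synonyms", tuple(self.synonyms))
        if not self.name and not self.ontology_ids:
            raise ValueError("DisorderSpec needs a name or at least one ontology ID")
        for ontology, identifier in self.ontology_ids:
            if not identifier or not str(identifier).strip():
                raise ValueError("ontology identifiers must be non-empty strings")
            if not ontology or not str(ontology).strip():
                raise ValueError("ontology names must be non-empty strings")

    def _id_set(self) -> set[tuple[str, str]]:
        return {(o.lower(), i) for o, i in self.ontology_ids}

    def _name_set(self) -> set[str]:
        names = {s.lower() for s in self.synonyms}
        if self.name:
            names.add(self.name.lower())
        return names

    def matches(self, other: "DisorderSpec") -> bool:
        """True if the two specs share an ontology ID (exact) or a
        name/synonym (case-insensitive)."""
        if self._id_set() & other._id_set():
            return True
        return bool(self._name_set() & other._name_set())


@dataclass(frozen=True)
class AssemblyPlacement:
    """Position and alleles of a variation on one reference assembly.

    Coordinates are 1-based and fully closed; ``reference_allele`` and
    ``alternate_allele`` are uppercase nucleotide strings or ``"-"``.
    """

    assembly: str
    chromosome: str
    start: int
    end: int
    reference_allele: str
    alternate_allele: str

    def normalized(self) -> "AssemblyPlacement":
        return AssemblyPlacement(
            assembly=self.assembly.strip(),
            chromosome=normalize_chromosome(self.chromosome),
            start=self.start,
            end=self.end,
            reference_allele=normalize_allele(self.reference_allele),
            alternate_allele=normalize_allele(self.alternate_allele),
        )


@dataclass(frozen=True)
class HGVSExpression:
    """An HGVS notation for a variation at genomic (g.), coding (c.) or
    protein (p.) level."""

    expression: str
    level: str


@dataclass(frozen=True)
class SignificanceAssertion:
    """One curated interpretation of a variation's role in a disorder.

    ``term_raw`` is the verbatim source term, ``term_class`` its canonical
    class.  A variation may carry several assertions from the same source;
    ``assertion_id`` distinguishes them (within-source conflicts are real
    data, not ingest errors).
    """

    term_raw: str
    term_class: str
    disorder: DisorderSpec
    source_name: str
    assertion_id: str = ""


@dataclass(frozen=True)
class StatisticalAssociationRecord:
    """One GWAS-style statistical association between a variation and a disorder.

    ``effect_scale`` states whether the effect estimate is a ratio (odds
    ratio, null value 1) or a difference (beta, null value 0); the
    relevance rule needs it to decide what "the CI crosses the null" means.
    """

    p_value: float
    ci_lower: float
    ci_upper: float
    effect_scale: str  # "ratio" or "difference"
    disorder: DisorderSpec
    study_id: str
    source_name: str


@dataclass
class VariationRecord:
    """One source's statement about one variation for one disorder."""

    source_name: str
    source_local_id: str = ""
    gene_symbol: Optional[str] = None
    hgvs: list[HGVSExpression] = field(default_factory=list)
    placements: list[AssemblyPlacement] = field(default_factory=list)
    assertions: list[SignificanceAssertion] = field(default_factory=list)
    statistics: list[StatisticalAssociationRecord] = field(default_factory=list)
    bibliography: list[str] = field(default_factory=list)
    external_refs: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True, order=True)
class CanonicalKey:
    """Canonical variant identity: exact match on normalised placement.

    Total lexicographic ordering over the fields makes every derived set,
    report and diff deterministic.
    """

    assembly: str
    chromosome: str
    start: int
    end: int
    reference_allele: str
    alternate_allele: str

    def __str__(self) -> str:  # the patient-report style spelling
        return (
            f"Chr{self.chromosome}:g.{self.start}-{self.end}:"
            f"{self.reference_allele}>{self.alternate_allele}({self.assembly})"
        )


@dataclass(frozen=True)
class Violation:
    """One validation failure: the offending field and the rule it broke."""

    field: str
    rule: str
    message: str


class UnresolvableRecordError(ValueError):
    """The record has no placement (direct or via genomic HGVS) on the
    requested assembly, so it cannot join integration."""


# Patient-report style genomic HGVS, e.g. "Chr2:g.29222407-29222407:G>A(GRCh38)".
_FULL_G_RE = re.compile(
    r"^(?:chr)?(?P<chrom>[\w.]+):g\.(?P<start>\d+)(?:[-_](?P<end>\d+))?"
    r":?(?P<ref>[ACGTNacgtn-]+)>(?P<alt>[ACGTNacgtn-]+)"
    r"(?:\((?P<assembly>[\w.]+)\))?$",
    flags=re.IGNORECASE,
)


def parse_genomic_hgvs(expression: str, default_assembly: Optional[str] = None
                       ) -> Optional[AssemblyPlacement]:
    """Parse a genomic HGVS substitution into a placement, or return None.

    Handles the chromosome-qualified style ``Chr2:g.29222407-29222407:G>A(GRCh38)``
    (the assembly suffix and the end coordinate are optional; a missing
    assembly falls back to ``default_assembly``).  Expressions without a
    chromosome cannot yield a placement.
    """
    m = _FULL_G_RE.match(expression.strip())
    if m is None:
        return None
    assembly = m.group("assembly") or default_assembly
    if assembly is None:
        return None
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    return AssemblyPlacement(
        assembly=assembly,
        chromosome=m.group("chrom"),
        start=start,
        end=end,
        reference_allele=m.group("ref"),
        alternate_allele=m.group("alt"),
    ).normalized()


def validate_record(record: VariationRecord,
                    vocabulary: Sequence[str] = DEFAULT_CLASS_VOCABULARY
                    ) -> list[Violation]:
    """Check every type invariant of a record; return the violations found.

    Validation never raises: an empty report means the record is valid.
    """
    violations: list[Violation] = []

    if not record.source_name or not record.source_name.strip():
        violations.append(Violation("source_name", "non-empty",
                                    "source_name must be a non-empty string"))

    for i, placement in enumerate(record.placements):
        where = f"placements[{i}]"
        if placement.start < 1 or placement.end < 1:
            violations.append(Violation(where, "positive-coordinates",
                                        f"coordinates must be >= 1, got "
                                        f"{placement.start}-{placement.end}"))
        if placement.start > placement.end:
            violations.append(Violation(where, "start<=end",
                                        f"start {placement.start} exceeds end "
                                        f"{placement.end}"))
        norm = placement.normalized()
        for which, allele in (("reference_allele", norm.reference_allele),
                              ("alternate_allele", norm.alternate_allele)):
            if not _ALLELE_RE.match(allele):
                violations.append(Violation(f"{where}.{which}", "allele-alphabet",
                                            f"allele {allele!r} is not [ACGTN-]+"))

    for i, hgvs in enumerate(record.hgvs):
        where = f"hgvs[{i}]"
        if not hgvs.expression or not hgvs.expression.strip():
            violations.append(Violation(where, "non-empty-expression",
                                        "HGVS expression must be non-empty"))
        if hgvs.level not in _LEVELS:
            violations.append(Violation(f"{where}.level", "known-level",
                                        f"level {hgvs.level!r} not in {_LEVELS}"))
        else:
            for prefix, level in _LEVEL_PREFIX.items():
                if (hgvs.expression.startswith(prefix)
                        or f":{prefix}" in hgvs.expression):
                    if level != hgvs.level:
                        violations.append(Violation(
                            f"{where}.level", "prefix-consistency",
                            f"expression uses {prefix!r} but level is "
                            f"{hgvs.level!r}"))
                    break

    vocab = set(vocabulary)
    for i, assertion in enumerate(record.assertions):
        if assertion.term_class not in vocab:
            violations.append(Violation(f"assertions[{i}].term_class",
                                        "class-in-vocabulary",
                                        f"class {assertion.term_class!r} not in "
                                        f"the configured vocabulary"))

    for i, assoc in enumerate(record.statistics):
        where = f"statistics[{i}]"
        if not (0.0 < assoc.p_value <= 1.0):
            violations.append(Violation(f"{where}.p_value", "p-in-(0,1]",
                                        f"p-value {assoc.p_value} outside (0, 1]"))
        if assoc.ci_lower > assoc.ci_upper:
            violations.append(Violation(f"{where}", "ci_lower<=ci_upper",
                                        f"CI [{assoc.ci_lower}, {assoc.ci_upper}] "
                                        f"inverted"))
        if assoc.effect_scale not in ("ratio", "difference"):
            violations.append(Violation(f"{where}.effect_scale", "known-scale",
                                        f"effect_scale {assoc.effect_scale!r} not "
                                        f"'ratio' or 'difference'"))

    has_genomic_hgvs = any(h.level == "genomic" for h in record.hgvs)
    if not record.placements and not has_genomic_hgvs:
        violations.append(Violation("placements/hgvs", "identity-derivability",
                                    "record needs a placement or a genomic-level "
                                    "HGVS expression to derive its identity"))

    return violations


def canonical_key(record: VariationRecord, target_assembly: str) -> CanonicalKey:
    """Resolve a record to its canonical identity on ``target_assembly``.

    Prefers an explicit placement on the target assembly; falls back to
    parsing a genomic HGVS expression (an expression without an assembly
    tag is taken to be on the target assembly).  Pure and deterministic:
    equal placements always give equal keys.

    Raises :class:`UnresolvableRecordError` if no placement on the target
    assembly can be derived.
    """
    for placement in record.placements:
        norm = placement.normalized()
        if norm.assembly == target_assembly:
            return CanonicalKey(norm.assembly, norm.chromosome, norm.start,
                                norm.end, norm.reference_allele,
                                norm.alternate_allele)
    for hgvs in record.hgvs:
        if hgvs.level != "genomic":
            continue
        placement = parse_genomic_hgvs(hgvs.expression,
                                       default_assembly=target_assembly)
        if placement is not None and placement.assembly == target_assembly:
            return CanonicalKey(placement.assembly, placement.chromosome,
                                placement.start, placement.end,
                                placement.reference_allele,
                                placement.alternate_allele)
    raise UnresolvableRecordError(
        f"record {record.source_name}:{record.source_local_id!r} has no "
        f"placement resolvable on assembly {target_assembly!r}")
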