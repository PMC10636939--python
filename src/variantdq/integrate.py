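"""Consolidating per-source records into one registry of unique variations.

Each distinct canonical key becomes one :class:`IntegratedVariation`
carrying every source's records, with assertions and statistics flattened
but provenance preserved.  On top of the registry sits the overlap (Venn)
algebra: counts of variations per exact subset-of-sources region,
per-source totals, exclusives and complements.

Records that cannot be resolved to a key on the target assembly never
enter the registry (and hence no metric denominator); they are listed in a
side report instead.  All outputs are ordered by canonical key, so the
registry and every derived report are reproducible byte for byte.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .ingest import DIALECT_VERSION, _disorder_to_json, record_to_json
from .model import (
    AssemblyPlacement,
    CanonicalKey,
    DisorderSpec,
    SignificanceAssertion,
    StatisticalAssociationRecord,
    UnresolvableRecordError,
    VariationRecord,
    canonical_key,
)


class UnknownSourceError(KeyError):
    """The named source is not part of the dataset."""


@dataclass
class IntegratedVariation:
    """One unique variation with every source's records merged under its key."""

    key: CanonicalKey
    records_by_source: dict[str, list[VariationRecord]]
    assertions: list[SignificanceAssertion] = field(default_factory=list)
    statistics: list[StatisticalAssociationRecord] = field(default_factory=list)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(self.records_by_source)


@dataclass
class UnresolvableReport:
    """Records excluded from integration, with the reason."""

    records: list[tuple[VariationRecord, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class IntegratedDataset:
    """The per-disorder registry of unique variations across sources."""

    disorder: DisorderSpec
    target_assembly: str
    sources: tuple[str, ...]
    variations: dict[CanonicalKey, IntegratedVariation]
    unresolvable: UnresolvableReport = field(default_factory=UnresolvableReport)

    @property
    def unique_total(self) -> int:
        return len(self.variations)

    def sorted_keys(self) -> list[CanonicalKey]:
        return sorted(self.variations)

    def source_count(self, source: str) -> int:
        """Number of unique variations the source holds."""
        if source not in self.sources:
            raise UnknownSourceError(source)
        return sum(1 for v in self.variations.values()
                   if source in v.records_by_source)


@dataclass(frozen=True)
class OverlapSummary:
    """Venn-region algebra of a dataset: one count per exact source subset."""

    region_counts: Mapping[frozenset[str], int]
    per_source_totals: Mapping[str, int]
    unique_total: int


def integrate(per_source: Mapping[str, Sequence[VariationRecord]],
              disorder: DisorderSpec,
              target_assembly: str) -> IntegratedDataset:
    """Merge per-source record lists into one registry of unique variations.

    Records sharing a canonical key collapse into one
    :class:`IntegratedVariation`; unresolvable records are excluded and
    reported, never raised.  The result is independent of source order and
    of record order within a source.
    """
    sources = tuple(per_source)
    variations: dict[CanonicalKey, IntegratedVariation] = {}
    unresolvable = UnresolvableReport()
    for source_name in sources:
        for record in per_source[source_name]:
            try:
                key = canonical_key(record, target_assembly)
            except UnresolvableRecordError as exc:
                unresolvable.records.append((record, str(exc)))
                continue
            variation = variations.get(key)
            if variation is None:
                variation = IntegratedVariation(key=key, records_by_source={})
                variations[key] = variation
            variation.records_by_source.setdefault(source_name, []).append(record)
            variation.assertions.extend(record.assertions)
            variation.statistics.extend(record.statistics)
    ordered = {key: variations[key] for key in sorted(variations)}
    return IntegratedDataset(disorder=disorder, target_assembly=target_assembly,
                             sources=sources, variations=ordered,
                             unresolvable=unresolvable)


def overlap_regions(dataset: IntegratedDataset) -> OverlapSummary:
    """Count variations per exact subset-of-sources (Venn) region.

    Satisfies, by construction, sum(region_counts) == unique_total and
    per_source_totals[s] == sum of counts over subsets containing s.
    """
    region_counts: dict[frozenset[str], int] = {}
    for variation in dataset.variations.values():
        region = variation.sources
        region_counts[region] = region_counts.get(region, 0) + 1
    per_source_totals = {
        source: sum(count for region, count in region_counts.items()
                    if source in region)
        for source in dataset.sources
    }
    return OverlapSummary(region_counts=region_counts,
                          per_source_totals=per_source_totals,
                          unique_total=dataset.unique_total)


def exclusive_to(dataset: IntegratedDataset, source: str) -> set[CanonicalKey]:
    """Keys of variations present in exactly this one source."""
    if source not in dataset.sources:
        raise UnknownSourceError(source)
    return {key for key, v in dataset.variations.items()
            if v.sources == frozenset({source})}


def missing_from(dataset: IntegratedDataset, source: str) -> set[CanonicalKey]:
    """Keys of variations the source does not hold (reported only elsewhere)."""
    if source not in dataset.sources:
        raise UnknownSourceError(source)
    return {key for key, v in dataset.variations.items()
            if source not in v.records_by_source}


def lookup(dataset: IntegratedDataset, placement: AssemblyPlacement
           ) -> Optional[IntegratedVariation]:
    """Find the integrated variation matching a (patient) placement, or None."""
    norm = placement.normalized()
    key = CanonicalKey(norm.assembly, norm.chromosome, norm.start, norm.end,
                       norm.reference_allele, norm.alternate_allele)
    return dataset.variations.get(key)


# --- registry and report writers -----------------------------------------

def region_label(region: Iterable[str]) -> str:
    return "+".join(sorted(region))


def write_registry(dataset: IntegratedDataset, path: Union[str, Path]) -> Path:
    """Write the consolidated per-disorder registry as one JSON object."""
    path = Path(path)
    payload = {
        "dialect_version": DIALECT_VERSION,
        "disorder": _disorder_to_json(dataset.disorder),
        "target_assembly": dataset.target_assembly,
        "sources": list(dataset.sources),
        "unique_total": dataset.unique_total,
        "unresolvable": [
            {"source": record.source_name,
             "source_local_id": record.source_local_id,
             "reason": reason}
            for record, reason in dataset.unresolvable.records
        ],
        "variations": [
            {
                "key": {
                    "assembly": key.assembly,
                    "chromosome": key.chromosome,
                    "start": key.start,
                    "end": key.end,
                    "reference_allele": key.reference_allele,
                    "alternate_allele": key.alternate_allele,
                },
                "sources": sorted(variation.sources),
                "records_by_source": {
                    source: [record_to_json(r) for r in records]
                    for source, records in sorted(
                        variation.records_by_source.items())
                },
            }
            for key, variation in sorted(dataset.variations.items())
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path


def write_overlap_tsv(summary: OverlapSummary, path: Union[str, Path]) -> Path:
    """Write Venn region counts as TSV (columns: subset, count) with a
    trailing total row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["subset", "count"])
        for region in sorted(summary.region_counts, key=region_label):
            writer.writerow([region_label(region),
                             summary.region_counts[region]])
        writer.writerow(["total", summary.unique_total])
    return path
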