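"""Shared fixtures: disorder specs and synthetic multi-source datasets."""

from __future__ import annotations

import pytest

from variantdq import (
    AssemblyPlacement,
    DisorderSpec,
    FixtureSpec,
    SignificanceAssertion,
    VariationRecord,
    generate_from_venn_spec,
    integrate,
)

ASSEMBLY = "GRCh38"


@pytest.fixture
def neuroblastoma():
    return DisorderSpec(name="Neuroblastoma",
                        ontology_ids=(("HPO", "HP:0003006"),))


@pytest.fixture
def aml():
    return DisorderSpec(name="Acute Myeloid Leukemia",
                        ontology_ids=(("OMIM", "601626"),),
                        synonyms=("AML",))


# Five-source region structure consistent with the published per-source
# totals for acute myeloid leukemia: ClinVar 767, Ensembl 514, LOVD 14,
# CIViC 8, GWAS Catalog 2; 797 unique variations, 30 of them absent from
# ClinVar (10 Ensembl + 14 LOVD + 2 GWAS Catalog + 4 CIViC exclusives).
AML_REGIONS = {
    frozenset({"ClinVar"}): 259,
    frozenset({"ClinVar", "Ensembl"}): 504,
    frozenset({"ClinVar", "CIViC"}): 4,
    frozenset({"Ensembl"}): 10,
    frozenset({"LOVD"}): 14,
    frozenset({"GWAS Catalog"}): 2,
    frozenset({"CIViC"}): 4,
}
AML_SOURCES = ("ClinVar", "Ensembl", "GWAS Catalog", "LOVD", "CIViC")


@pytest.fixture
def aml_fixture_spec(aml):
    return FixtureSpec(sources=AML_SOURCES, disorder=aml, assembly=ASSEMBLY,
                       seed=11, region_counts=AML_REGIONS)


@pytest.fixture
def aml_dataset(aml_fixture_spec, aml):
    fixture = generate_from_venn_spec(aml_fixture_spec)
    return integrate(fixture, aml, ASSEMBLY)


def make_record(source: str, chrom: str = "2", start: int = 29222407,
                end: int | None = None, ref: str = "G", alt: str = "A",
                assembly: str = ASSEMBLY, term_class: str | None = None,
                disorder: DisorderSpec | None = None,
                assertion_id: str = "a0") -> VariationRecord:
    """A minimal valid record with one placement and optionally one assertion."""
    record = VariationRecord(
        source_name=source,
        source_local_id=f"{source}-{chrom}-{start}",
        placements=[AssemblyPlacement(assembly, chrom, start,
                                      end if end is not None else start,
                                      ref, alt)],
    )
    if term_class is not None:
        record.assertions.append(SignificanceAssertion(
            term_raw=term_class, term_class=term_class,
            disorder=disorder or DisorderSpec(name="Synthetic disorder"),
            source_name=source, assertion_id=assertion_id))
    return record
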