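"""Synthetic multi-source fixtures with controlled overlap and conflict.

This module stands in for live extractions from public variant databases:
it fabricates per-source record sets whose *structure* — which variations
each source holds, how interpretations conflict, where GWAS statistics sit
relative to the relevance rule — is specified exactly or stochastically,
so every downstream metric has a known ground truth.

Two generation modes:

* **exact-count** (:func:`generate_from_venn_spec`): the caller states the
  number of variations in each Venn region (exact subset of sources);
  integration reproduces those counts with zero tolerance.
* **stochastic** (:func:`generate_stochastic`): per-source marginal counts
  with a uniform random-overlap model and probabilistic conflict
  injection; realised conflict rates converge to the configured rates.

Synthetic variations are consecutive positions on one synthetic
chromosome with cycling SNV alleles: trivially unique and auditable by
eye.  All randomness flows from the spec's seed, and emitted files are
byte-identical across runs for identical (spec, seed).
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from . import ingest
from .model import (
    AssemblyPlacement,
    DisorderSpec,
    SignificanceAssertion,
    StatisticalAssociationRecord,
    VariationRecord,
)

#: Display spellings used for term_raw, keyed by canonical class.
_RAW_TERMS = {
    "pathogenic": "Pathogenic",
    "likely_pathogenic": "Likely Pathogenic",
    "uncertain_significance": "Uncertain Significance",
    "likely_benign": "Likely Benign",
    "benign": "Benign",
    "risk_factor": "Risk Factor",
    "other": "association not provided",
}

#: For conflict injection: a class guaranteed to sit in a different default
#: equivalence class than the key.
_CONFLICT_PARTNER = {
    "pathogenic": "uncertain_significance",
    "likely_pathogenic": "uncertain_significance",
    "benign": "uncertain_significance",
    "likely_benign": "uncertain_significance",
    "uncertain_significance": "pathogenic",
    "risk_factor": "likely_benign",
    "other": "pathogenic",
}

_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))

DEFAULT_DISORDER = DisorderSpec(
    name="Synthetic disorder",
    ontology_ids=(("HPO", "HP:0000001"),),
)


@dataclass(frozen=True)
class InterpretationConfig:
    """How curated interpretations are attached to synthetic variations."""

    assertion_probability: float = 1.0
    class_weights: tuple[tuple[str, float], ...] = (
        ("pathogenic", 0.3),
        ("likely_pathogenic", 0.2),
        ("uncertain_significance", 0.3),
        ("likely_benign", 0.1),
        ("benign", 0.1),
    )
    between_source_conflict_rate: float = 0.0
    within_source_conflict_rate: float = 0.0


@dataclass(frozen=True)
class GwasConfig:
    """How GWAS statistics are attached to synthetic variations."""

    statistic_probability: float = 0.0
    relevant_fraction: float = 0.5
    conflict_rate: float = 0.0
    effect_scale: str = "ratio"


@dataclass(frozen=True)
class FixtureSpec:
    """A declarative recipe for one multi-source fixture.

    Exactly one of ``region_counts`` (exact mode) or ``marginals``
    (stochastic mode) must be given.  ``region_counts`` maps each
    non-empty subset of sources to the number of variations present in
    exactly that subset; ``marginals`` gives per-source totals drawn
    uniformly from a key universe of ``universe_size`` (default: the sum
    of the marginals).
    """

    sources: tuple[str, ...]
    disorder: DisorderSpec = DEFAULT_DISORDER
    assembly: str = "GRCh38"
    seed: int = 0
    region_counts: Optional[Mapping[frozenset[str], int]] = None
    marginals: Optional[Mapping[str, int]] = None
    universe_size: Optional[int] = None
    interp: InterpretationConfig = InterpretationConfig()
    gwas: GwasConfig = GwasConfig()
    chromosome: str = "1"
    base_position: int = 1_000_000

    def __post_init__(self) -> None:
        if (self.region_counts is None) == (self.marginals is None):
            raise ValueError("give exactly one of region_counts or marginals")
        if self.region_counts is not None:
            normalized: dict[frozenset[str], int] = {}
            for region, count in self.region_counts.items():
                subset = frozenset([region] if isinstance(region, str)
                                   else region)
                if not subset or not subset <= set(self.sources):
                    raise ValueError(f"region {sorted(subset)} is not a "
                                     f"non-empty subset of sources")
                if not isinstance(count, int) or count < 0:
                    raise ValueError(f"region count {count!r} must be a "
                                     f"non-negative integer")
                normalized[subset] = normalized.get(subset, 0) + count
            object.__setattr__(self, "region_counts", normalized)
        for rate in (self.interp.assertion_probability,
                     self.interp.between_source_conflict_rate,
                     self.interp.within_source_conflict_rate,
                     self.gwas.statistic_probability,
                     self.gwas.relevant_fraction,
                     self.gwas.conflict_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")


def expected_overlap(spec: FixtureSpec) -> tuple[dict[frozenset[str], int],
                                                 dict[str, int], int]:
    """The (region_counts, per_source_totals, unique_total) an exact-count
    spec implies — the ground truth for generator/metric closure checks."""
    if spec.region_counts is None:
        raise ValueError("expected_overlap needs an exact-count spec")
    regions = dict(spec.region_counts)
    totals = {s: sum(c for r, c in regions.items() if s in r)
              for s in spec.sources}
    return regions, totals, sum(regions.values())


def _placement(spec: FixtureSpec, index: int) -> AssemblyPlacement:
    ref, alt = _ALLELE_CYCLE[index % len(_ALLELE_CYCLE)]
    position = spec.base_position + index
    return AssemblyPlacement(assembly=spec.assembly,
                             chromosome=spec.chromosome,
                             start=position, end=position,
                             reference_allele=ref, alternate_allele=alt)


def _assertion(term_class: str, disorder: DisorderSpec, source: str,
               assertion_id: str) -> SignificanceAssertion:
    return SignificanceAssertion(term_raw=_RAW_TERMS[term_class],
                                 term_class=term_class, disorder=disorder,
                                 source_name=source, assertion_id=assertion_id)


def _relevant_stat(rng: random.Random, disorder: DisorderSpec, source: str,
                   study_id: str, scale: str) -> StatisticalAssociationRecord:
    p_value = 10 ** -rng.uniform(9.0, 12.0)  # well below genome-wide threshold
    if scale == "ratio":
        lower = 1.1 + rng.uniform(0.0, 0.3)
        upper = lower + rng.uniform(0.1, 0.4)
    else:
        lower = 0.1 + rng.uniform(0.0, 0.3)
        upper = lower + rng.uniform(0.1, 0.4)
    return StatisticalAssociationRecord(p_value=p_value, ci_lower=lower,
                                        ci_upper=upper, effect_scale=scale,
                                        disorder=disorder, study_id=study_id,
                                        source_name=source)


def _irrelevant_stat(rng: random.Random, disorder: DisorderSpec, source: str,
                     study_id: str, scale: str) -> StatisticalAssociationRecord:
    # fails both prongs: p above threshold and a CI straddling the null
    p_value = 10 ** -rng.uniform(0.5, 4.0)
    null = 1.0 if scale == "ratio" else 0.0
    lower = null - rng.uniform(0.05, 0.3)
    upper = null + rng.uniform(0.05, 0.3)
    return StatisticalAssociationRecord(p_value=p_value, ci_lower=lower,
                                        ci_upper=upper, effect_scale=scale,
                                        disorder=disorder, study_id=study_id,
                                        source_name=source)


def _records_from_membership(memberships: Sequence[frozenset[str]],
                             spec: FixtureSpec, rng: random.Random
                             ) -> dict[str, list[VariationRecord]]:
    classes = [c for c, _ in spec.interp.class_weights]
    weights = [w for _, w in spec.interp.class_weights]
    per_source: dict[str, list[VariationRecord]] = {s: [] for s in spec.sources}

    for index, members in enumerate(memberships):
        placement = _placement(spec, index)
        ordered = sorted(members)
        records = {
            source: VariationRecord(
                source_name=source,
                source_local_id=f"{_slug(source)}-{index}",
                placements=[placement],
            )
            for source in ordered
        }

        if rng.random() < spec.interp.assertion_probability:
            base = rng.choices(classes, weights=weights, k=1)[0]
            per_source_class = {source: base for source in ordered}
            if (len(ordered) >= 2
                    and rng.random() < spec.interp.between_source_conflict_rate):
                per_source_class[ordered[-1]] = _CONFLICT_PARTNER[base]
            for source in ordered:
                records[source].assertions.append(
                    _assertion(per_source_class[source], spec.disorder,
                               source, f"{_slug(source)}-{index}-a0"))
            if rng.random() < spec.interp.within_source_conflict_rate:
                first = ordered[0]
                records[first].assertions.append(
                    _assertion(_CONFLICT_PARTNER[per_source_class[first]],
                               spec.disorder, first,
                               f"{_slug(first)}-{index}-a1"))

        if rng.random() < spec.gwas.statistic_probability:
            relevant = rng.random() < spec.gwas.relevant_fraction
            make = _relevant_stat if relevant else _irrelevant_stat
            scale = spec.gwas.effect_scale
            for source in ordered:
                records[source].statistics.append(
                    make(rng, spec.disorder, source,
                         f"{_slug(source)}-{index}-s0", scale))
            if rng.random() < spec.gwas.conflict_rate:
                flipped = _irrelevant_stat if relevant else _relevant_stat
                first = ordered[0]
                records[first].statistics.append(
                    flipped(rng, spec.disorder, first,
                            f"{_slug(first)}-{index}-s1", scale))

        for source in ordered:
            per_source[source].append(records[source])

    return per_source


def generate_from_venn_spec(spec: FixtureSpec
                            ) -> dict[str, list[VariationRecord]]:
    """Generate records whose integration reproduces the requested Venn
    region counts exactly.  Deterministic given the spec's seed."""
    if spec.region_counts is None:
        raise ValueError("generate_from_venn_spec needs an exact-count spec")
    rng = random.Random(spec.seed)
    memberships: list[frozenset[str]] = []
    for region in sorted(spec.region_counts, key=lambda r: sorted(r)):
        memberships.extend([region] * spec.region_counts[region])
    return _records_from_membership(memberships, spec, rng)


def generate_stochastic(spec: FixtureSpec) -> dict[str, list[VariationRecord]]:
    """Generate records from per-source marginals under a uniform
    random-overlap model.  Identical seed, identical output."""
    if spec.marginals is None:
        raise ValueError("generate_stochastic needs a marginals spec")
    rng = random.Random(spec.seed)
    universe = spec.universe_size or sum(spec.marginals.values())
    if any(n > universe for n in spec.marginals.values()):
        raise ValueError("a marginal exceeds the key universe size")
    membership_of: dict[int, set[str]] = {}
    for source in spec.sources:
        count = spec.marginals.get(source, 0)
        for slot in rng.sample(range(universe), count):
            membership_of.setdefault(slot, set()).add(source)
    memberships = [frozenset(membership_of[slot])
                   for slot in sorted(membership_of)]
    return _records_from_membership(memberships, spec, rng)


def generate_concordance_fixture(n_interp_concordant: int,
                                 n_interp_discordant: int,
                                 n_gwas_concordant: int = 0,
                                 n_gwas_discordant: int = 0,
                                 disorder: DisorderSpec = DEFAULT_DISORDER,
                                 sources: tuple[str, str] = ("SourceA", "SourceB"),
                                 assembly: str = "GRCh38",
                                 seed: int = 0,
                                 ) -> dict[str, list[VariationRecord]]:
    """An exact-count concordance fixture: the stated numbers of unique
    variations with agreeing/conflicting interpretations, then with
    agreeing/conflicting GWAS evidence (evidence types disjoint so the
    two modes tally independently).  Deterministic given the seed."""
    first, second = sources[0], sources[1]
    rng = random.Random(seed)
    spec = FixtureSpec(sources=tuple(sources), disorder=disorder,
                       assembly=assembly, seed=seed,
                       region_counts={frozenset(sources): 0})
    per_source: dict[str, list[VariationRecord]] = {s: [] for s in sources}
    index = 0

    def shared_records() -> dict[str, VariationRecord]:
        placement = _placement(spec, index)
        return {
            source: VariationRecord(source_name=source,
                                    source_local_id=f"{_slug(source)}-{index}",
                                    placements=[placement])
            for source in sources
        }

    for _ in range(n_interp_concordant):
        records = shared_records()
        for source in sources:
            records[source].assertions.append(
                _assertion("pathogenic", disorder, source,
                           f"{_slug(source)}-{index}-a0"))
        for source in sources:
            per_source[source].append(records[source])
        index += 1
    for _ in range(n_interp_discordant):
        records = shared_records()
        records[first].assertions.append(
            _assertion("pathogenic", disorder, first,
                       f"{_slug(first)}-{index}-a0"))
        records[second].assertions.append(
            _assertion("uncertain_significance", disorder, second,
                       f"{_slug(second)}-{index}-a0"))
        for source in sources:
            per_source[source].append(records[source])
        index += 1
    for _ in range(n_gwas_concordant):
        records = shared_records()
        for source in sources:
            records[source].statistics.append(
                _relevant_stat(rng, disorder, source,
                               f"{_slug(source)}-{index}-s0", "ratio"))
        for source in sources:
            per_source[source].append(records[source])
        index += 1
    for _ in range(n_gwas_discordant):
        records = shared_records()
        records[first].statistics.append(
            _relevant_stat(rng, disorder, first,
                           f"{_slug(first)}-{index}-s0", "ratio"))
        records[second].statistics.append(
            _irrelevant_stat(rng, disorder, second,
                             f"{_slug(second)}-{index}-s0", "ratio"))
        for source in sources:
            per_source[source].append(records[source])
        index += 1

    return per_source


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


def emit_source_files(fixture: Mapping[str, Sequence[VariationRecord]],
                      out_dir: Union[str, Path],
                      disorder: DisorderSpec = DEFAULT_DISORDER,
                      spec: Optional[FixtureSpec] = None) -> list[Path]:
    """Write one dialect JSON file per source; returns the paths.

    When an exact-count ``spec`` is given, a ``manifest.json`` recording
    the recipe, the seed and the implied overlap ground truth is written
    alongside, for test harnesses.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for source in fixture:
        path = out_dir / f"{_slug(source)}.json"
        ingest.write_source_file(path, source, disorder, fixture[source])
        paths.append(path)
    if spec is not None:
        manifest: dict = {
            "dialect_version": ingest.DIALECT_VERSION,
            "sources": {source: f"{_slug(source)}.json" for source in fixture},
            "seed": spec.seed,
            "assembly": spec.assembly,
        }
        if spec.region_counts is not None:
            regions, totals, unique_total = expected_overlap(spec)
            manifest["expected"] = {
                "region_counts": {"+".join(sorted(r)): c
                                  for r, c in sorted(regions.items(),
                                                     key=lambda kv: sorted(kv[0]))},
                "per_source_totals": totals,
                "unique_total": unique_total,
            }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n",
            encoding="utf-8")
    return paths


def load_fixture_spec(path: Union[str, Path]) -> FixtureSpec:
    """Load a FixtureSpec from its declarative YAML form.

    Regions are keyed by ``+``-joined source subsets, e.g. ``"A+B": 3``.
    """
    import yaml

    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    disorder = (ingest.disorder_spec_from_config(payload["disorder"])
                if "disorder" in payload else DEFAULT_DISORDER)
    region_counts = None
    if "regions" in payload:
        region_counts = {frozenset(label.split("+")): int(count)
                         for label, count in payload["regions"].items()}
    interp_cfg = payload.get("interp", {})
    if "class_weights" in interp_cfg:
        interp_cfg = dict(interp_cfg)
        interp_cfg["class_weights"] = tuple(
            (c, float(w)) for c, w in interp_cfg["class_weights"])
    return FixtureSpec(
        sources=tuple(payload["sources"]),
        disorder=disorder,
        assembly=payload.get("assembly", "GRCh38"),
        seed=int(payload.get("seed", 0)),
        region_counts=region_counts,
        marginals=payload.get("marginals"),
        universe_size=payload.get("universe_size"),
        interp=InterpretationConfig(**interp_cfg),
        gwas=GwasConfig(**payload.get("gwas", {})),
    )
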