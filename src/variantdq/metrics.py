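"""The three data-quality metrics: schema completeness, data completeness,
and concordance.

* **CSL** (completeness at the schema level): the fraction of the
  eleven-entity reference subschema a source's internal schema represents.
* **CDL** (completeness at the data level): for one disorder, the fraction
  of all unique variations across sources that one source holds.
* **Concordance**: for each unique variation, whether all its evidence
  items agree.  Curated interpretations agree when every assertion falls
  in one equivalence class of pathogenicity terms (by default
  {pathogenic, likely_pathogenic} and {benign, likely_benign} are merged;
  ``strict_mode`` makes every distinct term its own class).  GWAS evidence
  agrees when every study reaches the same verdict under the relevance
  rule: p < 5e-8 and a confidence interval that does not cross the null
  value (1 on the ratio scale, 0 on the difference scale).

All fractions are kept as exact rationals; display strings are produced
by a configurable two-decimal formatter (round-half-up or truncation).
Concordance percentages are computed, per evidence mode, over the
variations that carry that kind of evidence (concordant + discordant); a
whole-registry denominator is available via ``denominator="all_unique"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal, localcontext
from enum import Enum
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .integrate import IntegratedDataset, UnknownSourceError
from .model import (
    DEFAULT_CLASS_VOCABULARY,
    ENTITY_UNIVERSE_SIZE,
    CanonicalKey,
    DisorderSpec,
    SchemaProfile,
    SignificanceAssertion,
    StatisticalAssociationRecord,
)


class EmptyDatasetError(ValueError):
    """CDL is undefined on a dataset with no unique variations."""


def format_percent(fraction: Optional[Fraction], style: str = "half_up") -> str:
    """Render an exact rational as a two-decimal percentage string.

    ``style`` is ``"half_up"`` (commercial rounding) or ``"truncate"``
    (drop digits past the second decimal).  ``None`` renders as ``"-"``,
    the convention for an inapplicable metric.
    """
    if fraction is None:
        return "-"
    if style not in ("half_up", "truncate"):
        raise ValueError(f"unknown percent style {style!r}")
    rounding = ROUND_HALF_UP if style == "half_up" else ROUND_DOWN
    with localcontext() as ctx:
        ctx.prec = 60
        value = Decimal(fraction.numerator) * 100 / Decimal(fraction.denominator)
        return f"{value.quantize(Decimal('0.01'), rounding=rounding)}%"


class Verdict(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    NOT_APPLICABLE = "not_applicable"


def _default_equivalence_classes(vocabulary: Sequence[str]
                                 ) -> tuple[frozenset[str], ...]:
    merged = [frozenset({"pathogenic", "likely_pathogenic"}),
              frozenset({"benign", "likely_benign"})]
    covered = set().union(*merged)
    singles = [frozenset({term}) for term in vocabulary if term not in covered]
    return tuple(merged + singles)


DEFAULT_EQUIVALENCE_CLASSES = _default_equivalence_classes(DEFAULT_CLASS_VOCABULARY)


@dataclass(frozen=True)
class ConcordancePolicy:
    """Tunable conventions for the concordance metric.

    ``equivalence_classes`` partitions the pathogenicity vocabulary into
    groups treated as the same verdict.  ``strict_mode`` overrides it:
    every distinct class label is its own group, so pathogenic vs likely
    pathogenic becomes a conflict.  The GWAS thresholds implement the
    genome-wide relevance rule; the p comparison is strict and a CI
    endpoint exactly at the null counts as crossing.
    """

    equivalence_classes: tuple[frozenset[str], ...] = DEFAULT_EQUIVALENCE_CLASSES
    strict_mode: bool = False
    gwas_p_threshold: float = 5e-8
    gwas_null_ratio: float = 1.0
    gwas_null_difference: float = 0.0
    denominator: str = "evidence"  # or "all_unique" (the literal definition)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cls in self.equivalence_classes:
            if seen & cls:
                raise ValueError("equivalence classes must be disjoint")
            seen |= cls
        if self.denominator not in ("evidence", "all_unique"):
            raise ValueError(f"unknown denominator {self.denominator!r}")

    def class_of(self, term_class: str) -> frozenset[str]:
        """The equivalence class a term belongs to (singleton fallback)."""
        if self.strict_mode:
            return frozenset({term_class})
        for cls in self.equivalence_classes:
            if term_class in cls:
                return cls
        return frozenset({term_class})

    def null_value(self, assoc: StatisticalAssociationRecord) -> float:
        return (self.gwas_null_ratio if assoc.effect_scale == "ratio"
                else self.gwas_null_difference)


@dataclass(frozen=True)
class CSLResult:
    """Schema-level completeness of one source."""

    source: str
    entities_represented: int
    entities_total: int
    fraction: Fraction
    percent_display: str


@dataclass(frozen=True)
class CDLResult:
    """Data-level completeness of one source for one disorder (or group)."""

    source: str
    disorder_label: str
    n_in_source: int
    n_unique_total: int
    fraction: Fraction
    percent_display: str


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-mode concordance counts and percentages for one disorder or group.

    A percentage is ``None`` (displayed "-") when no variation carries
    that kind of evidence, matching how an inapplicable mode is reported.
    """

    label: str
    interp_concordant: int
    interp_discordant: int
    interp_fraction: Optional[Fraction]
    interp_percent: str
    gwas_concordant: int
    gwas_discordant: int
    gwas_fraction: Optional[Fraction]
    gwas_percent: str
    verdicts: Mapping[CanonicalKey, tuple[Verdict, Verdict]] = field(default_factory=dict)


def csl(profile: SchemaProfile, style: str = "truncate") -> CSLResult:
    """Schema-level completeness: entities represented / 11.

    The display convention for this metric is truncation to two decimals
    (8/11 renders as "72.72%").
    """
    n = len(profile.entities)
    fraction = Fraction(n, ENTITY_UNIVERSE_SIZE)
    return CSLResult(source=profile.source_name, entities_represented=n,
                     entities_total=ENTITY_UNIVERSE_SIZE, fraction=fraction,
                     percent_display=format_percent(fraction, style))


def cdl(dataset: IntegratedDataset, source: str, style: str = "half_up"
        ) -> CDLResult:
    """Data-level completeness: variations in the source / unique variations."""
    if source not in dataset.sources:
        raise UnknownSourceError(source)
    if dataset.unique_total == 0:
        raise EmptyDatasetError(
            f"no unique variations for {dataset.disorder.name!r}; "
            f"CDL denominator undefined")
    n = dataset.source_count(source)
    fraction = Fraction(n, dataset.unique_total)
    return CDLResult(source=source, disorder_label=dataset.disorder.name,
                     n_in_source=n, n_unique_total=dataset.unique_total,
                     fraction=fraction,
                     percent_display=format_percent(fraction, style))


def classify_interpretation(assertions: Sequence[SignificanceAssertion],
                            policy: ConcordancePolicy = ConcordancePolicy()
                            ) -> Verdict:
    """Verdict for the curated-interpretation evidence of one variation.

    Concordant iff every assertion's class falls in one equivalence class;
    a within-source conflict counts exactly like a between-source one.
    Empty evidence is not applicable.
    """
    if not assertions:
        return Verdict.NOT_APPLICABLE
    classes = {policy.class_of(a.term_class) for a in assertions}
    return Verdict.CONCORDANT if len(classes) == 1 else Verdict.DISCORDANT


def gwas_relevant(assoc: StatisticalAssociationRecord,
                  policy: ConcordancePolicy = ConcordancePolicy()) -> bool:
    """The genome-wide relevance rule for one statistical association.

    True iff p is strictly below the threshold and the CI stays strictly
    on one side of the null value (an endpoint at the null crosses it).
    """
    null = policy.null_value(assoc)
    return (assoc.p_value < policy.gwas_p_threshold
            and (assoc.ci_lower > null or assoc.ci_upper < null))


def classify_gwas(stats: Sequence[StatisticalAssociationRecord],
                  policy: ConcordancePolicy = ConcordancePolicy()) -> Verdict:
    """Verdict for the GWAS evidence of one variation: concordant iff all
    studies agree on relevance."""
    if not stats:
        return Verdict.NOT_APPLICABLE
    verdicts = {gwas_relevant(s, policy) for s in stats}
    return Verdict.CONCORDANT if len(verdicts) == 1 else Verdict.DISCORDANT


def _mode_fraction(concordant: int, discordant: int, unique_total: int,
                   policy: ConcordancePolicy) -> Optional[Fraction]:
    if policy.denominator == "all_unique":
        if unique_total == 0:
            return None
        return Fraction(concordant, unique_total)
    applicable = concordant + discordant
    if applicable == 0:
        return None
    return Fraction(concordant, applicable)


def concordance_summary(dataset: IntegratedDataset,
                        policy: ConcordancePolicy = ConcordancePolicy(),
                        style: str = "half_up",
                        label: Optional[str] = None) -> ConcordanceResult:
    """Classify every variation in both evidence modes and tally the results.

    Variations without assertions (resp. statistics) are not applicable in
    the interpretation (resp. GWAS) mode and stay out of its counts.
    """
    verdicts: dict[CanonicalKey, tuple[Verdict, Verdict]] = {}
    ic = idc = gc = gdc = 0
    for key in dataset.sorted_keys():
        variation = dataset.variations[key]
        vi = classify_interpretation(variation.assertions, policy)
        vg = classify_gwas(variation.statistics, policy)
        verdicts[key] = (vi, vg)
        ic += vi is Verdict.CONCORDANT
        idc += vi is Verdict.DISCORDANT
        gc += vg is Verdict.CONCORDANT
        gdc += vg is Verdict.DISCORDANT
    interp_fraction = _mode_fraction(ic, idc, dataset.unique_total, policy)
    gwas_fraction = _mode_fraction(gc, gdc, dataset.unique_total, policy)
    return ConcordanceResult(
        label=label if label is not None else dataset.disorder.name,
        interp_concordant=ic, interp_discordant=idc,
        interp_fraction=interp_fraction,
        interp_percent=format_percent(interp_fraction, style),
        gwas_concordant=gc, gwas_discordant=gdc,
        gwas_fraction=gwas_fraction,
        gwas_percent=format_percent(gwas_fraction, style),
        verdicts=verdicts,
    )


# --- disorder-group aggregates -------------------------------------------

def aggregate_cdl(datasets: Sequence[IntegratedDataset], source: str,
                  label: str, style: str = "half_up") -> CDLResult:
    """Group-level CDL: per-disorder counts summed, without cross-disorder
    deduplication (a variation linked to two disorders counts twice)."""
    n = sum(d.source_count(source) for d in datasets)
    denominator = sum(d.unique_total for d in datasets)
    if denominator == 0:
        raise EmptyDatasetError(f"group {label!r} has no unique variations")
    fraction = Fraction(n, denominator)
    return CDLResult(source=source, disorder_label=label, n_in_source=n,
                     n_unique_total=denominator, fraction=fraction,
                     percent_display=format_percent(fraction, style))


def aggregate_concordance(results: Sequence[ConcordanceResult], label: str,
                          policy: ConcordancePolicy = ConcordancePolicy(),
                          style: str = "half_up") -> ConcordanceResult:
    """Group-level concordance: sums of per-disorder mode counts, with the
    percentage recomputed from the summed counts."""
    ic = sum(r.interp_concordant for r in results)
    idc = sum(r.interp_discordant for r in results)
    gc = sum(r.gwas_concordant for r in results)
    gdc = sum(r.gwas_discordant for r in results)
    interp_fraction = Fraction(ic, ic + idc) if ic + idc else None
    gwas_fraction = Fraction(gc, gc + gdc) if gc + gdc else None
    return ConcordanceResult(
        label=label,
        interp_concordant=ic, interp_discordant=idc,
        interp_fraction=interp_fraction,
        interp_percent=format_percent(interp_fraction, style),
        gwas_concordant=gc, gwas_discordant=gdc,
        gwas_fraction=gwas_fraction,
        gwas_percent=format_percent(gwas_fraction, style),
    )
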