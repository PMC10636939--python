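# Methods

## Data model and variant identity

The pipeline evaluates sources against an eleven-entity subschema of a
conceptual schema of the human genome, organised in four views: structural
(Gene), variation (Variation, HGVSExpression, AssemblyInfo), evidence
(GroupOfIndividuals, ExternalItem, StatisticalAssociation, Study,
Bibliography) and phenotype (Phenotype, Significance). Entity membership
is case-sensitive on the canonical names; the universe size (11) is the
fixed denominator of schema-level completeness.

A source's statement about one variation for one disorder is a
`VariationRecord`. Cross-source identity is resolved by an exact canonical
key: `(assembly, chromosome, start, end, reference allele, alternate
allele)` after normalisation — chromosome labels lose a leading
`chr`/`Chr` prefix, alleles are uppercased, and an absent allele in an
insertion or deletion is spelled `-` so the key stays total and printable.
Coordinates are 1-based and fully closed, matching the
`Chr2:g.29222407-29222407:G>A(GRCh38)` patient-report convention. When a
record has no placement on the target assembly, a genomic-level HGVS
expression in that chromosome-qualified style is parsed as a fallback (an
expression without an assembly tag is assumed to be on the target
assembly). Records resolvable neither way are excluded from integration
and from every metric denominator, and listed in a diagnostics report.

Exact matching is a deliberate design choice where several conventions
would have been defensible: it is auditable, order-independent and
sufficient for synthetic data whose keys are constructed unambiguous.
Consequences: no liftover between assemblies, no indel left-alignment, no
transcript-level equivalence of HGVS spellings — two sources describing
the same biological change in different normalisations would count as two
variations. Real-database inputs should be normalised upstream.

Validation never raises: `validate_record` returns a list of violations,
each naming the field and the rule, so a broken record in a file can be
reported with context rather than aborting blind.

## Ingest

Per-source, per-disorder inputs use a versioned JSON dialect (top-level
`dialect_version`, `source`, `disorder`, `records[]`, each record
mirroring `VariationRecord` field for field). The dialect is this
package's own definition; round-tripping (write → read) preserves record
lists exactly, which the suite asserts.

Raw significance terms are folded case- and whitespace-insensitively into
a canonical vocabulary (`pathogenic`, `likely_pathogenic`,
`uncertain_significance`, `likely_benign`, `benign`, `risk_factor`,
`other`). Folding is total: unknown terms become `other` and are logged,
never rejected, because an exotic curator label is data, not an error.

Disorder filtering keeps a record iff any of its assertions or statistics
references the disorder, preferring exact ontology-ID matches (HPO, OMIM,
ORPHA pairs) with case-insensitive name/synonym equality as a fallback.
No fuzzy matching: the behaviour must be auditable after the fact.

## Integration and overlap algebra

Integration groups records by canonical key into one registry per
disorder; assertions and statistics are flattened with their source names
preserved. The registry is sorted by key, making integration
order-invariant (permuting sources or records yields the same registry)
and reruns byte-identical. Overlap analysis classifies every unique
variation by its exact membership subset of sources (Venn region);
exclusives and complements (`exclusive_to`, `missing_from`) are derived
set queries. The suite checks the region counts against an independent
brute-force membership-tuple enumeration on random fixtures of up to six
sources.

## Metrics and display conventions

All metric fractions are exact rationals. Two display formatters exist,
both to two decimals: round-half-up (default for data-level completeness
and concordance tables) and truncation (default for schema-level
completeness, where 8/11 is conventionally printed 72.72%). Every emitted
table carries the raw counts next to the percentage, so a displayed value
is always re-derivable from its own row.

The concordance percentage for a mode divides the concordant count by the
number of variations carrying that kind of evidence (concordant +
discordant). The alternative — dividing by all unique variations in the
registry, evidence-bearing or not — is implemented behind
`ConcordancePolicy(denominator="all_unique")`; the evidence-based
denominator is the default because it is the one consistent with treating
"no evidence" as not applicable rather than as agreement. A mode with no
applicable variations reports `-` rather than a number.

Two genuinely open conventions were settled as follows:

* *Pathogenic vs likely pathogenic.* The default policy merges them (and
  the benign pair), reading "agrees the variation causes the disorder" as
  the unit of agreement. `strict_mode` makes every distinct term its own
  class, the reading under which a source asserting both Pathogenic and
  Likely Pathogenic for one variation is self-conflicting. Both are
  first-class because credible curation practice exists for each; strict
  concordance implies default concordance, never the reverse, and the
  suite asserts that implication.
* *GWAS boundaries.* "p below the genome-wide threshold" is a strict
  inequality (p = 5×10⁻⁸ exactly is not relevant) and a confidence
  interval with an endpoint exactly at the null counts as crossing it.
  Boundary cases are vanishingly rare in real data; fixing them keeps the
  rule total and testable.

Within-source conflicts (two assertions from one source in different
classes) are classified identically to between-source conflicts: the
metric asks whether the evidence agrees, not who disagrees.

Disorder-group aggregates sum per-disorder counts without cross-disorder
deduplication (a variation linked to two disorders in a group counts once
per disorder), and recompute group percentages from the summed counts.

## Synthetic data generator

The generator stands in for live database extractions. What it emulates:
the *structure* of multi-source variant knowledge — which variations each
source holds (exact Venn region counts, or per-source marginals under a
uniform random-overlap model), curated assertions with controllable
between-source and within-source conflict rates, and GWAS statistics
placed deliberately on either side of the relevance rule (relevant:
p ∈ [10⁻¹², 10⁻⁹], CI strictly off the null; irrelevant: p ≥ 10⁻⁴ and a
CI straddling the null — failing both prongs so tests never hinge on a
boundary).

Synthetic variations are consecutive positions on one synthetic chromosome
with cycling substitution alleles: trivially unique, so the region
structure requested is the region structure obtained, with zero tolerance
(the generator/metric closure property the suite asserts). All randomness
flows from the spec's seed; emitted files are byte-identical across runs.

What it does not emulate: realistic allele frequencies, mutational
spectra, coordinate dialect disagreements between sources, multi-allelic
sites, or records identifying the same change under different
normalisations. Passing tests therefore demonstrate that the metrics,
set algebra and report plumbing are correct on well-formed inputs; they do
not demonstrate robustness of variant matching against the notational
heterogeneity of real databases, which exact-match identity deliberately
does not attempt to absorb.

Defaults: assertion probability 1.0 (curated sources assert what they
list), conflict rates 0, no GWAS statistics unless requested, assembly
GRCh38. Conflict injection flips one member source (or adds a second
within-source assertion) to a class from a different default equivalence
class, so an injected conflict is discordant under both the default and
the strict policy.

## Pipeline, sizes and determinism

The run configuration is one YAML file (per-disorder source files, a
schema-profile file, target assembly, policy, optional disorder groups).
Outputs per disorder: registry JSON, overlap TSV, data-completeness TSV,
concordance TSV; plus one schema-completeness TSV and per-group aggregate
tables. `variantdq report` re-reads the emitted TSVs and renders aligned
text, so the rendered tables cannot diverge from the machine-readable
values. No timestamps enter value-bearing outputs; reruns on identical
inputs are byte-identical.

Problem sizes used by the test suite and acceptance script were chosen at
desk scale: the published table cells are ratios of printed counts, so
they are reproduced exactly from count-specified fixtures (the largest,
a ~54,000-variation concordance aggregate, runs in seconds); stochastic
rate-recovery uses 4,000 variations, where three binomial standard
deviations of a 25% rate is ±0.02.

## Known limitations

* Identity is exact-match; see above. No liftover, left-alignment or
  HGVS transcript equivalence.
* Only the eleven-entity subschema is modelled; schema profiles are
  declared, not introspected from live sources.
* The GWAS relevance rule is the fixed two-prong convention; no
  effect-size heterogeneity or meta-analysis across studies.
* Venn region *counts* are first-class outputs; diagram rendering is out
  of scope (the TSV is the artifact of record).
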