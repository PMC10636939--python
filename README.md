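# variantdq

Knowledge about DNA variations is dispersed across many public databases
(ClinVar, Ensembl, the GWAS Catalog, LOVD, disease-specific resources such
as CIViC or CardioDB), and clinicians who restrict a genomics-based
diagnosis to a single source they trust risk missing variations and
overlooking contradictory interpretations. `variantdq` is a small pipeline
for quantifying that risk: it integrates per-source variant statements for
a disorder under a common eleven-entity conceptual data model and computes
three data-quality metrics, together with a synthetic multi-source
generator so that every stage can be exercised with a known ground truth
instead of live database extractions.

It is aimed at people studying the data-quality side of precision
medicine: how complete is each source, how much do sources overlap, and
how often does the available evidence disagree.

## The metrics

For a source *s* and a disorder *d*, with `E(s)` the set of model entities
the source represents (out of the 11-entity universe) and `V_x` sets of
unique variations (identity = exact match on assembly, chromosome, start,
end, reference and alternate allele):

* **Completeness at the schema level** — `CSL(s) = |E(s)| / 11`.
* **Completeness at the data level** —
  `CDL(s, d) = |V_s(d)| / |⋃_t V_t(d)|`, the share of all unique
  variations known for the disorder that the source holds.
* **Concordance** — per unique variation, evaluated in two evidence modes:
  * *interpretation*: concordant iff every curated pathogenicity assertion
    (from any source, including several from the same source) falls in one
    equivalence class; by default {pathogenic, likely pathogenic} and
    {benign, likely benign} are merged and every other term (uncertain
    significance, risk factor, ...) is its own class. A `strict_mode`
    policy treats every distinct term as its own class.
  * *GWAS*: each study is *relevant* iff p < 5×10⁻⁸ and its confidence
    interval does not cross the null value (1 for ratio effects, 0 for
    differences); a variation is concordant iff all its studies agree on
    relevance.

  The reported percentage for each mode is
  `concordant / (concordant + discordant)` over the variations that carry
  that kind of evidence (a whole-registry denominator is available via
  `ConcordancePolicy(denominator="all_unique")`).

Fractions are kept exact (`fractions.Fraction`); displayed percentages use
a two-decimal formatter (round-half-up by default, truncation for CSL
tables).

## Worked example

Generate a three-source fixture with a declared overlap structure, run the
pipeline, and print the tables:

```
$ variantdq generate fixture.yaml --out fixtures
$ variantdq run run.yaml
$ variantdq report out
== csl.tsv ==
source   entities_represented  entities_total  csl_percent
ClinVar  8                     11              72.72%
Ensembl  8                     11              72.72%
LOVD     7                     11              63.63%

== demo_cardiomyopathy/cdl.tsv ==
disorder             source   n_in_source  n_unique_total  cdl_percent
Demo cardiomyopathy  ClinVar  70           80              87.50%
Demo cardiomyopathy  Ensembl  36           80              45.00%
Demo cardiomyopathy  LOVD     9            80              11.25%

== demo_cardiomyopathy/concordance.tsv ==
label                mode            concordant  discordant  concordance_percent
Demo cardiomyopathy  interpretation  75          5           93.75%
Demo cardiomyopathy  gwas            0           0           -

== demo_cardiomyopathy/overlap.tsv ==
subset                count
ClinVar               40
ClinVar+Ensembl       25
ClinVar+Ensembl+LOVD  5
Ensembl               6
LOVD                  4
total                 80
```

where `fixture.yaml` declared the Venn regions (ClinVar-only 40,
ClinVar∩Ensembl 25, all three 5, Ensembl-only 6, LOVD-only 4 — hence 80
unique variations, ClinVar holding 70 of them = 87.50%) and a 10%
between-source conflict rate, which the seeded generator realised as 5
discordant variations out of the 80 carrying interpretations (93.75%
concordant). The `-` marks a mode with no evidence to judge. The same
objects are available as a library:

```python
from variantdq import (FixtureSpec, generate_from_venn_spec, integrate,
                       cdl, concordance_summary, missing_from)

spec = FixtureSpec(sources=("A", "B"), seed=1,
                   region_counts={frozenset("A"): 3, frozenset("AB"): 2})
dataset = integrate(generate_from_venn_spec(spec), spec.disorder, "GRCh38")
print(cdl(dataset, "B").percent_display)      # 40.00%
print(len(missing_from(dataset, "B")))        # 3
```

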