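# Methods

## The screening procedure

The package operates on aggregate (cohort-level) allele-frequency summaries
of a single pharmacogene, the form in which the *All of Us* Data Browser
publishes variant data: one row per SNV/indel with a `chrom-pos-ref-alt`
identifier (GRCh38, 1-based), an rsID, a ClinVar significance class, an
overall cohort allele frequency, and frequencies for seven
genetic-ancestry subgroups. Three stages:

1. **Overall selection.** Keep variants with overall frequency ≥
   `overall_threshold` (default 0.10, comparison configurable to strict
   `>`). This restricts attention to alleles common enough to matter for
   population-level prescribing questions.
2. **Subgroup differences.** For each kept variant and each subgroup
   *g*, Δ₉ = *p*₉ − *p*₀ (signed; enrichment is positive). All seven
   subgroups are treated identically — no subgroup is excluded a priori.
3. **Flagging.** Under the default `delta` criterion a cell is flagged
   when Δ₉ ≥ `delta_threshold` (default 0.10). The `elevated` criterion
   instead requires *p*₉ ≥ `overall_threshold` and Δ₉ > 0.

Flagged variants are stratified by ClinVar class; flagged
"undefined"-class variants whose rsID occurs in ≥ 1 star allele having
≥ 1 sub-allele at "definitive" PharmVar evidence are nominated as
reclassification candidates. Candidates are ordered by descending maximum
Δ with the variant ID as a deterministic tie-break.

No statistical testing is attempted: the inputs are point frequencies
without denominators per subgroup, so the screen is a descriptive
threshold rule, not an inference procedure.

## Numerical choices

Frequencies are parsed from their decimal strings into `decimal.Decimal`
and never renormalized, so Δ is exact arithmetic on the published values
and threshold comparisons at exactly 0.10 are deterministic. A float
pipeline would misclassify boundary cells (e.g. 0.3 − 0.2 < 0.1 in binary
floating point), which is why the implementation, the test-suite's
independently written per-cell loop oracle, and the report generator all
stay in decimal.

Two delta modes are provided because the published cell markings the
fixtures carry cannot be reproduced by any single rule:

* `strict` (default): compare the exact Δ. Reproduces 76 of the 78
  published enrichment marks; the two exceptions (Δ = 0.096809 and
  Δ = 0.095591) sit just below 0.10.
* `rounded2dp`: round Δ half-up to two decimals first. Recovers those two
  marks but over-flags one unmarked cell (Δ = 0.095383 → 0.10).

Both behaviors are pinned by regression tests; the discrepancy log in the
summary report surfaces whichever residual applies. Percentages in reports
use round-half-up (whole percents for subgroup flag rates, one decimal for
class proportions, extra decimals only when a nonzero proportion would
otherwise print as 0.0, e.g. 2/6,359 → 0.03%), and every rendered
percentage is re-verified against its numerator/denominator at render
time.

Variant identifiers are validated (positive position, A/C/G/T alleles,
ref ≠ alt) but otherwise treated as opaque keys: no indel left-alignment
or normalization, so fixture identifiers survive round trips byte for
byte. rsIDs may legitimately repeat across rows (the packaged tables
contain two such pairs); all keyed operations therefore use the variant
ID, and the rsID is only the haplotype cross-reference key.

Partial records (a browser may suppress low-count subgroup cells) must be
opted into at read time; screening then skips — never flags — the missing
cells.

## Packaged fixtures

The published summary tables ship as TSVs: 11 drug-response and 60
undefined-class variants with full frequency spectra (71 variant IDs),
the published per-cell enrichment marks and definitive-evidence marks as
a separate truth file, and the published cross-reference listing. Printed
quirks are preserved deliberately — one duplicated cross-reference row,
one duplicated star-allele token (hence "41–76 names per row" as printed
vs 41–75 unique), and three printed deltas that disagree with the
frequency-table arithmetic — because tests pin recomputation against the
source exactly as printed and surface, rather than repair, its internal
inconsistencies. The quoted cohort-level class counts (89 + 6,262 + 17 +
2 + 14 = 6,384) do not sum to the quoted total of 6,359; the metadata
carries them as incomplete, and proportions use the quoted denominator.

The derived haplotype table assigns each listed star allele a single
Definitive sub-allele whose defining set is the rsIDs listing it — the
published listing only discloses that each named allele reaches
definitive evidence, not which sub-allele carries it or its full
definition, so the fixture encodes exactly the disclosed relation and no
more.

## The synthetic cohort generator

`generate_cohort` emulates the browser export so every stage is testable
without downloads. Per variant: a baseline frequency p₀ ~ Beta(α, β)
(default (0.2, 1.8), a rare-skewed spectrum with a minority of common
variants; clipped to keep logits finite); with probability
`enrichment_rate` (default 0.05) the variant is enriched in one subgroup
(two with probability 0.3), whose frequencies are shifted by
`enrichment_effect` (default 1.5) on the logit scale; all subgroups
receive N(0, `noise_sd`) logit jitter (default 0.1). Subgroup frequencies
are rounded to six decimals (browser display precision) and the overall
frequency is then the subgroup-weight mixture Σ w₉·p₉, so the
weighted-mean identity holds exactly in float arithmetic. Default
subgroup weights loosely mimic a majority-European national cohort
(African 0.20, European 0.51, Latin American 0.17, the rest small); the
default class mixture matches the fixture cohort's proportions (98.5%
undefined, 1.4% drug response). A planted-truth record carries the
enrichment sets, assigned classes, and the flag set a default strict
screen should find.

Planted-signal recovery runs use a deliberately constrained regime:
baseline clipped to [0.25, 0.55] (so every record clears the overall
screen and recall is measured on the full cohort), effect +4 logits (so
every planted Δ exceeds the 0.10 threshold by ≥ 0.02 even when the
majority-weight subgroup is enriched), 200–300 variants, 3 seeds. Under
those conditions precision and recall against the planted set are exactly
1.0; recall degrades monotonically as jitter grows (and precision
collapses faster, since a threshold screen has no noise model). What the
generator does **not** emulate: sampling error tied to subgroup sizes,
linkage between variants, Hardy–Weinberg/individual-level structure, or
copy-number and structural variation — passing tests demonstrate the
screening arithmetic, not robustness to those real-data features.

## Problem sizes

The fixture analyses are desk-scale (71 variants, 86 star alleles) and
run in well under a second; synthetic validation uses 200–1,000 variants
per cohort and a 3-seed × 4-noise-level grid, keeping the full suite and
the acceptance script to a few seconds.

## Known limitations

* The screen is descriptive; with per-subgroup denominators one could
  attach confidence intervals, but the aggregate export does not provide
  them.
* Candidate nomination inherits PharmVar's evidence labels at sub-allele
  granularity only as far as the packaged relation encodes them; it does
  not model allele function or metabolizer phenotype.
* Copy-number and structural variants — central to this gene's
  pharmacology — are absent from the input data model entirely.
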