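# Methods and design notes

## The screening model

The pipeline reproduces a two-tier dried-blood-spot (DBS) newborn screen
for Pompe disease. GAA activity is computed from multiple-reaction-
monitoring ion abundances as

    activity = (P / IS) · [IS] · V_IS / RF / V_blood / t        [µmol/L/h]

with product abundance `P`, internal-standard abundance `IS` and
concentration `[IS]` (µmol/L), internal-standard volume `V_IS` (µL),
response factor `RF`, blood volume `V_blood` (3.1 µL assigned to a 1/8-inch
punch) and incubation time `t` (hours, nominally 18 ± 2). `P` is assumed
blank-corrected upstream; there is no separate background-subtraction
operation. The formula is exactly multiplicative — homogeneous of degree +1
in `P` and −1 in each of `RF`, `t`, `V_blood` — and the test suite checks
those identities property-wise, since no worked numeric example is
available to pin.

Both tiers use the same fixed cutoff, 2.10 µmol/L/h, set at ~18% of the
apparently-normal newborn mean (so the implied normal mean is
2.10/0.18 ≈ 11.67 µmol/L/h). The comparison is **strict**: an activity of
exactly 2.10 is screen-negative on either tier. First low activity →
repeat specimen (message code 1); second low activity → reflex to full
*GAA* sequencing; ≥1 primary variant → referral (code 2);
pseudodeficiency-only or variant-negative sequencing → consult (code 3).
Records whose first-tier activity was never captured enter the algorithm at
the first tier for which data exist — several confirmed patients are on
record that way. A reported cardiomyopathy/symptom prompt at the first
abnormal result is carried as a `fast_track` annotation on the outcome; it
changes workflow urgency, never the classification.

## Genotype grammar and variant interpretation

Genotypes are slash-separated allele segments; semicolons join variants
reported in cis; `c.(A;B)` groups two in-cis variants under one prefix; a
trailing single-base segment (`.../C`) is multi-allelic shorthand kept as
one opaque token. Each segment contributes at most one **primary allele**:
pseudodeficiency and benign/likely-benign tokens are riders (phase is not
asserted) and never count toward the primary-allele number. A segment with
several non-rider variants (e.g. two VUS in cis) is one compound allele
whose class is its most severe constituent; `unknown` dominates so that an
uncurated variant can never silently contribute to a diagnosis. More than
two allele-bearing segments is a malformed genotype.

The knowledge base is a two-column TSV (spelling → class) shipped with the
package and replaceable by the user. Lookups are case-sensitive after
whitespace normalization; absence is the value `unknown`, never an error
and never pathogenic. Two transcription quirks of the source tables are
preserved deliberately:

* the intron-1 splice variant is spelled both `c.-32-13T>G` and
  `c.32-13T>G`; the spelling without the leading `-` normalizes to the
  canonical form (the affected patients are counted as splice homozygotes,
  and the cohort's splice-allele tallies — 12 homozygous, 23/31 with ≥1
  allele — only reconcile under this reading);
* `c.-32-13 T>C` and `c.546 G>A` (one patient's verbatim spellings, with
  internal spaces) are distinct KB entries rather than corrections: the
  same positions appear elsewhere with different classifications, and the
  laboratory's per-patient assignments are retained rather than
  second-guessed. Token classification therefore consults the verbatim
  spelling before the normalized one. Bare spellings lacking the `c.`
  prefix (`1655T>C`, `1194+3G>C`) are likewise kept verbatim as their own
  VUS entries.

## Diagnostic rules

Applied in order to a sequenced, screen-positive record:

1. two disease-causing (pathogenic/likely-pathogenic) alleles **and**
   an infantile presentation — cardiomyopathy, or CK, Hex4 and BNP all
   above their reference limits → **IOPD**;
2. two disease-causing alleles otherwise → **LOPD**;
3. two primary alleles with ≥1 VUS → **suspected LOPD**;
4. exactly one primary allele → **carrier** (a non-negative
   deletion/duplication result downgrades confidence via a warning only);
5. no primary allele, ≥1 pseudodeficiency rider → **pseudodeficiency**
   (homo- and heterozygous are not distinguished);
6. no variant at all → **false positive**.

The IOPD/LOPD split is clinical in the source program, not rule-stated; the
cardiomyopathy-or-biomarker-triad rule was chosen because both confirmed
infantile cases show exactly those findings and no late-onset case does.
Confirmatory enzyme activity never gates a label — two confirmed LOPD
patients had confirmatory values within normal limits — it is reported
alongside, and for false positives a normal value corroborates what the
negative sequencing already decides. Missing clinical data count as
"finding absent", which is the conservative direction for the IOPD call
only; with both tabulated infantile cases flagged for cardiomyopathy this
convention is exercised by the fixtures.

## Statistics

* **Incidence** `1:N` uses N = total/cases rounded half-up, computed in
  integer arithmetic (`(2T + c) // 2c`); this reproduces all eight
  published strings, including the `265,569.5 → 265,570` boundary case.
* **Group summaries** use the midpoint median (mean of the central pair for
  even n) and linear-interpolation quartiles; missing values are excluded,
  an all-missing group is an error. The midpoint convention reproduces the
  published medians 0.77, 72.5 and 42.5 on even-sized groups.
* **Rank-sum test**: mid-ranks for ties; statistic is the first group's
  rank-sum. For pooled n ≤ 12 the p-value is exact by full enumeration of
  all C(n, n1) rank assignments with the doubling convention
  (2·min(tail probabilities), capped at 1 — identical multisets give
  p = 1). Larger samples use a normal approximation with tie-corrected
  variance n1·n2/12·[(n+1) − Σ(t³−t)/(n(n−1))] and a 0.5 continuity
  correction; it matches an independent implementation to 1e−6 and agrees
  with the exact enumeration within 0.03 at n1 = n2 = 6 on continuous
  data. With heavy ties the doubling and symmetric-distance two-sided
  conventions can legitimately diverge, so the small-sample agreement is
  asserted tie-free. Published p-values for groups whose raw data are not
  tabulated are not asserted numerically; where both groups are printed
  (CK, LOPD vs suspected LOPD) the recomputed p (0.034) is checked against
  the published significance threshold.

## The synthetic cohort

The simulator emulates the screening population, not individual biology.
Each newborn draws a hidden category: the six diagnostic labels at their
observed prevalences (counts / 531,139 by default), a *transient-low*
category (first activity low, repeat normal; default rate 65/531,139, the
observed tier-1/tier-2 gap), or screen-negative. Conditional on category:

* screening activities and confirmatory biomarkers come from **triangular
  distributions** anchored at the published (min, median-as-mode, max)
  order statistics per group — the minimal bounded choice when only three
  order statistics are known. Positive-category activity bounds sit below
  the cutoff, so a true positive always completes the funnel. The two
  infantile cases and two false positives anchor their categories' narrow
  printed ranges.
* the screen-negative majority draws activity from a **log-normal** with
  mean 2.10/0.18 ≈ 11.67 µmol/L/h and CV 0.35 (strictly positive,
  right-skewed, consistent with a fixed-percentile cutoff; under these
  defaults a spurious tier-1 low among true negatives is a ≈5·10⁻⁷ event,
  and its repeat draw is clipped at the cutoff so it exits at tier 2).
* genotypes are sampled from label-specific pools: the tabulated confirmed
  and suspected genotypes; synthetic single-allele, pseudodeficiency-only
  and sequencing-negative strings (built from the same spellings) for
  carriers, pseudodeficiency and false positives. The pools are
  label-unambiguous, so pipeline labels must equal hidden labels — the
  recovery harness asserts 100%.
* confirmatory-biomarker missingness is applied missing-completely-at-
  random at per-column rates measured from the fixture tables (no
  missingness mechanism is reported); screening activities are never
  dropped so the funnel stays well defined.

One integer seed drives a single `numpy` Generator; category counts are
drawn first (multinomial), category blocks are generated in a fixed order,
and the assembled frame is shuffled by the same generator — identical
parameters give byte-identical cohorts. A full-size cohort (531,139 rows)
simulates and screens in a few seconds because tier decisions are
vectorized and only the ~180 reflexed rows take the per-record genotype
path.

What passing simulator tests do **not** show: the triangular shapes,
between-analyte independence, the negative-population CV and the
carrier/pseudodeficiency anchors (whose raw per-patient values are
unpublished) are modelling assumptions; real screening data have
correlated analytes, assay drift, gestational-age effects and
population-specific allele frequencies, none of which are modelled.

## Numerical and degenerate-input choices

Strict `<` at the cutoff on both tiers; activities must be finite and
non-negative. The exact rank-sum enumeration uses a 1e−9 tolerance when
comparing mid-rank sums. Empty groups, zero-case incidences, totals smaller
than positives, non-positive assay parameters and negative activities are
errors, not silent values. A record reflexed to sequencing with no
sequencing result on file is an error (the outcome vocabulary has no
pending-sequencing state); a record with no usable data at any tier is
likewise an error. Unparseable numeric cells in input tables (e.g. a
printed "ND") become missing values with a logged warning, with row/column
context.

## Known limitations

* The fixture tables carry the source report's internal inconsistencies
  (two false positives described with second-tier activities that are below
  the stated threshold in one place and above it in another; a figure
  legend's minima differing slightly from the table values). The pipeline
  follows the stated decision rules; medians, not minima, are the pinned
  statistics where the source disagrees with itself.
* CRIM status, treatment decisions, follow-up scheduling, turnaround
  times and specimen-quality handling are out of scope.
* The carrier/pseudodeficiency group statistics cannot be recomputed from
  per-patient data (not tabulated); they enter only as simulator anchors.
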