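# Methods

## Problem and model

Large pharmacovigilance datasets document tens of thousands of drug uses,
and any analysis of drug–drug or drug–gene interactions first needs to know,
per drug, whether it is a substrate of the polymorphic phase-I enzymes
CYP2D6, CYP2C9 and CYP2C19.  `cypmatch` implements two assessment routes and
the statistics to compare them:

* an **automatic** route that matches canonical English drug names against
  substrate resources (a Drugbank-style catalog export, FDA-style clinical
  substrate examples, a Flockhart-style teaching table), and
* a **manual** route ingested as a curated consensus table produced by human
  reviewers (the review process itself — independent reviewers, literature
  search, consensus on disagreement — happens outside this package).

Every assessment is tri-state: `substrate`, `non_substrate`, or
`not_assessed`.  The third state is load-bearing: agreement statistics are
computed only over drugs both methods actually assessed.

## Coverage policies

The single most consequential modelling choice is how far a resource's
assessment reaches, and it is explicit in the data model:

* `CATALOG` — the resource assesses every drug it catalogs.  A cataloged
  drug with no CYP2 substrate record is a *non-substrate*.  This matches
  catalog-style databases, which document most marketed drugs and therefore
  assess the large majority of any real dataset.
* `LISTED_ONLY` — the resource assesses only the drugs it explicitly lists.
  An unlisted drug is *not assessed*, never a non-substrate.  This matches
  curated substrate lists, which are examples rather than exhaustive
  inventories.

Both policies are available for any snapshot via the `#policy=` pragma; a
user who prefers the pragmatic reading "not listed ⇒ not a substrate" for a
curated list simply declares it `CATALOG`.

## Name resolution cascade

Raw entries from German records are resolved by a fixed cascade, recording
the method used: (1) substance-level ATC code lookup (7-character grammar:
letter, 2 digits, 2 letters, 2 digits; higher-level group codes are skipped
with a logged warning since they do not identify a substance); (2) exact
match of the normalized name; (3) the trailing-'e' heuristic — many German
names are the English name minus a final 'e'; (4) a manual override table;
(5) unresolved.  Normalization lowercases, collapses whitespace, strips
trailing dose tokens (`5mg`, `12,5 mg`, …) and a rule-table of German salt
suffixes (`-tartrat`, `-hydrochlorid`, …).  The dose/salt handling is this
package's design choice: sources for such pipelines rarely state it, and the
rule table keeps it editable.  Only the single-'e' rule is applied by
default; other orthographic bridges (k→c, umlaut folding) are deliberately
out of scope to keep resolution auditable.

Combination products are split on `/`, `+` and ` comb.` before resolution;
each component inherits the case id, and a combination-level ATC code is
attached to all components flagged ambiguous (it is never used for
resolution, since it does not identify a single substance).

Exclusion of unspecific names and food supplements is rule-table driven
(exact names plus ATC prefixes, defaults: vitamins A11, mineral supplements
A12), never hard-coded, and every excluded entry is logged with its rule.

## Frequency threshold for manual assessment

Manual review is limited to drugs documented in at least 3% of cases
(default, configurable).  The fraction is computed over *distinct cases*,
not entries: one multi-drug case should not push a drug over the threshold
by documenting it repeatedly.  The comparison is `case_fraction ≥ threshold`.

## Agreement statistics

Per enzyme, two methods are compared as binary raters over the jointly
assessed drugs.  With the 2×2 table (a both-substrate, b first-only,
c second-only, d neither; n = a+b+c+d):

    p_o = (a + d) / n
    p_e = ((a+b)(a+c) + (c+d)(b+d)) / n²
    κ   = (p_o − p_e) / (1 − p_e)

When p_e = 1 — both raters constant and identical, e.g. neither method
found any substrate — κ is reported as *undefined*, a status rather than a
number or an exception.  No continuity correction, confidence interval or
weighting is applied; the statistic is a point estimate.

A 2×2 table can also be *reconstructed* from published summaries: the
joint-set size, both substrate marginals, and the count of drugs only the
first method called substrate determine all four cells
(`reconstruct_contingency`).  This is how the worked examples rebuild the
published comparisons from the shipped transcription fixtures.

### Qualitative bands

Labels follow the conventional agreement bands, applied to κ rounded to two
decimals, with half-open intervals: `<0` poor, `[0, 0.20)` slight,
`[0.20, 0.41)` fair, `[0.41, 0.61)` moderate, `[0.61, 0.81)` substantial,
`[0.81, 1.00]` almost perfect.  Note one deliberate deviation from the
textbook convention, which places 0.20 in "slight": here the fair band opens
at 0.20, reflecting how these labels are commonly applied to
two-decimal-rounded values in the applied literature this package supports.

### Other reports

* `venn_summary` — per-method assessed-drug sets with all subset
  intersection sizes and exclusive region counts; the inclusion–exclusion
  identity is asserted internally.
* `disagreement_table` — drugs two methods classified differently, ordered
  by entry count in the dataset with entry percentage to one decimal, so
  clinically frequent disagreements surface first.
* `unique_classifications` — drugs called substrate by exactly one method.

## Synthetic data

The restricted clinical dataset and licensed catalog exports behind the
motivating analysis cannot ship, so the generator produces structurally
similar studies with full ground truth.  Defaults (chosen once): 500 cases,
a 200-drug vocabulary, ~7 entries per case (Poisson, matching the ~7.4 of
the motivating dataset), Zipf(1.2) drug popularity, 5% combination rows,
trailing-'e' dropped from 30% of 'e'-ending names, 5% opaque aliases
(covered by the override map), 60% of entries carrying the drug's ATC code.
The vocabulary construction guarantees the trailing-'e' rule is unambiguous
(no name equals another name ± 'e'), so the recoverable subset is exactly
known.  All randomness flows through one seeded `numpy` generator; equal
configs give byte-identical tables.

What the generator does **not** emulate: comorbidity and co-prescription
structure, dosing, ADR causality, brand names, misspellings beyond the two
mutation classes, and within-case repeat documentation (each drug appears at
most once per case, so planted entry and case counts coincide).  Passing the
recovery tests therefore shows the bookkeeping and the cascade are exact
under the stated mutations — not that resolution would be exhaustive on
messy real-world spellings, which is what the override table is for.

## Numerical and degenerate-input choices

* κ is computed in floating point; the test suite proves agreement with an
  exact-rational implementation over every 2×2 table with n ≤ 30.
* Rounding happens only at presentation (2 decimals for κ, 1 for entry
  percentages); internal values are unrounded.
* Empty joint set → error for contingency building (there is nothing to
  compare); undefined κ → status, not error.
* Snapshot duplicate drug rows merge by enzyme-set union with a warning;
  duplicate rows in a manual consensus table are an error.
* Ties in frequency ordering break alphabetically for deterministic output.

## Transcription fixtures

Files under `cypmatch/data/` that transcribe published comparison tables
(joint-set marginals, per-drug disagreement lists) and substrate-list
excerpts are limited to drugs those tables name, plus clearly marked
synthetic padding; they exist so examples and tests run without restricted
or licensed data, and are not usable as substrate references in a real
analysis.  Two published comparisons (the Flockhart CYP2D6 and CYP2C19
kappas) are internally inconsistent between the source summary tables and
their disagreement lists; their tables are omitted from reconstruction
rather than guessed.  One published disagreement row, "(dex)ibuprofen", is
encoded as two drugs (ibuprofen, dexibuprofen) — the only reading consistent
with the published CYP2C19 marginal.

## Limitations

Point-estimate κ only (no CIs, no multi-rater statistics); name matching is
exact after normalization (no fuzzy or phonetic matching); inhibitor and
inducer classification is an extension point, not implemented; the shipped
name index and rules are starters, not references — real analyses supply
their own index, overrides and licensed resource snapshots.
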