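# cypmatch

Classify the drugs in a medication-list dataset as substrates of the
polymorphic cytochrome P450 enzymes **CYP2D6, CYP2C9 and CYP2C19**, and
quantify how well different classification methods agree.

Pharmacovigilance datasets — here, German emergency-department adverse-drug-
reaction cases — document drug use as free-text substance names (often
German, often combination products) with optional ATC codes.  Analysing
drug–drug–gene interactions in such data needs every drug labelled, per
enzyme, as substrate / non-substrate / not assessed.  `cypmatch` provides
the full pipeline:

1. **normalize** — read the entry table, split combination products
   (`hydrochlorothiazide/ramipril` → two entries), resolve raw names to
   canonical English names via a fixed cascade (substance-level ATC code →
   exact name → trailing-'e' heuristic → manual override), clean unspecific
   names and food supplements by rule table, and aggregate per-drug entry
   and distinct-case counts;
2. **classify** — build a drug × method × enzyme tri-state matrix from any
   number of substrate resources (snapshot TSVs or a minimal Drugbank-style
   XML dialect) plus a curated manual consensus table, with each resource's
   coverage semantics (`CATALOG` vs `LISTED_ONLY`) made explicit;
3. **compare** — over the drugs jointly assessed by two methods, per enzyme:
   2×2 contingency tables, Cohen's kappa

   κ = (p_o − p_e)/(1 − p_e),  p_o = (a+d)/n,  p_e = ((a+b)(a+c)+(c+d)(b+d))/n²

   with qualitative bands (slight / fair / moderate / substantial / almost
   perfect), Venn summaries of assessed sets, and disagreement tables
   weighted by how often each drug occurs in the dataset.

A seeded synthetic generator emulates the dataset structure (Zipf-like drug
frequencies, combination rows, German spellings) with full ground truth, so
every stage is testable without restricted clinical data or licensed
database exports.

## Worked example

Rebuild the manual-vs-automatic agreement tables from the transcription
fixtures shipped with the package and compute their kappas
(`python examples/kappa_worked_examples.py`):

```
resource   enzyme     a   b   c   d    n  kappa  band
drugbank   CYP2C19    7   1   4  88  100   0.71  substantial
drugbank   CYP2C9     6   0  11  83  100   0.48  moderate
drugbank   CYP2D6     9   0   3  88  100   0.84  almost perfect
fda        CYP2C19    1   2   0   9   12   0.43  moderate
fda        CYP2C9     0   0   0  12   12    -    (undefined: no substrates on either side)
fda        CYP2D6     1   2   0   9   12   0.43  moderate
flockhart  CYP2C9     1   1   4  20   26   0.20  fair
```

Each row is one manual-vs-resource comparison for one enzyme: `a` drugs
called substrate by both methods, `b` by the manual method only, `c` by the
automatic method only, `d` by neither, over the `n` drugs both methods
assessed.  Manual vs the catalog-style resource agrees almost perfectly on
CYP2D6 (κ = 0.84) but only moderately on CYP2C9 (κ = 0.48), where the
automatic route calls many more substrates; when neither method finds any
substrate (FDA/CYP2C9), κ is undefined and reported as a status.

Other examples: `examples/synthetic_pipeline.py` (generate → resolve →
aggregate → frequent-drug selection, with exact ground-truth recovery) and
`examples/resource_lookup.py` (coverage policies and the XML dialect).

## Command line

```sh
cypmatch simulate --seed 1 -o study/                 # synthetic study + truth
cypmatch normalize -i study/medication.csv \
    --atc-index study/atc_index.tsv --names study/names.txt \
    --overrides study/overrides.tsv -o norm/
cypmatch classify -r norm/records.csv \
    --resource fda=src/cypmatch/data/fda_substrates.tsv \
    --manual src/cypmatch/data/manual_assessment.tsv -o cls/
cypmatch compare -m cls/matrix.csv -r norm/records.csv -o reports/
```

## Layout

- `src/cypmatch/` — library: `medication_dataset`, `name_resolution`,
  `substrate_resources`, `classification`, `agreement`, `synthetic`,
  `datafiles`, `cli`
- `src/cypmatch/data/` — transcription fixtures and starter rule tables
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, parameters, design choices, limitations
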