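"""Full preparation pipeline on a synthetic German-style medication table.

Generates a 200-case study (combination products, dropped trailing 'e's,
opaque aliases), then runs read -> split -> resolve -> aggregate -> select,
and checks the recovered counts against the generator's ground truth.
"""

from collections import Counter

from cypmatch.medication_dataset import (
    MedicationEntry,
    aggregate_drugs,
    select_frequent_drugs,
    split_combination,
)
from cypmatch.name_resolution import resolve
from cypmatch.synthetic import GeneratorConfig, generate_dataset

config = GeneratorConfig(seed=7, n_cases=200, n_drugs=120)
frame, truth = generate_dataset(config)
print(f"generated {len(frame)} rows across {config.n_cases} cases "
      f"({config.n_drugs}-drug vocabulary)")

entries = []
for i, row in enumerate(frame.itertuples(index=False), start=2):
    entry = MedicationEntry(row.case_id, row.name, row.atc or None, source_row=i)
    entries.extend(split_combination(entry))
print(f"{len(entries)} entries after splitting combination products")

index = truth.name_index()
resolutions = {
    e.raw_name: resolve(e.raw_name, None if e.atc_ambiguous else e.atc_code,
                        index, truth.overrides)
    for e in entries
}
methods = Counter(r.method for r in resolutions.values())
print("resolution methods over distinct raw spellings:",
      dict(sorted(methods.items())))

records, summary = aggregate_drugs(entries, resolutions)
assert {r.canonical_name: r.entry_count for r in records} == truth.entry_counts
print(f"aggregated {summary.n_drugs_final} drugs; planted per-drug entry and "
      "case counts recovered exactly")

frequent = select_frequent_drugs(records, 0.03)
assert sorted(r.canonical_name for r in frequent) == truth.frequent_drugs
print(f"{len(frequent)} drugs occur in >=3% of cases (eligible for manual "
      "review); top 3 by entries:")
for r in frequent[:3]:
    print(f"  {r.canonical_name:<16} {r.entry_count:>4} entries in "
          f"{r.case_count} cases ({100 * r.case_fraction:.1f}% of cases)")
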