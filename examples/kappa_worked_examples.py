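"""Rebuild the published manual-vs-automatic agreement tables and their kappas.

Each comparison's 2x2 table is uniquely determined by the joint-set
marginals plus the list of drugs only the manual method called substrate;
both ship with the package as transcription fixtures.  The table is planted
as two classification vectors, tallied back by the pipeline, and summarized
with Cohen's kappa and its qualitative band.
"""

from cypmatch import datafiles
from cypmatch.agreement import build_contingency, cohens_kappa
from cypmatch.synthetic import plant_matrix

print(f"{'resource':<10} {'enzyme':<8} {'a':>3} {'b':>3} {'c':>3} {'d':>3}"
      f" {'n':>4}  kappa  band")
for (resource, enzyme), table in sorted(datafiles.reconstructed_tables().items()):
    matrix = plant_matrix(table.a, table.b, table.c, table.d, enzyme=enzyme, seed=0)
    result = cohens_kappa(build_contingency(matrix, "METHOD_A", "METHOD_B", enzyme))
    kappa = "  -  " if not result.defined else f"{result.kappa_rounded:5.2f}"
    band = "(undefined: no substrates on either side)" if not result.defined else result.band
    print(f"{resource:<10} {enzyme:<8} {table.a:>3} {table.b:>3} {table.c:>3}"
          f" {table.d:>3} {table.n:>4}  {kappa}  {band}")

print()
print("a = substrate by both methods, b = manual only, c = automatic only,")
print("d = neither; kappa is chance-corrected agreement over the n jointly")
print("assessed drugs, banded slight/fair/moderate/substantial/almost perfect.")
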