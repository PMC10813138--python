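"""Tri-state substrate lookups under the two coverage policies.

A curated substrate list (LISTED_ONLY) says nothing about drugs it does not
list, while a catalog-style database (CATALOG) assesses every cataloged drug
— absence of a CYP2 record then means non-substrate.  That difference
decides which drugs count as jointly assessed when methods are compared.
"""

from cypmatch import datafiles
from cypmatch.substrate_resources import (
    CoveragePolicy,
    SubstrateResource,
    parse_drugbank_xml_dialect,
)

fda = datafiles.load_fda_fixture()
flockhart = datafiles.load_flockhart_fixture()

queries = [
    ("pantoprazole", "CYP2C19"),   # widely used, absent from the FDA examples
    ("metoprolol", "CYP2D6"),
    ("metoprolol", "CYP2C9"),
    ("losartan", "CYP2C9"),        # listed by the Flockhart-style table only
    ("valsartan", "CYP2C9"),
]
print(f"{'drug':<14} {'enzyme':<8} {'FDA':<14} Flockhart")
for drug, enzyme in queries:
    print(f"{drug:<14} {enzyme:<8} {fda.lookup(drug, enzyme).value:<14} "
          f"{flockhart.lookup(drug, enzyme).value}")

print()
print("Drugbank-dialect XML -> CATALOG resource: a drug with only inhibitor")
print("records stays cataloged, so it reads non_substrate, not not_assessed:")
xml = """<drugbank>
  <drug><name>Fluoxetine</name>
    <enzymes><enzyme><name>Cytochrome P450 2D6</name>
      <actions><action>inhibitor</action></actions></enzyme></enzymes>
  </drug>
</drugbank>"""
import tempfile, pathlib
with tempfile.TemporaryDirectory() as tmp:
    path = pathlib.Path(tmp) / "mini.xml"
    path.write_text(xml)
    rows = parse_drugbank_xml_dialect(path)
catalog = SubstrateResource.from_rows("drugbank_mini", rows, CoveragePolicy.CATALOG)
print(f"  fluoxetine/CYP2D6 -> {catalog.lookup('fluoxetine', 'CYP2D6').value}")
print(f"  unlisted drug     -> {catalog.lookup('tilidine', 'CYP2D6').value}")
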