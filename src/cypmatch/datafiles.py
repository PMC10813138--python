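"""Loaders for the data files shipped with the package.

Two kinds of files live under ``cypmatch/data``:

* transcription fixtures — rows copied from published comparison tables
  (joint-assessment marginals, per-drug disagreement lists, the drugs whose
  manual verdicts are documented) and substrate-list excerpts restricted to
  drugs those tables name.  They let worked examples and tests run without
  the restricted clinical dataset or any licensed database export;
* small reference tables — a starter English name index, cleaning rules.

Full, licensed resource exports plug into the exact same snapshot format at
run time; nothing here is a substitute for them in a real analysis.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .agreement import ContingencyTable2x2, reconstruct_contingency
from .classification import ManualAssessmentTable, load_manual_table
from .medication_dataset import ExclusionRules
from .name_resolution import NameIndex
from .substrate_resources import SubstrateResource, load_snapshot

_DATA = resources.files("cypmatch") / "data"


def data_path(filename: str) -> Path:
    """Filesystem path of a shipped data file."""
    path = Path(str(_DATA / filename))
    if not path.exists():
        raise FileNotFoundError(f"no shipped data file {filename!r}")
    return path


def load_joint_marginals() -> pd.DataFrame:
    """Published marginals: resource, enzyme, n_joint, per-method substrate counts."""
    return pd.read_csv(data_path("joint_marginals.tsv"), sep="\t", comment="#")


def load_disagreements() -> pd.DataFrame:
    """Published per-drug classification differences (manual vs each resource)."""
    df = pd.read_csv(
        data_path("disagreements.tsv"), sep="\t", comment="#", keep_default_na=False
    )
    return df


def manual_only_count(disagreements: pd.DataFrame, enzyme: str, resource: str) -> int:
    """Drugs the manual method alone called substrate, vs one resource.

    Counts rows where the manual flag is ``x`` and the resource assessed the
    drug as a non-substrate (``-``); ``NA`` rows are outside the joint set.
    """
    sub = disagreements[disagreements["enzyme"] == enzyme]
    return int(((sub["manual"] == "x") & (sub[resource] == "-")).sum())


def reconstructed_tables() -> dict[tuple[str, str], ContingencyTable2x2]:
    """All 2×2 agreement tables derivable from the shipped transcriptions.

    For each (resource, enzyme) pair the joint-set marginals fix the row and
    column sums; the disagreement list fixes the manual-only cell; together
    the table is unique.  Pairs whose published statistics are mutually
    inconsistent across the source tables are omitted (the Flockhart CYP2D6
    and CYP2C19 comparisons).
    """
    marginals = load_joint_marginals()
    disagreements = load_disagreements()
    out: dict[tuple[str, str], ContingencyTable2x2] = {}
    skip = {("flockhart", "CYP2D6"), ("flockhart", "CYP2C19")}
    for row in marginals.itertuples(index=False):
        key = (row.resource, row.enzyme)
        if key in skip:
            continue
        out[key] = reconstruct_contingency(
            n=int(row.n_joint),
            marginal_a=int(row.manual_substrates),
            marginal_b=int(row.automatic_substrates),
            a_only=manual_only_count(disagreements, row.enzyme, row.resource),
        )
    return out


def load_fda_fixture() -> SubstrateResource:
    """FDA clinical-substrate examples, transcription-limited, LISTED_ONLY."""
    return load_snapshot(data_path("fda_substrates.tsv"))


def load_flockhart_fixture() -> SubstrateResource:
    """Flockhart-style substrate rows, transcription-limited, LISTED_ONLY."""
    return load_snapshot(data_path("flockhart_substrates.tsv"))


def load_manual_fixture() -> ManualAssessmentTable:
    """Manual consensus flags for the drugs with documented verdicts."""
    return load_manual_table(data_path("manual_assessment.tsv"))


def load_default_exclusions() -> ExclusionRules:
    """Default cleaning rules (unspecific names, supplement ATC groups)."""
    return ExclusionRules.from_file(data_path("exclusion_rules.tsv"))


def load_starter_index() -> NameIndex:
    """Small English name index covering the drugs in the shipped fixtures."""
    return NameIndex.from_files(
        data_path("name_index_atc.tsv"), data_path("name_index_names.txt")
    )
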