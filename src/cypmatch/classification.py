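"""Build the drug × method × enzyme tri-state classification matrix.

Each *method* is one way of deciding substrate status: the manual
literature-review consensus (ingested as a curated table) or an automatic
match against a substrate resource.  The matrix records, for every drug,
method and enzyme, one of substrate / non-substrate / not-assessed, and is
the single input to all downstream agreement statistics.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .medication_dataset import DrugRecord
from .substrate_resources import DEFAULT_ENZYMES, SubstrateResource, TriState, lookup

logger = logging.getLogger(__name__)


@dataclass
class ManualAssessmentTable:
    """Curated per-drug substrate flags established by human reviewers.

    The review process (independent reviewers, consensus on disagreement) is
    upstream of this package; here it is data with optional provenance
    columns (reviewer ids, consensus flag).
    """

    flags: dict[str, frozenset[str]]  # canonical name -> substrate enzymes
    enzymes: tuple[str, ...] = DEFAULT_ENZYMES
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def drugs(self) -> set[str]:
        return set(self.flags)


def load_manual_table(
    path: str | Path,
    *,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> ManualAssessmentTable:
    """Read a manual-assessment TSV: ``name`` plus one boolean column per enzyme.

    Duplicate drug rows are an error (a consensus table has one verdict per
    drug); a missing enzyme column is an error naming the column.
    """
    path = Path(path)
    flags: dict[str, frozenset[str]] = {}
    provenance: dict[str, dict[str, str]] = {}
    with path.open(encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty manual table")
    header = [c.strip() for c in lines[0].rstrip("\n").split("\t")]
    if "name" not in header:
        raise ValueError(f"{path}: missing mandatory column 'name'")
    for enzyme in enzymes:
        if enzyme not in header:
            raise ValueError(f"{path}: missing enzyme column {enzyme!r}")
    extra_cols = [c for c in header if c != "name" and c not in enzymes]
    for line in lines[1:]:
        row = dict(zip(header, line.rstrip("\n").split("\t")))
        name = row["name"].strip().lower()
        if name in flags:
            raise ValueError(f"{path}: duplicate row for drug {name!r}")
        flags[name] = frozenset(
            e for e in enzymes if row.get(e, "").strip().lower() in {"1", "x", "true", "yes"}
        )
        if extra_cols:
            provenance[name] = {c: row.get(c, "") for c in extra_cols}
    return ManualAssessmentTable(flags=flags, enzymes=tuple(enzymes), provenance=provenance)


@dataclass
class ClassificationMatrix:
    """Tri-state assessments for every (drug, method, enzyme) triple.

    Missing triples read as NOT_ASSESSED, which keeps the mapping total over
    any drug/method pair ever added.
    """

    drugs: list[str]
    enzymes: tuple[str, ...] = DEFAULT_ENZYMES
    methods: list[str] = field(default_factory=list)
    _states: dict[tuple[str, str, str], TriState] = field(default_factory=dict)
    records: dict[str, DrugRecord] = field(default_factory=dict)

    def state(self, drug: str, method: str, enzyme: str) -> TriState:
        if method not in self.methods:
            raise KeyError(f"unknown method {method!r}; have {self.methods}")
        if enzyme not in self.enzymes:
            raise KeyError(f"unknown enzyme {enzyme!r}; have {self.enzymes}")
        return self._states.get((drug, method, enzyme), TriState.NOT_ASSESSED)

    def set_state(self, drug: str, method: str, enzyme: str, state: TriState) -> None:
        if method not in self.methods:
            self.methods.append(method)
        if drug not in self.drugs:
            self.drugs.append(drug)
        self._states[(drug, method, enzyme)] = state

    def add_method(
        self, method: str, states: Mapping[tuple[str, str], TriState]
    ) -> None:
        """Bulk-add one method's slice: ``{(drug, enzyme): TriState}``."""
        if method in self.methods:
            raise ValueError(f"method {method!r} already present")
        self.methods.append(method)
        for (drug, enzyme), state in states.items():
            if drug not in self.drugs:
                self.drugs.append(drug)
            self._states[(drug, method, enzyme)] = state

    def assessed_drugs(self, method: str) -> set[str]:
        """Drugs with at least one substrate / non-substrate call by ``method``."""
        if method not in self.methods:
            raise KeyError(f"unknown method {method!r}; have {self.methods}")
        return {
            drug
            for drug in self.drugs
            if any(
                self.state(drug, method, e) is not TriState.NOT_ASSESSED
                for e in self.enzymes
            )
        }

    def substrate_count(self, method: str, enzyme: str) -> int:
        return sum(
            1
            for drug in self.drugs
            if self.state(drug, method, enzyme) is TriState.SUBSTRATE
        )

    def counts_summary(self) -> dict:
        """Per-method assessed counts and per-enzyme substrate counts."""
        return {
            method: {
                "assessed": len(self.assessed_drugs(method)),
                "substrates": {
                    enzyme: self.substrate_count(method, enzyme)
                    for enzyme in self.enzymes
                },
            }
            for method in self.methods
        }

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (drug, method, enzyme)."""
        rows = [
            {
                "drug": drug,
                "method": method,
                "enzyme": enzyme,
                "state": self.state(drug, method, enzyme).value,
            }
            for drug in self.drugs
            for method in self.methods
            for enzyme in self.enzymes
        ]
        return pd.DataFrame(rows, columns=["drug", "method", "enzyme", "state"])

    def to_wide_frame(self, enzyme: str) -> pd.DataFrame:
        """Wide per-enzyme export: one row per drug, one column per method."""
        long = self.to_long_frame()
        sub = long[long["enzyme"] == enzyme]
        return sub.pivot(index="drug", columns="method", values="state").reset_index()

    @classmethod
    def from_long_frame(
        cls,
        frame: pd.DataFrame,
        *,
        records: Mapping[str, DrugRecord] | None = None,
    ) -> "ClassificationMatrix":
        enzymes = tuple(dict.fromkeys(frame["enzyme"]))
        matrix = cls(drugs=list(dict.fromkeys(frame["drug"])), enzymes=enzymes)
        matrix.methods = list(dict.fromkeys(frame["method"]))
        for row in frame.itertuples(index=False):
            matrix._states[(row.drug, row.method, row.enzyme)] = TriState(row.state)
        if records:
            matrix.records = dict(records)
        return matrix


def classify_automatic(
    drugs: Iterable[str | DrugRecord],
    resource: SubstrateResource,
    *,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> dict[tuple[str, str], TriState]:
    """Classify each drug against one resource; returns a matrix slice.

    Unresolved drugs (records flagged as never resolved to a canonical
    English name) cannot be matched and are NOT_ASSESSED with a warning.
    The operation is per-drug idempotent and order-independent.
    """
    slice_: dict[tuple[str, str], TriState] = {}
    for drug in drugs:
        if isinstance(drug, DrugRecord):
            name, resolved = drug.canonical_name, drug.resolved
        else:
            name, resolved = drug, True
        for enzyme in enzymes:
            if not resolved:
                slice_[(name, enzyme)] = TriState.NOT_ASSESSED
            else:
                slice_[(name, enzyme)] = lookup(resource, name, enzyme)
        if not resolved:
            logger.warning(
                "drug %r was never resolved to a canonical name; not assessed", name
            )
    return slice_


def classify_manual(
    drugs: Iterable[str | DrugRecord],
    table: ManualAssessmentTable,
    *,
    eligible: Iterable[str] | None = None,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> dict[tuple[str, str], TriState]:
    """Matrix slice for the manual method.

    ``eligible`` restricts assessment to the frequent-drug subset the manual
    review actually covered (drugs below the selection threshold stay
    NOT_ASSESSED even if the curated table happens to mention them).
    """
    eligible_set = None if eligible is None else {e.lower() for e in eligible}
    slice_: dict[tuple[str, str], TriState] = {}
    for drug in drugs:
        name = drug.canonical_name if isinstance(drug, DrugRecord) else drug
        assessed = name in table.flags and (eligible_set is None or name in eligible_set)
        for enzyme in enzymes:
            if not assessed:
                slice_[(name, enzyme)] = TriState.NOT_ASSESSED
            elif enzyme in table.flags[name]:
                slice_[(name, enzyme)] = TriState.SUBSTRATE
            else:
                slice_[(name, enzyme)] = TriState.NON_SUBSTRATE
    return slice_


@dataclass(frozen=True)
class UniqueClassification:
    drug: str
    method: str
    enzyme: str


def unique_classifications(
    matrix: ClassificationMatrix, enzyme: str
) -> list[UniqueClassification]:
    """Drugs called substrate by exactly one method for ``enzyme``.

    All other methods must say non-substrate or not-assessed; these rows are
    where methods genuinely disagree in what they add, e.g. a drug only the
    manual review recognizes as a substrate.
    """
    if len(matrix.methods) < 2:
        raise ValueError("unique classifications need at least two methods")
    out: list[UniqueClassification] = []
    for drug in matrix.drugs:
        callers = [
            m
            for m in matrix.methods
            if matrix.state(drug, m, enzyme) is TriState.SUBSTRATE
        ]
        if len(callers) == 1:
            out.append(UniqueClassification(drug=drug, method=callers[0], enzyme=enzyme))
    return out


def write_matrix_csv(matrix: ClassificationMatrix, path: str | Path) -> None:
    matrix.to_long_frame().to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> ClassificationMatrix:
    return ClassificationMatrix.from_long_frame(pd.read_csv(path))
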