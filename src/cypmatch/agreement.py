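"""Inter-method agreement on substrate classification.

Two classification methods are compared per enzyme as binary raters
(substrate vs non-substrate) over the *jointly assessed* drug set — drugs
either method left unassessed never enter a contingency cell.  Agreement is
quantified with Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where p_o = (a+d)/n is the observed agreement of the 2×2 table
(a both-substrate, b first-method-only, c second-method-only, d neither) and
p_e = ((a+b)(a+c) + (c+d)(b+d)) / n² the agreement expected from the
marginals alone.  When p_e = 1 (both raters constant and identical) kappa
is undefined and reported as such, not as a number.

Qualitative interpretation follows the conventional agreement bands
(slight / fair / moderate / substantial / almost perfect), applied to kappa
rounded to two decimals; see :func:`band` for the exact boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

from .medication_dataset import DrugRecord
from .classification import ClassificationMatrix
from .substrate_resources import TriState


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts over the jointly assessed drugs for one enzyme and method pair."""

    a: int  # substrate by both methods
    b: int  # substrate by method A only
    c: int  # substrate by method B only
    d: int  # substrate by neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n < 1:
            raise ValueError("contingency table needs at least one jointly assessed drug")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped_methods(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its ingredients and qualitative band."""

    kappa: float | None
    p_observed: float
    p_expected: float
    n: int

    @property
    def defined(self) -> bool:
        return self.kappa is not None

    @property
    def kappa_rounded(self) -> float | None:
        return None if self.kappa is None else round(self.kappa, 2)

    @property
    def band(self) -> str | None:
        return None if self.kappa is None else band(self.kappa_rounded)


def cohens_kappa(table: ContingencyTable2x2) -> KappaResult:
    """Chance-corrected agreement for a 2×2 table.

    Undefined (``kappa=None``) exactly when the expected agreement is 1,
    i.e. both methods gave the same constant verdict for every drug; the
    observed agreement is then uninformative about rater behaviour.
    """
    n = table.n
    p_o = (table.a + table.d) / n
    p_e = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / (n * n)
    if p_e == 1.0:
        return KappaResult(kappa=None, p_observed=p_o, p_expected=p_e, n=n)
    return KappaResult(
        kappa=(p_o - p_e) / (1.0 - p_e), p_observed=p_o, p_expected=p_e, n=n
    )


#: Half-open agreement bands applied to kappa rounded to 2 decimals.  The
#: fair band opens at 0.20 (the textbook convention opens it at 0.21 on
#: unrounded kappa); see the methods note for why this boundary is used.
_BANDS: tuple[tuple[float, str], ...] = (
    (0.00, "poor"),
    (0.20, "slight"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (1.00 + 1e-12, "almost perfect"),
)


def band(kappa_rounded: float) -> str:
    """Qualitative label for a kappa value already rounded to two decimals."""
    if not -1.0 <= kappa_rounded <= 1.0:
        raise ValueError(f"kappa {kappa_rounded} outside [-1, 1]")
    for upper, label in _BANDS:
        if kappa_rounded < upper:
            return label
    return "almost perfect"


def jointly_assessed(
    matrix: ClassificationMatrix, method_a: str, method_b: str
) -> set[str]:
    """Drugs assessed (substrate or non-substrate) by both methods."""
    return matrix.assessed_drugs(method_a) & matrix.assessed_drugs(method_b)


def build_contingency(
    matrix: ClassificationMatrix,
    method_a: str,
    method_b: str,
    enzyme: str,
) -> ContingencyTable2x2:
    """Tally the 2×2 substrate agreement table over the joint set.

    Raises ``ValueError`` on an empty joint set: with no drug assessed by
    both methods there is no agreement to measure.
    """
    joint = jointly_assessed(matrix, method_a, method_b)
    if not joint:
        raise ValueError(
            f"no drugs jointly assessed by {method_a!r} and {method_b!r}"
        )
    a = b = c = d = 0
    for drug in joint:
        sa = matrix.state(drug, method_a, enzyme) is TriState.SUBSTRATE
        sb = matrix.state(drug, method_b, enzyme) is TriState.SUBSTRATE
        if sa and sb:
            a += 1
        elif sa:
            b += 1
        elif sb:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def reconstruct_contingency(
    n: int, marginal_a: int, marginal_b: int, a_only: int
) -> ContingencyTable2x2:
    """Derive a 2×2 table from published marginals plus one off-diagonal cell.

    Given the joint-set size, each method's substrate marginal, and the
    number of drugs called substrate by method A only (the disagreement rows
    typically published alongside), the table is uniquely determined:
    a = marginal_a − b, c = marginal_b − a, d = n − a − b − c.
    """
    b = a_only
    a = marginal_a - b
    c = marginal_b - a
    d = n - a - b - c
    return ContingencyTable2x2(a, b, c, d)


@dataclass
class VennSummary:
    """Per-method assessed-drug sets and every subset-intersection size."""

    assessed: dict[str, frozenset[str]]

    def intersection_size(self, *methods: str) -> int:
        if not methods:
            raise ValueError("need at least one method")
        sets = [self.assessed[m] for m in methods]
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return len(out)

    def region_counts(self) -> dict[str, int]:
        """Exclusive Venn regions keyed by '+'-joined member methods."""
        methods = list(self.assessed)
        universe = set().union(*self.assessed.values()) if methods else set()
        regions: dict[str, int] = {}
        for mask in range(1, 2 ** len(methods)):
            members = [m for i, m in enumerate(methods) if mask >> i & 1]
            region = set(universe)
            for i, m in enumerate(methods):
                if mask >> i & 1:
                    region &= self.assessed[m]
                else:
                    region -= self.assessed[m]
            regions["+".join(members)] = len(region)
        return regions

    def to_json(self) -> str:
        payload = {
            "assessed_counts": {m: len(s) for m, s in self.assessed.items()},
            "pairwise_intersections": {
                f"{a}&{b}": self.intersection_size(a, b)
                for i, a in enumerate(self.assessed)
                for b in list(self.assessed)[i + 1 :]
            },
            "exclusive_regions": self.region_counts(),
        }
        return json.dumps(payload, indent=2)


def venn_summary(matrix: ClassificationMatrix) -> VennSummary:
    """Assessed-set sizes and intersections across all methods.

    The exclusive region counts satisfy inclusion–exclusion by construction;
    an internal check asserts the per-method totals recompose exactly.
    """
    if len(matrix.methods) < 1:
        raise ValueError("venn summary needs at least one method")
    summary = VennSummary(
        assessed={m: frozenset(matrix.assessed_drugs(m)) for m in matrix.methods}
    )
    regions = summary.region_counts()
    for method in matrix.methods:
        total = sum(
            count
            for key, count in regions.items()
            if method in key.split("+")
        )
        assert total == len(summary.assessed[method])
    return summary


@dataclass(frozen=True)
class DisagreementRow:
    """One drug two methods assessed but classified differently."""

    enzyme: str
    drug: str
    states: tuple[tuple[str, str], ...]  # (method, TriState value) pairs
    entry_count: int
    entry_percent: float


def disagreement_table(
    matrix: ClassificationMatrix,
    method_a: str,
    method_b: str,
    enzyme: str,
    records: Mapping[str, DrugRecord] | Mapping[str, int],
    total_entries: int,
    *,
    extra_methods: Sequence[str] = (),
) -> list[DisagreementRow]:
    """Drugs the two methods classify differently, weighted by dataset use.

    Rows are drugs both methods assessed whose substrate / non-substrate
    calls differ, ordered by how often the drug appears in the medication
    dataset (entry count descending) — a disagreement about a drug in 4% of
    entries matters more in practice than one about a drug seen twice.
    ``extra_methods`` adds informational columns (including NOT_ASSESSED)
    without influencing row selection.
    """
    rows: list[DisagreementRow] = []
    shown_methods = [method_a, method_b, *extra_methods]
    for drug in sorted(jointly_assessed(matrix, method_a, method_b)):
        state_a = matrix.state(drug, method_a, enzyme)
        state_b = matrix.state(drug, method_b, enzyme)
        if state_a is state_b:
            continue
        try:
            record = records[drug]
        except KeyError as exc:
            raise ValueError(f"drug {drug!r} has no entry count") from exc
        entry_count = record.entry_count if isinstance(record, DrugRecord) else int(record)
        rows.append(
            DisagreementRow(
                enzyme=enzyme,
                drug=drug,
                states=tuple(
                    (m, matrix.state(drug, m, enzyme).value) for m in shown_methods
                ),
                entry_count=entry_count,
                entry_percent=round(100.0 * entry_count / total_entries, 1),
            )
        )
    rows.sort(key=lambda r: (-r.entry_count, r.drug))
    return rows
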