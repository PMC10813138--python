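"""Synthetic medication datasets and planted classification fixtures.

The restricted clinical dataset and the licensed substrate database behind
the motivating analysis cannot ship with the package, so every pipeline
stage is exercised on generated data with recorded ground truth instead.
The generator emulates the *structure* of a German emergency-department
medication dataset: a few thousand case-level drug documentations, drug
popularity following a Zipf-like law, occasional combination products
joined with '/', and German raw spellings produced by dropping the trailing
'e' of the English name or by an opaque alias.  It makes no attempt at
clinical realism (no comorbidity structure, no dosing, no ADR causality).

All randomness flows through one ``numpy`` generator seeded from the
config; identical configs give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import ClassificationMatrix
from .name_resolution import NameIndex, ResolutionMethod
from .substrate_resources import (
    DEFAULT_ENZYMES,
    CoveragePolicy,
    SnapshotRow,
    SubstrateResource,
    TriState,
)

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"
_ATC_LETTERS = "ABCDGHJLMNPRSV"


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic dataset; defaults emulate the study structure.

    ``n_cases``/``n_drugs`` default to a desk-scale dataset (500 cases of a
    vocabulary of 200 drugs, ~7 entries per case, mirroring the ~7.4
    entries/case of the motivating dataset); ``zipf_exponent`` shapes the
    heavy-tailed drug popularity; ``combo_rate`` is the fraction of rows
    documenting a two-drug combination product; ``drop_e_rate`` and
    ``alias_rate`` control how raw German spellings deviate from the
    canonical English names.
    """

    seed: int
    n_cases: int = 500
    n_drugs: int = 200
    zipf_exponent: float = 1.2
    mean_entries_per_case: float = 7.0
    combo_rate: float = 0.05
    drop_e_rate: float = 0.3
    alias_rate: float = 0.05
    atc_rate: float = 0.6  # probability an entry carries its drug's ATC code
    frac_names_end_e: float = 0.45
    resource_coverage: float = 0.8
    substrate_rate: float = 0.15
    enzymes: tuple[str, ...] = DEFAULT_ENZYMES

    def __post_init__(self) -> None:
        for name in (
            "combo_rate",
            "drop_e_rate",
            "alias_rate",
            "atc_rate",
            "frac_names_end_e",
            "resource_coverage",
            "substrate_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.combo_rate > 0 and self.n_drugs < 2:
            raise ValueError("combination rows need at least two drugs")
        if self.n_cases < 1 or self.n_drugs < 1:
            raise ValueError("n_cases and n_drugs must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    canonical_names: list[str]
    raw_spellings: dict[str, str]  # canonical -> documented raw form
    spelling_class: dict[str, str]  # canonical -> EXACT | E_DROP | ALIAS
    atc_codes: dict[str, str]  # canonical -> substance-level ATC
    entry_counts: dict[str, int]
    case_counts: dict[str, int]
    n_cases: int
    n_rows: int
    n_entries: int  # after combination splitting
    frequent_threshold: float = 0.03
    frequent_drugs: list[str] = field(default_factory=list)
    e_recoverable: list[str] = field(default_factory=list)
    overrides: dict[str, str] = field(default_factory=dict)
    substrate_truth: dict[str, list[str]] = field(default_factory=dict)
    covered_drugs: list[str] = field(default_factory=list)

    def name_index(self) -> NameIndex:
        return NameIndex(
            atc_to_name={atc: name for name, atc in self.atc_codes.items()},
            name_set=set(self.canonical_names),
        )

    def expected_method(self, canonical: str, entry_has_atc: bool) -> str:
        """Resolution method the cascade must report for this drug's raw form."""
        if entry_has_atc:
            return ResolutionMethod.ATC
        return {
            "EXACT": ResolutionMethod.EXACT,
            "E_DROP": ResolutionMethod.E_SUFFIX,
            "ALIAS": ResolutionMethod.OVERRIDE,
        }[self.spelling_class[canonical]]

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2)


def _make_vocabulary(rng: np.random.Generator, config: GeneratorConfig) -> list[str]:
    """Unique pronounceable names; no name equals another name plus 'e'."""
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < config.n_drugs:
        n_syll = int(rng.integers(3, 5))
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if rng.random() < config.frac_names_end_e:
            if not word.endswith("e"):
                word = word[:-1] + "ne"
        elif word.endswith("e"):
            word = word[:-1] + "ol"
        # keep the trailing-'e' heuristic unambiguous on the fixture
        if word in seen or word + "e" in seen or (word.endswith("e") and word[:-1] in seen):
            continue
        seen.add(word)
        names.append(word)
    return names


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a raw medication table plus full ground truth.

    Returns a DataFrame with columns ``case_id``, ``name``, ``atc`` (one row
    per documented product, combinations joined with '/') and the
    :class:`GroundTruth` recording canonical names, per-drug counts, the
    frequent subset at the 3% case threshold, which raw spellings the
    trailing-'e' rule can recover, and the override map for aliases.
    """
    rng = np.random.default_rng(config.seed)
    canonical = _make_vocabulary(rng, config)

    atc_codes = {
        name: (
            _ATC_LETTERS[i % len(_ATC_LETTERS)]
            + f"{(i // len(_ATC_LETTERS)) % 100:02d}"
            + "XX"
            + f"{i % 100:02d}"
        )
        for i, name in enumerate(canonical)
    }
    raw: dict[str, str] = {}
    spelling_class: dict[str, str] = {}
    overrides: dict[str, str] = {}
    for name in canonical:
        u = rng.random()
        if name.endswith("e") and u < config.drop_e_rate:
            raw[name] = name[:-1]
            spelling_class[name] = "E_DROP"
        elif rng.random() < config.alias_rate:
            alias = name[::-1] + "ix"  # opaque alias no orthographic rule bridges
            raw[name] = alias
            spelling_class[name] = "ALIAS"
            overrides[alias] = name
        else:
            raw[name] = name.capitalize()
            spelling_class[name] = "EXACT"

    weights = 1.0 / np.arange(1, config.n_drugs + 1) ** config.zipf_exponent
    weights /= weights.sum()

    rows: list[dict] = []
    entry_counts: dict[str, int] = {n: 0 for n in canonical}
    case_sets: dict[str, set[str]] = {n: set() for n in canonical}
    n_entries = 0
    for case_no in range(config.n_cases):
        case_id = f"case{case_no + 1:05d}"
        k = 1 + rng.poisson(max(config.mean_entries_per_case - 1.0, 0.0))
        k = min(k, config.n_drugs)
        picks = rng.choice(config.n_drugs, size=k, replace=False, p=weights)
        i = 0
        while i < len(picks):
            drug = canonical[picks[i]]
            partner = None
            if config.combo_rate > 0 and i + 1 < len(picks) and rng.random() < config.combo_rate:
                partner = canonical[picks[i + 1]]
                i += 1
            i += 1
            members = [drug] if partner is None else [drug, partner]
            for member in members:
                entry_counts[member] += 1
                case_sets[member].add(case_id)
            n_entries += len(members)
            if partner is None:
                has_atc = rng.random() < config.atc_rate
                rows.append(
                    {
                        "case_id": case_id,
                        "name": raw[drug],
                        "atc": atc_codes[drug] if has_atc else "",
                    }
                )
            else:
                # combination products carry no single-substance ATC
                rows.append(
                    {
                        "case_id": case_id,
                        "name": f"{raw[drug]}/{raw[partner]}",
                        "atc": "",
                    }
                )

    used = [n for n in canonical if entry_counts[n] > 0]
    threshold = 0.03
    truth = GroundTruth(
        canonical_names=canonical,
        raw_spellings=raw,
        spelling_class=spelling_class,
        atc_codes=atc_codes,
        entry_counts={n: entry_counts[n] for n in used},
        case_counts={n: len(case_sets[n]) for n in used},
        n_cases=config.n_cases,
        n_rows=len(rows),
        n_entries=n_entries,
        frequent_threshold=threshold,
        frequent_drugs=sorted(
            n for n in used if len(case_sets[n]) / config.n_cases >= threshold
        ),
        e_recoverable=sorted(
            n for n in used if spelling_class[n] == "E_DROP"
        ),
        overrides=overrides,
    )

    frame = pd.DataFrame(rows, columns=["case_id", "name", "atc"])
    return frame, truth


def generate_resource(
    config: GeneratorConfig,
    truth: GroundTruth,
    *,
    resource_id: str = "synthetic_catalog",
    policy: CoveragePolicy = CoveragePolicy.CATALOG,
) -> SubstrateResource:
    """A synthetic substrate resource over the generated vocabulary.

    Coverage and per-enzyme substrate flags are drawn at the configured
    rates and recorded in the ground truth (``substrate_truth`` holds the
    planted enzyme sets, ``covered_drugs`` the assessed names).
    """
    rng = np.random.default_rng(config.seed + 1)
    rows: list[SnapshotRow] = []
    covered: list[str] = []
    substrate_truth: dict[str, list[str]] = {}
    for name in truth.canonical_names:
        if rng.random() >= config.resource_coverage:
            continue
        enz = frozenset(
            e for e in config.enzymes if rng.random() < config.substrate_rate
        )
        covered.append(name)
        substrate_truth[name] = sorted(enz)
        rows.append(SnapshotRow(name=name, enzymes=enz, atc_codes=(truth.atc_codes[name],)))
    truth.covered_drugs = covered
    truth.substrate_truth = substrate_truth
    return SubstrateResource.from_rows(
        resource_id, rows, policy, version="synthetic", enzymes=config.enzymes
    )


def plant_agreement(
    a: int,
    b: int,
    c: int,
    d: int,
    *,
    seed: int = 0,
    drug_prefix: str = "drug",
) -> tuple[list[str], dict[str, TriState], dict[str, TriState]]:
    """Two classification vectors whose 2×2 tally is exactly (a, b, c, d).

    Drug order is shuffled by ``seed`` so downstream code cannot rely on
    cell-ordered input.
    """
    if min(a, b, c, d) < 0 or a + b + c + d < 1:
        raise ValueError("cell counts must be non-negative with n >= 1")
    n = a + b + c + d
    drugs = [f"{drug_prefix}{i + 1:04d}" for i in range(n)]
    cells = (
        [(TriState.SUBSTRATE, TriState.SUBSTRATE)] * a
        + [(TriState.SUBSTRATE, TriState.NON_SUBSTRATE)] * b
        + [(TriState.NON_SUBSTRATE, TriState.SUBSTRATE)] * c
        + [(TriState.NON_SUBSTRATE, TriState.NON_SUBSTRATE)] * d
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    states_a = {drugs[i]: cells[order[i]][0] for i in range(n)}
    states_b = {drugs[i]: cells[order[i]][1] for i in range(n)}
    return drugs, states_a, states_b


def plant_matrix(
    a: int,
    b: int,
    c: int,
    d: int,
    *,
    enzyme: str = DEFAULT_ENZYMES[0],
    method_a: str = "METHOD_A",
    method_b: str = "METHOD_B",
    seed: int = 0,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> ClassificationMatrix:
    """A two-method :class:`ClassificationMatrix` with planted 2×2 counts."""
    drugs, states_a, states_b = plant_agreement(a, b, c, d, seed=seed)
    matrix = ClassificationMatrix(drugs=list(drugs), enzymes=tuple(enzymes))
    matrix.add_method(
        method_a, {(drug, enzyme): state for drug, state in states_a.items()}
    )
    matrix.add_method(
        method_b, {(drug, enzyme): state for drug, state in states_b.items()}
    )
    # other enzymes: assessed, non-substrate, so joint-set logic sees per-drug
    # assessment like a catalog resource would
    for other in enzymes:
        if other == enzyme:
            continue
        for drug in drugs:
            matrix.set_state(drug, method_a, other, TriState.NON_SUBSTRATE)
            matrix.set_state(drug, method_b, other, TriState.NON_SUBSTRATE)
    return matrix


def write_dataset(config: GeneratorConfig, outdir: str | Path) -> GroundTruth:
    """Materialize a synthetic study to disk: table, index, overrides, truth.

    Writes ``medication.csv``, ``atc_index.tsv``, ``names.txt``,
    ``overrides.tsv`` and ``truth.json`` into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame, truth = generate_dataset(config)
    frame.to_csv(outdir / "medication.csv", index=False)
    with (outdir / "atc_index.tsv").open("w", encoding="utf-8") as fh:
        fh.write("atc\tname\n")
        for name, atc in sorted(truth.atc_codes.items()):
            fh.write(f"{atc}\t{name}\n")
    (outdir / "names.txt").write_text(
        "\n".join(truth.canonical_names) + "\n", encoding="utf-8"
    )
    with (outdir / "overrides.tsv").open("w", encoding="utf-8") as fh:
        fh.write("raw\tcanonical\n")
        for alias, name in sorted(truth.overrides.items()):
            fh.write(f"{alias}\t{name}\n")
    (outdir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    return truth
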