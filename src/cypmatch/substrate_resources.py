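"""Substrate resources: named catalogs of CYP substrate knowledge.

A resource (e.g. a Drugbank-style export, the FDA clinical-substrates table,
a Flockhart-style teaching table) maps canonical drug names to the set of
polymorphic CYP2 enzymes for which the drug is a substrate.  Resources differ
in *coverage semantics*: a catalog-style database implicitly assesses every
drug it contains (a cataloged drug with no CYP2 substrate record is a
non-substrate), whereas a curated substrate list says nothing about drugs it
does not list.  The :class:`CoveragePolicy` makes that distinction explicit,
because it decides which drugs count as "assessed" when two classification
methods are compared.

Lookups are tri-state: substrate, non-substrate, or not assessed.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

#: Polymorphic CYP2 enzymes with clinically relevant genetic variability.
DEFAULT_ENZYMES: tuple[str, ...] = ("CYP2D6", "CYP2C9", "CYP2C19")

_TRUE_TOKENS = {"1", "x", "true", "yes", "substrate"}
_FALSE_TOKENS = {"0", "-", "", "false", "no"}


class TriState(enum.Enum):
    """Outcome of asking a method whether a drug is a substrate of an enzyme."""

    SUBSTRATE = "substrate"
    NON_SUBSTRATE = "non_substrate"
    NOT_ASSESSED = "not_assessed"

    def __bool__(self) -> bool:  # guard against accidental truthiness tests
        raise TypeError("TriState is not boolean; compare explicitly")


class CoveragePolicy(enum.Enum):
    """How far a resource's assessment reaches.

    CATALOG
        Every cataloged drug is assessed; absence of a substrate record for
        an enzyme means non-substrate.
    LISTED_ONLY
        Only drugs explicitly listed are assessed; anything else is
        not assessed.
    """

    CATALOG = "CATALOG"
    LISTED_ONLY = "LISTED_ONLY"


class SnapshotFormatError(ValueError):
    """Raised when a snapshot file violates the documented format."""


@dataclass(frozen=True)
class SnapshotRow:
    """One drug row extracted from an external resource dump."""

    name: str
    enzymes: frozenset[str]
    atc_codes: tuple[str, ...] = ()
    note: str = ""


@dataclass
class SubstrateResource:
    """A named substrate resource with explicit coverage semantics.

    ``entries`` maps canonical (lowercase) drug names to the set of enzymes
    the resource marks as substrate targets; ``catalog_names`` is the full
    set of drugs the resource knows about (equal to ``entries`` keys under
    ``LISTED_ONLY``, possibly larger in spirit for ``CATALOG`` where every
    key is assessed even with an empty enzyme set).
    """

    resource_id: str
    policy: CoveragePolicy
    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    catalog_names: set[str] = field(default_factory=set)
    version: str = ""
    enzymes: tuple[str, ...] = DEFAULT_ENZYMES
    atc_index: dict[str, str] = field(default_factory=dict)  # optional ATC -> name

    def __post_init__(self) -> None:
        enzyme_set = set(self.enzymes)
        for name, enz in self.entries.items():
            extra = enz - enzyme_set
            if extra:
                raise ValueError(
                    f"{self.resource_id}: entry {name!r} references enzymes "
                    f"outside the configured set: {sorted(extra)}"
                )
        if self.policy is CoveragePolicy.CATALOG:
            missing = set(self.entries) - self.catalog_names
            if missing:
                raise ValueError(
                    f"{self.resource_id}: CATALOG policy requires every entry in "
                    f"catalog_names; missing {sorted(missing)[:5]}"
                )
        else:
            self.catalog_names = set(self.entries)

    @property
    def assessed_names(self) -> set[str]:
        """Drugs for which this resource yields a substrate / non-substrate call."""
        if self.policy is CoveragePolicy.CATALOG:
            return set(self.catalog_names)
        return set(self.entries)

    def lookup(self, canonical_name: str, enzyme: str) -> TriState:
        """Tri-state substrate query for one drug and one enzyme."""
        return lookup(self, canonical_name, enzyme)

    @classmethod
    def from_rows(
        cls,
        resource_id: str,
        rows: Iterable[SnapshotRow],
        policy: CoveragePolicy,
        *,
        version: str = "",
        enzymes: Sequence[str] = DEFAULT_ENZYMES,
    ) -> "SubstrateResource":
        """Assemble a resource from snapshot rows, merging duplicates by union."""
        entries: dict[str, frozenset[str]] = {}
        atc_index: dict[str, str] = {}
        enzyme_set = set(enzymes)
        for row in rows:
            name = row.name.strip().lower()
            if not name:
                raise SnapshotFormatError("snapshot row with empty drug name")
            kept = frozenset(row.enzymes) & enzyme_set
            if name in entries:
                logger.warning(
                    "%s: duplicate snapshot rows for %r merged by enzyme-set union",
                    resource_id,
                    name,
                )
                kept = kept | entries[name]
            entries[name] = kept
            for atc in row.atc_codes:
                atc_index.setdefault(atc.upper(), name)
        return cls(
            resource_id=resource_id,
            policy=policy,
            entries=entries,
            catalog_names=set(entries),
            version=version,
            enzymes=tuple(enzymes),
            atc_index=atc_index,
        )


def lookup(resource: SubstrateResource, canonical_name: str, enzyme: str) -> TriState:
    """Tri-state lookup under the resource's coverage policy.

    Raises ``ValueError`` for enzymes outside the resource's configured set;
    the answer for any in-set query is total (never raises on unknown drugs).
    """
    if enzyme not in resource.enzymes:
        raise ValueError(
            f"enzyme {enzyme!r} outside configured set {resource.enzymes}"
        )
    name = canonical_name.strip().lower()
    if resource.policy is CoveragePolicy.CATALOG:
        if name not in resource.catalog_names:
            return TriState.NOT_ASSESSED
        hit = resource.entries.get(name, frozenset())
    else:
        if name not in resource.entries:
            return TriState.NOT_ASSESSED
        hit = resource.entries[name]
    return TriState.SUBSTRATE if enzyme in hit else TriState.NON_SUBSTRATE


def _parse_bool(token: str, *, path: Path, line_no: int, column: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise SnapshotFormatError(
        f"{path}:{line_no}: cannot interpret {token!r} as boolean in column {column!r}"
    )


def load_snapshot(
    path: str | Path,
    *,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> SubstrateResource:
    """Read a snapshot TSV into a :class:`SubstrateResource`.

    Format: leading pragma lines ``#policy=CATALOG|LISTED_ONLY`` (mandatory),
    ``#resource_id=...`` and ``#version=...`` (optional), then a tab-separated
    header ``name`` [``atc``] one column per enzyme [``note``], then one row
    per drug with boolean enzyme flags (``1/0``, ``x/-``, ``true/false``).
    Duplicate drug rows merge by enzyme-set union with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pragmas: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[SnapshotRow] = []
    enzyme_set = set(enzymes)
    with path.open(encoding="utf-8") as fh:
        for line_no, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    pragmas[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                known = {"name", "atc", "note"}
                for col in header:
                    if col not in known and col not in enzyme_set:
                        raise SnapshotFormatError(
                            f"{path}:{line_no}: unknown enzyme column {col!r} "
                            f"(configured enzymes: {sorted(enzyme_set)})"
                        )
                if "name" not in header:
                    raise SnapshotFormatError(f"{path}: header lacks 'name' column")
                continue
            record = dict(zip(header, fields))
            flags = frozenset(
                enz
                for enz in enzymes
                if enz in record
                and _parse_bool(record[enz], path=path, line_no=line_no, column=enz)
            )
            atc = record.get("atc", "").strip().upper()
            rows.append(
                SnapshotRow(
                    name=record["name"],
                    enzymes=flags,
                    atc_codes=(atc,) if atc else (),
                    note=record.get("note", ""),
                )
            )
    if "policy" not in pragmas:
        raise SnapshotFormatError(f"{path}: missing '#policy=' pragma line")
    try:
        policy = CoveragePolicy(pragmas["policy"])
    except ValueError as exc:
        raise SnapshotFormatError(
            f"{path}: unknown policy {pragmas['policy']!r}"
        ) from exc
    return SubstrateResource.from_rows(
        pragmas.get("resource_id", path.stem),
        rows,
        policy,
        version=pragmas.get("version", ""),
        enzymes=enzymes,
    )


def write_snapshot(resource: SubstrateResource, path: str | Path) -> None:
    """Write a resource back to snapshot TSV; inverse of :func:`load_snapshot`."""
    path = Path(path)
    name_to_atc: dict[str, str] = {}
    for atc, name in resource.atc_index.items():
        name_to_atc.setdefault(name, atc)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#policy={resource.policy.value}\n")
        fh.write(f"#resource_id={resource.resource_id}\n")
        if resource.version:
            fh.write(f"#version={resource.version}\n")
        fh.write("name\tatc\t" + "\t".join(resource.enzymes) + "\n")
        for name in sorted(resource.catalog_names):
            enz = resource.entries.get(name, frozenset())
            flags = "\t".join("1" if e in enz else "0" for e in resource.enzymes)
            fh.write(f"{name}\t{name_to_atc.get(name, '')}\t{flags}\n")


# Mapping from long-form enzyme labels used by Drugbank-style XML dumps.
_ENZYME_ALIASES = {
    "cytochrome p450 2d6": "CYP2D6",
    "cytochrome p450 2c9": "CYP2C9",
    "cytochrome p450 2c19": "CYP2C19",
}


def _canonical_enzyme(label: str) -> str | None:
    token = label.strip()
    if token.upper().startswith("CYP"):
        return token.upper().replace(" ", "")
    return _ENZYME_ALIASES.get(token.lower())


def parse_drugbank_xml_dialect(
    path: str | Path,
    *,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> list[SnapshotRow]:
    """Parse a minimal Drugbank-style XML dialect into snapshot rows.

    Expected structure::

        <drugbank>
          <drug>
            <name>Ramipril</name>
            <atc-codes><atc-code code="C09AA05"/></atc-codes>
            <enzymes>
              <enzyme>
                <name>Cytochrome P450 2D6</name>
                <actions><action>substrate</action></actions>
              </enzyme>
            </enzymes>
          </drug>
        </drugbank>

    Only enzyme records whose actions include ``substrate`` and whose enzyme
    resolves to the configured set contribute flags; every drug yields a row
    (possibly with an empty enzyme set), so a catalog-policy resource built
    from these rows assesses all of them.
    """
    path = Path(path)
    enzyme_set = set(enzymes)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SnapshotFormatError(f"{path}: malformed XML: {exc}") from exc
    rows: list[SnapshotRow] = []
    for i, drug in enumerate(tree.getroot().iter("drug"), start=1):
        name_el = drug.find("name")
        if name_el is None or not (name_el.text or "").strip():
            raise SnapshotFormatError(
                f"{path}: drug element #{i} ({tree.getpath(drug)}) lacks a <name>"
            )
        atcs = tuple(
            code.get("code", "").upper()
            for code in drug.iterfind("atc-codes/atc-code")
            if code.get("code")
        )
        flags: set[str] = set()
        for enzyme_el in drug.iterfind("enzymes/enzyme"):
            label_el = enzyme_el.find("name")
            if label_el is None:
                continue
            actions = {
                (a.text or "").strip().lower()
                for a in enzyme_el.iterfind("actions/action")
            }
            if "substrate" not in actions:
                continue
            canon = _canonical_enzyme(label_el.text or "")
            if canon in enzyme_set:
                flags.add(canon)
        rows.append(
            SnapshotRow(name=name_el.text.strip(), enzymes=frozenset(flags), atc_codes=atcs)
        )
    return rows
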