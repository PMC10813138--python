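"""Resolve raw (German-documented) substance names to canonical English names.

Medication lists from German hospitals document substances in German
orthography, often with dose strengths or salt forms attached
("Metoprololtartrat 95mg").  Resolution runs a fixed cascade per entry:

1. full substance-level ATC code lookup, when a specific code is documented;
2. exact match of the normalized name against the canonical name set;
3. the trailing-'e' heuristic — many German substance names are the English
   name minus a final 'e' (hydrochlorothiazid → hydrochlorothiazide);
4. a manual override table for everything orthography cannot bridge;
5. unresolved.

The method that produced each resolution is recorded so downstream reports
can audit how much of a dataset each rule carried.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Substance-level ATC grammar: letter, 2 digits, 2 letters, 2 digits.
_ATC_FULL = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

# Trailing dose/strength tokens, e.g. "5mg", "12,5 mg", "100 i.e.", "0.5 ml".
_DOSE_TOKEN = re.compile(
    r"(\d+([.,]\d+)?\s*(mg|g|ml|l|%|i\.?e\.?|ie|µg|ug|mcg)?)\s*$", re.IGNORECASE
)

#: Default German salt/ester suffixes stripped before matching.  Rule-table
#: driven: each pair is (suffix, replacement appended after stripping).
DEFAULT_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("tartrat", ""),
    ("succinat", ""),
    ("fumarat", ""),
    ("hydrochlorid", ""),
    ("sulfat", ""),
    ("maleat", ""),
    ("mesilat", ""),
    ("besilat", ""),
)


class ResolutionMethod:
    """Cascade step labels, in the order the cascade tries them."""

    ATC = "ATC"
    EXACT = "EXACT"
    E_SUFFIX = "E_SUFFIX"
    OVERRIDE = "OVERRIDE"
    UNRESOLVED = "UNRESOLVED"

    ORDER = (ATC, EXACT, E_SUFFIX, OVERRIDE, UNRESOLVED)


@dataclass(frozen=True)
class NameResolution:
    """Outcome of resolving one raw name (with optional ATC) to canonical form."""

    raw_name: str
    canonical_name: str | None
    method: str
    atc_used: str | None = None

    def __post_init__(self) -> None:
        if (self.canonical_name is None) != (self.method == ResolutionMethod.UNRESOLVED):
            raise ValueError("canonical_name is None exactly when method is UNRESOLVED")
        if self.canonical_name is not None:
            object.__setattr__(self, "canonical_name", self.canonical_name.strip().lower())

    @property
    def resolved(self) -> bool:
        return self.canonical_name is not None


@dataclass
class NameIndex:
    """Canonical English vocabulary: ATC → name map plus the plain name set."""

    atc_to_name: dict[str, str]
    name_set: set[str]

    def __post_init__(self) -> None:
        self.atc_to_name = {
            atc.upper(): name.strip().lower() for atc, name in self.atc_to_name.items()
        }
        for atc in self.atc_to_name:
            if not _ATC_FULL.match(atc):
                raise ValueError(f"index ATC key {atc!r} is not a substance-level code")
        self.name_set = {n.strip().lower() for n in self.name_set}
        self.name_set.update(self.atc_to_name.values())

    @classmethod
    def from_files(cls, atc_tsv: str | Path, names_file: str | Path) -> "NameIndex":
        """Load from a two-column TSV ``atc<TAB>name`` plus a one-name-per-line list.

        Header lines (``atc``/``name``) and ``#`` comments are skipped.
        """
        atc_to_name: dict[str, str] = {}
        for line in Path(atc_tsv).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("atc"):
                continue
            atc, _, name = line.partition("\t")
            if not name:
                raise ValueError(f"{atc_tsv}: expected two tab-separated columns: {line!r}")
            atc_to_name[atc.strip()] = name
        names = {
            line.strip()
            for line in Path(names_file).read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#") and line.strip().lower() != "name"
        }
        return cls(atc_to_name=atc_to_name, name_set=names)


class OverrideMap(dict):
    """raw normalized name → canonical name, for hand-translated substances."""

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        *,
        index: NameIndex | None = None,
        whitelist: Iterable[str] = (),
    ) -> "OverrideMap":
        """Load a two-column TSV ``raw<TAB>canonical``.

        When an index is given, override targets must exist in its name set or
        in the explicit whitelist — this catches typos in hand curation.
        """
        overrides = cls()
        allowed = set(whitelist)
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("raw"):
                continue
            raw, _, target = line.partition("\t")
            if not target:
                raise ValueError(f"{path}: expected two tab-separated columns: {line!r}")
            target = target.strip().lower()
            if index is not None and target not in index.name_set and target not in allowed:
                raise ValueError(
                    f"{path}: override target {target!r} not in the canonical name set "
                    "and not whitelisted"
                )
            overrides[raw.strip().lower()] = target
        return overrides


def is_specific_atc(atc_code: str | None) -> bool:
    """True iff the code is a full 7-character substance-level ATC code.

    Higher-level group codes ("C09", "C09AA") identify drug classes, not
    single substances, and cannot resolve a name.
    """
    if not atc_code:
        return False
    return bool(_ATC_FULL.match(atc_code.strip().upper()))


def normalize_raw(
    raw_name: str,
    suffix_rules: Iterable[tuple[str, str]] = DEFAULT_SUFFIX_RULES,
) -> str:
    """Lowercase, collapse whitespace, strip dose tokens and salt suffixes.

    Raises ``ValueError`` when nothing is left after stripping.
    """
    name = " ".join(raw_name.split()).lower()
    while True:
        stripped = _DOSE_TOKEN.sub("", name).strip()
        if stripped == name:
            break
        name = stripped
    for suffix, replacement in suffix_rules:
        if name.endswith(suffix) and len(name) > len(suffix):
            name = name[: -len(suffix)] + replacement
            break
    name = name.strip(" -")
    if not name:
        raise ValueError(f"name {raw_name!r} empty after normalization")
    return name


def resolve(
    raw_name: str,
    atc_code: str | None,
    index: NameIndex,
    overrides: Mapping[str, str] | None = None,
    *,
    suffix_rules: Iterable[tuple[str, str]] = DEFAULT_SUFFIX_RULES,
) -> NameResolution:
    """Run the resolution cascade for one documented substance.

    The cascade order is fixed: ATC → exact name → trailing-'e' → override →
    unresolved.  A documented but non-specific or unknown ATC code merely
    skips step 1 (with a log message); it never aborts resolution.
    """
    overrides = overrides or {}
    if atc_code:
        code = atc_code.strip().upper()
        if is_specific_atc(code):
            hit = index.atc_to_name.get(code)
            if hit is not None:
                return NameResolution(raw_name, hit, ResolutionMethod.ATC, atc_used=code)
        else:
            logger.warning(
                "ATC code %r for %r is not substance-level; falling back to name match",
                atc_code,
                raw_name,
            )
    try:
        norm = normalize_raw(raw_name, suffix_rules)
    except ValueError:
        return NameResolution(raw_name, None, ResolutionMethod.UNRESOLVED)
    if norm in index.name_set:
        return NameResolution(raw_name, norm, ResolutionMethod.EXACT)
    if norm + "e" in index.name_set:
        return NameResolution(raw_name, norm + "e", ResolutionMethod.E_SUFFIX)
    if norm in overrides:
        return NameResolution(raw_name, overrides[norm], ResolutionMethod.OVERRIDE)
    return NameResolution(raw_name, None, ResolutionMethod.UNRESOLVED)
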