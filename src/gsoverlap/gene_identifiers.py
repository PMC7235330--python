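"""Gene symbol normalization and cross-naming-convention harmonization.

Curated ischemia-hypoxia response sets mix human, mouse and rat gene symbols
(e.g. human ``CACNA1C`` vs rodent ``Cacna1c``). Before any set arithmetic,
every member is brought onto one canonical vocabulary: trimmed, uppercased,
and optionally mapped through a user-supplied alias/ortholog table. Symbols
the table cannot resolve are kept in normalized form rather than dropped —
silently shrinking a query set would change every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "InvalidSymbolError",
    "AliasTableError",
    "AliasTable",
    "HarmonizationReport",
    "normalize_symbol",
    "resolve_symbol",
    "harmonize_members",
]

logger = logging.getLogger("gsoverlap")


class InvalidSymbolError(ValueError):
    """Raised for empty or whitespace-only gene symbols."""


class AliasTableError(ValueError):
    """Raised for malformed alias tables (chains, cycles, bad lines)."""


def normalize_symbol(raw: str) -> str:
    """Return the canonical form of a raw gene symbol.

    Trims surrounding whitespace and uppercases all cased letters. Hyphens,
    dots and digits are preserved verbatim; the alias table is *not*
    consulted. Idempotent: normalizing a canonical symbol returns it
    unchanged.

    Raises
    ------
    InvalidSymbolError
        If ``raw`` is empty or whitespace-only.
    """
    token = raw.strip().upper()
    if not token:
        raise InvalidSymbolError(f"empty or whitespace-only gene symbol: {raw!r}")
    return token


@dataclass(frozen=True)
class AliasTable:
    """Mapping from alias tokens to canonical human gene symbols.

    Keys and values are stored normalized; lookup is therefore
    case-insensitive. Chains (an alias target that is itself re-mapped to a
    different symbol) are rejected at construction: a chained table is
    malformed input, and resolving it transitively would hide the error.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for alias, canonical in self.entries.items():
            a = normalize_symbol(alias)
            c = normalize_symbol(canonical)
            if a in normalized and normalized[a] != c:
                raise AliasTableError(
                    f"alias {a!r} maps to both {normalized[a]!r} and {c!r}"
                )
            normalized[a] = c
        for alias, canonical in normalized.items():
            # no chains: a canonical target that is also a key must self-map
            if canonical in normalized and normalized[canonical] != canonical:
                raise AliasTableError(
                    f"alias chain: {alias!r} -> {canonical!r} -> "
                    f"{normalized[canonical]!r}"
                )
        object.__setattr__(self, "entries", normalized)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.entries

    @classmethod
    def empty(cls) -> "AliasTable":
        return cls({})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasTable":
        """Load a two-column ``alias<TAB>canonical`` table.

        ``#`` comment lines and blank lines are ignored; UTF-8.
        """
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                fields = stripped.split("\t")
                if len(fields) != 2:
                    raise AliasTableError(
                        f"{path}:{lineno}: expected 2 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                alias, canonical = fields
                a = normalize_symbol(alias)
                if a in entries and entries[a] != normalize_symbol(canonical):
                    raise AliasTableError(
                        f"{path}:{lineno}: conflicting mapping for alias {a!r}"
                    )
                entries[a] = canonical
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for alias in sorted(self.entries):
                handle.write(f"{alias}\t{self.entries[alias]}\n")


def resolve_symbol(raw: str, aliases: AliasTable) -> tuple[str, bool]:
    """Normalize ``raw`` and map it through the alias table if present.

    Returns ``(symbol, resolved_flag)`` where the flag is true iff an alias
    entry was applied (self-mappings count). Unmapped symbols come back
    normalized with flag false — they are never dropped here.
    """
    token = normalize_symbol(raw)
    if token in aliases.entries:
        return aliases.entries[token], True
    return token, False


@dataclass(frozen=True)
class HarmonizationReport:
    """Bookkeeping for one harmonization pass.

    ``input == len(members) + collapsed_duplicates`` always holds;
    ``unresolved`` counts distinct output symbols that had no alias entry
    (they are retained, not dropped).
    """

    input: int
    resolved_via_alias: int
    collapsed_duplicates: int
    unresolved: int


def harmonize_members(
    raw_members: Iterable[str], aliases: AliasTable
) -> tuple[set[str], HarmonizationReport]:
    """Normalize, alias-resolve and deduplicate a list of raw symbols.

    Duplicates are collapsed *after* resolution, so two aliases of the same
    canonical gene count as one member. Unresolvable symbols are kept in
    normalized form with a warning.
    """
    members: set[str] = set()
    n_input = 0
    n_resolved = 0
    unresolved: set[str] = set()
    for raw in raw_members:
        n_input += 1
        symbol, was_resolved = resolve_symbol(raw, aliases)
        if was_resolved:
            n_resolved += 1
        elif len(aliases) > 0:
            unresolved.add(symbol)
        members.add(symbol)
    report = HarmonizationReport(
        input=n_input,
        resolved_via_alias=n_resolved,
        collapsed_duplicates=n_input - len(members),
        unresolved=len(unresolved),
    )
    if report.unresolved:
        logger.warning(
            "%d symbol(s) had no alias-table entry; kept normalized",
            report.unresolved,
        )
    return members, report
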