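"""Gene-set containers, GMT / symbol-list I/O, and set arithmetic.

A :class:`GeneSet` is a named, deduplicated collection of canonical gene
symbols. Sets are read from standard GMT files (one set per line: name,
description, then members) or from one-symbol-per-line text files, with
members harmonized through a caller-supplied alias table on load. Analysis
subsets — e.g. the mutation-intolerant portion of a GWAS gene list — are
built by intersecting a query set with an annotation set.

Set semantics are used throughout: a gene listed under two loci counts
once, because overlaps count genes, not loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .gene_identifiers import AliasTable, HarmonizationReport, harmonize_members

__all__ = [
    "GeneSet",
    "OverlapResult",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_symbol_list",
    "intersect",
    "subset_by_membership",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT lines or duplicate set names."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members


@dataclass(frozen=True)
class OverlapResult:
    """Observed overlap between a query set and a reference set.

    ``n`` is the query size, ``O = |shared|`` the observed number of shared
    genes; ``0 <= O <= min(n, |reference|)`` by construction.
    """

    query_name: str
    reference_name: str
    n: int
    O: int
    shared: frozenset[str] = field(repr=False)


def read_gmt(
    path: str | Path,
    aliases: AliasTable | None = None,
    collect: dict[str, HarmonizationReport] | None = None,
) -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated, one set per line).

    Each line needs at least name and description fields; members are
    harmonized through ``aliases`` and deduplicated. A zero-member line
    (name and description only) loads as an empty set. Duplicate set names
    are a load error. When ``collect`` is given, the per-set harmonization
    reports are stored there keyed by set name.
    """
    aliases = aliases if aliases is not None else AliasTable.empty()
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise GmtParseError(
                    f"{path}:{lineno}: GMT line needs at least name and "
                    f"description fields, got {len(fields)}"
                )
            name, description, *raw_members = fields
            if name in seen:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            raw_members = [m for m in raw_members if m.strip()]
            members, report = harmonize_members(raw_members, aliases)
            if collect is not None:
                collect[name] = report
            sets.append(GeneSet(name, frozenset(members), provenance=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT; members in lexicographic order.

    ``read_gmt(write_gmt(S))`` reproduces names and member sets exactly.
    """
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            fields = [gs.name, gs.provenance or "na", *sorted(gs.members)]
            handle.write("\t".join(fields) + "\n")


def read_symbol_list(
    path: str | Path,
    name: str | None = None,
    aliases: AliasTable | None = None,
    collect: dict[str, HarmonizationReport] | None = None,
) -> GeneSet:
    """Read a one-symbol-per-line gene list.

    Blank lines and ``#`` comments are skipped; members are harmonized and
    deduplicated. The set name defaults to the file stem. When ``collect``
    is given, the harmonization report is stored there under the set name.
    """
    aliases = aliases if aliases is not None else AliasTable.empty()
    path = Path(path)
    raw: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            raw.append(stripped)
    members, report = harmonize_members(raw, aliases)
    set_name = name or path.stem
    if collect is not None:
        collect[set_name] = report
    return GeneSet(set_name, frozenset(members), provenance=str(path))


def intersect(query: GeneSet, reference: GeneSet) -> OverlapResult:
    """Observed overlap between a query and a reference set.

    Both sets must already be harmonized on the same vocabulary.
    """
    shared = query.members & reference.members
    return OverlapResult(
        query_name=query.name,
        reference_name=reference.name,
        n=len(query),
        O=len(shared),
        shared=frozenset(shared),
    )


def subset_by_membership(
    query: GeneSet, annotation: GeneSet, new_name: str
) -> GeneSet:
    """Restrict ``query`` to members carrying an annotation.

    Returns ``GeneSet(new_name, query ∩ annotation)`` with provenance
    recording both parents; the result is reused as a new, smaller query
    (e.g. the mutation-intolerant subset of a GWAS gene list).
    """
    return GeneSet(
        new_name,
        query.members & annotation.members,
        provenance=f"intersection of {query.name!r} and {annotation.name!r}",
    )
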