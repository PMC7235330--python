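"""Config-driven orchestration of the full overlap-enrichment grid.

A run is declared in a single YAML file naming the query set(s), the
annotation sets used to carve subsets out of each query, the reference
sets tested against, an optional alias table, the universe size and the
significance family. The pipeline loads and harmonizes everything, builds
the subsets (each query plus query ∩ annotation for every annotation),
tests every (subset, reference) pair at the Bonferroni-adjusted threshold,
and renders a machine-readable TSV plus a human-readable markdown report.
Identical inputs always produce byte-identical outputs.

Config keys::

    universe_size: 18000          # assumed expressed-genome size G
    family_alpha: 0.05            # family-wise level before correction
    m: 3                          # Bonferroni divisor; default = #references
    method: gof_1sample           # or chisq_2x2 / fisher_exact
    alias_table: aliases.tsv      # optional
    query_sets: [gwas.txt]        # .gmt files or one-symbol-per-line lists
    annotation_sets: [lof.txt]    # optional; subsets = query ∩ annotation
    reference_sets: [refs.gmt]

Relative paths resolve against the config file's directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gene_identifiers import AliasTable, HarmonizationReport
from .geneset_store import (
    GeneSet,
    intersect,
    read_gmt,
    read_symbol_list,
    subset_by_membership,
)
from .enrichment_stats import (
    DEFAULT_UNIVERSE,
    BackgroundModel,
    EnrichmentResult,
    assess_enrichment,
    bonferroni_alpha,
    format_p,
    round_percent,
)

__all__ = [
    "RunConfig",
    "SubsetSummary",
    "AnalysisReport",
    "build_subsets",
    "run_analysis",
    "render_report",
]

logger = logging.getLogger("gsoverlap")

RESULT_COLUMNS = [
    "query",
    "reference",
    "n",
    "O",
    "E",
    "statistic",
    "df",
    "p",
    "p_formatted",
    "method",
    "alpha",
    "significant",
    "direction",
]


@dataclass(frozen=True)
class RunConfig:
    query_paths: tuple[Path, ...]
    reference_paths: tuple[Path, ...]
    annotation_paths: tuple[Path, ...] = ()
    alias_table_path: Path | None = None
    universe_size: int = DEFAULT_UNIVERSE
    family_alpha: float = 0.05
    m: int | None = None  # Bonferroni divisor; None -> number of references
    method: str = "gof_1sample"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        base = path.parent

        def _paths(key: str) -> tuple[Path, ...]:
            return tuple(base / p for p in raw.get(key, []) or [])

        alias = raw.get("alias_table")
        return cls(
            query_paths=_paths("query_sets"),
            reference_paths=_paths("reference_sets"),
            annotation_paths=_paths("annotation_sets"),
            alias_table_path=base / alias if alias else None,
            universe_size=int(raw.get("universe_size", DEFAULT_UNIVERSE)),
            family_alpha=float(raw.get("family_alpha", 0.05)),
            m=int(raw["m"]) if raw.get("m") is not None else None,
            method=str(raw.get("method", "gof_1sample")),
        )

    def validate(self) -> list[str]:
        """Return a list of problems; empty means the config is runnable."""
        problems: list[str] = []
        if not self.query_paths:
            problems.append("no query sets declared")
        if not self.reference_paths:
            problems.append("no reference sets declared")
        for p in (
            *self.query_paths,
            *self.reference_paths,
            *self.annotation_paths,
            *([self.alias_table_path] if self.alias_table_path else []),
        ):
            if not Path(p).is_file():
                problems.append(f"missing input file: {p}")
        if self.universe_size <= 0:
            problems.append("universe_size must be positive")
        if not 0 < self.family_alpha < 1:
            problems.append("family_alpha must lie in (0, 1)")
        if self.m is not None and self.m < 1:
            problems.append("m must be >= 1")
        if self.method not in ("gof_1sample", "chisq_2x2", "fisher_exact"):
            problems.append(f"unknown method {self.method!r}")
        return problems


@dataclass(frozen=True)
class SubsetSummary:
    name: str
    parent: str
    size: int
    parent_size: int

    @property
    def percent(self) -> int:
        return round_percent(self.size, self.parent_size)


@dataclass(frozen=True)
class AnalysisReport:
    rows: tuple[EnrichmentResult, ...]
    subsets: tuple[SubsetSummary, ...]
    harmonization: dict[str, HarmonizationReport] = field(default_factory=dict)
    alpha: float = 0.05
    method: str = "gof_1sample"
    universe_size: int = DEFAULT_UNIVERSE


def build_subsets(query: GeneSet, annotations: list[GeneSet]) -> list[GeneSet]:
    """The full query plus one intersection subset per annotation set.

    Subsets are named ``<query>∩<annotation>`` and reused as smaller
    queries against every reference set.
    """
    subsets = [query]
    for annotation in annotations:
        subsets.append(
            subset_by_membership(query, annotation, f"{query.name}∩{annotation.name}")
        )
    return subsets


def _load_collection(
    paths: tuple[Path, ...],
    aliases: AliasTable,
    collect: dict[str, HarmonizationReport],
) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for path in paths:
        if Path(path).suffix.lower() == ".gmt":
            loaded = read_gmt(path, aliases, collect=collect)
        else:
            loaded = [read_symbol_list(path, aliases=aliases, collect=collect)]
        for gs in loaded:
            if gs.name in seen:
                raise ValueError(f"duplicate set name across inputs: {gs.name!r}")
            seen.add(gs.name)
            logger.info("loaded %s: %d members after harmonization", gs.name, len(gs))
        sets.extend(loaded)
    return sets


def run_analysis(cfg: RunConfig) -> AnalysisReport:
    """Execute the full (subset × reference) enrichment grid.

    Every query set is expanded into itself plus its annotation subsets;
    each is tested against every reference set at
    alpha = family_alpha / m. Deterministic for fixed inputs.
    """
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid run config: " + "; ".join(problems))
    aliases = (
        AliasTable.from_tsv(cfg.alias_table_path)
        if cfg.alias_table_path
        else AliasTable.empty()
    )
    harmonization: dict[str, HarmonizationReport] = {}
    queries = _load_collection(cfg.query_paths, aliases, harmonization)
    annotations = _load_collection(cfg.annotation_paths, aliases, harmonization)
    references = _load_collection(cfg.reference_paths, aliases, harmonization)

    m = cfg.m if cfg.m is not None else len(references)
    alpha = bonferroni_alpha(cfg.family_alpha, m)

    rows: list[EnrichmentResult] = []
    summaries: list[SubsetSummary] = []
    for query in queries:
        subsets = build_subsets(query, annotations)
        for subset in subsets[1:]:
            summaries.append(
                SubsetSummary(
                    name=subset.name,
                    parent=query.name,
                    size=len(subset),
                    parent_size=len(query),
                )
            )
        for subset in subsets:
            if len(subset) == 0:
                logger.warning("skipping empty subset %s", subset.name)
                continue
            for reference in references:
                bg = BackgroundModel(
                    reference_size=len(reference), G=cfg.universe_size
                )
                result = assess_enrichment(
                    intersect(subset, reference), bg, alpha, method=cfg.method
                )
                logger.info(
                    "%s vs %s: n=%d O=%d E=%.2f p=%s %s",
                    result.query_name,
                    result.reference_name,
                    result.n,
                    result.O,
                    result.E,
                    format_p(result.p),
                    "SIGNIFICANT" if result.significant else "ns",
                )
                rows.append(result)
    if not rows:
        raise ValueError("analysis produced no comparisons")
    return AnalysisReport(
        rows=tuple(rows),
        subsets=tuple(summaries),
        harmonization=harmonization,
        alpha=alpha,
        method=cfg.method,
        universe_size=cfg.universe_size,
    )


def _tsv_lines(report: AnalysisReport) -> list[str]:
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in report.rows:
        lines.append(
            "\t".join(
                [
                    r.query_name,
                    r.reference_name,
                    str(r.n),
                    str(r.O),
                    f"{r.E:.6g}",
                    f"{r.statistic:.6g}",
                    str(r.df),
                    f"{r.p:.6g}",
                    format_p(r.p),
                    r.method,
                    f"{r.alpha:.6g}",
                    str(r.significant),
                    r.direction,
                ]
            )
        )
    return lines


def _markdown_lines(report: AnalysisReport) -> list[str]:
    lines = [
        "# Overlap-enrichment report",
        "",
        f"Universe size G = {report.universe_size}; method = {report.method}; "
        f"per-comparison alpha = {report.alpha:.3f}.",
        "",
    ]
    if report.subsets:
        lines += ["## Subset sizes", ""]
        for s in report.subsets:
            lines.append(
                f"- {s.name}: {s.size} of {s.parent_size} ({s.percent}% of"
                f" {s.parent})"
            )
        lines.append("")
    lines += [
        "## Enrichment tests",
        "",
        "| query | reference | n | O | E | p | significant | direction |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for r in report.rows:
        lines.append(
            f"| {r.query_name} | {r.reference_name} | {r.n} | {r.O} "
            f"| {r.E:.1f} | {format_p(r.p)} "
            f"| {'yes' if r.significant else 'no'} | {r.direction} |"
        )
    lines.append("")
    return lines


def render_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the machine TSV and the human markdown report.

    Returns the paths written, keyed ``tsv`` and ``markdown``.
    """
    if not report.rows:
        raise ValueError("refusing to render an empty report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "results.tsv"
    md_path = out_dir / "report.md"
    tsv_path.write_text("\n".join(_tsv_lines(report)) + "\n", encoding="utf-8")
    md_path.write_text("\n".join(_markdown_lines(report)) + "\n", encoding="utf-8")
    return {"tsv": tsv_path, "markdown": md_path}
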