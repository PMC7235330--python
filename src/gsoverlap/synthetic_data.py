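"""Synthetic gene universes and sets with planted overlap structure.

Everything downstream of raw data — harmonization, set arithmetic, the
enrichment tests, the pipeline — is testable without downloads by
generating universes and sets whose statistical structure is known:

* a universe of G distinct synthetic symbols (default scale 18,000,
  matching the assumed expressed genome);
* a reference set sampled uniformly without replacement (scale
  1,600–2,500, matching the curated ischemia-hypoxia sets);
* a query of n genes (scale 50–500, matching GWAS-derived lists) whose
  members fall inside the reference with probability fold·f each, where
  f = |reference|/G — fold = 1 is the exact null of the one-sample test,
  fold > 1 plants enrichment with expected overlap n·fold·f;
* alias noise that corrupts a fraction of members into invented alias
  tokens together with the truth table that exactly inverts it.

A single seeded :class:`numpy.random.Generator` is threaded through all
sampling, so a fixed seed reproduces every set and rate bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gene_identifiers import AliasTable
from .geneset_store import GeneSet
from .enrichment_stats import Method, chisq_2x2, chisq_gof, fisher_exact

__all__ = [
    "SyntheticConfig",
    "make_universe",
    "sample_reference",
    "sample_query",
    "inject_alias_noise",
    "simulate_rejection_rate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic scenario.

    ``fold`` multiplies the null membership probability f = reference/G;
    fold = 1 is the null, fold·f must not exceed 1. ``alias_noise_rate``
    is the per-member corruption probability.
    """

    G: int = 18_000
    reference_size: int = 1_629
    n: int = 458
    fold: float = 1.0
    alias_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("universe size must be >= 1")
        if not 0 < self.reference_size <= self.G:
            raise ValueError("reference_size must lie in [1, G]")
        if not 0 <= self.n <= self.G:
            raise ValueError("query size must lie in [0, G]")
        if self.fold < 0:
            raise ValueError("fold must be >= 0")
        if self.fold * self.reference_size / self.G > 1.0 + 1e-12:
            raise ValueError(
                f"infeasible fold: fold*f = "
                f"{self.fold * self.reference_size / self.G:.4f} > 1"
            )
        if not 0.0 <= self.alias_noise_rate <= 1.0:
            raise ValueError("alias_noise_rate must lie in [0, 1]")

    @property
    def f(self) -> float:
        return self.reference_size / self.G


def make_universe(G: int, seed: int = 0) -> list[str]:
    """G distinct synthetic symbols, zero-padded sequential tokens.

    Deterministic (the tokens are sequential; the seed is accepted for
    interface symmetry with the samplers).
    """
    if G < 1:
        raise ValueError("universe size must be >= 1")
    width = len(str(G - 1))
    return [f"SYN{i:0{width}d}" for i in range(G)]


def sample_reference(
    universe: list[str], reference_size: int, seed: int
) -> GeneSet:
    """Uniform sample without replacement from the universe."""
    if reference_size > len(universe):
        raise ValueError("reference_size exceeds universe size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=reference_size, replace=False)
    members = frozenset(universe[i] for i in idx)
    return GeneSet("REF", members, provenance="synthetic uniform reference")


def sample_query(
    universe: list[str],
    reference: GeneSet,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> GeneSet:
    """Query of n genes with planted overlap enrichment.

    Each member independently lands inside the reference with probability
    fold·f, so the overlap count is Binomial(n, fold·f) and the expected
    overlap is n·fold·f; members are distinct (drawn without replacement
    within each stratum). fold = 0 forces zero overlap; fold = 1/f forces
    the query inside the reference.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    f = len(reference) / len(universe)
    p_in = cfg.fold * f
    if p_in > 1.0 + 1e-12:
        raise ValueError(f"infeasible fold: fold*f = {p_in:.4f} > 1")
    p_in = min(p_in, 1.0)
    inside = sorted(reference.members)
    outside = sorted(set(universe) - reference.members)
    k = int(rng.binomial(cfg.n, p_in))
    k = min(k, len(inside))
    n_out = min(cfg.n - k, len(outside))
    picked_in = rng.choice(len(inside), size=k, replace=False) if k else []
    picked_out = (
        rng.choice(len(outside), size=n_out, replace=False) if n_out else []
    )
    members = frozenset(
        [inside[i] for i in picked_in] + [outside[i] for i in picked_out]
    )
    return GeneSet(
        "QUERY",
        members,
        provenance=f"synthetic query, fold={cfg.fold}, seed={cfg.seed}",
    )


def inject_alias_noise(
    gene_set: GeneSet,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], AliasTable]:
    """Corrupt a fraction of members into invented alias tokens.

    Returns the raw member list (aliased tokens in place of originals) and
    the alias table that exactly inverts the corruption, so harmonizing
    the raw list with the truth table recovers the original set.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    raw: list[str] = []
    truth: dict[str, str] = {}
    for symbol in sorted(gene_set.members):
        if rng.random() < cfg.alias_noise_rate:
            alias = f"{symbol}-ALT"
            raw.append(alias)
            truth[alias] = symbol
        else:
            raw.append(symbol)
    return raw, AliasTable(truth)


def _pvalues(O: np.ndarray, cfg: SyntheticConfig, method: Method) -> np.ndarray:
    if method == "gof_1sample":
        # vectorized form of chisq_gof over the overlap counts
        e_in = cfg.n * cfg.f
        e_out = cfg.n * (1.0 - cfg.f)
        statistic = (O - e_in) ** 2 / e_in + ((cfg.n - O) - e_out) ** 2 / e_out
        return stats.chi2.sf(statistic, df=1)
    if method == "chisq_2x2":
        return np.array(
            [chisq_2x2(int(o), cfg.n, cfg.reference_size, cfg.G)[1] for o in O]
        )
    if method == "fisher_exact":
        return np.array(
            [fisher_exact(int(o), cfg.n, cfg.reference_size, cfg.G) for o in O]
        )
    raise ValueError(f"unknown method {method!r}")


def simulate_rejection_rate(
    cfg: SyntheticConfig,
    reps: int,
    alpha: float,
    method: Method = "gof_1sample",
) -> float:
    """Fraction of replicates flagged significant at ``alpha``.

    Each replicate draws the overlap count O ~ Binomial(n, fold·f) — the
    law :func:`sample_query` induces by construction — and applies the
    test with the one-sided enrichment rule (significant requires O > E,
    the null expectation n·f). Deterministic given ``cfg.seed``. At
    fold = 1 this measures the type-I error; at fold > 1, power.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    p_in = min(cfg.fold * cfg.f, 1.0)
    O = rng.binomial(cfg.n, p_in, size=reps)
    E = cfg.n * cfg.f
    pvals = _pvalues(O.astype(float), cfg, method)
    rejected = (pvals < alpha) & (O > E)
    return float(rejected.mean())
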