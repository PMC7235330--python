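"""Overlap-enrichment statistics against a fixed expressed-genome background.

The background model assumes G expressed protein-coding genes (default
18,000 = a conservative 20k genome × >90% expressed in the developing
brain). A reference set of size |D| then occupies a fixed fraction
f = |D|/G of the background, and a random query of n genes is expected to
share E = n·f members with it.

Three test constructions are provided and every report names the one used:

``gof_1sample`` (default)
    One-sample chi-square goodness-of-fit on the two categories
    {shared, not shared} with expected proportion f — the most literal
    reading of "observed vs randomly expected overlap":

        chi2 = (O - nf)^2 / (nf) + ((n-O) - n(1-f))^2 / (n(1-f)),  df = 1

``chisq_2x2``
    Pearson chi-square on the 2×2 table (query membership × reference
    membership) over the universe G, df = 1, no continuity correction by
    default.

``fisher_exact``
    Two-sided exact p from the hypergeometric distribution of O given the
    margins (n, |D|, G); the p-value sums all table probabilities not
    exceeding that of the observed table.

Significance uses a Bonferroni-adjusted threshold (alpha/m, m comparisons
per family) combined with a one-sided enrichment rule: a result is flagged
only when O > E, so depleted overlaps are never reported as significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "BackgroundModel",
    "EnrichmentResult",
    "DEFAULT_UNIVERSE",
    "background_fraction",
    "expected_overlap",
    "chisq_gof",
    "chisq_2x2",
    "fisher_exact",
    "bonferroni_alpha",
    "assess_enrichment",
    "round_percent",
    "format_p",
]

#: Assumed number of expressed protein-coding genes: 20k genome x 90% expressed.
DEFAULT_UNIVERSE = 18_000

Method = Literal["gof_1sample", "chisq_2x2", "fisher_exact"]


def background_fraction(reference_size: int, G: int) -> float:
    """Fraction of the expressed genome covered by a reference set.

    ``background_fraction(1629, 18000)`` -> 0.0905, i.e. the 9% background
    used for the brain ischemia-hypoxia response set.
    """
    if G <= 0 or reference_size <= 0:
        raise ValueError("reference_size and G must be positive")
    if reference_size > G:
        raise ValueError(f"reference_size {reference_size} exceeds universe {G}")
    return reference_size / G


def expected_overlap(n: int, f: float) -> float:
    """Chance-expected overlap E = n*f for a query of n genes."""
    if n < 0:
        raise ValueError("query size must be non-negative")
    if not 0.0 <= f <= 1.0:
        raise ValueError("background fraction must lie in [0, 1]")
    return n * f


@dataclass(frozen=True)
class BackgroundModel:
    """Fixed-universe background for one reference set.

    ``f = reference_size / G`` exactly; G defaults to 18,000.
    """

    reference_size: int
    G: int = DEFAULT_UNIVERSE

    def __post_init__(self) -> None:
        background_fraction(self.reference_size, self.G)  # validates

    @property
    def f(self) -> float:
        return self.reference_size / self.G


def chisq_gof(O: int, n: int, f: float) -> tuple[float, float]:
    """One-sample goodness-of-fit chi-square on {shared, not shared}.

    Expected counts are (nf, n(1-f)); df = 1; p is the upper tail of
    chi-square(1). Raises for degenerate expectations (nf or n(1-f) zero).
    """
    if n < 1:
        raise ValueError("query size must be >= 1")
    if not 0 <= O <= n:
        raise ValueError(f"observed overlap {O} outside [0, {n}]")
    expected_in = n * f
    expected_out = n * (1.0 - f)
    if expected_in <= 0.0 or expected_out <= 0.0:
        raise ValueError(
            f"degenerate expectation: nf={expected_in}, n(1-f)={expected_out}"
        )
    statistic = (O - expected_in) ** 2 / expected_in + (
        (n - O) - expected_out
    ) ** 2 / expected_out
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def _table_cells(O: int, n: int, reference_size: int, G: int) -> tuple[int, ...]:
    cells = (O, n - O, reference_size - O, G - n - reference_size + O)
    if any(c < 0 for c in cells):
        raise ValueError(
            f"inconsistent counts: implied 2x2 cells {cells} for "
            f"O={O}, n={n}, reference_size={reference_size}, G={G}"
        )
    return cells


def chisq_2x2(
    O: int, n: int, reference_size: int, G: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2×2 query × reference membership table.

    Computed via N(|ad-bc| - c_N)^2 / (r1 r2 c1 c2) with c_N = N/2 under
    the optional Yates continuity correction, else 0. df = 1.
    """
    a, b, c, d = _table_cells(O, n, reference_size, G)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate margin: a zero row or column total")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - G / 2.0)
    statistic = G * diff**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def fisher_exact(O: int, n: int, reference_size: int, G: int) -> float:
    """Two-sided exact p for the observed overlap given fixed margins.

    Under the null, O follows a hypergeometric law with population G,
    reference_size successes and n draws. The two-sided p sums the
    probabilities of every attainable overlap whose probability does not
    exceed that of the observed table (with a 1+1e-7 relative tolerance
    for floating-point ties).
    """
    _table_cells(O, n, reference_size, G)
    support = np.arange(
        max(0, n + reference_size - G), min(n, reference_size) + 1
    )
    pmf = stats.hypergeom.pmf(support, G, reference_size, n)
    p_obs = stats.hypergeom.pmf(O, G, reference_size, n)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison threshold family_alpha / m.

    With the conventional 0.05 family level and m=3 reference sets this is
    0.0167, reported as 0.017 after 3-decimal rounding (see report
    formatting).
    """
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


@dataclass(frozen=True)
class EnrichmentResult:
    query_name: str
    reference_name: str
    n: int
    O: int
    E: float
    statistic: float
    df: int
    p: float
    method: str
    alpha: float
    significant: bool
    direction: Literal["enriched", "depleted", "none"]


def assess_enrichment(
    overlap,
    bg: BackgroundModel,
    alpha: float,
    method: Method = "gof_1sample",
) -> EnrichmentResult:
    """Run the chosen test on an observed overlap and apply the decision rule.

    ``significant`` requires both p < alpha and O > E: the tests are
    two-sided but only excess overlap counts as enrichment, so depleted
    overlaps (O < E) are reported as non-significant with direction
    "depleted".
    """
    n, O = overlap.n, overlap.O
    E = expected_overlap(n, bg.f)
    if method == "gof_1sample":
        statistic, p = chisq_gof(O, n, bg.f)
        df = 1
    elif method == "chisq_2x2":
        statistic, p = chisq_2x2(O, n, bg.reference_size, bg.G)
        df = 1
    elif method == "fisher_exact":
        statistic, df = float("nan"), 0
        p = fisher_exact(O, n, bg.reference_size, bg.G)
    else:
        raise ValueError(f"unknown method {method!r}")
    if O > E:
        direction = "enriched"
    elif O < E:
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentResult(
        query_name=overlap.query_name,
        reference_name=overlap.reference_name,
        n=n,
        O=O,
        E=E,
        statistic=statistic,
        df=df,
        p=p,
        method=method,
        alpha=alpha,
        significant=bool(p < alpha and O > E),
        direction=direction,
    )


def round_percent(numerator: int, denominator: int) -> int:
    """Integer percent, rounding half away from zero.

    Reproduces the report convention for subset and background fractions,
    e.g. 96/458 -> 21, 1629/18000 -> 9, 2449/18000 -> 14.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = 100.0 * numerator / denominator
    return int(math.floor(value + 0.5)) if value >= 0 else -int(
        math.floor(-value + 0.5)
    )


def format_p(p: float) -> str:
    """Render a p-value in report style: four decimals, floored at 0.0001.

    The unrounded p is always retained alongside in machine-readable
    output; this rendering only drives the human-facing report.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if p < 0.0001:
        return "0.0001"
    return f"{p:.4f}"
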