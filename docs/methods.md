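# Methods

## Model

The package performs overrepresentation analysis of a query gene list
against reference gene sets under a *fixed-background* model. The
expressed genome is taken to contain G protein-coding genes
(default G = 18,000, i.e. a conservative 20,000-gene genome of which
more than 90% is expressed in the developing brain). A reference set of
size |D| then covers a fixed fraction f = |D|/G of that background — for
the three hypoxia-related reference sets at their full database sizes,
f = 1,629/18,000 ≈ 9%, 2,449/18,000 ≈ 14% and 2,289/18,000 ≈ 12.7%.
Note the last of these rounds to 13% under the package's half-away-from-
zero integer rounding; the originally reported 12% is not reproducible
at G = 18,000 and is treated as a documented discrepancy, not a target.
The background fraction always uses the full database size, not the
post-harmonization size, because the stated percentages derive from the
full sizes.

A random query of n genes drawn from the background is expected to share
E = n·f members with the reference. The model's key assumptions: genes
are exchangeable within the background (no expression-level or
gene-length bias), reference membership is a fixed property, and the
query size n is small relative to G.

## Test constructions

The default test, `gof_1sample`, is a one-sample chi-square
goodness-of-fit over the two categories {shared, not shared}:

    chi2 = (O − nf)²/(nf) + ((n−O) − n(1−f))²/(n(1−f)),  df = 1,

equivalently (O − nf)²/(nf(1−f)). This is the most literal reading of
"observed overlap vs randomly expected overlap at a fixed percentage":
it conditions only on n and treats f as a known constant.

Two alternatives are provided because the construction behind published
p-values of this kind is often under-specified:

* `chisq_2x2` — Pearson chi-square on the 2×2 table (query membership ×
  reference membership) over the universe G, df = 1, no continuity
  correction by default (Yates available as an option). Algebraically
  the 2×2 statistic equals the GOF statistic times G/(G−n), so the two
  agree to within n/(G−n) relative difference — under 3% in the intended
  regime (n ≤ 500, G = 18,000) but materially different when the query
  is a sizeable fraction of the universe. Large expected cells do *not*
  close this gap; only n ≪ G does.
* `fisher_exact` — two-sided exact p from the hypergeometric law of O
  given the margins (n, |D|, G); the p-value sums all attainable-table
  probabilities not exceeding that of the observed table, with a
  1 + 1e-7 relative tolerance for floating-point ties (the convention of
  standard implementations). Verified in the test suite against exact
  rational enumeration for every table with G ≤ 30.

Reported p-values from the original analysis of this design (e.g. 0.0002
for 25 shared genes in a 112-gene query at the 9% background) are not
reproduced by any of the three constructions at G = 18,000 — the GOF
test gives p ≈ 1e-6 for that comparison and the 2×2 and exact variants
agree closely with it. The software therefore makes no attempt to match
those printed values; it reports its own construction, named in every
output row, and treats the published significance *decisions* (which all
constructions reproduce) as the meaningful quantity.

## Decision rule

Tests are two-sided, but the significance decision is one-sided for
enrichment: a comparison is flagged only when p < α *and* O > E, so
depleted overlaps are reported with direction "depleted" and never as
significant. The per-comparison threshold is α = family_alpha/m
(Bonferroni), with family_alpha = 0.05 and m defaulting to the number of
reference sets in the run (three in the motivating design, giving
α = 0.0167, rendered as 0.017 at three decimals). No FDR procedure is
offered; the fixed-α rule mirrors the design this package reproduces.

Report formatting: p-values render at four decimals with values below
0.0001 floored to "0.0001" (unrounded values are always kept in the
machine-readable TSV); percentages round half away from zero to integer
percent, which reproduces 21% (96/458), 28% (452/1,629), 24%
(270/1,112), 9% and 14%.

## Symbol harmonization

All set members pass through normalization (trim, uppercase; hyphens,
dots and digits preserved) and an optional user-supplied alias table
(two-column TSV, alias → canonical human symbol) before any set
operation. Choices that matter:

* Unresolvable symbols are kept in normalized form with a logged
  warning, never dropped — dropping would silently shrink n and change
  every statistic.
* Case-insensitive matching via uppercasing, since rodent symbols differ
  from their human orthologs only by case in most instances.
* Alias chains and cycles are rejected at load time rather than resolved
  transitively: a chained table indicates a curation error, and
  transitive closure would hide it.
* Deduplication happens after resolution, so two aliases of one
  canonical gene count once; the harmonization report reconciles exactly
  (input = members + collapsed duplicates) and records alias resolutions
  and unresolved symbols per input file.

No ortholog database is bundled and no probe-to-gene resolution is
attempted; the alias table is data, not code.

## Synthetic data and calibration

The generator emulates the study's scale: a universe of ~18,000
synthetic symbols, references of ~1,600–2,500, queries of ~50–500, and
planted fold-enrichment 1–3. A query member lands inside the reference
independently with probability fold·f (members distinct overall), so the
overlap count O is Binomial(n, fold·f) with expected overlap n·fold·f;
fold = 1 is exactly the null of the one-sample test, which is what makes
type-I calibration meaningful. Alias noise replaces a Binomial fraction
of members with invented alias tokens and returns the truth table that
exactly inverts the corruption.

`simulate_rejection_rate` exploits the fact that the test statistic
depends on the data only through (O, n): it draws O directly from
Binomial(n, fold·f) — the law the set-level sampler induces by
construction — rather than materializing member sets per replicate,
which makes 5,000-replicate calibration essentially instant. Set-level
sampling is exercised end to end in the test suite and in the
parameter-recovery analysis (mean O/E over 200 seeded runs at
G = 2,000, reference 200, query 100, a scale chosen so the whole
recovery run completes in seconds while keeping expected cells large).
Default calibration uses 5,000 replicates: the standard error of a
0.017 rejection rate is then ≈ 0.0018, small enough to detect gross
miscalibration. All sampling flows through a single seeded
`numpy.random.Generator`; a fixed seed reproduces every set, file and
rate bit-identically.

Because O is integer-valued, the attainable type-I level at a nominal
α = 0.017 sits below α (the null calibration check allows
[0, α + 3·SE ≈ 0.026]). What passing these simulations shows is that the
test is calibrated *under the model's own null*; it says nothing about
real-data violations such as correlated reference sets, expression-level
sampling bias in GWAS loci, or error in the assumed G — sensitivity to G
is exposed as a config knob instead.

## Pipeline

A run is a declarative YAML config naming query sets, annotation sets
(each query is expanded into itself plus query ∩ annotation subsets),
reference sets, an optional alias table, G, the family alpha, m and the
method. Outputs are a TSV (query, reference, n, O, E, statistic, df, p,
formatted p, method, alpha, significance, direction), a markdown report
with subset-size percentages, and INFO-level logging of every set size
after harmonization — deliberately, so input-list discrepancies (such as
a set documented at one size but harmonizing to another) surface rather
than pass silently. Identical inputs produce byte-identical outputs.
Empty subsets are skipped with a warning; an analysis that yields no
comparisons is an error, never a silent empty file.

## Known limitations

* The fixed-background model ignores gene length, LD-driven locus
  clustering and expression filtering; it counts genes, not loci, and
  accepts the locus→gene mapping as input.
* The 2×2 and exact variants condition on both margins and therefore
  differ from the default GOF construction by the finite-population
  factor; none of the three reproduces the originally published
  p-values, whose construction is unknown.
* Background conditioning for annotation subsets (e.g. restricting f to
  the annotated portion of the universe) is not performed; the global f
  is reused for subsets, matching the reproduced design's apparent
  choice.
* The synthetic generator plants independent Bernoulli membership; it
  does not model biological correlation between reference sets or GWAS
  summary statistics.
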