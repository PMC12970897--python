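# Methods

## Counting model and data handling

The unit of observation is the deduplicated report: a report contributes
once to each cell of a drug × event 2×2 table no matter how many drug or
event rows it carries. The background/reference set is all other reports
in the same database; no comparator drug class is used.

Deduplication follows each database's convention. FAERS-shaped data
(including synthetic data, which mimics FAERS versioning) keeps, per
case id, the row with the greatest version key built from
(fda_dt, primaryid), so later submissions supersede earlier ones; ties
on the key keep the lexicographically greatest report id and are
logged. JADER-shaped data drops identical rows from the drug and event
tables and keeps the first demographic row per case id; CVAR-shaped
data keeps one row per Report_ID. Deduplication is idempotent.

Exposure is restricted by drug role: primary suspect (PS) for FAERS,
the single "suspect" code for JADER and CVAR, both overridable. Drug
names are matched against a generic/trade/former-name dictionary after
Unicode NFKC normalization, casefolding and whitespace collapsing —
trade names appear in mixed case and full-width characters across
sources. The default adverse-event query for EGPA includes both the
current preferred term and the legacy "Churg-Strauss syndrome" term,
because older reports are coded under the latter.

Partial dates (year or year-month only) are imputed to the first day
and flagged; the flag matters only for time-to-onset, where imputed
records can be excluded as a sensitivity option. Reports with wholly
missing dates stay in the disproportionality analysis and drop out of
the onset analysis with a tallied reason.

## Disproportionality statistics

ROR and PRR use Wald intervals on the log scale. Pearson χ² is computed
without the Yates continuity correction: on screening tables rebuilt
from published marginals, the uncorrected statistic matches the
published values to well under 0.1%, while the corrected variant does
not. Zero cells raise an error by default; an optional Haldane
(+0.5-per-cell) correction is available and flagged in the output.

The information component is reported in the raw convention
IC = log₂(a/E), which makes IC exactly log₂ of the relative reporting
ratio and matches published screening tables where IC = log₂(EBGM)
row by row. A shrunk variant log₂((a+½)/(E+½)) is available. IC025 is
reported two ways: the closed-form bound IC − 3.3(a+½)^−½ − 2(a+½)^−3/2
(used for the signal flag, being deterministic) and, on request, the
Monte-Carlo 2.5th percentile of log₂ λ under the Gamma(a+½, E+½)
posterior. The two agree (within ~0.02 bits at large a) only when both
are anchored at the shrunk IC, since both derive from that posterior;
anchored at the raw IC the closed form tracks the published convention
instead.

### MGPS

The empirical-Bayes model is a ~ Poisson(λE) with a two-component gamma
mixture prior on λ (five hyperparameters: α₁, β₁, α₂, β₂, w). The prior
is fitted by maximizing the mixture-of-negative-binomials marginal
likelihood over all drug–event pairs in the database, from the
documented start (0.2, 0.1, 2, 4, ⅓), using L-BFGS-B on log/logit-
transformed parameters with a Nelder-Mead polish on non-convergence;
non-convergence after that raises an error carrying the best-so-far
parameters. The per-pair posterior is a gamma mixture with components
(αᵢ+a, βᵢ+E); EBGM = exp E[ln λ | a] via digamma, and EB05 solves the
mixture CDF = 0.05 by bracketed root-finding. The pair list for prior
fitting is the full ingredient × PT grid including zero-count pairs.

By default results are reported in the negligible-shrinkage form
EBGM = a/E with EB05 the 5th percentile of the Gamma(a, E) posterior
(an improper-scale-prior bound that converges to a/E as counts grow);
published screening tables for strong signals sit in this regime.
Full shrinkage is a flag, not the default, so single-pair analyses do
not silently depend on the rest of the database. No stratified E is
used by default (stratification hooks exist via subgroup analysis);
no multiplicity adjustment is applied — the joint four-criterion rule
is the published decision rule.

The joint rule flags a pair when ROR CI lower > 1 and n ≥ 3, PRR > 2
and χ² ≥ 4, IC025 > 0, and EBGM05 > 2. "PRR > 2" uses the point
estimate (the CI is printed alongside); the published phrasing is
ambiguous between the estimate and its bound.

### Subgroups and co-medication

Each stratum (age < 65 / ≥ 65; female / male; asthma / other
indication) is analysed as its own complete database — all four cells
recomputed within the stratum; reports with a missing stratum value are
excluded from that axis. A report's indication class comes from the
indication terms on any of its drug rows (any row matching "asthma"
classifies the report as asthma). Co-medication analysis restricts the
whole database to reports listing (require) or not listing (exclude)
the co-medication in any role before re-running the full analysis.

## Weibull time-to-onset

TTO is onset date minus the earliest start date of the index drug
within the report, in days; non-positive and incomputable intervals are
excluded with reason counts. The MLE solves the one-dimensional profile
equation for the shape (Σxᵢ^β ln xᵢ/Σxᵢ^β − 1/β = mean ln x) by
bracketed root-finding, then the scale in closed form. 95% CIs come
from the observed information on (ln α, ln β), computed by central
finite differences (step 1e−5) and back-transformed — standard,
asymmetric on the natural scale, and consistent with published CI
asymmetry. Classification: "early failure" iff β̂ < 1 and the CI upper
bound < 1; "wear-out" iff β̂ > 1 and the CI lower bound > 1; otherwise
(CI containing or touching 1) "random". Coverage of the shape CI is
93–97% in simulation at (α=250, β=0.75, n=300). No onset cap is applied
by default.

## Network stage

Gene symbols are upper-cased and deduplicated. The interaction graph
keeps STRING-style edges with combined score ≥ 0.4 (integer 0–1000
scores are rescaled); duplicate pairs collapse keeping the maximum
score; self-loops are dropped.

MCODE follows the seeded vertex-weighting scheme: each vertex is
weighted by k × density of the highest k-core of its closed
neighborhood (vertices below the degree cutoff, default 2, get weight
0); clusters grow from the highest-weight unseen vertex, admitting
neighbors with weight ≥ seed weight × (1 − node score cutoff, default
0.2) within a depth limit; post-processing peels each cluster to its
2-core (which subsumes the haircut of singly-connected vertices — the
haircut step is applied iteratively for the general k-core setting) and
optionally fluffs (off by default, matching common defaults). Density
excludes self-loops: 2|E|/(|V|(|V|−1)). Cluster score is density ×
size; ordering is by score, then size, then seed name, making output
independent of node input order. All parameters are surfaced since no
canonical values are published for this analysis.

Enrichment is the upper-tail hypergeometric probability per term with
Benjamini–Hochberg FDR across tested terms; the universe defaults to
all genes in the annotation collection (configurable); query symbols
outside the universe are dropped with a count; zero-overlap terms are
omitted. Deriving the disease gene list itself (differential expression
from raw array data) is out of scope: the stage consumes a prepared
disease gene list file.

## Synthetic data generator

The generator emulates what the screening statistics see, with
closed-form ground truth: per-report drug exposure as independent
Bernoulli draws per drug; event probability = baseline × relative
reporting rate (RR) for each planted signal drug present (capped at 1);
one primary-suspect drug chosen uniformly among those present, the rest
concomitant; onset intervals for signal pairs drawn
Weibull(scale, shape) after the signal drug's start date (background
events get an exponential lag, mean 180 d); duplicates injected as
re-versioned copies at a configurable rate; demographics from a
two-component adult/elderly age mixture, log-normal weight, categorical
sex/reporter/country/outcome; missingness MCAR per field. Everything is
reproducible under a fixed seed.

Deliberate departures from real SRS data: reports may carry zero drugs
or zero events (the independent draws are not conditioned), there is no
co-prescription correlation structure, missingness is uninformative,
and the PS assignment is independent of the event. Passing tests on
this generator therefore demonstrate correctness of the counting and
estimation machinery under a known mechanism, not robustness to the
reporting biases, duplicates-beyond-versioning, or informative
missingness of real databases.

The default planted pair uses RR = 50 against a rare-event baseline and
Weibull(391.08 d, 0.76) onset — the operating point of the motivating
EGPA analysis — so defaults exercise the strong-signal, early-failure
regime.

The network fixture plants: an exact drug/disease overlap of the
requested size (default 81 of 553 drug targets and 3,555 disease
genes), a near-clique of 6 overlap genes with high edge scores against
a sparse background containing sub-threshold edges, and one annotation
term concentrated on the clique.

## Problem sizes in the test suite

Tests and acceptance checks run at sizes chosen to make the Monte-Carlo
error a small fraction of each tolerance: marginal-convergence checks
at 10⁵ reports (3-standard-error bands); ROR-coverage across 10
replicates at 1.5×10⁵ reports; Weibull recovery over 100 replicates of
n = 316; prior-weight recovery at 10⁵ pairs; operating characteristics
of the joint criterion on 1,000 null and 400 planted multinomial
tables at N = 2×10⁵ with E ≈ 5–6; MCODE verified exhaustively against
a brute-force oracle on every non-isomorphic graph with ≤ 7 nodes plus
100 seeded 8-node random graphs; enrichment verified against complete
enumeration on universes of ≤ 20 genes.

## Known limitations

- Disproportionality measures reporting association, not causation or
  incidence; the package computes the statistics, interpretation
  limits are the analyst's.
- The JADER-style screening row in published tables is not internally
  consistent under a single background N for the Bayesian cells;
  reconstruction checks for such rows are restricted to ROR/PRR.
- No probabilistic record linkage: deduplication is rule-based on ids
  and versions.
- The Weibull fit ignores censoring and truncation (reports without an
  event never enter), as in standard WSP screening practice.
- CVAR/JADER file schemas are simplified English-language dialects of
  the public extracts; column mapping is documented in `io.py` and
  tolerant of extra columns.
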