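# Methods

## Cohort construction

Reports follow a subset of the openFDA drug-event schema: a report id, a
CCYYMMDD receipt date, a `patientsex` code (1 = male, 2 = female, anything
else — including 0 or absence — treated as unknown), per-drug entries with
a generic name and an optional per-drug indication, and a set of reaction
MedDRA preferred terms. All terms are matched after normalization
(uppercase, trimmed, inner whitespace collapsed), and reaction sets
deduplicate by construction, so all downstream counting is case-level: a
report contributes at most once to any event count.

A case cohort for (drug, sex) keeps reports that (i) carry the requested
sex — unknown-sex reports never enter either stratum, mirroring the
exclusion used when gender composition is itself an outcome; (ii) have a
receipt date in the half-open window [2004-01-01, 2014-07-01), realizing
"January 2004 through June 2014"; (iii) have at least one drug entry that
matches the drug (case-insensitive, against a configurable synonym list
defaulting to the generic name) *and* whose own indication is in the query
list — the indication must sit on the matching drug's entry, not on a
co-medication, because the openFDA `drugindication` field is per-drug; and
(iv) list no drug from the exclusion set. For pairwise drug comparisons the
comparator is excluded and vice versa, keeping the two arms disjoint;
combination-exposure reports are too few to analyze separately and are
dropped. The default indication list is the eight MedDRA alopecia terms
(ALOPECIA, ALOPECIA AREATA, ALOPECIA EFFLUVIUM, ALOPECIA SCARRING,
ALOPECIA TOTALIS, ALOPECIA UNIVERSALIS, ANDROGENETIC ALOPECIA, DIFFUSE
ALOPECIA).

Whether the original openFDA query matched indications per drug entry or
per report is not documented anywhere we could check; the per-drug rule
above is this package's design choice, not a claim about the original
query.

## PRR, confidence interval, Fisher test

PRR_X = (A1/A0)/(B1/B0). The 95% CI is the delta-method interval on the
log scale, exp(ln PRR ± 1.96·sqrt(1/A1 + 1/B1 − 1/A0 − 1/B0)); the
radicand is nonnegative whenever A1 ≤ A0 and B1 ≤ B0. Degenerate rows use
sentinels rather than continuity corrections: B1 = 0 makes the PRR
undefined (rendered "N/A"), A1 = 0 with B1 > 0 makes it exactly zero
(rendered "0.00"), and the CI is suppressed whenever either affected count
is zero. No multiplicity adjustment is applied across event rows — the
comparison tables report raw p-values — and no other disproportionality
statistic (ROR, IC, EBGM) is computed.

The two-tailed Fisher exact p sums, over all 2×2 tables with the observed
margins, the hypergeometric probabilities not exceeding the observed
table's probability within relative tolerance 1e-7 (guarding
floating-point ties); probabilities are accumulated in log space. One
deliberate and load-bearing convention: for the event comparison the four
counts (A1, A0, B1, B0) enter as the four *cells* — each drug's row is
(affected, total), not (affected, unaffected). The reporting-rate tables
this package reproduces were computed that way; all 28 printed p-values
match this construction (and none match the textbook affected/unaffected
table). The gender-composition test uses the standard (male, female)
cells against the reference population. One printed female-stratum
p-value (palpitations, 0.52) matches neither construction and is
presumably a typo for 0.052; both round to the same empty stars column.

p-values below 1e-300 render as "0" but are floored, never zero,
internally. Table renderings round PRR and CI bounds half-up to 2
decimals, proportions to 2 decimals (1 for gender composition), p-values
to 3 significant digits; full precision is kept internally. A handful of
published CI bounds differ from the formula in the last digit (e.g. a
chorioretinopathy upper bound printed 0.08 where the formula gives 0.087);
the formula's value is reported as computed, not patched per-row.

Stars: * p < 0.05, ** p < 0.01, *** p < 0.001. Comparison-table row sets
default to the union of both cohorts' top-10 most-reported terms; ranking
is by affected-case count, ties broken lexicographically.

## Synthetic reports

The generator draws, per arm: sex ~ Bernoulli(p_male), masked to unknown
with probability p_sex_missing (the drawn sex still drives event draws);
each event term independently with its sex-specific probability; a
uniformly drawn background reaction if no event fired (reaction sets are
never empty in real spontaneous reports; rescuing rather than resampling
keeps the per-term probabilities exactly calibrated); and an indication
that is off-label with probability p_offlabel_indication. Receipt dates
are uniform over the study window. Everything derives from one
numpy default_rng seed, so identical specs give byte-identical JSON-lines
output. Defaults model a plausible reporting stream (5% missing sex, 5%
off-label); events are independent within a report because the
disproportionality statistics treat each term marginally.

`fixture_from_counts` reconstructs cohorts from printed (affected, total)
margins by co-assigning every event to the earliest report ids, so all
marginal counts round-trip exactly; padding reports get per-report-unique
filler reactions that cannot disturb event rankings.

The CI-recovery configuration (`recovery_spec`) uses two all-male arms of
2000 reports each with event probabilities 0.40 vs 0.05 (true ratio 8.0)
and no missing sex or off-label indications, isolating binomial sampling
noise; over 500 seeded replicates the delta-method CI covers the true
ratio at its nominal ~95% rate. What these simulations do *not* emulate —
duplicate submissions, reporting biases, secular trends, correlated
reactions — means passing recovery tests demonstrates correctness of the
estimator, not robustness of PRRs to real-world confounding.

## Drug–gene network

The network is the first neighborhood of the drug's directly associated
genes (FAGs): nodes are the drug, the FAGs, and every protein-interaction
partner of a FAG (IAGs); edges are drug–FAG edges plus interaction edges
with at least one FAG endpoint. IAG–IAG edges are not recruited — the
published network of this kind has barely more edges than nodes, i.e.
first-neighbor recruitment without closure — and the graph is simple and
undirected (direction and multiplicity in source files collapse).

The topological coefficient follows the Cytoscape convention:
TC(n) = avg_m J(n,m) / k_n over nodes m sharing at least one neighbor with
n, J counting shared neighbors plus 1 if n and m are adjacent; it is
undefined for nodes with no qualifying partner. Whether that exact
convention produced the original published panels is not stated there;
this is the definition implemented and tested. Betweenness is
networkx's shortest-path betweenness with the undirected pair
normalization 2/((N−1)(N−2)), checked against a brute-force
path-enumeration oracle. Power-law fits are ordinary least squares on
(ln x, ln y) after dropping nonpositive y; R² is computed on that log-log
scale, defined as 1.0 for constant-y input (a zero-slope line with zero
residuals; avoids 0/0). Per-degree metric profiles average defined values
only.

The published network's exact size (260 nodes / 262 edges) and panel R²
values depend on unprinted database snapshots and are not reproduction
targets; the property suite covers the algorithms instead.

## Enrichment

Over-representation of a query gene list in GMT gene-set collections:
p_raw = P(X ≥ k) for X ~ Hypergeometric(N, K, n), summed in log space;
Benjamini–Hochberg step-up adjustment across all categories with k ≥ 1.
The default universe is the union of all annotated genes in the loaded
collection (the reference-set behavior of enrichment servers when no
background is supplied), overridable explicitly. Two effect sizes are
emitted because published "OR of enrichment" columns are ambiguous: the
enrichment ratio k/(n·K/N), labeled OR for table parity, and the
conditional odds ratio of the 2×2 (infinite when a zero cell makes it
undiverging). Published enrichment p-values/ORs are not reproduction
targets (they depend on annotation-release universes); the
bundled reproductive-toxicity gene lists exercise the machinery.

## Problem sizes in tests

Oracle comparisons run exhaustively where enumeration is cheap: all 2×2
tables with cohort totals ≤ 24 for Fisher, universes ≤ 30 genes for the
hypergeometric tail, 50 random graphs of ≤ 12 nodes for betweenness. The
recovery study uses 500 replicates at 2000 reports/arm, sized so the
binomial uncertainty of the coverage estimate (~1 pp) sits well inside the
±3 pp acceptance band.

## Known limitations

PRRs from spontaneous reports are qualitative signals, not incidence
ratios; confounding by age, comorbidity and co-medication is untouched.
The ingester treats MedDRA terms as opaque strings (no hierarchy), does
not deduplicate near-identical reports, and the package neither queries
live databases nor renders graphics.
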