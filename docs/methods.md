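# Methods

## The analysis model

The unit of analysis is the individual case safety report (ICSR): one
spontaneous adverse-event report carrying patient demographics and the set
of distinct medicinal ingredients reported for that patient.  Combination
analysis only makes sense on reports with at least two drugs, so the
pipeline first runs an exclusion cascade in a fixed order:

1. remove reports flagged as possible duplicates;
2. remove drug entries whose name is unknown or cannot be assigned an
   Anatomical Therapeutic Chemical (ATC) code;
3. collapse repeated ingredients within a report to a set (a pair can be
   counted at most once per report — the only convention under which
   pair prevalence arithmetic is consistent with set-valued reports);
4. keep reports with ≥ 2 distinct drugs.

Stage counts are recorded as flow counters; applying the cascade to its own
output is a no-op (idempotence is unit-tested).  Drug role (suspected /
interacting / concomitant) is kept as metadata but never used to filter,
since spontaneous reports are known to under-label concomitant medication.
Ingredients mapping to several ATC codes resolve deterministically to the
lexicographically smallest code (logged); combination products map only if
the ATC table lists them as one name.

### Observed-to-expected ratio

For a retained cohort of N reports, drug *d* has marginal prevalence
`n_d / N`.  A k-drug combination (k = 2, 3) with `n_obs` co-reporting
reports has observed prevalence `n_obs / N` and, under independence of its
members, expected prevalence `∏ (n_i / N)`.  The O/E ratio is their
quotient, algebraically `n_obs · N^(k−1) / ∏ n_i`.  Three conventions
matter and are enforced:

* all prevalences share the same denominator N — the ≥ 2-drug retained
  cohort, not the full extraction (the only convention that reproduces the
  published expected-prevalence cells end to end);
* O/E is a point estimate: no shrinkage, no confidence interval, no
  multiple-testing correction (an optional Monte-Carlo permutation null —
  shuffling drug sets across reports while preserving set sizes — is
  provided for exploration but off by default, and output headers carry the
  caveat);
* comparison and sorting always use unrounded values; the 2-decimal
  half-up rounding is display-only.

Rare combinations produce large, unstable O/E values (a pair seen once
whose members each appear once has O/E = N); ranked tables therefore sort
by count, not by O/E, unless asked otherwise.

### Network and community detection

The co-reporting network has one node per retained drug (attributes: report
count, prevalence, ATC-1 main group as the conventional color key) and an
undirected edge per co-reported pair, weighted by the pair count.  Node
identity is the normalized ingredient name, not the ATC code — distinct
drugs share ATC groups.  Edge weights are raw counts; the pair O/E can be
attached as an optional edge attribute but never replaces the weight.

Communities maximize Newman–Girvan modularity

    Q = (1/2m) Σ_ij [A_ij − k_i k_j/(2m)] δ(c_i, c_j)

with weighted adjacency A, weighted degrees k and total edge weight m.

**Louvain** (primary): alternate (i) local moving — each node, in an order
shuffled once per sweep from the seeded generator, joins the neighboring
community with the largest positive modularity gain, smallest community
label winning ties — with (ii) aggregation of communities into a weighted
super-graph with self-loops, until an outer iteration no longer increases
Q.  The (graph, seed) pair determines the partition completely.  The
resolution parameter is fixed at 1 (classic modularity) and exposed only
for exploration.

**Leading eigenvector** (robustness check): recursive bisection by the sign
pattern of the leading eigenvector of the generalized modularity matrix
`B(g)_ij = B_ij − δ_ij Σ_{l∈g} B_il` restricted to the current group.  A
split is accepted only if the leading eigenvalue exceeds 1e-9 (eigensolver
tolerance; below that the group is spectrally indivisible) and the
bipartition strictly increases Q.  The sign convention fixes the
largest-magnitude component positive, so the bipartition is invariant to
eigenvector negation.  Groups larger than 500 nodes use a Lanczos solver
with a fixed deterministic start vector; smaller groups a full symmetric
eigendecomposition.

Both are validated against an exhaustive set-partition oracle on all random
suite graphs of ≤ 8 nodes (both reach ≥ 95% of the global optimum; in
practice they hit it exactly on these sizes) and cross-checked against
networkx (modularity, Louvain) and python-igraph (leading eigenvector).
Disconnected graphs need no special handling — components simply never
merge profitably.

Stratified analyses re-run graph construction plus both clusterings within
sex (female vs male) and age strata.  The age boundary is <65 vs ≥ 65:
reports aged exactly 65 go to the older stratum, and reports with unknown
sex/age are excluded from that stratification only.

### Descriptive tables

Cohort characteristics use counts (%) for categorical rows and mean (SD) /
median (IQR) for age and drugs per report.  Between-stratum tests are
Pearson chi-squared for categorical characteristics (no continuity
correction above 2×2; Yates optional for 2×2) and the Welch unequal-variance
t-test for numeric ones — the conservative default where the variance
assumption cannot be checked.  Percentage denominators are
per-characteristic: reporter type and seriousness use known-value
denominators (their unknowns are substantial and conventionally excluded),
all other rows use the full cohort.

## Synthetic data

Real spontaneous-report databases cannot be shipped, so two synthetic
sources stand in.

**The generator** (`agepnet.simulate`) draws each report as follows: with
probability `single_drug_fraction` the report lists exactly one drug (the
common only-the-suspect-reported pattern, later removed by the ≥ 2-drug
restriction); otherwise each *therapy profile* (a labelled block of drugs
with per-drug inclusion probabilities) activates independently with its
activation probability, contributing its drugs, and every background drug
joins independently at its background rate, scaled per report by a mean-1
gamma frailty that produces the overdispersed drug counts of real
polypharmacy data.  Empty drug sets are redrawn (up to 10 rounds, then one
uniformly chosen profile is forced) — this conditions every marginal up by
exactly 1/(1 − P(empty)), which `expected_marginal_rates` accounts for.
Demographics are sampled from stated categorical distributions (ages
uniform within their bracket); death can optionally depend on age group but
defaults to the marginal rate.  Duplicates are flagged near-copies appended
to the table; unknown-name noise replaces an entry's name with an
unmappable token.  All draws come from one seeded generator in a fixed
documented order, so identical config + seed gives byte-identical tables.

`default_agep_like_config()` emulates a published AGEP cohort: 5983
extracted reports filtering to ≈ 2649 retained (≈ 44%), 59.3% female, mean
age ≈ 57, median 3 (IQR 2–5) drugs per report, ≈ 92% serious, 2.5% fatal,
with antibiotic / analgesic / cardiovascular / gastro-protective /
corticosteroid / antiepileptic profiles named after the drugs that dominate
AGEP reporting.  Inclusion probabilities were calibrated once against the
published per-drug prevalences (iterative proportional rescaling at
n = 40 000), and the background scale and single-drug fraction against the
median/IQR and retention targets (`calibrate_background_scale` implements
the bisection); the resulting values are frozen in the config and not
data-dependent at run time.

`planted_two_profile_config()` is the community-recovery benchmark: two
disjoint 5-drug profiles (inclusion 0.8, activation 0.35 each) over 1200
background drugs at rate 0.005, n = 5000.  The background pool is
deliberately wide so that reports activating no profile still usually meet
the ≥ 2-drug criterion: retention then barely conditions on profile
activity, profile activations stay ≈ independent in the analyzed cohort,
and cross-profile pair O/E concentrates near 1 while within-profile pairs
are strongly over-represented (O/E ≈ 2.8) — at the cost of an unrealistically
high drugs-per-report mean (~10) in this benchmark only.  Because the 25
cross-profile pairs share their 10 marginal counts, the sampling error of
their mean O/E is estimated by a report-level bootstrap, not a per-pair
standard error (which understates it ~6-fold).

**The reference cohort** (`agepnet.synthetic_reference`) is a deterministic
N = 2649 cohort that *exactly* realizes the published marginal counts of the
six drugs whose marginals are printed, every published pair/triad count
among those six, the thickest cardiovascular edge, and the published
demographic margins.  Exact simultaneous realization of *all* published
pairs and triads is impossible with ≤ 3-drug reports (published triads
overlap inside larger real reports: the triads containing
amoxicillin + furosemide already sum past that pair's printed count), so the
cohort realizes this closed subset.  It is a validation fixture for the
arithmetic and the network/table plumbing — not a reconstruction of the
real data, whose cluster memberships it cannot and does not reproduce.

### What passing tests do and do not show

The synthetic sources emulate block-structured co-prescription, heavy-tailed
marginals, missingness and duplicate/noise patterns.  They do not emulate
reporting-over-time dynamics, country-level reporting heterogeneity,
MedDRA coding choices, correlated demographics (beyond the optional
age–death link), or the confounding-by-indication that shapes real
co-reporting.  Green tests therefore certify the statistics and algorithms,
not any clinical claim about real drug combinations.

## Numerical choices

* Modularity uses dense adjacency with self-loop weights doubled (row sums
  are then weighted degrees; `A.sum()` is 2m) — exact for the graph sizes
  this package targets (thousands of nodes).
* Louvain accepts a move only if its gain exceeds the current best by
  1e-12; outer iterations stop when Q improves by ≤ 1e-12.  A stored
  partition's Q reproduces from the graph and labels to within 1e-12.
* Eigen tolerance 1e-9 (leading eigenvalue at or below it counts as
  non-positive and stops bisection).
* Half-up decimal rounding (not banker's) for displayed percentages and
  ratios, matching the convention of published tables.
* Ties everywhere break lexicographically (drug names) or by smallest
  community label, making every output order-stable.

## Known limitations

* O/E ratios carry no uncertainty quantification by design; rare-combination
  ratios are noisy and should be read alongside their counts.
* The independence null ignores confounding by indication; O/E > 1 flags
  co-reporting, not interaction.
* Louvain is a greedy heuristic: on large graphs the partition is a local
  optimum that can depend on the seed (the seed is therefore part of the
  pipeline config and recorded in the manifest).
* The exhaustive modularity oracle is limited to ~10 nodes (Bell-number
  growth) and exists only for validation.
* The generator's profiles are mutually independent blocks; real regimens
  correlate (e.g. antibiotic + analgesic), which the default config does not
  model.
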