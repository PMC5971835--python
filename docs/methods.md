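# Methods

## Background and scope

Zygantral facets on snake vertebrae accrete bone appositionally and show
no internal remodelling, so the grooves between successive growth ridges
record every annual growth cycle from hatching to death. Counting those
lines gives a per-vertebra age in years; along one articulated column the
counts agree almost everywhere, diverging by at most one line on a small
fraction of facets. `zygochron` turns this observation into a two-stage
pipeline: stage 1 summarizes articulated reference columns; stage 2
resolves commingled, isolated vertebrae into candidate individuals.

## Stage 1: column profiling

**Count tables.** Per-side tallies run over intact facets only. The
per-vertebra ("combined") tally uses the *both-sides-divergent* rule: a
vertebra is tallied at the column-modal count when at least one intact
facet shows it, and at its own (shared, or maximal) divergent value only
when both facets miss the mode. This is the convention under which the
published combined columns for six extant species are reproducible from
their per-side tallies, and it makes the combined total equal the number
of vertebrae with at least one intact facet.

**Percentages.** Integer percents are `floor(100·tally/total + 0.5)`
(round half away from zero). This is the only integer rounding consistent
with all 36 printed percentage cells of the reference count table; no
exact .5 case occurs in those data. Percents are derived from tallies on
demand and never stored.

**Modal age.** The modal combined count with its support fraction; ties
are reported as ambiguous with all candidates — never silently broken.

**Centrum statistics.** Arithmetic mean, *sample* (n−1) standard
deviation, and CV% = 100·σ/mean. The source material does not state the
σ denominator; the sample convention is this package's choice. Published
σ(%) cells are treated as authoritative constants where they disagree in
the last digit with recomputation from the rounded mean and σ.

**Spacing patterns.** The consensus pattern is the element-wise mean of
normalized line-position vectors restricted to modal-count facets.
Dissimilarity between two patterns is the RMS difference of aligned
positions; patterns whose lengths differ by one are aligned by dropping
whichever terminal element of the longer minimizes the RMS. On
equal-length patterns this is a scaled Euclidean distance, hence a
pseudometric.

## Stage 2: fingerprinting

**Combined count for isolated vertebrae.** The default `max_intact`
policy takes the larger intact facet count: divergent facets
overwhelmingly show one line too *few* (faint peripheral lines are lost,
not invented), so the maximum is the better point estimate, and the rare
opposite case is absorbed by the ±1-year margin. `agree_only` is
available for users who prefer to flag disagreement instead.

**Compatibility rule.** Records u, v are compatible iff
(a) |c(u) − c(v)| ≤ age_margin (default 1, the observed intra-column
variation); (b) when both centrum lengths are present,
|L(u) − L(v)| ≤ k_sigma·(cv_percent/100)·mean(L(u), L(v)) with k_sigma = 2
by default — the *pair mean* is used as the reference scale because it is
symmetric and order-invariant; and (c), only when a spacing threshold is
configured and both records carry patterns, RMS dissimilarity below the
threshold. A missing centrum length passes the size test by default
(policy `pass`): excluding an otherwise-compatible record would silently
raise the individual count. The size envelope is evaluated at both
cv_percent = 12.7 and 19.5 — the within-column CVs of the two extant
species bracketing the fossil phylogenetically — and both results are
reported; on the packaged fossil data they are identical.

**Admissible partitions.** An assignment of vertebrae to individuals must
put pairwise-compatible vertebrae in each individual (blocks are cliques
of the compatibility graph) and must not leave two individuals that could
be one (no two blocks whose union is a clique — the *coarsest* condition).
Formalizing "either four or five individuals" as the span of block counts
over coarsest clique partitions is the central interpretive decision of
this package: it excludes the all-singletons reading (a mergeable pair is
never left split) while still exposing genuine ambiguity, and it exactly
reproduces the published per-lot ranges (4,5) and (4,4) and totals (8,9).

The enumerator builds blocks one at a time, each containing the smallest
unassigned node, iterating over all cliques containing that node and
pruning any branch whose newly closed block is mergeable with an earlier
one; every admissible partition is generated exactly once. Components are
enumerated independently and combined by Cartesian product. Enumeration
is exponential in general, so graphs above a configurable cap (default 16
nodes per lot) are refused rather than silently truncated. A brute-force
oracle (filter all set partitions, via sympy) verifies the enumerator on
random graphs in the test suite. The minimum block count over admissible
partitions equals the minimum clique cover of the graph, because merging
two mergeable blocks never increases the count.

**Candidate labels.** To reproduce "2, 3"-style entries: take the finest
admissible partition (ties broken by a deterministic block key), number
its blocks ascending by their youngest member — label 1 is the youngest
candidate individual; in any admissible partition a record inherits the
minimal reference label present in its block, and a record's candidate
set is the union over partitions. On the packaged fossil data this
reproduces every printed individual-count entry of both lots.

**Per-lot analysis** is the default: lots collected separately are kept
separate, and totals are sums of per-lot minima and maxima. `--pool`
enables cross-lot edges for users who reject the taphonomic separation.

**Age structure** reports min, median (midpoint rule for even n) and max
of the combined counts, with per-count tallies.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes; it
defines the conditions under which the recovery guarantees are tested.

**Growth law.** The source observations give spacing patterns (line
spacing decreases monotonically toward the facet periphery; in a two-year
reference individual the first line sits at about 2/3 of facet length)
but no growth equation. We adopt a saturating, von-Bertalanffy-form law
L(t) = 1 − (1 − l0_frac)·exp(−k_rate·t), which yields geometrically
decreasing spacings for any parameters. Line i of an individual dead at
age A sits at L(i)/L(A + s), with s = 0.15 yr of post-line terminal
growth. Defaults l0_frac = 0.1, k_rate = 0.7 are calibrated so the
two-year default individual puts line 1 at 0.691 ≈ 2/3 and line 2 at
0.972, near the perimeter. Deep in saturation (k·age ≳ 35) exact
positions become closer than double precision; positions are then nudged
apart by single ulps so the strictly-increasing invariant survives.

**Counting noise.** Per facet, independently: one line fewer with
`miscount_prob` (default 0.03), one extra with `overcount_prob` (default
0.005), unscorable with `damage_prob` (default 0.01). The downward bias
reflects the observed direction of divergence; the small upward rate
covers the documented opposite case. Per-side independence makes
both-sides-divergent vertebrae occur at roughly the squared rate,
matching their reported rarity when per-side rates are a few percent.
Miscounted facets drop a uniformly chosen line; overcounts insert one at
the midpoint of a uniformly chosen gap.

**Centrum lengths.** Column-wide size variation is mostly positional, not
noise, so lengths follow a smooth symmetric hump (1 + a·sin(πx), peaking
mid-column) carrying ~70% of the target variance, times independent
multiplicative noise carrying the rest; the hump amplitude is solved by
bisection against the realized discrete profile so the column CV
approximates `cl_cv_percent` (default 12.7). Only the realized CV is
contractually tested (within 20% relative error for n ≥ 100).

**Assemblages** concatenate columns, drop vertebrae independently with
`fragmentation_prob`, strip column position and specimen identity,
anonymize and shuffle record ids, and emit a ground-truth table. All
randomness flows through one explicit seeded `numpy` generator; a fixed
seed fixes the complete output stream bit-for-bit.

**What the simulator does not model.** Taphonomic colour/preservation
differences between lots, spatial clustering of miscounts along the
column (divergent vertebrae are placed independently; any real clustering
structure is unknown), resorption (absent in this skeletal element by
assumption), and inter-specific differences in growth law. Passing
recovery tests therefore demonstrates correctness of the combinatorial
machinery under the stated assumptions, not robustness to real-world
violations of them.

## Numerical and procedural choices

* Absent values are explicit (`None`), never zero: absence drives the
  missing-length policy and the damage report.
* Table dialect: comma-delimited UTF-8, header required, "." decimal
  separator, positions packed with ";" — one documented dialect, no
  sniffing.
* Recovery tests use assemblages of 2–6 individuals with pairwise age
  gaps ≥ 2 years, 3–6 vertebrae each, no counting noise, and a small
  (2%) column CV so that every within-column pair is certain to sit
  inside the 2σ·12.7% envelope. At realistic column CVs (12.7–19.5%) the
  extreme vertebrae of a *long* column can legitimately violate the
  published 2σ rule (the full range of a sample exceeds 2σ as n grows) —
  a property of the rule itself, relevant mainly to near-complete
  columns, not to the few-vertebrae lots it was designed for.
* Noisy-column modal-age checks use 100 columns of length 60 with the
  default noise rates; the exact-enumeration cap is raised to 40 nodes for
  simulated assemblages, whose components stay small.
* CLI exit taxonomy: 0 ok, 1 validation/data, 2 usage, 3 size cap. Logs
  go to stderr; every output embeds the echoed configuration and seed, so
  re-running from the header reproduces the output byte-for-byte.

## Known limitations

* The coarsest-partition rule forbids two same-age, same-size individuals
  contributing indistinguishable vertebrae to one lot; the MNI range is
  conditional on that parsimony assumption (which is what "minimum"
  means here).
* The ±1-year margin is a constant; it does not scale with observed
  damage rates.
* Exact enumeration is exponential; the cap refuses rather than
  approximates. Assemblage-scale inputs (tens of vertebrae per lot, sparse
  compatibility) are well inside the practical range.
* Spacing-pattern compatibility is off by default because no quantitative
  threshold is established; the RMS dissimilarity is provided for users
  with calibration data of their own.
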