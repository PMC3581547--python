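# Methods

## CNV density and locus selection

The per-chromosome CNV density is the count of catalogued CNV loci on a
chromosome divided by its length in bp. Chromosome length biases raw counts,
so densities are normalized by the mean raw density over all chromosomes of
the genome build; by construction the normalized values average to exactly 1,
and the package property-tests this to 1e-12. A chromosome is flagged
*enriched* when its normalized density exceeds 1 by more than one sample
standard deviation (n−1 denominator) of the normalized densities. Because the
mean of the normalized values is 1, "mean + 1 SD" and "1 + SD" coincide. The
normalization is a reconstruction: the source analysis presents its density
formula only as a figure, and the reconstruction here is fixed by two
constraints of its narrative — values are interpreted relative to 1 (the mean
of all chromosomal densities), and chromosomes within one SD of the mean are
not called enriched. Chromosomes with zero CNVs are retained; they lower the
mean and are never enriched.

Locus selection keeps CNVs reported as only-deleted or only-duplicated by at
least 2 independent studies, and CNVs reported with both states by at least 6
("more than 5"), both thresholds configurable. The filter is idempotent and
order-preserving.

## miRNA mapping and CNV state

Coordinates are held internally 0-based half-open (BED convention); tabular
inputs declare their convention and are converted on read. Overlap is computed
by a sorted endpoint sweep, O((n+m) log(n+m)) plus output size, checked in the
test suite against an all-pairs oracle. The default assignment policy is full
containment — a hairpin partially clipped by a CNV breakpoint is not a clean
copy-number change of the miRNA — with `any_overlap` (≥ 1 bp) available.
Strand is ignored: CNVs are unstranded events.

A miRNA's state is the union over the classes of all loci containing it:
DELETED if every host locus is deletion-only, DUPLICATED if every host locus
is duplication-only, DELETED_DUPLICATED otherwise (any both-class locus, or
membership in loci of opposite classes). The three states partition the mapped
miRNAs. Distinct genomic copies of one miRNA family (e.g. miR-124-1 vs
miR-124-3) are distinct records.

## Consensus targets and the bipartite network

A (miRNA, gene) pair becomes a PREDICTED edge only when every one of the
required prediction sources (default: miranda, mirdb, mirwalk, targetscan)
reports a 3′UTR site with a seed match of at least 7 nt; any validated
interaction row yields a VALIDATED edge regardless of consensus, and
VALIDATED supersedes PREDICTED for the same pair. The filter is monotone:
enlarging the required source set never adds edges, lowering the seed
threshold never removes them. Gene symbols are upper-cased and trimmed before
any set operation, since merged symbol lists from different databases disagree
on case.

Edges are semantically directed miRNA → gene, but all topology metrics are
computed on the undirected view, following the conventions of the
NetworkAnalyzer-style tooling whose metric set this module reproduces; the
directed count survives as `out_edge_count`. Definitions (unit edge weights,
per connected component):

- `avg_shortest_path(v)`: mean distance to reachable nodes; `closeness = 1/asp`
  (not the (k−1)/Σd variant);
- `eccentricity(v)`: max distance within the component;
- `radiality(v) = (Δc + 1 − asp(v))/Δc` with Δc the component diameter;
- `betweenness(v)`: Brandes pair-dependencies, endpoints excluded, normalized
  by (n−1)(n−2)/2 *within each component* (the analysed networks are
  disconnected, so whole-graph normalization would deflate small components);
- `stress(v)`: number of shortest s–t paths through v;
- `topological_coefficient(v)`: mean over partners sharing ≥ 1 neighbor of
  (shared neighbors + 1 if adjacent)/degree(v); 0 for nodes of degree ≤ 1,
  matching the reference tool's convention;
- isolated nodes take 0 for every path-based metric; radiality of a singleton
  component is 0.

Distance and shortest-path-count matrices come from per-component BFS;
betweenness and stress are evaluated from them directly. The whole metric set
is acceptance-tested for exact (integer) / 1e-9 (real) agreement against a
brute-force all-pairs-BFS, exhaustive-path-enumeration oracle on 200 seeded
random bipartite graphs.

Hub ranking is by degree, descending, ties broken lexicographically, over the
miRNA side by default (the regulators are the actionable hubs; a flag widens
to all nodes). The power-law check is a descriptive least-squares line on
log10 count vs log10 degree over positive-count bins — not a maximum-
likelihood fit — because the underlying claim it supports is qualitative.

## Null comparison and knockouts

The null model resamples, uniformly and reproducibly under a seed, an equal
number of miRNAs from outside the CNV set and rebuilds the network by the
identical procedure; it is a resampled-node null, not an edge rewiring.
Per-node metric vectors of the two networks (all nodes by default, one
partition side optionally) are compared with the two-sample KS test.
D is the maximum ECDF gap over the pooled points. The exact p-value is the
full permutation p over all C(n+m, n) label assignments, computed by
lattice-path counting in exact integer arithmetic (valid for untied samples,
n·m ≤ 10 000); it matches full enumeration exactly on small samples and
scipy's exact method to 1e-16. The asymptotic p uses the Kolmogorov tail at
λ = (√ne + 0.12 + 0.11/√ne)·D. Its type-I error at α = 0.05, n = m = 100 is
calibrated to [0.03, 0.07] in the acceptance suite; against the exact p it can
deviate by up to ≈ 0.04 at mid-range p for n = m = 50 (tail p-values agree
much more closely). Benjamini–Hochberg adjustment is reported across the
compared properties.

**Caveat.** Per-node path-derived metrics (average shortest path, closeness,
eccentricity, radiality, neighborhood connectivity, stress) are strongly
dependent within one network — a fluctuation in global structure shifts the
whole vector — so treating them as iid samples makes the KS comparison
anticonservative for exactly those metrics: between two *independent
replicates* of the generator with no planted difference, they reject at rates
far above nominal, while degree, betweenness, topological coefficient and
directed edge count stay near nominal (property-tested ≤ 0.10). Significance
calls on path-based properties from this comparison should be read as
descriptive, not calibrated — which also tempers the interpretation of the
published procedure this stage mirrors.

Knockouts remove each listed node independently from the intact network
("one at a time"; a cumulative mode is available) and recompute the global
properties. Count-valued changes (connected components, isolated nodes) are
tested with single-observation Poisson count tests: the default Wald statistic
z = (x₂ − x₁)/√(x₁ + x₂), and the exact conditional test (given N = x₁ + x₂,
two-sided equal-tail binomial at p = ½). The underlying published analysis
names only "a t-test for Poisson counts" without a formula; both tests here
are standard constructions and both are reported. They agree within 0.02 when
the counts clearly differ (max gap ≈ 0.006 over a seeded sweep of Poisson(30)
vs Poisson(90) pairs with N ≥ 100) but can differ by up to ≈ 0.08 at
near-equal counts, where both p-values are near 1 and no call changes. A
metric at 0 before and after removal carries no information and is reported
untested. Whether diameter, characteristic path length and density moved
beyond 1e-9 is reported alongside.

## Dosage, inverse pairs, loops, biogenesis

The dosage partition intersects the target sets of the three miRNA CNV
classes into 7 disjoint regions covering all targeted genes. Exclusive regions
get directional labels — deleted-only → INCREASE (losing a repressor raises
target dosage), duplicated-only → DECREASE, mixed-class-only → FLUCTUATE —
the triple intersection is CENTRAL, and the three pairwise-only regions, for
which no single direction is defensible, are labelled MIXED rather than given
an invented direction.

Inverse pairs scan individual-level calls for a miRNA carried in one state and
a network target of that miRNA carried in the opposite state (any two
individuals); both orientations are emitted, and the search can be restricted
to the top hubs. TF loops: for every miRNA→TF interaction, the TF-mediated
loop affects the disease genes of that TF's regulon; genes the miRNA also
targets directly upgrade it to DUAL. TF identifiers live in a namespace
separate from gene symbols even when lexically identical, because TFs are
simultaneously targets and regulators. The per-TF summary counts disease genes
per regulon and the union coverage of the network's disease targets. The
biogenesis stage filters the (unrestricted) CNV-miRNA edge set to the 13
miRNA-processing genes, kept under their legacy published symbols (HIWI, P68,
P72, RNASEN) without modernization, and counts distinct regulators per gene,
retaining zero-regulator genes.

## Synthetic data generator

`synthgen` emulates the statistical structure the analysis assumes: CNV loci
placed with probability ∝ chromosome length × enrichment multiplier, class
drawn from a three-point law, supporting-study counts from a shifted geometric
law (minimum 1, so both filter branches are exercised); miRNA and gene loci
placed uniformly; per-miRNA true target sets with planted high-degree hubs;
each true pair detected independently by each of 4 sources with probability
`source_detection_prob` (seed ≥ 7 nt with probability 0.9, 3′UTR with 0.95),
plus per-source false pairs and a validated subset; a disease gene list as a
random universe fraction with hub targets favoured (p = 0.8); individual-level
calls for CNV-resident elements with states consistent with the host locus
class; and TF regulons over the disease genes. One seed per bundle is split
into named substreams per output file, so adding an output type never perturbs
the others. Consensus survival of a true pair has the closed form
(0.9·0.9·0.95)⁴ ≈ 0.35 at the defaults, property-tested within 3 standard
errors.

Defaults mirror the catalog-scale study the pipeline was designed around:
24 chromosomes (250→50 Mb), 1145 CNV loci with three 3×-enriched chromosomes,
a 500-miRNA universe, a 1000-gene universe including the 13 biogenesis
symbols, 10 planted hubs, and a background target count of 50 chosen so that
after 4-source consensus (~0.35 retention) and disease-gene restriction the
network lands near the published scale (~60–70 CNV-miRNAs, ~900–1200 edges,
mean regulator degree ≈ 13–15). What the generator does *not* emulate: real
genomic coordinate structure, sequence-based seed matching, correlated errors
between prediction programs, study-level ascertainment bias, or linkage
between CNV loci — so passing tests demonstrate the correctness and
calibration of the machinery on known structure, not fidelity of any
biological conclusion on real catalogs.

Tests and the acceptance script run reduced configurations (4–6 chromosomes,
tens of miRNAs, 30–600 CNVs, 100 seeded replicates) — sizes at which the
planted-structure recovery rates are already saturated, chosen as the
package's standard small-problem regime.

## Numerical and design choices

- Coordinates: internal 0-based half-open everywhere; readers convert from a
  declared input convention (default for CNV tables: 1-based closed,
  browser-style) and reject inverted or non-positive intervals with line
  numbers. Duplicate prediction rows collapse with a logged count.
- Hub ties are broken lexicographically and logged; `rank_hubs` returns
  min(k, candidates).
- Isolated-node and singleton-component conventions are 0 (documented above)
  to avoid infinities.
- The exact KS method refuses cross-sample ties (the permutation distribution
  is no longer that of the tie-free statistic); the asymptotic method
  evaluates ECDF gaps at pooled points, which handles ties.
- Poisson tests refuse x₁ = x₂ = 0.
- The pipeline writes every stage artifact before running downstream stages,
  records input SHA-256 checksums, per-stage counts and the failed stage (if
  any) in `manifest.json`, and is byte-reproducible for identical config and
  seed.

## Known limitations

- The KS comparison over path-derived per-node metrics is anticonservative
  (see caveat above); interpret those p-values descriptively.
- The power-law fit is descriptive regression on binned counts, biased
  relative to maximum-likelihood estimators; it is not intended for inference.
- The generator's independence assumptions (sources, loci, individuals) are
  idealized; real prediction programs share features and errors.
- Exact KS is limited to n·m ≤ 10 000 and untied samples; beyond that, the
  corrected asymptotic tail is used.
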