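# Methods

## Network model

A *dataset* is one screen's identifier list together with its core gene
symbol, organism and technique label. Building a dataset yields a wheel: the
validated core node plus one directed edge `core → target` per resolved
target, typed with the technique. Self-loops (a core listed among its own
targets) are dropped by default with a warning — they carry no information
in a wheel — and can be enabled per call.

Merging takes the union of node sets keyed by primary identifier and the
union of edges de-duplicated on the `(source, target, interaction type)`
triple. The same ordered gene pair contributed by two datasets under
different techniques keeps both edges: provenance must not be lost, and
Cytoscape renders parallel edges. Merging is order-independent up to the
canonical row order (dataset registration order, then input row order),
which makes output files diff-stable.

Curated interactions are stored as unordered pairs with a recorded query
gene; at integration time the edge is emitted `query-gene → partner`, typed
`genetic` or `physical`. Integration is monotone — it only adds nodes and
edges — so a network never loses screen evidence by consulting the resolver.

## Identifier resolution

The resolver contract has three duties: validate a core symbol (fatal on
failure — a misspelled core makes the whole wheel meaningless), update
submitted identifiers to current primary identifiers, and return curated
interactions. Symbol matching is exact first, then case-insensitive with a
warning, because user-typed symbols vary in case while database symbols are
canonical.

Unresolved identifiers are never silently dropped: they are reported, and by
default passed through as bare nodes (primary identifier = submitted text)
so that offline fixtures and partially-resolvable lists keep stable network
sizes; a switch excludes them instead. Identifier updating and interaction
fetching are independent switches, since a user may want current
identifiers without pulling interactions.

The live backend speaks the InterMine JSON web-service API (batched, one
retry); the local backend is driven by two CSV tables (submitted →
primary/symbol/secondary mapping; `id_a,id_b,kind` interactions) and is the
deterministic path all tests use.

## Attribute mapping

Attributes are either *List* (membership) or *valued* (discrete/continuous).
Identifiers in attribute tables are updated through the resolver before
mapping, so the emitted `Mapping Key` column joins cleanly onto the network
CSV in Cytoscape. Booleans are written as literal `true`/`false` (the
strings Cytoscape discrete mappings key on); valued cells pass through as
the exact text read from the source, avoiding float round-trip surprises.
Every network node gets exactly one row whether or not any attribute
matched it, because unmatched nodes must fall back to the default style
rather than disappear from the table. Within one table a duplicated
identifier keeps the last value with a warning; a duplicated attribute
*name* across tables is an error.

## Filtration

Degrees are computed on the simple directed graph: parallel edges between
one ordered pair (different interaction types) count once, so type
multiplicity never inflates connectivity. Total degree (in + out) is the
default criterion because it matches the intuition of a *terminal node* — a
node attached to the rest of the network by a single link — and it makes a
2-cycle (mutual feedback) self-sustaining at threshold 2. The alternative
`in_or_out` mode (keep when either in-degree or out-degree alone meets the
threshold) is exposed because the phrase "in/out degree ≥ 2" is genuinely
ambiguous; both modes are tested against an independent one-node-at-a-time
pruning oracle, whose fixpoint is unique regardless of removal order.

Two passes are the default (terminal nodes, then newly-terminal linkers);
`fixpoint` iterates until stable, which is idempotent and removes every
linear path. Core genes get no protection: a collapsed wheel drops.

## Enrichment statistics

Classification is `value ≥ threshold` with the boundary included (default
50, the RPKM convention for "highly expressed" in the motivating data).

The test statistic is the hypergeometric **point** probability
(`dhyper(x, m, n, k)` semantics), not the tail sum — this is what the
motivating analysis computed, and the package reproduces its printed values
as point masses; the upper tail is available behind a flag. No
multiple-testing correction is applied by default (none was applied in the
motivating analysis over its four tests); a Bonferroni factor is trivially
applied by the caller over the report's row count.

Numerically, the point mass is evaluated in log space via the saddle-point
binomial factorization
`dbinom(x; m, π) · dbinom(k−x; n, π) / dbinom(k; m+n, π)` with
`π = k/(m+n)`, where each binomial density uses log-gamma for small counts
and Stirling-series remainders (`stirlerr`) plus a stable binomial deviance
(`bd0`) elsewhere. Direct log-gamma differencing of binomial coefficients
loses about five significant digits to cancellation at populations of 1e4;
the saddle-point form keeps relative error at a few ulp, verified
exhaustively against big-integer rational arithmetic for all populations up
to 60 and by whole-support normalization (sums within 1e-12) at populations
up to 1e4. Tail sums accumulate the point masses over the support directly
— supports here are at most ~1e4 wide, where pairwise float summation is
already at the 1e-14 level.

In the enrichment report, each core wheel is tested against the genome
background supplied by the caller (genome high / not-high counts are
explicit inputs, never derived from the network), while multi-core
co-target blocks are tested against the network's own high/not-high split —
the question being whether shared targets are enriched *beyond* the
combined wheels.

## Synthetic fixtures

The generators emulate the combinatorial skeleton of a multi-core
target-list study and nothing else: no DamID signal distributions, no
RNA-seq count noise, no real identifier vocabulary. Exclusive overlap
blocks are assigned directly from a seeded permutation of the universe, so
planted truth is exact rather than approximate; passing the recovery tests
therefore shows that the pipeline's set arithmetic, resolution and
partitioning are correct, not that the method is robust to noisy real
screens.

Defaults are matched to the motivating study's scale: three cores with
1072, 3692 and 309 targets in a 15682-gene universe, a three-way
co-regulated block of 23 genes, a genome-wide high-expression rate of 8%
(1251/15682 ≈ 0.080) and a planted rate of 35% (8/23 ≈ 0.35), threshold 50.
The pairwise overlaps (150, 40, 60) are not published quantities; they were
chosen once as plausible for screens of these sizes and yield a combined
network of ~4850 genes, close to the study's 4458. Expression values are
drawn uniformly within [0, threshold) or [threshold, 1000] and rounded to
two decimals, guaranteeing classification recovers the planted high set
exactly. Identifiers follow a fixed-width `SYN0000001` pattern so
format-sensitive code paths see realistic accession-like strings.

Stale aliases (`OLD...`) exercise identifier updating; planted feedback
2-cycles among network members must survive fixpoint filtration, and
planted leaf edges to outsider genes must not.

## Problem sizes in the test suite

Unit tests run on toy graphs and tables. The system-level suite runs the
full-scale synthetic study for 20 seeds (~0.15 s per seed), checks the
hypergeometric implementation exhaustively for populations ≤ 60 (~800k
instances, vectorized), and validates filtration on 500 random ≤ 30-node
digraphs — the whole suite completes in well under a minute.

## Known limitations

* The live InterMine backend is a thin client and is not exercised by the
  offline test suite; endpoint schemas drift, and the query templates may
  need adjustment per mine.
* The co-target partition keys on direct `core → node` edges only; indirect
  regulation through intermediate nodes is out of scope.
* List-attribute ingestion consumes prepared CSV lists; retrieving GO
  category membership from annotation services is deliberately not
  implemented.
* Visual styling and layout are left entirely to Cytoscape; the package
  emits data, not style.
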