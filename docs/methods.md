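# Methods

## The network model

`mirnet` analyses a disease-centred, heterogeneous regulatory network built
around a set of microRNAs. Nodes are biological entities with one or more
roles — `MIRNA`, `TF` (transcription factor), `TCOF` (transcription
co-factor), `TARGET` (disease-associated miRNA target) — plus a
disease-association flag. miRNA names and gene symbols are treated as
disjoint namespaces, so a node never mixes the `MIRNA` role with a protein
role; a protein may carry several protein roles at once (e.g. a TF that is
itself a disease gene).

Three edge types connect them:

| type | direction | meaning |
|---|---|---|
| `TARGETING` | miRNA → protein | experimentally verified target repression |
| `REGULATION` | TF → miRNA | predicted binding site in the miRNA gene's promoter window |
| `PPI` | undirected | protein–protein interaction (including TF–TcoF links) |

Construction from the five association tables applies these retention
rules: keep every miRNA with at least one verified target on the disease
gene list, and those targets; keep every TF with at least one binding-site
hit (core and matrix score ≥ 0.9, inclusive) inside a retained miRNA's
promoter window; keep every TcoF with a high-confidence interaction with a
retained TF; induce PPI edges on the retained protein set only, so no
partner proteins outside the four role classes enter the network. Multiple
binding sites of one TF in one promoter collapse to a single `REGULATION`
edge; PPIs are deduplicated on the unordered endpoint pair, and
self-interactions are kept as a single undirected self-edge. TF–TcoF
associations enter as `PPI` edges (there is no fourth edge type); the TcoF
identity survives as a node role. A protein that appears both on the
disease gene list and as a retained TF becomes one node with both roles.

Two promoter windows are supported (1000 nt core promoter, 5000 nt
extended); since every 1000 nt hit is also a 5000 nt hit, the core-window
network's regulation edges are a subset of the extended network's.

Identifier handling is case-preserving exact string match. Alias/orthology
mapping is out of scope; an id referenced by a network edge file but absent
from the nodes file is a hard error naming the id, never a silent drop.

## Stochastic edge-weight node ranking

Each node `n` is scored by its first- and second-degree outgoing edges:

    S_n = Σ e_n1 + w · Σ e_n2

where `e_n1` sums the type weights of n's outgoing edges, and `e_n2` sums
the type weights of the outgoing edges of n's *distinct* first-degree
out-neighbors. Edge weights depend only on type: `e_t = 1` for targeting
(verified, directed — most trusted), `e_r` for TF→miRNA regulation
(predicted but directed), `e_i` for PPIs (undirected — least informative).
Undirected PPI edges count as outgoing from both endpoints, so proteins
whose only connections are PPIs still score.

Rather than committing to one weighting, each repetition draws
`e_r ~ U(0,1)`, then `e_i ~ U(0, e_r)` — enforcing `1 = e_t > e_r > e_i > 0`
by construction — and the second-degree discount `w ~ U(0,1)`. One draw is
shared by all edges of a type within a repetition (three scalars per
repetition, not per-edge weights; draw order is fixed as `e_r, e_i, w`).
Nodes are ranked by score (rank 1 = highest); the final statistic is each
node's mean rank over 10,000 repetitions (default).

Numerical/design choices that the score definition leaves open:

* **Ties** within a repetition receive the fractional (average) rank of the
  positions they occupy. This makes the per-repetition rank mean exactly
  `(N+1)/2` — a conservation law the test suite checks — and removes any
  dependence on node order. The *final* output additionally assigns
  positions 1..N by ascending average rank, ties broken lexicographically.
* **First-degree sums are per edge**: a neighbor reachable through two edge
  types contributes both weights. **Second-degree sums are per distinct
  neighbor**: each out-neighbor contributes its full weighted out-degree
  once, including edges pointing back at `n` (for a lone PPI pair D–E with
  weights `e_i = 0.25, w = 0.5`, `S_D = 0.25 + 0.5·0.25 = 0.375`). Excluding
  back-edges is available as `include_backlinks=False` for sensitivity
  analysis; the default keeps the formula as stated.
* The ranker is vectorised: per-node edge-type counts `C (N×3)`, a sparse
  neighbor indicator `A (N×N)`, and scores for a batch of `R` draws as
  `S = C·Wᵀ + w ⊙ (A·C·Wᵀ)`, ranked column-wise. Repetitions are chunked to
  cap the dense score matrix at ~2·10⁷ entries. A 10,000-repetition run on
  a ~658-node / ~20,000-edge network takes a few seconds on one CPU.

The score resembles a two-step, out-edge-restricted Katz-style influence
measure; no expression levels or interaction signs enter the model.

## Motif census

Two motif shapes are enumerated, both requiring exact edge-set membership:

* **self-loop**: miRNA `m` targets one of its own predicted TFs
  (`REGULATION tf→m` and `TARGETING m→tf`). Reported both as distinct
  (miRNA, TF) pairs and as distinct miRNAs, since either convention is
  defensible.
* **feedback loop**: ordered triple (tf, mirna, target) with
  `REGULATION tf→mirna`, `TARGETING mirna→target`, a PPI between target and
  tf, `target ≠ tf`, and the target disease-associated. Loops are counted
  as distinct ordered triples — a TF–target pair closed through two miRNAs
  is two loops. Whether the closing protein is a TcoF does not change loop
  identity; it is recorded as a `target_is_tcof` annotation. No
  activator/repressor sign inference is attempted: the data do not
  determine whether a loop is self-promoting or self-cancelling.

The enumerator walks regulation × targeting adjacency with set lookups;
tests verify exact agreement with an exhaustive O(N³) triple scan.

## Pathway enrichment

Loop-involved target genes are compared against the disease-gene background
with a one-sided hypergeometric (Fisher) tail: the probability of at least
`k` pathway members among `n` foreground genes drawn from a background of
`N` genes containing `K` members, computed exactly via
`scipy.stats.hypergeom`. No multiple-testing correction is applied for a
single pathway; Benjamini–Hochberg is available behind a flag when a
multi-pathway table is supplied. Pathway members outside the background are
ignored; a foreground gene outside the background is an error.

## Synthetic data generator

`synthgen.generate` emits the five input tables plus a ground-truth
*ledger* so every stage is testable without database downloads. What it
emulates: heavy-tailed miRNA out-degree (truncated geometric — real
targeting data has hub genes hit by dozens of miRNAs); nested promoter
windows (every 1000 nt site also appears as a 5000 nt row, and a
configurable set of "distal" TFs binds only beyond 1000 nt); binding scores
straddling the 0.9 filter threshold; low-confidence TcoF links; role
overlaps (a fraction of TFs share ids with disease targets); and four noise
channels that construction must discard (non-disease targets, failing
scores, low-confidence links, PPIs touching unretained proteins). Planted
self-loops and feedback loops are injected after background sampling and
deduplicated against it; the ledger records the final truth. Every miRNA
is guaranteed one disease target, every disease gene one miRNA, and every
TF one passing site in its window (unless the config forces all scores
below threshold), so the configured counts equal the constructed role
counts.

The ledger (per-window expected census, per-table row counts, planted motif
lists) is computed from the generator's own bookkeeping, not by running the
construction code, which makes ledger-vs-pipeline equality a genuine
cross-check.

What it does **not** emulate: real identifier vocabularies, correlated
degree structure between edge types, database-specific biases, or
literature-derived motif frequencies. Passing tests therefore demonstrate
algorithmic correctness on data with the assumed statistical shape, not
biological conclusions about any real disease network.

`published_scale_config()` reproduces the published census scale: 162 miRNAs,
131 targets, 244 TFs (7 distal-only), 140 TcoFs, 19 TF/target id overlaps
(so 651 / 658 total nodes), with densities calibrated so expected per-type
edge counts approximate the published 434 targeting / 5327 and 14720
regulation / ~4400 PPI edges. The calibration is in expectation:
single-seed counts fluctuate a few percent (heavy-tailed degrees), and the
mean across 20 seeds sits within ~1% of the targets. Degree-distribution
shapes are conveniences, parameterised rather than fitted.

## Determinism

All randomness flows through `numpy.random.default_rng(seed)`: the
generator's tables are byte-identical per seed, and a ranking rerun with the
same seed reproduces the output file exactly. The vectorised weight sampler
consumes the random stream in the same order as the scalar one, so batch
size does not affect results.

## Known limitations

* Role assignment gives the `TARGET` role to every retained protein on the
  disease list, whether or not a targeting edge points at it (relevant only
  when a disease-listed TF/TcoF is never targeted).
* The enumeration-based enrichment oracle, and hence the exactness claim,
  covers backgrounds up to 12 genes; beyond that correctness rests on
  `scipy.stats.hypergeom`.
* The score treats multi-edges between the same pair as independent
  contributions in the first degree but collapses neighbors in the second
  degree; other conventions are defensible and would shift scores, not
  ranks' qualitative order, for sparse biological graphs.
* Loop counting allows a target that is also a TF elsewhere in the network;
  loops are topology only — no dynamics, signs, or expression data.
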