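# Methods

## Data model

A coded interview corpus consists of a **codebook** (themes with ids
"1"…"T"; codes with ids "t.k", each prefixed by its theme id), a **roster**
of interviewees (role `patient` or `expert`; experts subdivide into
`clinician_health_system` and `basic_scientist`), and a long-format
**response table** of (interviewee, code) records, optionally carrying a
per-response concern label. Files are comma-separated UTF-8 with a header
row. Public identifiers are always the string ids; matrix indices are an
internal detail.

Multiple coded phrases by one interviewee for one code collapse to a single
binary link: the incidence matrix *B* is binary by definition, so
multiplicity is discarded at incidence level. Exact duplicate rows collapse
with a logged warning; duplicates with *conflicting* concern labels are an
error, because each response carries one key statement and conflicts must be
resolved by the analyst, not silently by software. The data model permits
one interviewee to hold records under many codes (independent records); it
takes no position on whether a single phrase may feed several codes.

Row order follows the codebook, column order the roster (patients first);
this makes every output deterministic without tie-breaking rules.

## Network construction and degree statistics

The bipartite network is stored as a `networkx.Graph` with partition, theme,
role and subgroup node attributes; the dense block matrix
*A* = [[0, B], [Bᵀ, 0]] is materialized on demand and agrees element-wise
with the graph view (asserted in tests). Self-loops cannot arise. Reported
mean degrees are rounded to the nearest integer, half away from zero — the
corpus's 220 links over 16 interviewees give 13.75 → 14, and over 43 codes
5.12 → 5. Degree-maximum ties are reported as full id lists in input order.
Graph export (GraphML/GEXF via networkx) writes string node ids and the
attributes `partition`, `theme`, `role`, `subgroup`, `degree`.

## Maximal biclique enumeration

Maximal bicliques of a bipartite graph are exactly the formal concepts of
its incidence relation that have two non-empty sides. The enumerator runs
NextClosure over the smaller partition with bitmask closures: closed sets
are visited in lectic order, each concept exactly once, with cost
O(concepts · M · N) — exhaustive, not heuristic, and instant at the corpus
scale of 43×16. Output is canonically ordered (descending code-set size,
then descending interviewee-set size, then lexicographic code ids) so runs
are reproducible file-for-file. Because the number of maximal bicliques is
worst-case exponential, enumeration aborts with a `CapacityError` beyond a
configurable cap (default 10⁶). Single-node sides are legal bicliques by
default (`min_codes = min_interviewees = 1`); the thresholds only filter the
output and never change maximality.

The test suite and the acceptance script check the enumerator against an
independent brute-force oracle: enumerate every non-empty code subset, map
it to its common-neighbor column set, group candidates by column set taking
the union of row sets, and keep pairs with both sides non-empty. Exact set
equality is required on hundreds of random instances up to 12×12, and every
emitted biclique additionally passes stand-alone completeness and
maximality checks.

## Concern dichotomization and the multigraph

Responses labelled `yes` (concern voiced; negatively connoted) or `no` are
kept; `unclassifiable` (a statement that cannot be dichotomized) and
`absent` (no annotation supplied) are counted as excluded. A code retaining
no labelled response is excluded entirely — exclusion operates at both the
response and the code level. The kept counts form *B*′ with row
(#y<sub>i</sub>, #n<sub>i</sub>), each row summing to ≥ 1 by construction,
and the multigraph adjacency *A*′ = [[0, B′], [B′ᵀ, 0]] with the yes node
ordered before the no node. Conservation (Σ(#y+#n) + excluded = all
records) and the yes↔no antisymmetry (relabelling swaps the *B*′ columns and
swaps the no-concern and all-concern sets) are asserted as properties.

## The packaged corpus fixture

The fixture ships the published per-code patient/expert response counts of
a 43-code, 7-theme, 16-interviewee corpus (2 patients, 10
clinician/health-system experts, 4 basic scientists). Internal consistency
— per-theme totals recompute from per-code counts; the grand total is 220 —
is tested. Two things the fixture deliberately does **not** contain:

* the interviewee-level incidence (unpublished). Demonstration networks are
  drawn by `table1_consistent_incidence(seed)`: per code, the patient links
  are placed uniformly at random without replacement among the 2 patient
  columns and the expert links among the 14 expert columns. Row (code)
  marginals therefore hold exactly for every draw, but interviewee degrees
  are random — in particular, the corpus's reported maximal interviewee
  degree of 20 and its two-way tie are *not* reproduced, and the biclique
  census of a draw illustrates the method rather than the original corpus.
  Which named expert belongs to which subgroup is likewise an arbitrary
  (size-correct) assignment.
* the full per-code yes/no table (unpublished). The packaged
  `concern_splits_synthetic.csv` is a labelled **reconstruction**: it agrees
  with every published per-code split (e.g. 4-of-5 for informed consents
  1.1, 5-of-9 for big-data concerns 6.4, the five no-concern codes 1.6,
  2.2, 6.3, 6.5, 7.6) and with the published totals (28 dichotomizable
  codes, 22 responses excluded within them, a 5/11/12
  no-concern/controversial/all-concern partition); the splits of codes the
  publication does not break down individually were chosen freely under
  those constraints. One published percentage (83% for code 3.5) lacks a
  printed denominator and is realised as 5 of 6 classified responses.

## Synthetic-data generator

`generate(GeneratorConfig)` draws each (interviewee, code) link as an
independent Bernoulli with a group-by-theme probability — the simplest
structure consistent with different stakeholder groups attending to
different topics; dependence between links is out of scope. Lookup prefers
the most specific key: (subgroup, theme) over (role, theme) over wildcards.
Per link, the response is `unclassifiable` with probability
`unclassifiable_prob`, otherwise `yes` with the code's `concern_prob`, else
`no`.

Defaults emulate the studied corpus and are fixed once: group sizes 2/10/4,
theme sizes (7, 9, 5, 4, 5, 5, 8), uniform response probability 0.32
(≈ 220/688, the corpus density), concern probability 0.7 (≈ 96/137, the
yes-fraction of the reconstruction) and unclassifiable probability 0.14
(≈ 22/159). A single integer seed drives one explicit `numpy` generator;
no global random state is touched. `plant_biclique` forces a cross-product
of links to be present and records the planting in the dataset's `truth`;
planted links carry no concern annotation.

What passing tests on synthetic data do and do not show: they validate the
*machinery* (exact enumeration, conservation laws, marginal pinning,
calibration of the generator to its own parameters) on data with the
assumed independence structure; they cannot validate the thematic coding
itself, interviewer effects, or correlations between topics that real
interviews exhibit.

## Pipeline, reporting, CLI

`run_pipeline` composes the module operations with no hidden
transformations (tested by comparing against a manual composition) and logs
one line per stage with input/output cardinalities. Input modes: explicit
CSVs, the packaged fixture (realised marginal-consistently with the run
seed), or the synthetic generator. If no response carries a yes/no label
the concern stage is omitted with an explicit notice rather than an error.
`render_report` writes machine-readable CSVs, GraphML/GEXF exports,
fixed-style PNG plots of the degree distributions and biclique sizes, and a
plain-text summary; the manifest lists every file written. CLI exit codes:
0 success, 2 validation/format error, 3 runtime/capacity error.

## Problem sizes

The acceptance script uses 200 random ≤ 12×12 instances for the oracle
comparison, 20 sparse backgrounds for planted recovery and 200 replicates
for generator calibration; the whole run takes a few seconds on one core.

## Known limitations

* Statistics that depend on the unpublished interviewee-level matrix
  (individual degrees, the true biclique frequency table, the exact yes/no
  table) are reproduced only in distribution or via labelled
  reconstructions, never claimed as the original data.
* The generator's independent-Bernoulli links understate the clustering
  real interview corpora show; planted bicliques are the only dependence
  mechanism provided.
* One-mode projections, weighted biclique relaxations and statistical
  hypothesis testing on network metrics are out of scope.
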