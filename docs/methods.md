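# Methods

## Pedigree model and curation

A pedigree table lists one variety per row with up to two named parents.
Curation builds a directed acyclic multigraph with edges child → parent
(the direction score flows); a self-cross is a parallel edge pair to the
same parent, so out-degree counts multiplicity and is at most 2.

Rules, applied in order:

* **Synonyms** (explicit table plus a per-row `synonyms` column) are
  collapsed onto the canonical name before anything else.
* **Placeholder names** containing `unknown`, `seedling`, or the
  intermediate-hybrid marker `" x"` (flanked by a space or at the end of
  the name, to avoid hits inside words) are dropped from the node set;
  as parents they become missing slots.
* **Duplicate display names** stay as distinct records with unique ids
  `<NAME>_<n>` (`n` = file order). A parent reference to a duplicated
  name resolves only if release dates single out one candidate released
  no later than the child; otherwise the slot points at a dummy node
  `<NAME>_?`. Dummy nodes have no parents and are permanently blocked:
  score accumulates there but passes no further.
* Parents never listed as rows become implicit founder records; cycles
  are a hard error (propagation needs a DAG) rather than silently broken.

Descriptive statistics follow the same table: the missing-parentage
census counts a parent slot as unknown when its raw recorded name
contains `unknown`, `?`, `variety` or `seedling`; an entirely blank
parentage counts two unknown slots, and a half-blank record counts one
(the blank slot) — the source convention only fixes the all-blank case,
so the single-blank choice is ours. Country-of-origin statistics
normalise historical codes (BDR/DDR/GER → Germany), exclude digit-bearing
names (breeding-line codes) both as focal varieties and as ancestors —
the conservative reading, toggleable via `exclude_digit_names` — and
count up to six recent-ancestor slots (2 parents + 4 grandparents,
multiplicity included) with known country.

## Contribution propagation

Seeds `s(v)` are held as exact `fractions.Fraction` values; halving keeps
every mass a dyadic rational, so the conservation ledger balances
identically (the tests assert imbalance ≤ 1e-9; it is in fact 0). In
topological order (children first) each node's outgoing mass is

    M(v) = s(v)            if v is blocked
    M(v) = s(v) + S(v)     otherwise

split into two halves, one per parent slot: recorded parents receive
M(v)/2 each (a self-cross delivers both halves to the one parent), a
missing slot's half is lost, and a parentless node absorbs M(v) whole.
The reported score S(v) is the mass *received*; a node's own seed never
counts toward itself. The ledger splits total seeded mass into absorbed,
lost-at-missing-slots and discarded-at-blocked-nodes, and must balance
exactly — this is the principal guard against double-counting bugs.

Walk counting uses the same traversal with integer path counts: walks
W(a) sum distinct descending paths from seeded varieties (parallel edges
count separately; blocked nodes terminate passing paths but a seeded
blocked node still originates them); reach(a) counts seeded varieties
with at least one surviving path. Ranking is competition-style (tied
scores share a rank, the next is skipped) on scores rounded to two
decimals.

## Genotype-seeded tracing

For one SNP cluster, each genotyped variety is seeded with its mean
derived-allele dosage over member SNPs (missing calls excluded from the
mean). A variety observed at dosage 0 for every non-missing member gets
the −1.0 sentinel and is blocked: an introgressed haplotype cannot have
passed through a confirmed non-carrier, while the sentinel itself
propagates to full depth to penalise false lineages. Ungenotyped
varieties are transparent conduits (seed 0, unblocked): missing data is
not evidence of absence. Negative inherited mass propagates normally
through unblocked nodes. Numeric outputs are uncapped; only visual
exports clamp scores below at −1.0.

"Independent lineages" are defined operationally: take the top-25
positive-scoring ancestors, add every variety on a directed pedigree
path between two of them, and report the weakly connected components,
each with its ancestor-most (apex) nodes flagged as candidate donor
entry points. The connected-component reading is an explicit
interpretation; conflicting parentage records are retained as parallel
paths and surfaced, not adjudicated.

## SNP filtering and clustering

A SNP is *modern* when every non-missing historical (pre-cutoff, default
1945) dosage equals 0, or every one equals 4, and at least one later
sample departs from that value; SNPs unobserved in all historical
samples are excluded and logged. For clustering, each SNP is a point in
sample-dosage space (missing imputed as 0), projected onto the first 5
principal components (mean-centred, unscaled — dosages share one scale)
and grouped by HDBSCAN (`min_cluster_size = 5`, `min_samples = 5`,
`allow_single_cluster = True` so the degenerate one-block case is not
refused). Noise points are discarded; clusters below mean carrier
frequency 0.003 in the focal panel are dropped; each cluster is assigned
to its members' majority chromosome (minority members kept and logged),
numbered per chromosome in descending mean frequency — an
interpretation, since the source ordering criterion is unstated — and at
most 25 clusters per chromosome are kept. Frequencies are carrier
fractions (dosage > 0 among focal genotyped varieties), not allele
fractions. A cluster is high-confidence when any member allele occurs in
at least 5 focal varieties. First-observed attribution maps each allele
to its earliest-released carrier (ties break by sample id and are
logged; suspect samples can be dropped and the map recomputed), and a
cluster's attributed origin is the majority vote over members.

## Temporal reports

Haplotype groups come from agglomerative clustering of per-variety
dosage vectors (Euclidean, average linkage, cut at exactly k groups,
default k = 8; varieties pre-sorted by id so results are input-order
invariant). Occurrence over time bins focal genotyped varieties into a
pre-cutoff group (< 1945), a transition group (1945–1970), then decades
closed on the right ([1971–1980], …) — the decade edges are our choice
and configurable. A variety carries a cluster when any member dosage is
positive. Enrichment uses the Pearson chi-squared test on the 2×2
subpopulation-by-carrier table without continuity correction (df = 1);
zero marginals return a flagged NaN result. Subpopulation labels (e.g.
"starch") are inputs, never inferred.

## Synthetic data

The generator's defaults are the study conditions of the test suite: 50
founders plus 19 generations of 50 crosses (1,001 varieties with the
donor), release years 1850–2015 with a seven-year breeding cycle,
historical cutoff 1945, missing-parent rate 0.05, duplicate-name rate
0.01, self-cross rate 0.02, 60 background SNPs, one 8-SNP introgression
block entering circa 1950, half of all varieties genotyped, 2% missing
calls.

Inheritance is random bivalent pairing: each parent transmits
h ~ Hypergeometric(4, dosage, 2) copies per gamete, with no double
reduction (an acknowledged simplification; the gamete law is an
extension point). Block SNPs co-transmit with probability 0.95 per
meiosis via a shared inverse-CDF uniform — a single Bernoulli linkage
model rather than positional recombination, since the analysis consumes
co-occurrence, not genetic maps. The donor enters as a parentless
wild-accession record (as collected clones do in real pedigrees) and
receives a 12× parent-selection weight, mimicking deliberate use of an
introgression carrier in breeding; under the defaults this yields
carrier fractions of 0.3–0.9 (mean ≈ 0.6) among genotyped post-donor
varieties, satisfying the ≥ 30% study condition and comparable to the
~50% frequency that headline real introgressions reach. Background SNPs
are redrawn until polymorphic in the historical genotyped panel, so by
construction none can masquerade as a modern introgression. All
randomness flows from the single config seed; the truth set records
carriers, donor and the actual transmission edges.

What the simulator does **not** emulate: genotyping error and allele-
dosage miscalls, positional recombination within blocks, population
structure beyond preferential attachment, selection on background loci,
and pedigree-record errors other than missing parents and duplicate
names. Passing tests therefore demonstrate correctness of the machinery
under a clean generative model, not robustness to every artefact of
real array data.

## Benchmark conventions and problem sizes

The propagation engine is validated against exhaustive path enumeration
on 200 random DAGs of ≤ 12 nodes (exact equality of scores, walks and
reach); mass conservation on three 1,000-variety simulations; planted-
donor recovery over 100 seeded replicates (rank-1 genotype-MCA on the
true transmission lineage); planted-partition recovery over 20 seeded
replicates of two 8-SNP blocks plus 50 rare singleton background SNPs.
For the adjusted Rand index, recovered clusters containing no planted
SNP fold into the background class before comparison: the planted truth
constrains no co-occurrence structure *within* the background, whereas
any split, merge or contamination of a planted block lowers the index.

## Known limitations

* Pure halving ignores identity-by-descent corrections and inbreeding;
  scores are expected-share weights, not kinship coefficients.
* Genotype seeds use raw mean dosage (0–4), so varieties transmitting
  more copies weigh more — a sampling-bias caveat inherent to the
  method; tracing single SNPs is the mitigation.
* Mutation-sport descent is treated as an ordinary single-parent edge.
* The reference-data reproduction check needs the externally curated
  pedigree/variety/genotype tables placed under `data/reference/`; they
  are not distributed with the package.
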