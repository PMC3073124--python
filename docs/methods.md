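# Methods

`parsiphy` implements unordered (Fitch) maximum parsimony for discrete
morphological matrices, together with the operations a complete cladistic
study needs: heuristic and exact tree search, consensus trees, decay
(Bremer) support, ensemble fit statistics and synapomorphy mapping.  It
ships the 78-taxon × 43-character matrix of arminid nudibranchs (and their
outgroups) as a packaged dataset, with two preset analyses that exercise the
whole stack.

## The optimality criterion

A character assigns each taxon a state set: a singleton for a determinate
observation, several states for a polymorphism, and — after policy
resolution — the full set of states observed in that column for missing
(`?`) and inapplicable (`-`) cells.  The length of a tree is the minimum
number of state changes needed to explain every character on it, summed over
characters; all characters are unordered (any state may change into any
other at unit cost) and unweighted.  Fitch's algorithm computes this by a
post-order pass that intersects child state sets, taking the union and
adding one step when the intersection is empty.  State sets are uint8
bitmasks and the pass is vectorized across characters; a per-character
scalar implementation over Python sets is kept as the reference the fast
path must reproduce bit for bit, and both are tested against an exhaustive
enumeration of internal-node labelings on all trees with up to seven leaves.

Two per-character bounds frame the observed steps `s_i`:

* `m_i` — minimum conceivable steps: (number of distinct determinate states) − 1;
* `g_i` — maximum steps on any tree, attained on the star tree: (number of
  determinate cells) − (count of the modal state).

The ensemble statistics over a tree of length `S = Σ s_i` are the
consistency index `CI = M/S` and retention index `RI = (G−S)/(G−M)` with
`M = Σ m_i`, `G = Σ g_i`.  Both an all-characters and an
informative-characters-only variant are computed; the all-characters variant
is the reporting default because it reproduces the packaged study's printed
values exactly (`M = 54`, `G = 692`, so `CI = 54/236 = 0.229` and
`RI = 456/638 = 0.715` at the optimum of 236 steps).  Reported values are
rounded half-up to three decimals.

## Missing, inapplicable and polymorphic cells

The source table gives no inapplicable-state policy, so `-` is treated like
`?` by default (effective state set = states observed in the column), the
common treatment of gaps in standard data; `state_sets(gap="newstate")`
instead gives `-` a private extra state.  Two cells of the packaged matrix
carry a bare `&`, a polymorphism whose member states the source does not
record; they are resolved at parse time to a polymorphism over all states
observed in their columns (the conservative superset).  Ambiguous cells
never introduce states absent from determinate observations, and resolved
state sets are never empty.

## Tree search

Starting trees come from seeded random-addition stepwise insertion: taxa are
added in random order, each at the attachment edge minimising tree length,
ties broken uniformly from the seeded stream.  Swapping is
tree-bisection-reconnection (TBR; SPR and NNI are available as restricted
neighbourhoods): an edge is removed, and the two fragments are reconnected
across every pair of edges.  Reconnection is scored incrementally — for each
bisection the two fragments' lengths and per-edge "edge-rooted" Fitch state
sets are computed once, after which any reconnection costs one O(C) bit
scan (`length = L1 + L2 + #characters whose root sets are disjoint`).  The
scan is exact (validated move-by-move against full rescoring) and is
compiled with numba when available, with a pure-Python fallback.

Strict descent TBR reliably sticks a few steps above the optimum on this
kind of matrix: the equal-length plateaus are large and must be crossed.
The search therefore drifts when stuck — it takes a random not-yet-visited
equal-length TBR move (reservoir-sampled from the whole neighbourhood,
tabu on canonical topologies) and gives up after `patience` consecutive
sideways steps (default 1500, chosen so that single replicates on the
packaged 55-taxon matrix reach the optimum roughly half the time; with the
default 10 replicates the optimum is found essentially always, in a few
minutes on one CPU).  After the replicates, swapping continues on the
retained optimal trees, pooling distinct equally parsimonious topologies up
to `maxtrees` (flagged, not fatal, when the cap is hit).  Identical config
and seed give identical results.

Retained topologies are post-processed by the collapse policy: by default,
internal branches whose minimum length over all most-parsimonious
reconstructions is zero are collapsed (an exact test via the dynamic program
below), so counts of distinct trees are convention-dependent — which is why
published most-parsimonious-tree *counts* are recorded but never asserted.

`branch_and_bound` gives provably complete results for up to 12 taxa by
depth-first insertion with an admissible bound (partial-tree length plus,
per character, the number of states confined to not-yet-inserted taxa), and
can retain all trees within a slack of the optimum — the engine of the
suboptimal-sweep decay estimator and of the enumeration-based tests.

## Consensus and decay support

Strict consensus keeps exactly the splits present in every input tree;
majority rule keeps splits above a frequency threshold (> 0.5 guarantees
compatibility) and annotates them with frequencies.  Both are assembled from
canonical bipartitions (smaller side, lexicographic tie-break), so results
are independent of tree rooting and child order.

The decay (Bremer) index of a clade is the extra length at which trees
lacking the clade first appear.  The default estimator is a
converse-constraint search: TBR/SPR moves that would create the forbidden
bipartition are rejected during swapping, and the constrained minimum minus
the unconstrained minimum is the decay.  Heuristic constrained searches can
only overestimate decay, so values from them are flagged non-exact; the
suboptimal-sweep estimator (complete enumeration within a growing slack) is
exact and is cross-checked against full topology enumeration on small
instances.

## Synapomorphy mapping

Mapping uses a unit-cost Sankoff dynamic program over at most five states
per character (four symbols plus the optional gap state).  Inside and
outside subtree costs give, exactly: whether a branch can be changeless in
some most-parsimonious reconstruction (drives `collapse-zero-length-min`),
whether it changes in *every* reconstruction (the `unambiguous` mapping),
and optimal state assignments.  ACCTRAN resolves ties toward making the
change on the current branch (rootward, favouring reversal), DELTRAN toward
keeping the parent state (tipward, favouring parallelism); both are exact
backtraces, so each character maps exactly its Fitch step count and the
total mapped changes on a fully resolved tree equal the tree length.  A
character is flagged homoplastic on a tree when `s_i > m_i`.  Polarity comes
from rooting on the outgroup (no recoding); rooting never changes tree
length or the unrooted split set.

## Synthetic data

The generator emulates the statistical shape of a discrete morphology
study: a seeded random tree (discrete Yule tip-splitting, or uniform by
random edge insertion), k-state characters (k ≤ 4) starting from a uniform
root state and accruing a Poisson number of changes placed uniformly over
branches, then cell corruption into `?`, `-` or two-state polymorphisms at
configurable fractions.  Changes are placed per branch rather than per unit
branch length on purpose — parsimony consumes step counts, not rates — and
inapplicable cells are injected independently of any character hierarchy.
The true change log is returned so mapping and recovery can be tested
against ground truth.  Defaults (8 taxa, 50 characters, 3 states, one
expected change per character, no corruption) are the "clean data" world in
which recovery rates are defined: with 200 such characters the generating
topology lies in the exact optimal set in ≥ 95% of seeds.  What a green
synthetic test does *not* establish: behaviour under correlated characters,
hierarchical inapplicability, or rate-heterogeneous evolution, none of
which the generator models.

## Numerical and procedural choices

* Rounding for reported indices: half-up to three decimals.
* Characters with no determinate observation contribute zero to `M`, `S`, `G`.
* Ties anywhere in search draw from the seeded stream; no platform-dependent
  ordering.  Newick output canonicalizes child order by smallest descendant
  leaf, so serialized results are byte-stable.
* The two packaged analyses: `full_78taxa` roots on *Berthella canariensis*;
  `arminidae_55taxa` restricts to the 55 arminid rows (19 *Armina*, 35
  *Dermatobranchus*, *Histiomena marginata*) and roots on *Histiomena*.

## Known limitations and source discrepancies

* Only unordered parsimony is implemented: no ordered/Wagner, Dollo or
  step-matrix costs, no likelihood/Bayesian scoring, no bootstrap.
* Character 21 of the packaged metadata carries a third state that the
  descriptive character list does not define but the matrix uses for two
  taxa; the matrix is treated as authoritative.
* Two published numbers are not reproducible from the published matrix and
  the package reports the computed values instead: the 55-taxon retention
  index computes to 0.729 (printed: 0.730; the printed value would need
  `G = 384–385` where the matrix gives 383), and the decay index of the
  all-*Dermatobranchus* clade computes to 2 (printed: 6) — trees of length
  135 lacking that clade exist and have been verified with an independent
  implementation.  Similarly, the nine classic proctonotid taxa are not
  monophyletic in any optimal tree: the strict consensus nests *Hero* and
  *Pinufius* among them.  The corresponding acceptance tests assert the
  published values and are expected to fail; they are kept failing rather
  than weakened.
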