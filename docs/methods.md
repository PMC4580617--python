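# Methods

This note records the models, conventions and numerical choices behind
`parsimonia`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where genuinely open design choices were resolved.

## Character matrices

A matrix is taxa × characters over discrete states 0..k−1 (k ≤ 10). Cells
are a state set: a singleton (ordinary scoring), a set of ≥2 states
(polymorphism — the taxon exhibits, or cannot be distinguished among,
several states), MISSING (`?`, compatible with every state), or
INAPPLICABLE (`-`). Inapplicable cells are *scored* exactly like missing
ones — standard practice in morphological parsimony, since no coherent
secondary-character costing is attempted — but the two are preserved
distinctly on output, so files round-trip byte-faithfully in content.
Character indices are 1-based everywhere a user sees them, matching the way
character lists are published. NEXUS parsing is delegated to dendropy
(DATA/CHARACTERS blocks, interleaved or not, `{..}`/`(..)` polymorphism);
the writer emits a minimal canonical block that re-reads to an equal
matrix. A minimal TNT `xread` reader covers the other common morphology
format.

## Parsimony scoring

Unordered (Fitch) characters: any state change costs 1. Ordered (Wagner)
characters: a change from i to j costs |i−j|, computed by Sankoff dynamic
programming; the two agree whenever all characters are binary. Missing
cells never force a step (they enter the dynamic programs as the full state
set); polymorphic tips contribute their observed set, i.e. the tip resolves
to whichever member state is cheapest in context.

**Polytomies.** Binary trees are scored by rooting on a leaf edge, which
makes the Fitch pass exact. Polytomous trees (consensus trees) are scored
with the sequential-Fitch convention used by classic cladistics programs
when reporting consensus lengths: a node's children are folded left to
right into a running intersection, adding one step and taking the union
whenever the next child's set is disjoint from it. On binary nodes this is
exactly Fitch; on multifurcations it can differ from the true hard-polytomy
minimum (which would require a Hartigan/Sankoff treatment), e.g. a single
node with children in states 0,0,1,1 scores 1 under the convention but 2
under Sankoff. The convention is deliberate — consensus lengths are
reported under the same rule the reference statistics were produced with —
and exact Sankoff scoring is used instead wherever correctness matters
internally (ordered characters, and the branch-collapse test below).

**Homoplasy indices.** For character i, m_i is the minimum conceivable
steps on any tree: for unordered characters the smallest hitting set of the
tip state sets minus one (polymorphic and missing tips resolve as
favourably as possible); for ordered characters the length of the shortest
interval meeting every tip set. M_i is the star-tree maximum: number of
scoring tips minus the modal state frequency (unordered), or the minimised
sum of distances to a median state (ordered). Polymorphic tips resolve to
their most globally frequent member before computing M; missing tips drop
out (their optimal resolution adds one tip and one modal count, leaving the
bound unchanged). Then CI = Σm / L and RI = (ΣM − L)/(ΣM − Σm), computed in
full precision and displayed to two decimals. Degenerate conventions:
CI = 1 when L = 0, RI = 1 when ΣM = Σm (logged as uninformative).
Deactivated characters contribute nothing anywhere.

## Tree search

**Branch and bound.** Taxa are added stepwise, each on every edge of every
surviving partial tree; a partial tree dies when its length plus an
admissible bound for the unplaced taxa exceeds the best complete length
found so far (plus the slack, when enumerating near-optimal trees). The
bound counts, per character, unplaced taxa whose entire state set is
disjoint from every state already available (each must force ≥1 step); the
addition order puts taxa with many decisive codings in informative
characters first, which tightens bounds early; a greedy Wagner tree seeds
the incumbent. The search is exact: on seven-taxon instances it returns
precisely the optimum set found by scoring all 945 topologies. A wall-clock
budget can be attached; exceeding it raises a timeout that the pipeline
catches to fall back to the heuristic.

**Collapse rule.** The count of "distinct" most-parsimonious trees depends
on how unsupported branches are collapsed, and published counts are
sensitive to the chosen rule. Default rule `min`: an internal branch is
collapsed when its minimum length over all optimal reconstructions is zero,
decided exactly by contracting the edge and rescoring the polytomous tree
with uniform-cost Sankoff — if the length is unchanged, some optimal
reconstruction assigns both endpoints the same state. All qualifying edges
are collapsed simultaneously and duplicate topologies are removed by split
set. Rule `none` keeps all binary optima (used wherever a test compares
against exhaustive enumeration). Tree counts are therefore treated as
advisory in the expected-statistics checker; lengths and consensus
topologies are the hard targets.

**Heuristic.** Random-addition-sequence Wagner construction followed by
steepest-descent tree-bisection-reconnection: every edge is broken, and
every rerooting of the detached part is reattached to every edge of the
rest; the best strictly improving neighbour is adopted until none exists.
Replicate r draws its addition order from `seed + r`, making runs fully
reproducible; the result is the set of distinct best trees across
replicates, flagged `exact=False`. On eight-taxon matrices the heuristic
has not been observed to miss the branch-and-bound optimum.

**Suboptimal enumeration and Bremer support.** All binary topologies
within `slack` steps of the optimum are enumerated by the same
branch-and-bound with a relaxed incumbent (the published protocol used a
slack of ten steps). A clade's Bremer support is the length excess of the
best enumerated tree *not* containing it; when every tree within the slack
contains the clade, the support is reported as the lower bound
"≥ slack + 1". Supports are non-decreasing in the slack by construction.

## Consensus

Consensus operates on unrooted splits. The strict consensus keeps exactly
the splits present in all inputs; the majority-rule consensus keeps splits
in strictly more than the threshold fraction (default 0.5 — a clade in
exactly half the trees is excluded, which also guarantees the retained set
is mutually compatible). Clades are annotated with integer occurrence
percentages. For display the tree can be rooted on a designated outgroup
(the basal-most taxon of the study group); rooting never affects scores.
Consensus trees are scored with the polytomy convention above, so their
lengths and CI/RI are directly comparable with published consensus
statistics.

## Allometry

Mass scales allometrically with linear dental dimensions, so the model is a
line in log space: ln(mass g) = a + b·ln(length mm), fitted by ordinary
least squares. The packaged calibration table (lower molar row lengths and
masses of Paleogene hyaenodonts) lies on a single such line to within
2×10⁻⁴ in ln space, so the dental model is *re-derived from the printed
pairs* instead of embedding legacy regression coefficients: the module is
self-contained, and leave-one-out refits reproduce every printed mass to
well under 1%. The fitted coefficients (b ≈ 3.51, a ≈ −3.04) are exposed on
the model object. Skull-length and astragalar regressions, whose
coefficients are not part of the calibration data, are supported only as
user-supplied models (TOML config with intercept, slope and the focal
measurement); combined estimates are summarised by the plain median (mean
of the central pair for even counts) and the min–max range. The ordinal
body-mass character uses bins <1, 1–11, 11–31, 31–100, >100 kg; the
sources describe the bins with open phrasing, so boundary ownership is a
convention: a boundary mass belongs to the *upper* bin (31 kg → state 3).

## Synthetic data

The generator produces a random unrooted binary tree (uniform over
topologies via sequential insertion on a uniformly chosen edge, or a Yule
process) and evolves each character from a uniform root state; each branch
changes the state with probability `p_change`, the new state uniform over
the remaining ones. Missing and polymorphic cells are injected cell-wise at
configured fractions. This is a per-branch Bernoulli model, not a
continuous-time Markov chain: the artifact needs controllable homoplasy for
search and consensus tests, not evolutionary realism, and under it the
fraction of variable characters has the closed form 1 − (1−p)^B (B =
branches) up to O(p²) masking, which the tests verify by simulation.

What the generator does *not* emulate: correlated characters, rate
heterogeneity across branches or characters, state ordering, and the
non-random concentration of missing data in fragmentary taxa. Passing
recovery tests therefore show the machinery is sound on clean,
exchangeable-character data, not that real fossil matrices carry as much
signal.

`fossil_study_matrix` mimics the shape of a real hyaenodont matrix: 25 taxa ×
50 characters (one five-state ordinal size character, 32 binary, 17
three-to-four-state), 20% missing cells, 2% polymorphic, per-branch change
probability 0.15.

**Low-noise reference condition.** The parameter-recovery experiment runs
at 20 taxa × 50 five-state characters with p_change = 0.08 (preset
`low_noise_config`). The choice balances two failure modes analytically: a
branch escapes all 50 characters with probability (1−p)⁵⁰ ≈ 1.5% (almost
every true clade has a potential synapomorphy), while each character
carries only ~3 expected changes spread over 5 states, keeping convergence
rare. Lower p starves branches of changes; higher p erases them with
homoplasy; binary characters cannot satisfy both requirements at this
matrix size at any p. Recovery is measured as the fraction of the true
tree's 17 non-trivial clades contained in the strict consensus of the trees
found by the TBR heuristic (2 replicates — exact search is infeasible at 20
taxa, and the heuristic was not observed to miss the optimum found by
8-replicate runs). Measured recovery at this condition averages just under
0.9 over the 20-seed reference grid (≈ 0.89, i.e. roughly one clade short
in a third of runs), and degrades sharply by p = 0.4; the residual gap to
full recovery is intrinsic to the estimator (strict consensus over
equally parsimonious trees), not to the search.

## Pipeline and problem sizes

The pipeline presets encode the three published analysis designs (all data;
drop *Leakitherium*; additionally drop character 1). Exact search is
attempted first under a configurable time budget (default 300 s) with a
fourfold budget for the Bremer enumeration; on timeout the run falls back
to the heuristic (default 100 replicates) and reports `exact=False`, with
Bremer supports omitted since they require the complete suboptimal sweep.
Reports are written alongside the tree files and are recomputable from
them; reruns with the same seed are bit-identical. The test suite exercises
the full pipeline on 8–9-taxon simulated matrices and the search oracles on
5–7 taxa, where exhaustive enumeration (≤ 945 topologies) is cheap; the
recovery experiment uses the 20-taxon reference condition above.

## Known limitations

- Consensus-tree lengths depend on the sequential-Fitch convention and on
  child order within polytomies; they are reported for comparability, not
  as hard-polytomy optima.
- The star-tree M_i convention for polymorphic cells (resolve to the modal
  state) follows common practice, but other programs differ in the second
  decimal of ensemble RI in polymorphism-heavy matrices; the alternative
  (resolve to maximise the bound) is a one-line change if needed.
- Branch and bound is practical to roughly a dozen taxa in this
  implementation; beyond that the heuristic carries the load, and tree
  *counts* (as opposed to lengths) inherit collapse-rule sensitivity.
- Step-matrix (arbitrary-cost) characters, implied weighting, likelihood
  and Bayesian scoring are out of scope.
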