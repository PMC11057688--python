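# Methods

This note records the model assumptions, the numerical and design choices the
implementation makes where the problem statement leaves freedom, and what the
synthetic evaluation does and does not establish.

## Data model and conventions

A genome is a graph on marker extremities: each marker `m` has a tail `m^t`
and head `m^h`; adjacencies form a matching on extremities, and extremities
without an adjacency are telomeres.  Orientation convention: a `+` marker
contributes (tail, head) in reading order, a `−` marker (head, tail); the
adjacency between consecutive markers joins the right extremity of the first
with the left extremity of the second.  Occurrence numbers distinguish copies
within a family; they are assigned in file order and never affect homology
(family = name string).

`write_genomes` emits a canonical form — circular chromosomes from the
rotation/reflection whose signed-family sequence is lexicographically
smallest (positive orientation ordered before negative), linear chromosomes
from the smaller end — so round trips and golden outputs are deterministic.

Insertions may attach at an adjacency, at a telomere, close into a new
circular chromosome, or stand as a new linear chromosome; the options are
mutually exclusive (an insertion either attaches or creates a chromosome,
never both).

## Distance formula and the ceiling

The restricted halving distance for a resolved homology is

    d = l + n − c∘ + ⌈(q + δ)/2⌉,    q = p_g|g + max(p_G∘g, p_G|g) − p_G|G

with δ = 1 iff p_g|g is odd and p_G∘g = p_G|g.  Two conventions deserve
mention:

* **Ceiling.**  The census parity allows odd `q` (exactly when the odd-cycle
  count is odd), making the plain half-sum half-integral.  The implementation
  takes the ceiling.  This reproduces the pure-DCJ halving limit
  `n − c∘ − ⌊p_G|G/2⌋` when no singular markers exist (since
  `⌈−p/2⌉ = −⌊p/2⌋`), always yields integers, and agrees with the exhaustive
  brute-force search on every one of the >1000 small instances the acceptance
  suite enumerates (e.g. linear `[1 −1 3]`: q = 1, δ = 0, distance 2).
* **Isolated telomere-lava vertices** (a singular marker extremity that is
  also a telomere) count as one even pier each; this is what makes the
  formula assign one deletion per linear singleton chromosome.

Circular singletons (circular chromosomes of only singular markers) are
removed in preprocessing and contribute one deletion each (`l`).

## Sorting

The published algorithm for the resolved case is a case analysis over
component types; its exact step list is reconstructed here *behaviourally*: a
greedy loop proposes guided candidate operations — deletions of maximal
singular runs (including circular singletons), "pairing" DCJs that join the
partner extremities of an unpaired adjacency (extracting an even 2-cycle),
telomere-pairing cuts, and finally an exhaustive fallback over all DCJs and
singular sub-segment deletions — and emits the first candidate whose
application lowers the distance by exactly one (evaluated on a lightweight
adjacency-map state, not a full genome copy).  Existence of such a step for
every non-SD genome is exactly the statement that the formula is the true
minimum, so the loop terminates with a scenario whose length equals the
formula; both post-conditions (length and final SD-ness) are asserted.
Candidate order makes scenarios deterministic.  Insertions are never needed
by this construction; the scenario verifier nevertheless accepts them and
enforces restricted legality (only singular markers deleted, at most the one
missing homolog inserted per singular marker).

## The ILP for natural genomes

The ILP selects a maximum matching and evaluates the same census objective,
without capping: one pseudo-cap vertex per telomere (indexed before all
regular vertices) gives every component an adjacency edge while keeping the
model linear in the number of linear chromosomes.

Reconstruction choices where the constraint algebra was open:

* One binary per candidate sibling pair `{m, n}` activates both extremity
  edges `{m^t,n^t}`, `{m^h,n^h}` at once, enforcing sibling consistency
  structurally.  Per marker, active pairs plus the deletion indicator sum to
  one; per family, the number of deleted markers equals `|F| mod 2`
  (equality rather than ≤ tightens the LP relaxation; with pairing parity the
  two are equivalent).
* `y`-variables are equal across active edges and bounded by `ix(v)`;
  components containing a lava vertex force `y = 0`; `ix(v)·z_v ≤ y_v` lets
  at most the minimum-index vertex of a lava-free component report.
* Reports are per adjacency edge with at most one report per edge.  Even/odd
  cycles and odd viaducts (the terms that lower the objective) require a
  reporting vertex on the edge; cycle reports additionally require `a = 1` at
  both edge ends (pseudo-caps carry `a = 0`, so viaducts cannot pose as
  cycles); viaduct and pier reports are restricted to pseudo-cap edges;
  pontoon reports to lava-incident edges.
* A pier report *forces* the `a`-flip at its pseudo-cap edge (`a = 1` on the
  regular side) rather than merely permitting it.  Without this, an even
  viaduct can masquerade as an odd viaduct plus an odd pier and illegitimately
  dodge the δ edge case by half a unit — found by randomised cross-checking
  against the closed form and worth recording as the one genuinely sharp
  corner of the reconstruction.
* δ is linearised via `p_g|g = 2k + O` and a two-sided |p_G∘g − p_G|g| split
  gated by one auxiliary binary; the solver may exploit the documented
  freedom to trade δ against an extra census unit, which leaves the objective
  unchanged, so the decoded distance is always recomputed from the decoded
  matching with the closed form.

The objective `n − c + (p_g|g + T − p_G|G + δ)/2 + s` can be half-integral;
the distance is `ceil(objective − 1e−6)`.  The backend is the HiGHS solver
shipped with scipy (`scipy.optimize.milp`); it is deterministic and
single-threaded, `--threads`/`--seed` are recorded and forwarded only where a
backend supports them, and `write_lp` exports plain CPLEX-LP text for any
external solver.  Correctness of the reconstruction is established
behaviourally: objective equality with the closed form on resolved inputs and
with exhaustive maximum-matching enumeration on small natural genomes.

## Simulator

`evolve` follows a fixed protocol: a root of singular markers on one linear
chromosome (default 5000), a linear tree `(((G)D)S)R;`, one WGD on the branch
into `D`, and per non-WGD branch a fixed number of DCJs (default 2500) plus
insertions, duplications and deletions at rates 0.2 / 0.3 / 1.0 relative to
the DCJ count, with the deletion rate 0 before the WGD.  Indel and
duplication lengths are Zipf with shapes 4 and 6; the inverse-CDF table is
truncated at cumulative mass 1 − 1e−12 and renormalised.  Unspecified
sampling details are fixed as: uniform choice of two distinct cut sites and
uniform legal rejoin for DCJs; tandem duplications at a uniform position;
insertions of brand-new families at a uniform site; uniform contiguous
deletions; uniform shuffle of the per-branch operation multiset with one RNG
stream per branch.  These choices are echoed into `truth.json` so runs are
self-describing; they are this package's own protocol, not a claim about any
other implementation's sampler.

The truth log records exact per-branch counts and marker bookkeeping.  Because
every post-WGD event can be reverted by at most one restricted operation, the
computed halving distance is bounded by the post-WGD operation count; the
acceptance suite checks this bound, and a mean distance/truth ratio ≥ 0.8, at
a low-rearrangement operating point (200 root markers, 20 DCJs per branch, 50
seeds) where back-rearrangement saturation is negligible.  What passing these
tests shows is that the pipeline is exact under its own generative model; real
genomes add marker-inference noise, non-uniform breakpoint usage and much
heavier loss, so distances on real data are lower bounds of evolutionary
distance, increasingly so the fewer non-singular markers survive.

`make_fixture` derives three instance flavours from the same machinery:
`sd` (a scrambled genome, then doubled — distance 0 by construction),
`resolved` (doubling followed by DCJs, deletions and novel insertions, family
sizes ≤ 2) and `natural` (additionally single-marker duplications up to a
family-size cap, default 4).

## Brute-force references

The oracle searches breadth-first over all legal DCJs, all contiguous
singular-segment deletions and single-marker homolog insertions, deduplicating
states by canonical form (chromosome order / rotation / reflection,
occurrence numbers dropped); the SD test is definitional (marker and adjacency
equivalence classes of size exactly 2), independent of the census formula.
Restricting insertion moves to single markers is justified by the uni-indel
decomposition of longer insertions, whose intermediate states the search
reaches anyway within the depth bound.  The guard of 6 markers keeps the
state space enumerable.  Maximum matchings are enumerated per family
(`f!/(2^⌊f/2⌋ ⌊f/2⌋!)` pairings, one optional singular for odd `f`) and
combined across families.

## Problem sizes in the test suite

The suite runs at sizes chosen to exercise every code path densely while
staying convenient for routine development: exhaustive ≤ 4-marker instances
(~1100 after canonical deduplication) against brute force, 500 sorting
instances up to ~30 markers, 50 + 50 ILP instances (resolved ≤ 40 markers,
natural with family sizes ≤ 4), and 50 simulator seeds at 200 root markers.
The full-scale protocol (5000 markers, 2500 operations, duplication-rate and
operation-count sweeps) runs through the same code paths via the CLI.

## Yeast WGD case study (external data)

The distances 356 (*Naumovozyma castellii*, GCA_000237345.1) and 117
(*Nakaseomyces glabratus*, GCA_000002545.2) are reproducible with externally
prepared inputs; the preparation is deliberately not part of this package:

1. download the GenBank assemblies (also GCA_000146045.2 for *S. cerevisiae*);
2. extract the longest coding sequence per gene as the marker set;
3. all-vs-all BLAST, keep hits with E ≤ 0.01, form families as the
   *transitive* closure of significant hits;
4. write each genome's gene order in the UniMoG dialect (one file per taxon,
   `data/yeast/castellii.txt`, `data/yeast/glabratus.txt`);
5. `dcjhalving ilp <file> --time-limit 32400`.

The corresponding test is red without these files and without hours of MILP
time.  Known limitation, visible in that experiment: with few non-singular
markers the matching is small and the distance is systematically
underestimated — an affine indel cost (charging segment lengths as well as
events) would be needed to counter it.

## Known limitations

* The ILP reconstruction is validated behaviourally, not syntactically; on
  inputs far outside the tested regimes (very large ambiguous families,
  heavily nested components) the HiGHS backend, not the model size, is the
  practical bound.
* The sorter's exhaustive fallback is quadratic in sites per step; it is a
  correctness net, not the expected path.
* `bruteforce_halving` is exponential and guarded at 6 markers.
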