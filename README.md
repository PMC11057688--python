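# dcjhalving

Genome halving under the DCJ-indel model: reconstruct the *structurally
doubled* (SD) ancestor that existed right after a whole-genome duplication
(WGD), given only a present-day genome, and measure how far the genome has
drifted from it.

WGDs double both the gene content and the adjacency structure of a genome and
are typically followed by massive gene loss, so classic halving methods that
require every marker to occur exactly twice do not apply to real post-WGD
genomes.  This package works with **natural genomes** — arbitrary family
sizes, including singular (unpaired) markers — under the double-cut-and-join
(DCJ) model extended with segmental insertions and deletions (indels).  It is
aimed at comparative genomics researchers studying paleopolyploidy (e.g. the
yeast WGD) and at method developers who need a reference implementation,
ground-truth simulator and brute-force oracles for rearrangement distances.

## The model

A genome is a set of linear/circular chromosomes of signed markers; homology
is given by shared marker names (a *family*).  The halving distance is the
minimum number of DCJs and restricted indels (only singular markers may be
deleted; only the single missing homolog of a singular marker may be
inserted) that turn the genome into an SD genome.

For **resolved** homologies (families of size ≤ 2) the distance has a closed
form over the component census of the supernatural graph (vertices =
extremities, adjacency edges + extremity edges between homologous
extremities, which decomposes into simple paths and cycles):

    d = l + n − c∘ + ⌈(p_g|g + max(p_G∘g, p_G|g) − p_G|G + δ) / 2⌉

where `l` counts circular singletons, `n` matched pairs, `c∘` even cycles,
`p_g|g` odd pontoons (paths ending in two lava vertices), `p_G∘g`/`p_G|g`
even/odd piers (telomere-to-lava paths), `p_G|G` odd viaducts
(telomere-to-telomere paths), and `δ = 1` exactly when `p_g|g` is odd with
equal pier counts.  `sort_halving` also produces an explicit optimal scenario
and the SD ancestor.

For **natural** genomes the problem is NP-hard: the package builds a
capping-free integer linear program that simultaneously chooses a maximum
matching (at most one singular marker per family) and the census-minimising
decomposition, with model size linear in markers and telomeres.  It is solved
with the bundled HiGHS backend (`scipy.optimize.milp`); the model can also be
exported in LP format for any external MILP solver.

A tree-guided simulator (`evolve`) generates post-WGD genomes with known
operation counts — DCJs, Zipf-length indels, tandem duplications, one WGD —
for benchmarking, and a brute-force search (`oracle`) provides exact
distances on tiny instances.

## Worked example

A genome five rearrangement/loss events after a WGD:

```sh
$ printf '>post_wgd\n1 2 3 2 1 |\n' > r.txt
$ dcjhalving dist r.txt
genome post_wgd
  n                    2
  c_even               0
  q                    2
  delta                0
  circular_singletons  0
  distance             3
```

Families `1` and `2` are paired (`n = 2`), marker `3` is singular; the census
yields `q = 2`, so the genome is three operations away from an SD ancestor.
The scenario and ancestor:

```sh
$ dcjhalving sort r.txt
# genome post_wgd: 3 operations
DEL 3.1
DCJ cut {h2.1,t2.2} join {h1.2,t2.2}
DCJ cut  join {h2.1,t1.1}
```

— delete the orphaned marker `3`, then two DCJs pair up the remaining
adjacencies and telomeres.  For ambiguous inputs (family sizes > 2) use the
ILP instead:

```sh
$ printf '>tetra\n1 2 3 4 -3 |\n5 1 2 4 )\n' > wgd.txt
$ dcjhalving ilp wgd.txt
genome tetra: distance 4 (objective 4, status optimal)
```

The library mirrors the CLI: `halving_distance`, `sort_halving`,
`build_ilp`/`solve_ilp`/`halve_natural`, `evolve`, `make_fixture`.

## Input format

UniMoG-dialect gene orders: `>name` starts a genome, whitespace-separated
signed marker tokens follow, `|` ends a linear chromosome, `)` a circular
one, `#` starts a comment.  Markers with the same name are homologs.

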