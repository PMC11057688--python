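"""Tree-guided genome evolution with a whole-genome duplication.

The simulator evolves a genome of singular markers along a (possibly linear)
phylogeny.  Each branch performs a fixed number of DCJs plus insertions,
duplications and deletions in proportion to that number; one designated branch
performs a whole-genome duplication (WGD), doubling content and adjacency
structure.  Deletions are switched off before the WGD (they would not affect
the halving scenario) and on after it.  Segment lengths for indels and
duplications follow a Zipf law p(l) = l^(-a) / zeta(a).

Sampling choices the protocol leaves open are fixed as follows and recorded in
the truth log: DCJs cut two distinct sites chosen uniformly among adjacencies
and telomeres and rejoin uniformly among the legal outcomes; duplications are
tandem copies of a uniformly placed segment; insertions introduce brand-new
families at a uniform site; deletions remove a uniformly placed contiguous
segment.  The per-branch operation multiset is shuffled uniformly, one RNG
stream per branch.

The leaf genome together with the exact per-branch operation counts is the
ground truth against which the computed halving distance is evaluated: every
post-WGD event is one legal operation of the restricted model, so the
distance never exceeds the post-WGD operation count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import zeta

from .genome_model import Chromosome, Genome, Homology, Marker

__all__ = ["SimParams", "SimResult", "zipf_length", "evolve", "make_fixture"]


@dataclass
class SimParams:
    """Simulation protocol parameters.

    ``ops_per_branch`` DCJs are performed on every branch except the WGD
    branch (which carries only the duplication event); the other operation
    counts are ``round(rate * ops_per_branch)`` each.  ``wgd_branch`` names
    the child node of the branch on which the WGD happens.
    """

    root_markers: int = 5000
    tree: str = "(((G)D)S)R;"
    ops_per_branch: int = 2500
    insertion_rate: float = 0.2
    duplication_rate: float = 0.3
    deletion_rate_post: float = 1.0
    deletion_rate_pre: float = 0.0
    zipf_shape_dup: float = 6.0
    zipf_shape_indel: float = 4.0
    wgd_branch: str = "D"
    seed: int | None = None

    def validate(self) -> None:
        if min(self.insertion_rate, self.duplication_rate,
               self.deletion_rate_post, self.deletion_rate_pre) < 0:
            raise ValueError("rates must be non-negative")
        if self.zipf_shape_dup <= 1 or self.zipf_shape_indel <= 1:
            raise ValueError("Zipf shape parameters must exceed 1")
        if self.wgd_branch not in _parse_tree(self.tree):
            raise ValueError(f"wgd_branch {self.wgd_branch!r} not in tree")


@dataclass
class SimResult:
    """Genomes at every tree node plus the exact per-branch truth log."""

    genomes: dict  # node name -> Genome
    truth: dict  # per-branch operation counts, WGD flag, marker bookkeeping

    @property
    def leaf_names(self) -> list:
        children = {b["child"] for b in self.truth["branches"]}
        parents = {b["parent"] for b in self.truth["branches"]}
        return sorted(children - parents)


def _parse_tree(newick: str) -> dict:
    """Parse a names-only Newick string into child -> parent."""
    import io

    try:
        import dendropy
    except ImportError:  # pragma: no cover
        dendropy = None
    if dendropy is not None:
        tree = dendropy.Tree.get(data=newick, schema="newick")
        parent = {}
        for node in tree.preorder_node_iter():
            name = node.taxon.label if node.taxon else node.label
            if node.parent_node is not None:
                pname = (
                    node.parent_node.taxon.label
                    if node.parent_node.taxon
                    else node.parent_node.label
                )
                parent[name] = pname
            else:
                parent[name] = None
        return parent
    raise RuntimeError("dendropy is required to parse Newick trees")


_ZIPF_CACHE: dict = {}


def zipf_length(shape: float, rng: np.random.Generator) -> int:
    """Sample a segment length from p(l) = l^(-shape) / zeta(shape).

    Inverse-CDF sampling on precomputed tail sums, truncated once the
    cumulative mass reaches 1 - 1e-12 (renormalised); the table is cached per
    shape.
    """
    if shape <= 1:
        raise ValueError("Zipf shape must exceed 1")
    key = float(shape)
    cdf = _ZIPF_CACHE.get(key)
    if cdf is None:
        z = zeta(key, 1)
        n = 1024
        while True:
            pmf = np.arange(1, n + 1, dtype=float) ** (-key) / z
            cdf = np.cumsum(pmf)
            if cdf[-1] >= 1 - 1e-12 or n >= 1 << 20:
                break
            n *= 2
        cdf = cdf / cdf[-1]
        _ZIPF_CACHE[key] = cdf
    u = rng.random()
    return int(np.searchsorted(cdf, u, side="right")) + 1


class _EvoState:
    """Mutable genome for simulation: extremity neighbour array over markers.

    Extremities of marker ``i`` are ``2i`` (tail) and ``2i+1`` (head);
    ``nb[e] == -1`` marks a telomere; dead markers are tombstoned.
    """

    def __init__(self):
        self.fams: list = []
        self.alive: list = []
        self.nb: list = []

    @classmethod
    def linear(cls, families) -> "_EvoState":
        st = cls()
        prev_head = None
        for f in families:
            i = st.new_marker(f)
            if prev_head is not None:
                st.link(prev_head, 2 * i)
            prev_head = 2 * i + 1
        return st

    def new_marker(self, family: str) -> int:
        self.fams.append(family)
        self.alive.append(True)
        self.nb.extend([-1, -1])
        return len(self.fams) - 1

    def link(self, a: int, b: int) -> None:
        self.nb[a], self.nb[b] = b, a

    def unlink(self, a: int) -> int:
        b = self.nb[a]
        if b >= 0:
            self.nb[a] = self.nb[b] = -1
        return b

    def marker_count(self) -> int:
        return sum(self.alive)

    def sites(self) -> tuple:
        adjacencies, telomeres = [], []
        for i, ok in enumerate(self.alive):
            if not ok:
                continue
            for e in (2 * i, 2 * i + 1):
                o = self.nb[e]
                if o < 0:
                    telomeres.append(e)
                elif e < o:
                    adjacencies.append((e, o))
        return adjacencies, telomeres

    # --- operations -------------------------------------------------------

    def dcj(self, rng: np.random.Generator) -> None:
        adjacencies, telomeres = self.sites()
        sites = adjacencies + telomeres
        if len(sites) < 2:
            return
        i, j = rng.choice(len(sites), size=2, replace=False)
        s1, s2 = sites[int(i)], sites[int(j)]
        if isinstance(s1, tuple) and isinstance(s2, tuple):
            a, b = s1
            c, d = s2
            self.unlink(a)
            self.unlink(c)
            if rng.random() < 0.5:
                self.link(a, c)
                self.link(b, d)
            else:
                self.link(a, d)
                self.link(b, c)
        elif isinstance(s1, tuple) or isinstance(s2, tuple):
            (a, b), t = (s1, s2) if isinstance(s1, tuple) else (s2, s1)
            self.unlink(a)
            if rng.random() < 0.5:
                self.link(a, t)
            else:
                self.link(b, t)
        else:
            self.link(s1, s2)

    def _segment_from(self, start_marker: int, length: int) -> list:
        """Consecutive alive markers along the chromosome, stopping at a telomere."""
        seg = [start_marker]
        e = 2 * start_marker + 1  # walk rightwards from the head
        while len(seg) < length:
            nxt = self.nb[e]
            if nxt < 0:
                break
            m = nxt // 2
            if m == seg[0] and nxt % 2 == 0:
                break  # wrapped a circular chromosome
            if m in seg:
                break
            seg.append(m)
            e = nxt ^ 1
        return seg

    def _random_alive(self, rng) -> int:
        alive_idx = [i for i, ok in enumerate(self.alive) if ok]
        return int(alive_idx[int(rng.integers(len(alive_idx)))])

    def delete(self, rng: np.random.Generator, length: int) -> int:
        """Delete a uniformly placed contiguous segment; returns markers removed."""
        if self.marker_count() <= length:
            raise RuntimeError("deletion would empty the genome")
        seg = self._segment_from(self._random_alive(rng), length)
        flanks = []
        segset = set(seg)
        for m in seg:
            for e in (2 * m, 2 * m + 1):
                o = self.unlink(e)
                if o >= 0 and o // 2 not in segset:
                    flanks.append(o)
            self.alive[m] = False
        if len(flanks) == 2:
            self.link(flanks[0], flanks[1])
        return len(seg)

    def insert(self, rng: np.random.Generator, families: list) -> None:
        """Insert a chain of new markers at a uniform adjacency/telomere site."""
        ids = [self.new_marker(f) for f in families]
        for p, q in zip(ids, ids[1:]):
            self.link(2 * p + 1, 2 * q)
        left, right = 2 * ids[0], 2 * ids[-1] + 1
        cutoff = 2 * ids[0]
        adjacencies, telomeres = self.sites()
        sites = [s for s in adjacencies if s[0] < cutoff] + [
            t for t in telomeres if t < cutoff
        ]
        if not sites:
            return  # stays a new linear chromosome
        s = sites[int(rng.integers(len(sites)))]
        if isinstance(s, tuple):
            a, b = s
            self.unlink(a)
            self.link(a, left)
            self.link(right, b)
        else:
            self.link(s, left)

    def duplicate(self, rng: np.random.Generator, length: int, start: int | None = None) -> int:
        """Tandem-duplicate a uniformly placed segment; returns markers added."""
        if start is None:
            start = self._random_alive(rng)
        seg = self._segment_from(start, length)
        # orientation of each copied marker as read along the walk
        signs = []
        e = 2 * seg[0]
        for m in seg:
            signs.append(1 if e == 2 * m else -1)
            nxt = self.nb[e ^ 1]
            e = nxt if nxt >= 0 else e
        ids = [self.new_marker(self.fams[m]) for m in seg]
        ends = [(2 * i, 2 * i + 1) if s > 0 else (2 * i + 1, 2 * i) for i, s in zip(ids, signs)]
        for (l1, r1), (l2, r2) in zip(ends, ends[1:]):
            self.link(r1, l2)
        # splice right after the original segment
        last = seg[-1]
        right_end = (2 * last + 1) if signs[-1] > 0 else (2 * last)
        after = self.unlink(right_end)
        self.link(right_end, ends[0][0])
        if after >= 0:
            self.link(ends[-1][1], after)
        return len(seg)

    def wgd(self) -> int:
        """Duplicate every chromosome: content, adjacencies, new occurrences."""
        old = [i for i, ok in enumerate(self.alive) if ok]
        clone = {i: self.new_marker(self.fams[i]) for i in old}
        for i in old:
            for side in (0, 1):
                o = self.nb[2 * i + side]
                if o >= 0 and (o // 2 in clone) and self.nb[2 * clone[i] + side] < 0:
                    self.link(2 * clone[i] + side, 2 * clone[o // 2] + (o % 2))
        return len(old)

    # --- export -----------------------------------------------------------

    def to_genome(self, name: str = "") -> Genome:
        occ: dict = {}
        marker_obj: dict = {}
        for i, ok in enumerate(self.alive):
            if ok:
                f = self.fams[i]
                occ[f] = occ.get(f, 0) + 1
                marker_obj[i] = Marker(f, occ[f])
        used: set = set()
        chroms = []

        def walk(entry: int):
            seq = []
            e = entry
            while True:
                m = e // 2
                used.add(m)
                seq.append((marker_obj[m], 1 if e % 2 == 0 else -1))
                nxt = self.nb[e ^ 1]
                if nxt < 0:
                    return seq, False
                if nxt == entry:
                    return seq, True
                e = nxt

        for i in sorted(marker_obj):
            for e in (2 * i, 2 * i + 1):
                if self.nb[e] < 0 and i not in used:
                    seq, _ = walk(e)
                    chroms.append(Chromosome(tuple(seq), circular=False))
        for i in sorted(marker_obj):
            if i not in used:
                seq, circ = walk(2 * i)
                chroms.append(Chromosome(tuple(seq), circular=circ))
        return Genome(name=name, chromosomes=chroms)


def evolve(params: SimParams) -> SimResult:
    """Run the simulation protocol and return genomes plus the truth log."""
    params.validate()
    parent_of = _parse_tree(params.tree)
    root = next(n for n, p in parent_of.items() if p is None)
    children: dict = {}
    for child, par in parent_of.items():
        if par is not None:
            children.setdefault(par, []).append(child)
    # deterministic branch order: preorder, sorted children
    branches = []
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in sorted(children.get(node, []), reverse=True):
            branches.append((node, ch))
            stack.append(ch)

    seed_seq = np.random.SeedSequence(params.seed)
    branch_seeds = seed_seq.spawn(len(branches))

    state = _EvoState.linear([f"m{i + 1}" for i in range(params.root_markers)])
    genomes = {root: state.to_genome(root)}
    states = {root: state}
    truth_branches = []
    wgd_seen_at: set = set()

    def after_wgd(node: str) -> bool:
        while node is not None:
            if node in wgd_seen_at:
                return True
            node = parent_of[node]
        return False

    for (par, child), bseed in zip(branches, branch_seeds):
        rng = np.random.default_rng(bseed)
        st = _copy_state(states[par])
        log = {
            "parent": par,
            "child": child,
            "wgd": child == params.wgd_branch,
            "dcj": 0,
            "insertions": 0,
            "deletions": 0,
            "duplications": 0,
            "markers_inserted": 0,
            "markers_deleted": 0,
            "markers_duplicated": 0,
            "markers_in": st.marker_count(),
        }
        if child == params.wgd_branch:
            st.wgd()
            wgd_seen_at.add(child)
            nops = 0
        else:
            nops = params.ops_per_branch
        if nops:
            post = after_wgd(child)
            del_rate = params.deletion_rate_post if post else params.deletion_rate_pre
            plan = (
                ["dcj"] * nops
                + ["ins"] * round(params.insertion_rate * nops)
                + ["dup"] * round(params.duplication_rate * nops)
                + ["del"] * round(del_rate * nops)
            )
            order = rng.permutation(len(plan))
            fresh = 0
            for idx in order:
                op = plan[int(idx)]
                if op == "dcj":
                    st.dcj(rng)
                    log["dcj"] += 1
                elif op == "ins":
                    length = zipf_length(params.zipf_shape_indel, rng)
                    fresh += 1
                    fams = [f"i{child}{fresh}x{j}" for j in range(length)]
                    st.insert(rng, fams)
                    log["insertions"] += 1
                    log["markers_inserted"] += length
                elif op == "dup":
                    length = zipf_length(params.zipf_shape_dup, rng)
                    added = st.duplicate(rng, length)
                    log["duplications"] += 1
                    log["markers_duplicated"] += added
                else:
                    length = zipf_length(params.zipf_shape_indel, rng)
                    removed = st.delete(rng, length)
                    log["deletions"] += 1
                    log["markers_deleted"] += removed
        log["markers_out"] = st.marker_count()
        truth_branches.append(log)
        states[child] = st
        genomes[child] = st.to_genome(child)

    post_total = sum(
        b["dcj"] + b["insertions"] + b["deletions"] + b["duplications"]
        for b in truth_branches
        if after_wgd(b["child"]) and not b["wgd"]
    )
    truth = {
        "params": {
            "root_markers": params.root_markers,
            "tree": params.tree,
            "ops_per_branch": params.ops_per_branch,
            "insertion_rate": params.insertion_rate,
            "duplication_rate": params.duplication_rate,
            "deletion_rate_post": params.deletion_rate_post,
            "deletion_rate_pre": params.deletion_rate_pre,
            "zipf_shape_dup": params.zipf_shape_dup,
            "zipf_shape_indel": params.zipf_shape_indel,
            "wgd_branch": params.wgd_branch,
            "seed": params.seed,
            "sampling": "uniform DCJ sites; tandem duplications; novel-family "
            "insertions; uniform contiguous deletions",
        },
        "branches": truth_branches,
        "post_wgd_operations": post_total,
    }
    return SimResult(genomes=genomes, truth=truth)


def _copy_state(st: _EvoState) -> _EvoState:
    new = _EvoState()
    new.fams = list(st.fams)
    new.alive = list(st.alive)
    new.nb = list(st.nb)
    return new


def make_fixture(kind: str, size: int, seed: int | None = None, max_family: int = 4):
    """Random test instance of a given flavour; returns (Genome, Homology).

    ``sd``: a structurally doubled genome (halving distance 0 under some
    matching).  ``resolved``: family sizes capped at two, with singular
    markers from deletions and novel insertions.  ``natural``: additional
    duplications push at least one family to size >= 3 (up to ``max_family``).
    ``size`` is the approximate marker count of the result.
    """
    rng = np.random.default_rng(seed)
    half = max(1, size // 2)
    state = _EvoState.linear([f"m{i + 1}" for i in range(half)])
    # random pre-doubling scrambling and chromosome structure
    for _ in range(int(rng.integers(0, half + 1))):
        state.dcj(rng)
    state.wgd()
    if kind == "sd":
        return _fixture_result(state)
    if kind not in ("resolved", "natural"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    n_dcj = int(rng.integers(0, max(2, size // 2)))
    n_del = int(rng.integers(0, max(2, size // 4)))
    n_ins = int(rng.integers(0, max(2, size // 6)))
    n_dup = int(rng.integers(1, max(2, size // 4))) if kind == "natural" else 0
    counts: dict = {}
    for f in state.fams:
        counts[f] = counts.get(f, 0) + 1
    dup_done = 0
    for _ in range(n_dup * 4):
        if dup_done >= n_dup:
            break
        m = state._random_alive(rng)
        if counts.get(state.fams[m], 0) >= max_family:
            continue
        state.duplicate(rng, 1, start=m)
        counts[state.fams[m]] = counts.get(state.fams[m], 0) + 1
        dup_done += 1
    for _ in range(n_dcj):
        state.dcj(rng)
    for j in range(n_ins):
        state.insert(rng, [f"x{j + 1}"])
    for _ in range(n_del):
        if state.marker_count() > 2:
            state.delete(rng, 1)
    if kind == "natural" and dup_done == 0:
        state.duplicate(rng, 1)
    return _fixture_result(state)


def _fixture_result(state: _EvoState):
    g = state.to_genome("fixture")
    return g, Homology.of(g)
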