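"""The supernatural graph (SNG) and its component census.

The SNG of a genome under a homology has one vertex per extremity, an
*adjacency edge* per genome adjacency and an *extremity edge* between every
pair of equivalent extremities (tails with tails, heads with heads of
homologous markers).  A matching keeps at most one extremity edge per vertex,
so the restricted graph — a *consistent decomposition* — consists of simple
cycles and simple paths only.

Components are classified by the parity of their extremity-edge count and by
their path endpoints.  A vertex without an incident extremity edge (it belongs
to a singular marker) is a *lava* vertex; other vertices are *safe*; vertices
without an adjacency edge are *telomeres*.  Paths ending in two safe telomeres
are *viaducts*, in a telomere and a lava vertex *piers*, and in two lava
vertices *pontoons*.  An isolated vertex that is both telomere and lava counts
as one even pier.

For the ILP, *pseudo-caps* may be added: one artificial vertex per telomere,
attached by an adjacency edge, indexed before all regular vertices, so that
every vertex has exactly one incident adjacency edge.  The census is identical
with or without pseudo-caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome_model import (
    Extremity,
    Genome,
    Homology,
    Matching,
    find_circular_singletons,
)

__all__ = [
    "PseudoCap",
    "SNGraph",
    "SimpleSNG",
    "ComponentCensus",
    "build_sng",
    "add_pseudo_caps",
    "decompose",
    "classify_components",
    "census_of",
    "to_dot",
]


@dataclass(frozen=True, order=True)
class PseudoCap:
    """Artificial vertex attached by an adjacency edge to one telomere."""

    telomere: Extremity

    def __str__(self) -> str:
        return f"cap({self.telomere})"


@dataclass
class SNGraph:
    """Vertices = extremities (+ optional pseudo-caps), adjacency + extremity edges.

    ``vertex_index`` is a total order with all pseudo-caps before all regular
    vertices (indices start at 1).
    """

    genome: Genome
    homology: Homology
    vertices: list
    adjacency_edges: list  # list of frozenset({u, v})
    extremity_edges: list  # list of frozenset({u, v})
    vertex_index: dict = field(default_factory=dict)

    @property
    def has_pseudo_caps(self) -> bool:
        return any(isinstance(v, PseudoCap) for v in self.vertices)


@dataclass
class Component:
    """A simple path or cycle of a consistent decomposition."""

    vertices: list
    is_cycle: bool
    extremity_edge_count: int
    endpoints: tuple = ()  # for paths: the two end vertices (possibly equal ids)

    @property
    def odd(self) -> bool:
        return self.extremity_edge_count % 2 == 1


@dataclass
class SimpleSNG:
    """An SNG restricted to the extremity edges induced by a matching."""

    graph: SNGraph
    matching: Matching
    components: list


@dataclass
class ComponentCensus:
    """Counts of the component taxonomy of a consistent decomposition.

    ``n`` is the number of matched marker pairs; ``c_even``/``c_odd`` count
    cycles by extremity-edge parity; viaducts ``p_GG_*`` end in two safe
    telomeres, piers ``p_Gg_*`` in a telomere and a lava vertex, pontoons
    ``p_gg_*`` in two lava vertices.  Circular singletons are removed before
    the census and counted in ``circular_singletons``.
    """

    n: int = 0
    c_even: int = 0
    c_odd: int = 0
    p_GG_odd: int = 0
    p_GG_even: int = 0
    p_Gg_even: int = 0
    p_Gg_odd: int = 0
    p_gg_odd: int = 0
    p_gg_even: int = 0
    circular_singletons: int = 0

    @property
    def piers(self) -> int:
        return self.p_Gg_even + self.p_Gg_odd

    @property
    def extremity_edges(self) -> int:
        """Total extremity edges over all components (= 2n)."""
        return 2 * self.n


def build_sng(genome: Genome, homology: Homology) -> SNGraph:
    """Build the supernatural graph of ``genome`` under ``homology``."""
    vertices = list(genome.extremities())
    adjacency_edges = [frozenset(a) for a in sorted(genome.adjacencies(), key=_edge_key)]
    extremity_edges = []
    for fam in homology.families.values():
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                extremity_edges.append(frozenset((fam[i].tail, fam[j].tail)))
                extremity_edges.append(frozenset((fam[i].head, fam[j].head)))
    index = {v: i + 1 for i, v in enumerate(sorted(vertices))}
    return SNGraph(genome, homology, vertices, adjacency_edges, extremity_edges, index)


def add_pseudo_caps(sng: SNGraph) -> SNGraph:
    """Attach one pseudo-cap per telomere; caps get the lowest vertex indices."""
    caps = [PseudoCap(t) for t in sorted(sng.genome.telomeres())]
    if not caps:
        return sng
    vertices = caps + [v for v in sng.vertices if not isinstance(v, PseudoCap)]
    adjacency_edges = list(sng.adjacency_edges) + [
        frozenset((c, c.telomere)) for c in caps
    ]
    index = {c: i + 1 for i, c in enumerate(caps)}
    for v in sorted(v for v in vertices if not isinstance(v, PseudoCap)):
        index[v] = len(index) + 1
    return replace(
        sng, vertices=vertices, adjacency_edges=adjacency_edges, vertex_index=index
    )


def _edge_key(e) -> tuple:
    return tuple(sorted(map(str, e)))


def _neighbour_maps(adjacency_edges, extremity_edges):
    adj, ext = {}, {}
    for e in adjacency_edges:
        u, v = tuple(e)
        adj[u], adj[v] = v, u
    for e in extremity_edges:
        u, v = tuple(e)
        ext[u], ext[v] = v, u
    return adj, ext


def _walk_components(vertices, adj, ext) -> list:
    """Components of a graph whose adjacency and extremity edges are matchings."""
    seen = set()
    components = []
    order = sorted(vertices, key=str)

    def traverse(start, first_via_adj):
        """Walk from ``start`` alternating edge types; return (vertices, #ext, closed)."""
        path = [start]
        ecount = 0
        via_adj = first_via_adj
        cur = start
        while True:
            nxt = (adj if via_adj else ext).get(cur)
            if nxt is None:
                return path, ecount, False
            if not via_adj:
                ecount += 1
            if nxt == start:
                return path, ecount, True
            path.append(nxt)
            cur = nxt
            via_adj = not via_adj

    for v in order:
        if v in seen:
            continue
        # find a free end if the component is a path
        has_adj, has_ext = v in adj, v in ext
        if not has_adj and not has_ext:
            seen.add(v)
            components.append(Component([v], False, 0, endpoints=(v, v)))
            continue
        # walk in one direction; if we come back, it is a cycle
        start_via_adj = has_adj
        path, ecount, closed = traverse(v, start_via_adj)
        if closed:
            comp = Component(path, True, ecount)
        else:
            # v may be interior; walk the other direction too
            if has_adj and has_ext:
                back, becount, _ = traverse(v, False)
                path = list(reversed(back[1:])) + path
                ecount += becount
            comp = Component(path, False, ecount, endpoints=(path[0], path[-1]))
        seen.update(path)
        components.append(comp)
    return components


def decompose(sng: SNGraph, matching: Matching) -> SimpleSNG:
    """Restrict the SNG to the extremity edges induced by ``matching``.

    For each matched pair {m, n} the edges {m^t, n^t} and {m^h, n^h} (siblings)
    are kept and no others; the result is simple.
    """
    kept = []
    for p in sorted(matching.pairs, key=_edge_key):
        m, n = sorted(p)
        if m.family != n.family:
            raise ValueError(f"matching pairs markers of different families: {m}, {n}")
        kept.append(frozenset((m.tail, n.tail)))
        kept.append(frozenset((m.head, n.head)))
    adj, ext = _neighbour_maps(sng.adjacency_edges, kept)
    components = _walk_components(sng.vertices, adj, ext)
    graph = replace(sng, extremity_edges=kept)
    return SimpleSNG(graph, matching, components)


def classify_components(simple: SimpleSNG, matching: Matching) -> ComponentCensus:
    """Census of a consistent decomposition (taxonomy by endpoints and parity).

    Circular singletons of the underlying genome are counted separately and
    their components are excluded from the path/cycle counts, so the distance
    formula's preprocessing is already reflected here.
    """
    singleton_markers = {
        m
        for c in find_circular_singletons(simple.graph.genome, matching)
        for m in c.markers()
    }
    census = ComponentCensus(
        n=len(matching.pairs),
        circular_singletons=len(
            find_circular_singletons(simple.graph.genome, matching)
        ),
    )
    ext_of = {}
    for e in simple.graph.extremity_edges:
        u, v = tuple(e)
        ext_of[u], ext_of[v] = v, u
    for comp in simple.components:
        if any(
            not isinstance(v, PseudoCap) and v.marker in singleton_markers
            for v in comp.vertices
        ):
            continue
        _tally(census, comp, ext_of, matching)
    return census


def _tally(census: ComponentCensus, comp: Component, ext_of, matching: Matching) -> None:
    odd = comp.odd
    if comp.is_cycle:
        if odd:
            census.c_odd += 1
        else:
            census.c_even += 1
        return

    def end_is_lava(v) -> bool:
        if isinstance(v, PseudoCap):
            return False
        return v not in ext_of

    a, b = comp.endpoints
    lava_ends = end_is_lava(a) + end_is_lava(b)
    # an isolated telomere-lava vertex has one telomere end and one lava end
    if len(comp.vertices) == 1 and not isinstance(comp.vertices[0], PseudoCap):
        lava_ends = 1
    if lava_ends == 0:
        if odd:
            census.p_GG_odd += 1
        else:
            census.p_GG_even += 1
    elif lava_ends == 1:
        if odd:
            census.p_Gg_odd += 1
        else:
            census.p_Gg_even += 1
    else:
        if odd:
            census.p_gg_odd += 1
        else:
            census.p_gg_even += 1


def census_of(genome: Genome, matching: Matching) -> ComponentCensus:
    """One-pass census for ``genome`` under ``matching`` (no graph objects).

    Equivalent to ``classify_components(decompose(build_sng(...), matching))``
    but built directly from neighbour maps; used by the distance/sorting hot
    paths.
    """
    singleton_chroms = [
        c
        for c in genome.chromosomes
        if c.circular and all(matching.is_singular(m) for m in c.markers())
    ]
    skip = {m for c in singleton_chroms for m in c.markers()}
    census = ComponentCensus(
        n=len(matching.pairs), circular_singletons=len(singleton_chroms)
    )
    adj = {}
    for c in genome.chromosomes:
        for a in c.adjacencies():
            u, v = tuple(a)
            if u.marker in skip:
                continue
            adj[u], adj[v] = v, u
    ext = {}
    for p in matching.pairs:
        m, n = tuple(p)
        ext[m.tail], ext[n.tail] = n.tail, m.tail
        ext[m.head], ext[n.head] = n.head, m.head
    vertices = [e for m in genome.markers() if m not in skip for e in (m.tail, m.head)]
    for comp in _walk_components(vertices, adj, ext):
        _tally(census, comp, ext, matching)
    return census


def to_dot(sng: SNGraph) -> str:
    """Export the graph in DOT format for debugging."""
    lines = ["graph sng {"]
    for v in sng.vertices:
        lines.append(f'  "{v}";')
    for e in sng.adjacency_edges:
        u, v = sorted(map(str, e))
        lines.append(f'  "{u}" -- "{v}" [kind=adjacency];')
    for e in sng.extremity_edges:
        u, v = sorted(map(str, e))
        lines.append(f'  "{u}" -- "{v}" [kind=extremity];')
    lines.append("}")
    return "\n".join(lines) + "\n"
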