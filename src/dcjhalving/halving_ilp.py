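"""Capping-free ILP halving for natural genomes (arbitrary family sizes).

Finding the maximum matching that minimises the restricted DCJ-indel halving
distance is NP-hard, so the minimisation is written as an integer linear
program over consistent decompositions of the supernatural graph.  One binary
per candidate sibling pair of markers selects the matching (keeping an
extremity edge together with its sibling); per-vertex variables label each
component of the selected decomposition so that per-adjacency-edge *report*
variables can tally the census classes the distance formula needs:

* ``y``/``z`` designate one *reporting vertex* per lava-free component (the
  minimum-index vertex); components containing a lava vertex have ``y`` forced
  to zero.
* ``a`` marks the telomere/lava character of a path's ends (0 at pseudo-caps,
  1 at lava vertices) and may only change across an adjacency edge reporting a
  pier.
* ``b`` tracks parity: 0 at pseudo-caps and lava vertices, flipping across
  every active extremity edge; it may differ across an adjacency edge only
  when an odd component type is reported there.

Pseudo-caps (one artificial neighbour per telomere, indexed before all
regular vertices) guarantee every component contains an adjacency edge, and
keep the model linear in the number of linear chromosomes — no quadratic
capping.  Reports of viaducts and piers are canonised to pseudo-cap edges,
pontoon reports to lava-incident edges, and cycle reports require both report
endpoints to carry ``a = 1``, so no component class can masquerade as a
cheaper one.  The objective

    minimise  n - c + (p_g|g + T - p_G|G + delta)/2 + s

(with ``T`` bounding both pier counts from above and ``s`` counting fully
deleted circular chromosomes) may be half-integral; the distance is its
ceiling.  Optima are validated behaviourally against the closed form on
resolved inputs and against exhaustive matching enumeration on small natural
genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome_model import Genome, Homology, Marker, Matching
from .halving_resolved import (
    DistanceBreakdown,
    Scenario,
    distance_under_matching,
    sort_halving,
)
from .sng import ComponentCensus, PseudoCap, add_pseudo_caps, build_sng, census_of

__all__ = [
    "ILPModel",
    "ILPSolution",
    "SolverUnavailableError",
    "build_ilp",
    "write_lp",
    "solve_ilp",
    "halve_natural",
]

OBJ_TOL = 1e-6


class SolverUnavailableError(RuntimeError):
    """No MILP backend is available for the requested mode."""


@dataclass
class _Constraint:
    tag: str
    coeffs: dict  # variable name -> coefficient
    lb: float
    ub: float


@dataclass
class ILPModel:
    """A MILP in generic form: named variables, tagged rows, linear objective."""

    variables: list = field(default_factory=list)  # (name, lb, ub, is_integer)
    constraints: list = field(default_factory=list)
    objective: dict = field(default_factory=dict)
    objective_constant: float = 0.0
    # decode metadata
    pair_vars: dict = field(default_factory=dict)  # var name -> frozenset({m, n})
    genome: Genome | None = None
    homology: Homology | None = None

    _index: dict = field(default_factory=dict)

    def add_var(self, name: str, lb=0.0, ub=1.0, integer=True) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name}")
        self._index[name] = len(self.variables)
        self.variables.append((name, lb, ub, integer))
        return name

    def add_constraint(self, tag: str, coeffs: dict, lb=-math.inf, ub=math.inf) -> None:
        self.constraints.append(_Constraint(tag, dict(coeffs), lb, ub))

    @property
    def num_variables(self) -> int:
        return len(self.variables)

    @property
    def num_constraints(self) -> int:
        return len(self.constraints)


@dataclass
class ILPSolution:
    """Solver output plus the decoded matching, census and distance."""

    objective: float
    bound: float
    gap: float
    status: str
    assignment: dict
    matching: Matching
    census: ComponentCensus
    breakdown: DistanceBreakdown

    @property
    def distance(self) -> int:
        """Integerised objective (the objective itself may be half-integral)."""
        return math.ceil(self.objective - OBJ_TOL)


def _vname(v) -> str:
    if isinstance(v, PseudoCap):
        return f"cap_{v.telomere}"
    return str(v)


def build_ilp(genome: Genome, homology: Homology | None = None) -> ILPModel:
    """Construct the halving ILP for a natural genome.

    Model size is linear in markers plus telomeres: one binary per candidate
    marker pair, a fixed handful of variables per vertex (including
    pseudo-caps) and per adjacency edge.
    """
    if homology is None:
        homology = Homology.of(genome)
    model = ILPModel(genome=genome, homology=homology)
    markers = sorted(genome.markers())
    if not markers:
        return model

    sng = add_pseudo_caps(build_sng(genome, homology))
    ix = sng.vertex_index
    vertices = sorted(ix, key=ix.get)
    U = max(ix.values())
    adj_edges = sorted(sng.adjacency_edges, key=lambda e: tuple(sorted(map(_vname, e))))

    d = {m: model.add_var(f"d_{m}") for m in markers}

    # candidate sibling pairs (C.01-C.05: consistent decomposition)
    pairs_at: dict = {m: [] for m in markers}
    for fam in sorted(homology.families.values()):
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                m, n = fam[i], fam[j]
                x = model.add_var(f"x_{m}_{n}")
                model.pair_vars[x] = frozenset((m, n))
                pairs_at[m].append(x)
                pairs_at[n].append(x)
    for m in markers:
        model.add_constraint(
            "C.01", {**{x: 1 for x in pairs_at[m]}, d[m]: 1}, lb=1, ub=1
        )
    # C.06: maximum matching — exactly (|F| mod 2) singular markers per family
    for fname, fam in sorted(homology.families.items()):
        model.add_constraint(
            "C.06", {d[m]: 1 for m in fam}, lb=len(fam) % 2, ub=len(fam) % 2
        )

    a = {v: model.add_var(f"a_{_vname(v)}") for v in vertices}
    b = {v: model.add_var(f"b_{_vname(v)}") for v in vertices}
    z = {v: model.add_var(f"z_{_vname(v)}") for v in vertices}
    y = {v: model.add_var(f"y_{_vname(v)}", 0, ix[v], integer=False) for v in vertices}

    def marker_of(v):
        return None if isinstance(v, PseudoCap) else v.marker

    # reports: viaducts/piers at pseudo-cap edges (C.19), cycles/pontoons elsewhere
    r: dict = {}
    cap_edge = {}
    for e in adj_edges:
        u, v = sorted(e, key=_vname)
        ename = f"{_vname(u)}__{_vname(v)}"
        is_cap = isinstance(u, PseudoCap) or isinstance(v, PseudoCap)
        cap_edge[e] = is_cap
        kinds = ("GG1", "Gg0", "Gg1") if is_cap else ("c0", "c1", "gg1")
        r[e] = {k: model.add_var(f"r{k}_{ename}") for k in kinds}
        model.add_constraint("C.15/one", {var: 1 for var in r[e].values()}, ub=1)

    # --- component labelling ------------------------------------------------
    for e in adj_edges:
        u, v = tuple(e)
        re = r[e]
        odd = [re[k] for k in ("GG1", "Gg1", "c1", "gg1") if k in re]
        # y equal across adjacency edges (active by construction)
        model.add_constraint("C.18", {y[u]: 1, y[v]: -1}, lb=0, ub=0)
        # b equal unless an odd type is reported here (C.14)
        model.add_constraint(
            "C.14", {b[u]: 1, b[v]: -1, **{o: -1 for o in odd}}, ub=0
        )
        model.add_constraint(
            "C.14", {b[v]: 1, b[u]: -1, **{o: -1 for o in odd}}, ub=0
        )
        # a equal unless a pier is reported here (C.10); piers only at cap edges
        piers = [re[k] for k in ("Gg0", "Gg1") if k in re]
        model.add_constraint("C.10", {a[u]: 1, a[v]: -1, **{p: -1 for p in piers}}, ub=0)
        model.add_constraint("C.10", {a[v]: 1, a[u]: -1, **{p: -1 for p in piers}}, ub=0)
        # ... and a pier report forces the a-flip: a = 1 on the regular side
        # (stops even viaducts from masquerading as odd viaduct + odd pier)
        if piers:
            regular = v if isinstance(u, PseudoCap) else u
            model.add_constraint(
                "C.19", {**{p: 1 for p in piers}, a[regular]: -1}, ub=0
            )
        # odd reports force a b-flip across this edge (C.16)
        for o in odd:
            model.add_constraint("C.16", {o: 1, b[u]: -1, b[v]: -1}, ub=0)
            model.add_constraint("C.16", {o: 1, b[u]: 1, b[v]: 1}, ub=2)
        # negative/neutral reports only at the reporting vertex (C.15)
        neg = [re[k] for k in ("c0", "c1", "GG1") if k in re]
        if neg:
            model.add_constraint(
                "C.15", {**{g: 1 for g in neg}, z[u]: -1, z[v]: -1}, ub=0
            )
        # cycle reports require a = 1 at both ends: no telomeres (C.17)
        for k in ("c0", "c1"):
            if k in re:
                model.add_constraint("C.17", {re[k]: 1, a[u]: -1}, ub=0)
                model.add_constraint("C.17", {re[k]: 1, a[v]: -1}, ub=0)
        # pontoon reports at a lava end (C.20)
        if "gg1" in re:
            dd = [d[marker_of(w)] for w in (u, v) if marker_of(w) is not None]
            model.add_constraint(
                "C.20", {re["gg1"]: 1, **{t: -1 for t in dd}}, ub=0
            )

    for v in vertices:
        m = marker_of(v)
        if m is None:
            model.add_constraint("C.07", {a[v]: 1}, lb=0, ub=0)
            model.add_constraint("C.11", {b[v]: 1}, lb=0, ub=0)
        else:
            model.add_constraint("C.08", {a[v]: 1, d[m]: -1}, lb=0)
            model.add_constraint("C.12", {b[v]: 1, d[m]: 1}, ub=1)
            # components containing a lava vertex have y = 0 (C.18)
            model.add_constraint("C.18", {y[v]: 1, d[m]: ix[v]}, ub=ix[v])
        # reporting vertex: z only at the component's minimum index (via y)
        model.add_constraint("C.15z", {z[v]: ix[v], y[v]: -1}, ub=0)

    # extremity edges: a/b/y propagation gated by the pair variable
    for x, pair in sorted(model.pair_vars.items()):
        m, n = sorted(pair)
        for u, v in ((m.tail, n.tail), (m.head, n.head)):
            model.add_constraint("C.09", {a[u]: 1, a[v]: -1, x: 1}, ub=1)
            model.add_constraint("C.09", {a[v]: 1, a[u]: -1, x: 1}, ub=1)
            # b flips across an active extremity edge (C.13)
            model.add_constraint("C.13", {b[u]: 1, b[v]: 1, x: -1}, lb=0)
            model.add_constraint("C.13", {b[u]: 1, b[v]: 1, x: 1}, ub=2)
            model.add_constraint("C.18", {y[u]: 1, y[v]: -1, x: U}, ub=U)
            model.add_constraint("C.18", {y[v]: 1, y[u]: -1, x: U}, ub=U)

    # --- census tallies (C.21-C.29) ----------------------------------------
    def tally(name: str, kind: str) -> str:
        var = model.add_var(name, 0, len(adj_edges), integer=False)
        coeffs = {re[kind]: 1 for re in r.values() if kind in re}
        model.add_constraint("C.21-29", {**coeffs, var: -1}, lb=0, ub=0)
        return var

    c_even = tally("c", "c0")
    p_GG1 = tally("p_GG_odd", "GG1")
    p_Gg0 = tally("p_Gg_even", "Gg0")
    p_Gg1 = tally("p_Gg_odd", "Gg1")
    p_gg1 = tally("p_gg_odd", "gg1")
    n_var = model.add_var("n", 0, len(markers) // 2, integer=False)
    model.add_constraint(
        "C.21-29", {**{d[m]: 1 for m in markers}, n_var: 2}, lb=len(markers), ub=len(markers)
    )
    T = model.add_var("T", 0, len(adj_edges), integer=False)
    model.add_constraint("C.21-29", {T: 1, p_Gg0: -1}, lb=0)
    model.add_constraint("C.21-29", {T: 1, p_Gg1: -1}, lb=0)

    # --- delta edge case (C.30-C.32) ---------------------------------------
    O = model.add_var("O")
    k_par = model.add_var("k_parity", 0, len(adj_edges), integer=True)
    model.add_constraint("C.30", {p_gg1: 1, k_par: -2, O: -1}, lb=0, ub=0)
    NE = model.add_var("NE")
    Dp = model.add_var("Dplus", 0, len(adj_edges), integer=False)
    Dm = model.add_var("Dminus", 0, len(adj_edges), integer=False)
    gsel = model.add_var("gsel")
    M = len(adj_edges) + 1
    model.add_constraint("C.31", {p_Gg0: 1, p_Gg1: -1, Dp: -1, Dm: 1}, lb=0, ub=0)
    model.add_constraint("C.31", {Dp: 1, gsel: -M}, ub=0)
    model.add_constraint("C.31", {Dm: 1, gsel: M}, ub=M)
    model.add_constraint("C.31", {NE: 1, Dp: -1, Dm: -1}, ub=0)
    delta = model.add_var("delta")
    model.add_constraint("C.32", {delta: 1, O: -1, NE: 1}, lb=0)

    # --- circular singletons (C.33-C.34) -----------------------------------
    s_total = model.add_var("s", 0, len(genome.chromosomes), integer=False)
    s_terms = {}
    for di, chrom in enumerate(genome.chromosomes):
        if not chrom.circular:
            continue
        s_D = model.add_var(f"sD_{di}")
        s_terms[s_D] = 1
        model.add_constraint(
            "C.33",
            {s_D: 1, **{d[m]: -1 for m in chrom.markers()}},
            lb=1 - len(chrom.content),
        )
    model.add_constraint("C.34", {**s_terms, s_total: -1}, lb=0, ub=0)

    # --- objective ----------------------------------------------------------
    model.objective = {
        n_var: 1.0,
        c_even: -1.0,
        p_gg1: 0.5,
        T: 0.5,
        p_GG1: -0.5,
        delta: 0.5,
        s_total: 1.0,
    }
    return model


def write_lp(model: ILPModel, path) -> None:
    """Write the model as a CPLEX-LP format file (deterministic output)."""
    lines = ["Minimize", " obj:"]
    terms = [
        f" {'+' if c >= 0 else '-'} {abs(c):g} {v}" for v, c in model.objective.items()
    ]
    lines.extend(terms or [" 0 dummy"])
    lines.append("Subject To")
    for i, con in enumerate(model.constraints):
        expr = " ".join(
            f"{'+' if c >= 0 else '-'} {abs(c):g} {v}" for v, c in sorted(con.coeffs.items())
        )
        if con.lb == con.ub:
            lines.append(f" c{i}_{con.tag.replace('.', '_').replace('/', '_')}: {expr} = {con.lb:g}")
        else:
            if con.ub != math.inf:
                lines.append(
                    f" c{i}a_{con.tag.replace('.', '_').replace('/', '_')}: {expr} <= {con.ub:g}"
                )
            if con.lb != -math.inf:
                lines.append(
                    f" c{i}b_{con.tag.replace('.', '_').replace('/', '_')}: {expr} >= {con.lb:g}"
                )
    lines.append("Bounds")
    for name, lb, ub, _ in model.variables:
        lines.append(f" {lb:g} <= {name} <= {ub:g}")
    ints = [name for name, _, _, is_int in model.variables if is_int]
    if ints:
        lines.append("Generals")
        lines.extend(f" {name}" for name in ints)
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _solve_highs(model: ILPModel, time_limit, mip_gap):
    from scipy.optimize import Bounds, LinearConstraint, milp

    nvar = model.num_variables
    idx = model._index
    c = np.zeros(nvar)
    for v, coef in model.objective.items():
        c[idx[v]] = coef
    lb = np.array([v[1] for v in model.variables], dtype=float)
    ub = np.array([v[2] for v in model.variables], dtype=float)
    integrality = np.array([1 if v[3] else 0 for v in model.variables])
    from scipy.sparse import lil_matrix

    A = lil_matrix((len(model.constraints), nvar))
    clb = np.empty(len(model.constraints))
    cub = np.empty(len(model.constraints))
    for i, con in enumerate(model.constraints):
        for v, coef in con.coeffs.items():
            A[i, idx[v]] = coef
        clb[i], cub[i] = con.lb, con.ub
    options = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    if mip_gap is not None:
        options["mip_rel_gap"] = float(mip_gap)
    res = milp(
        c=c,
        constraints=LinearConstraint(A.tocsr(), clb, cub),
        bounds=Bounds(lb, ub),
        integrality=integrality,
        options=options,
    )
    return res


def solve_ilp(
    model: ILPModel,
    backend: str = "auto",
    time_limit: float | None = None,
    threads: int = 1,
    seed: int | None = None,
    mip_gap: float | None = None,
) -> ILPSolution:
    """Solve the halving ILP and decode matching, census and distance.

    ``backend``: ``auto``/``highs`` use the HiGHS solver bundled with scipy;
    ``lp-only`` raises :class:`SolverUnavailableError` (export the model with
    :func:`write_lp` instead).  ``threads`` and ``seed`` are recorded and
    forwarded where the backend supports them (HiGHS via scipy exposes
    neither; it is deterministic and single-threaded).
    """
    if backend == "lp-only":
        raise SolverUnavailableError(
            "backend 'lp-only' cannot solve; use write_lp() to export the model"
        )
    if backend not in ("auto", "highs"):
        raise SolverUnavailableError(f"unknown MILP backend {backend!r}")
    genome, homology = model.genome, model.homology
    if genome is None:
        raise ValueError("model lacks decode metadata; build it with build_ilp")
    markers = genome.markers()
    if not markers:
        matching = Matching(frozenset(), frozenset())
        census = census_of(genome, matching)
        return ILPSolution(
            0.0, 0.0, 0.0, "optimal", {}, matching, census,
            distance_under_matching(genome, matching),
        )
    res = _solve_highs(model, time_limit, mip_gap)
    if res.status not in (0, 1) or res.x is None:
        raise RuntimeError(f"MILP solve failed: {res.message}")
    names = [v[0] for v in model.variables]
    assignment = dict(zip(names, res.x))
    pairs = [
        pair for vname, pair in model.pair_vars.items() if assignment[vname] > 0.5
    ]
    matching = Matching.from_pairs(pairs, markers)
    census = census_of(genome, matching)
    breakdown = distance_under_matching(genome, matching)
    bound = getattr(res, "mip_dual_bound", res.fun)
    gap = getattr(res, "mip_gap", 0.0)
    status = "optimal" if res.status == 0 else "feasible"
    return ILPSolution(
        objective=float(res.fun),
        bound=float(bound if bound is not None else res.fun),
        gap=float(gap if gap is not None else 0.0),
        status=status,
        assignment=assignment,
        matching=matching,
        census=census,
        breakdown=breakdown,
    )


def _relabel_resolved(genome: Genome, matching: Matching):
    """Rename matched pairs/singulars to unique families (a resolved instance)."""
    mapping: dict = {}
    for i, p in enumerate(sorted(matching.pairs, key=lambda p: tuple(sorted(p)))):
        m, n = sorted(p)
        mapping[m] = Marker(f"p{i}", 1)
        mapping[n] = Marker(f"p{i}", 2)
    for j, m in enumerate(sorted(matching.singular)):
        mapping[m] = Marker(f"s{j}", 1)
    from .genome_model import Chromosome

    chroms = [
        Chromosome(tuple((mapping[m], s) for m, s in c.content), circular=c.circular)
        for c in genome.chromosomes
    ]
    return Genome(name=genome.name, chromosomes=chroms), mapping


def _map_scenario(scenario: Scenario, mapping: dict) -> Scenario:
    """Rewrite a scenario from relabelled markers back to the originals."""
    from .genome_model import Extremity, Operation

    inverse = {v: k for k, v in mapping.items()}

    def conv_ext(e: Extremity) -> Extremity:
        m = inverse.get(e.marker)
        if m is None:  # marker inserted during sorting: keep the new label
            return e
        return Extremity(m, e.side)

    def conv_adj(adj):
        return frozenset(conv_ext(e) for e in adj)

    ops = []
    for op in scenario.operations:
        if op.kind == "dcj":
            ops.append(
                Operation.dcj([conv_adj(c) for c in op.cuts], [conv_adj(j) for j in op.joins])
            )
        elif op.kind == "deletion":
            ops.append(Operation.deletion([inverse.get(m, m) for m in op.segment]))
        else:
            seg = [(inverse.get(m, m), s) for m, s in op.segment]
            place = op.placement
            if isinstance(place, tuple):
                kind, site = place
                site = conv_adj(site) if kind == "adjacency" else conv_ext(site)
                place = (kind, site)
            ops.append(Operation.insertion(seg, place))
    return Scenario(operations=ops)


def halve_natural(
    genome: Genome,
    homology: Homology | None = None,
    backend: str = "auto",
    time_limit: float | None = None,
    threads: int = 1,
    seed: int | None = None,
):
    """Optimal matching, distance breakdown and sorting scenario for a genome.

    Resolved inputs bypass the solver; otherwise the ILP selects the matching
    and the resolved sorting machinery produces the scenario.  Returns
    ``(matching, breakdown, scenario)``.
    """
    if homology is None:
        homology = Homology.of(genome)
    if homology.resolved:
        matching = Matching.from_resolved_homology(homology)
    else:
        model = build_ilp(genome, homology)
        sol = solve_ilp(model, backend=backend, time_limit=time_limit, threads=threads, seed=seed)
        matching = sol.matching
    breakdown = distance_under_matching(genome, matching)
    relabelled, mapping = _relabel_resolved(genome, matching)
    inner = sort_halving(relabelled)
    scenario = _map_scenario(inner, mapping)
    inverse = {v: k for k, v in mapping.items()}
    from .genome_model import Chromosome

    scenario.final_genome = Genome(
        name=genome.name,
        chromosomes=[
            Chromosome(
                tuple((inverse.get(m, m), s) for m, s in c.content), circular=c.circular
            )
            for c in inner.final_genome.chromosomes
        ],
    )
    assert len(scenario) == breakdown.distance
    return matching, breakdown, scenario
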