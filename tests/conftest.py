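"""Shared helpers: compact genome construction and random legal DCJs."""

from __future__ import annotations

import numpy as np
import pytest

from dcjhalving.genome_model import (
    Genome,
    Homology,
    Matching,
    Operation,
    adjacency,
    apply_operation,
    parse_genomes,
)


def genome(text: str, name: str = "G") -> Genome:
    """Build a genome from chromosome specs like 'c:1 2 3' / 'l:1 -2'.

    Family names repeat to express homology (family = marker name).
    """
    lines = [f">{name}"]
    for chunk in text.split(";"):
        chunk = chunk.strip()
        kind, _, body = chunk.partition(":")
        lines.append(body.strip() + (" )" if kind == "c" else " |"))
    return parse_genomes("\n".join(lines))[0]


def resolved_matching(g: Genome) -> Matching:
    return Matching.from_resolved_homology(Homology.of(g))


def random_dcj(g: Genome, rng: np.random.Generator) -> Operation | None:
    """A uniformly sampled legal DCJ on two distinct sites of ``g``."""
    adjacencies = sorted(g.adjacencies(), key=lambda s: sorted(map(str, s)))
    telomeres = sorted(g.telomeres())
    sites = adjacencies + telomeres
    if len(sites) < 2:
        return None
    i, j = rng.choice(len(sites), size=2, replace=False)
    s1, s2 = sites[int(i)], sites[int(j)]
    if isinstance(s1, frozenset) and isinstance(s2, frozenset):
        a, b = sorted(s1)
        c, d = sorted(s2)
        if rng.random() < 0.5:
            return Operation.dcj([s1, s2], [adjacency(a, c), adjacency(b, d)])
        return Operation.dcj([s1, s2], [adjacency(a, d), adjacency(b, c)])
    if isinstance(s1, frozenset) or isinstance(s2, frozenset):
        s, t = (s1, s2) if isinstance(s1, frozenset) else (s2, s1)
        a, b = sorted(s)
        end = a if rng.random() < 0.5 else b
        return Operation.dcj([s], [adjacency(end, t)])
    return Operation.dcj([], [adjacency(s1, s2)])


def scramble(g: Genome, n_dcjs: int, seed: int) -> Genome:
    """Apply ``n_dcjs`` random DCJs (marker content unchanged)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_dcjs):
        op = random_dcj(g, rng)
        if op is not None:
            g = apply_operation(g, op)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
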