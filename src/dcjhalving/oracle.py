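"""Brute-force references for testing the halving machinery on tiny inputs.

``bruteforce_halving`` searches breadth-first over all legal DCJ operations,
restricted deletions (any contiguous run of singular markers) and restricted
insertions (the single missing homolog of a singular marker, at every
attachment site) until a structurally doubled genome is reached.  States are
deduplicated by a canonical form that identifies genomes equal up to
chromosome order, rotation and reflection.  The SD test is definitional
(marker and adjacency classes of size exactly two), independent of the
distance formula.

``enumerate_maximum_matchings`` yields every maximum matching of a homology
(at most one singular marker per family), and ``min_over_matchings`` minimises
the closed-form distance over them — the reference for the ILP on small
natural genomes.
"""

from __future__ import annotations

from itertools import product

from .genome_model import Genome, Homology, Matching
from .halving_resolved import distance_under_matching

__all__ = [
    "bruteforce_halving",
    "enumerate_maximum_matchings",
    "min_over_matchings",
    "state_of_genome",
]

MAX_MARKERS = 6  # guard: the search is exponential

# A state is a sorted tuple of chromosomes; a chromosome is
# (circular: bool, seq: tuple[(family, sign)]), canonicalized.


def _seq_key(seq: tuple) -> tuple:
    return tuple((f, 0 if g > 0 else 1) for f, g in seq)


def _canon_chromosome(circ: bool, seq: tuple) -> tuple:
    if circ:
        best = None
        for s in (seq, tuple((f, -g) for f, g in reversed(seq))):
            for i in range(len(s)):
                cand = s[i:] + s[:i]
                if best is None or _seq_key(cand) < _seq_key(best):
                    best = cand
        return (True, best)
    rev = tuple((f, -g) for f, g in reversed(seq))
    return (False, min(seq, rev, key=_seq_key))


def _canon_state(chromosomes) -> tuple:
    return tuple(sorted(_canon_chromosome(c, s) for c, s in chromosomes))


def state_of_genome(genome: Genome) -> tuple:
    """Canonical search state of a genome (occurrence numbers dropped)."""
    return _canon_state(
        (c.circular, tuple((m.family, s) for m, s in c.content))
        for c in genome.chromosomes
    )


def _is_sd_state(state: tuple) -> bool:
    counts: dict = {}
    for _, seq in state:
        for f, _ in seq:
            counts[f] = counts.get(f, 0) + 1
    if any(v != 2 for v in counts.values()):
        return False
    labels: dict = {}

    def add(a, b):
        key = (a, b) if a <= b else (b, a)
        labels[key] = labels.get(key, 0) + 1

    for circ, seq in state:
        k = len(seq)
        bounds = k if circ else k - 1
        for i in range(bounds):
            f1, s1 = seq[i]
            f2, s2 = seq[(i + 1) % k]
            right = (f1, "h" if s1 > 0 else "t")
            left = (f2, "t" if s2 > 0 else "h")
            add(right, left)
    return all(v == 2 for v in labels.values())


def _family_counts(state: tuple) -> dict:
    counts: dict = {}
    for _, seq in state:
        for f, _ in seq:
            counts[f] = counts.get(f, 0) + 1
    return counts


def _rebuild(n: int, fams: list, nb: list) -> tuple:
    """Chromosomes from an extremity neighbour array (2i tail, 2i+1 head)."""
    used = [False] * n
    chromosomes = []

    def walk(entry: int):
        seq = []
        e = entry
        while True:
            mid = e // 2
            used[mid] = True
            sign = 1 if e % 2 == 0 else -1
            seq.append((fams[mid], sign))
            exit_e = e ^ 1
            nxt = nb[exit_e]
            if nxt < 0:
                return seq, False
            if nxt == entry:
                return seq, True
            e = nxt

    for i in range(n):
        for e in (2 * i, 2 * i + 1):
            if nb[e] < 0 and not used[i]:
                seq, circ = walk(e)
                chromosomes.append((circ, tuple(seq)))
    for i in range(n):
        if not used[i]:
            seq, circ = walk(2 * i)
            chromosomes.append((True, tuple(seq)))
    return _canon_state(chromosomes)


def _successors(state: tuple):
    """All states reachable by one legal restricted operation."""
    counts = _family_counts(state)
    # flatten to an extremity graph
    fams: list = []
    nb_template: list = []
    adjacencies: list = []
    telomeres: list = []
    for circ, seq in state:
        base = len(fams)
        ends = []
        for f, s in seq:
            i = len(fams)
            fams.append(f)
            ends.append((2 * i + 1, 2 * i) if s < 0 else (2 * i, 2 * i + 1))
        k = len(seq)
        for j in range(k - 1):
            adjacencies.append((ends[j][1], ends[j + 1][0]))
        if circ:
            adjacencies.append((ends[-1][1], ends[0][0]))
        else:
            telomeres.append(ends[0][0])
            telomeres.append(ends[-1][1])
    n = len(fams)
    nb = [-1] * (2 * n)
    for a, b in adjacencies:
        nb[a], nb[b] = b, a

    def with_edges(remove, addl):
        arr = nb[:]
        for a, b in remove:
            arr[a] = arr[b] = -1
        for a, b in addl:
            arr[a], arr[b] = b, a
        return _rebuild(n, fams, arr)

    out = []
    # --- DCJs over all site pairs
    na = len(adjacencies)
    for i in range(na):
        a, b = adjacencies[i]
        for j in range(i + 1, na):
            c, d = adjacencies[j]
            out.append(with_edges([(a, b), (c, d)], [(a, c), (b, d)]))
            out.append(with_edges([(a, b), (c, d)], [(a, d), (b, c)]))
        for t in telomeres:
            out.append(with_edges([(a, b)], [(a, t)]))
            out.append(with_edges([(a, b)], [(b, t)]))
        out.append(with_edges([(a, b)], []))  # ab -> a, b
    for i in range(len(telomeres)):
        for j in range(i + 1, len(telomeres)):
            out.append(with_edges([], [(telomeres[i], telomeres[j])]))

    # --- deletions: all contiguous singular sub-segments
    state_list = list(state)
    for ci, (circ, seq) in enumerate(state_list):
        k = len(seq)
        singular = [counts[f] == 1 for f, _ in seq]
        if all(singular):
            rest = state_list[:ci] + state_list[ci + 1 :]
            out.append(_canon_state(rest))
        max_len = k - 1 if circ else k
        for start in range(k):
            for length in range(1, max_len + 1):
                if not circ and start + length > k:
                    break
                idx = [(start + x) % k for x in range(length)]
                if not all(singular[y] for y in idx):
                    break
                keep = [seq[y] for y in range(k) if y not in set(idx)]
                if not keep:
                    continue
                if circ:
                    rotated = [seq[(start + length + x) % k] for x in range(k - length)]
                    new_chrom = (True, tuple(rotated))
                else:
                    new_chrom = (False, tuple(keep))
                rest = state_list[:ci] + [new_chrom] + state_list[ci + 1 :]
                out.append(_canon_state(rest))

    # --- insertions: the single missing homolog of a singular marker
    singular_fams = sorted(f for f, v in counts.items() if v == 1)
    for f in singular_fams:
        for ci, (circ, seq) in enumerate(state_list):
            k = len(seq)
            positions = range(k) if circ else range(k + 1)
            for pos in positions:
                for sign in (1, -1):
                    new_seq = seq[:pos] + ((f, sign),) + seq[pos:]
                    rest = state_list[:ci] + [(circ, new_seq)] + state_list[ci + 1 :]
                    out.append(_canon_state(rest))
        out.append(_canon_state(state_list + [(False, ((f, 1),))]))
        out.append(_canon_state(state_list + [(True, ((f, 1),))]))
    return out


def bruteforce_halving(genome: Genome, matching: Matching | None = None, max_depth: int = 8):
    """Minimum restricted halving scenario length by exhaustive search.

    Homology is by family name; a supplied ``matching`` must be the resolved
    one induced by families (the search state drops occurrence numbers).
    Returns the minimum depth at which an SD genome is reached, or ``None``
    if it exceeds ``max_depth``.
    """
    markers = genome.markers()
    if len(markers) > MAX_MARKERS:
        raise ValueError(f"instance too large for brute force (> {MAX_MARKERS} markers)")
    if matching is not None:
        induced = Matching.from_resolved_homology(Homology.of(genome))
        if matching.pairs != induced.pairs:
            raise ValueError("brute force supports the family-induced matching only")
    start = state_of_genome(genome)
    if _is_sd_state(start):
        return 0
    visited = {start}
    frontier = [start]
    for depth in range(1, max_depth + 1):
        nxt = []
        for st in frontier:
            for succ in _successors(st):
                if succ in visited:
                    continue
                if _is_sd_state(succ):
                    return depth
                visited.add(succ)
                nxt.append(succ)
        if not nxt:
            return None
        frontier = nxt
    return None


def _pairings(items: tuple):
    """All ways to pair up an even-sized tuple ((f-1)!! of them)."""
    if not items:
        yield ()
        return
    first = items[0]
    for i in range(1, len(items)):
        rest = items[1:i] + items[i + 1 :]
        for sub in _pairings(rest):
            yield (frozenset((first, items[i])),) + sub


def enumerate_maximum_matchings(homology: Homology, max_family: int = 6):
    """Every maximum matching: per family, a pairing with at most one singular."""
    per_family = []
    for fam in sorted(homology.families.values()):
        if len(fam) > max_family:
            raise ValueError(f"family of size {len(fam)} too large to enumerate")
        options = []
        if len(fam) % 2 == 0:
            options = list(_pairings(fam))
        else:
            for skip in range(len(fam)):
                rest = fam[:skip] + fam[skip + 1 :]
                options.extend(_pairings(rest))
        per_family.append(options)
    all_markers = [m for fam in homology.families.values() for m in fam]
    for combo in product(*per_family):
        pairs = [p for sub in combo for p in sub]
        yield Matching.from_pairs(pairs, all_markers)


def min_over_matchings(genome: Genome, homology: Homology | None = None) -> int:
    """Minimum closed-form distance over all maximum matchings."""
    if homology is None:
        homology = Homology.of(genome)
    return min(
        distance_under_matching(genome, m).distance
        for m in enumerate_maximum_matchings(homology)
    )
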