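"""Genomes as signed gene orders, homology, matchings and rearrangement operations.

A genome is a set of chromosomes, each an ordered list of signed markers and
flagged linear or circular.  Every marker ``m`` has two extremities, its tail
``m^t`` and head ``m^h``; the chromosome structure is equivalently captured by
the set of *adjacencies* (unordered pairs of extremities that are consecutive
on a chromosome).  Extremities that take part in no adjacency are *telomeres*.

Homology is an equivalence relation on markers given implicitly by shared
marker names: a *family* is the set of markers with the same name.  A homology
is *resolved* if every family has at most two members.  A *matching* is a
resolved sub-homology pairing markers within families; markers left unpaired
are *singular*.

The transformation operations of the model are the double-cut-and-join (DCJ),
which cuts at up to two adjacencies or telomeres and rejoins the freed ends,
and segmental insertions/deletions (indels).  In the restricted indel model
only singular markers may be deleted and only the unique missing homolog of a
singular marker may be inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

TAIL = "t"
HEAD = "h"

__all__ = [
    "TAIL",
    "HEAD",
    "Marker",
    "Extremity",
    "Chromosome",
    "Genome",
    "Homology",
    "Matching",
    "Operation",
    "GenomeFormatError",
    "OperationError",
    "parse_genomes",
    "write_genomes",
    "apply_operation",
    "is_sd",
    "find_circular_singletons",
]


class GenomeFormatError(ValueError):
    """Raised for malformed genome files."""


class OperationError(ValueError):
    """Raised when an operation cannot be applied to a genome."""


@dataclass(frozen=True, order=True)
class Marker:
    """A concrete marker occurrence: ``family`` name plus ``occurrence`` number.

    ``(family, occurrence)`` is unique within a problem instance; the
    occurrence number is internal bookkeeping and never affects homology.
    """

    family: str
    occurrence: int

    @property
    def tail(self) -> "Extremity":
        return Extremity(self, TAIL)

    @property
    def head(self) -> "Extremity":
        return Extremity(self, HEAD)

    def extremity(self, side: str) -> "Extremity":
        return Extremity(self, side)

    def __str__(self) -> str:
        return f"{self.family}.{self.occurrence}"


@dataclass(frozen=True, order=True)
class Extremity:
    """One of the two ends of a marker (tail ``t`` or head ``h``)."""

    marker: Marker
    side: str

    @property
    def other(self) -> "Extremity":
        return Extremity(self.marker, HEAD if self.side == TAIL else TAIL)

    def __str__(self) -> str:
        return f"{self.side}{self.marker}"


Adjacency = frozenset  # frozenset of two Extremities (or one, for a 1-marker circle)


def adjacency(a: Extremity, b: Extremity) -> Adjacency:
    return frozenset((a, b))


@dataclass(frozen=True)
class Chromosome:
    """An ordered tuple of ``(marker, sign)`` with a linear/circular flag."""

    content: tuple  # tuple[(Marker, int sign)]
    circular: bool = False

    def __len__(self) -> int:
        return len(self.content)

    def markers(self) -> Iterator[Marker]:
        for m, _ in self.content:
            yield m

    def oriented_extremities(self) -> list:
        """Per marker in reading order, its (left, right) extremity pair."""
        out = []
        for m, sign in self.content:
            if sign > 0:
                out.append((m.tail, m.head))
            else:
                out.append((m.head, m.tail))
        return out

    def adjacencies(self) -> list:
        """Adjacencies induced by the reading order (k for circular, k-1 linear)."""
        ext = self.oriented_extremities()
        adj = [adjacency(ext[i][1], ext[i + 1][0]) for i in range(len(ext) - 1)]
        if self.circular and ext:
            adj.append(adjacency(ext[-1][1], ext[0][0]))
        return adj

    def telomeres(self) -> list:
        if self.circular or not self.content:
            return []
        ext = self.oriented_extremities()
        return [ext[0][0], ext[-1][1]]


@dataclass
class Genome:
    """A genome: chromosomes plus the derived adjacency/telomere structure."""

    name: str = ""
    chromosomes: list = field(default_factory=list)

    # -- derived structure -------------------------------------------------

    def markers(self) -> list:
        return [m for c in self.chromosomes for m in c.markers()]

    def adjacencies(self) -> set:
        adj = set()
        for c in self.chromosomes:
            adj.update(c.adjacencies())
        return adj

    def telomeres(self) -> set:
        tel = set()
        for c in self.chromosomes:
            tel.update(c.telomeres())
        return tel

    def extremities(self) -> list:
        out = []
        for m in self.markers():
            out.append(m.tail)
            out.append(m.head)
        return out

    def validate(self) -> None:
        """Check the adjacency-matching invariant (no extremity used twice)."""
        seen = set()
        for adj in (a for c in self.chromosomes for a in c.adjacencies()):
            for e in adj:
                if e in seen:
                    raise ValueError(f"extremity {e} occurs in two adjacencies")
                seen.add(e)
        markers = self.markers()
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate (family, occurrence) marker")

    # -- reconstruction from the adjacency set -----------------------------

    @classmethod
    def from_adjacencies(
        cls, markers: Iterable[Marker], adjacencies: Iterable[Adjacency], name: str = ""
    ) -> "Genome":
        """Rebuild chromosome lists from markers plus an adjacency matching.

        The chromosome order, rotations of circular chromosomes and reading
        directions are chosen canonically so reconstruction is deterministic.
        """
        markers = sorted(set(markers))
        neighbour: dict = {}
        for adj in adjacencies:
            pair = tuple(adj)
            if len(pair) == 1:  # self-adjacency of a 1-marker circular chromosome
                raise ValueError("adjacency must join two distinct extremities")
            a, b = pair
            for e in (a, b):
                if e in neighbour:
                    raise ValueError(f"extremity {e} occurs in two adjacencies")
            neighbour[a] = b
            neighbour[b] = a

        used: set = set()
        chromosomes = []

        def walk(entry: Extremity) -> tuple:
            """Follow markers starting by entering ``entry``'s marker at ``entry``."""
            content = []
            e = entry
            while True:
                m = e.marker
                used.add(m)
                sign = 1 if e.side == TAIL else -1
                content.append((m, sign))
                exit_e = e.other
                nxt = neighbour.get(exit_e)
                if nxt is None:
                    return tuple(content), exit_e, False
                if nxt.marker in used:
                    if nxt == entry:
                        return tuple(content), exit_e, True
                    raise ValueError("adjacency set does not describe chromosomes")
                e = nxt

        # linear chromosomes first: start at each unused telomere
        telomeres = sorted(e for m in markers for e in (m.tail, m.head) if e not in neighbour)
        for t in telomeres:
            if t.marker in used:
                continue
            content, _, circ = walk(t)
            assert not circ
            chromosomes.append(Chromosome(content, circular=False))
        # remaining markers lie on circular chromosomes
        for m in markers:
            if m in used:
                continue
            content, _, circ = walk(m.tail)
            if not circ:
                raise ValueError("adjacency set does not describe chromosomes")
            chromosomes.append(Chromosome(content, circular=True))
        g = cls(name=name, chromosomes=chromosomes)
        return canonicalize(g)


# ---------------------------------------------------------------------------
# homology and matchings
# ---------------------------------------------------------------------------


@dataclass
class Homology:
    """Partition of markers into families (equivalence classes by name)."""

    families: dict  # family name -> tuple of Markers

    @classmethod
    def of(cls, genome: Genome) -> "Homology":
        fam: dict = {}
        for m in genome.markers():
            fam.setdefault(m.family, []).append(m)
        return cls({k: tuple(sorted(v)) for k, v in fam.items()})

    @property
    def resolved(self) -> bool:
        return all(len(v) <= 2 for v in self.families.values())

    def family_of(self, m: Marker) -> tuple:
        return self.families[m.family]


@dataclass
class Matching:
    """Disjoint pairs of markers within families; the rest are singular."""

    pairs: frozenset  # frozenset of frozenset({m, n})
    singular: frozenset  # frozenset of Markers

    def __post_init__(self) -> None:
        partner = {}
        for p in self.pairs:
            m, n = tuple(p)
            if m.family != n.family:
                raise ValueError(f"matched markers {m}, {n} are not homologous")
            for a, b in ((m, n), (n, m)):
                if a in partner or a in self.singular:
                    raise ValueError(f"marker {a} matched twice")
                partner[a] = b
        self._partner = partner

    @classmethod
    def from_pairs(cls, pairs: Iterable, all_markers: Iterable[Marker]) -> "Matching":
        pairs = frozenset(frozenset(p) for p in pairs)
        matched = {m for p in pairs for m in p}
        singular = frozenset(m for m in all_markers if m not in matched)
        return cls(pairs, singular)

    @classmethod
    def from_resolved_homology(cls, homology: Homology) -> "Matching":
        """The unique maximum matching of a resolved homology."""
        if not homology.resolved:
            raise ValueError("homology is not resolved; a matching must be chosen")
        pairs = []
        singular = []
        for fam in homology.families.values():
            if len(fam) == 2:
                pairs.append(frozenset(fam))
            else:
                singular.extend(fam)
        return cls(frozenset(pairs), frozenset(singular))

    def partner(self, m: Marker) -> Optional[Marker]:
        return self._partner.get(m)

    def is_singular(self, m: Marker) -> bool:
        return m not in self._partner

    def is_maximum(self, homology: Homology) -> bool:
        """At most one singular marker per family (Maximum Matching model)."""
        count: dict = {}
        for m in self.singular:
            count[m.family] = count.get(m.family, 0) + 1
        return all(v <= 1 for v in count.values())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Operation:
    """A DCJ, deletion or insertion.

    DCJ: ``cuts`` are the adjacencies removed (0-2) and ``joins`` the
    adjacencies added (0-2).  Every extremity in a join must be freed by a cut
    or be a telomere of the genome; extremities freed but not rejoined become
    telomeres.  This uniformly covers all forms of the operation
    (ab,cd -> ac,bd; ab -> a,b; ab,s -> as,b; s,t -> st).

    Deletion: ``segment`` is the contiguous run of markers removed (their
    order/signs are taken from the genome); flanking extremities are joined.

    Insertion: ``segment`` is a tuple of (Marker, sign) of *new* markers and
    ``placement`` one of ``None`` (new linear chromosome), ``"circular"``
    (new circular chromosome), ``("adjacency", ab)`` or ``("telomere", s)``.
    The left end of the oriented segment attaches at the telomere / the
    lexicographically smaller extremity of the split adjacency.
    """

    kind: str
    cuts: tuple = ()
    joins: tuple = ()
    segment: tuple = ()
    placement: object = None

    @classmethod
    def dcj(cls, cuts: Iterable, joins: Iterable) -> "Operation":
        return cls("dcj", cuts=tuple(cuts), joins=tuple(joins))

    @classmethod
    def deletion(cls, segment: Iterable[Marker]) -> "Operation":
        return cls("deletion", segment=tuple(segment))

    @classmethod
    def insertion(cls, segment: Iterable, placement=None) -> "Operation":
        return cls("insertion", segment=tuple(segment), placement=placement)

    def __str__(self) -> str:
        if self.kind == "dcj":
            cut = " ".join("{%s}" % ",".join(sorted(map(str, c))) for c in self.cuts)
            join = " ".join("{%s}" % ",".join(sorted(map(str, j))) for j in self.joins)
            return f"DCJ cut {cut} join {join}".rstrip()
        if self.kind == "deletion":
            return "DEL " + " ".join(str(m) for m in self.segment)
        seg = " ".join(("" if s > 0 else "-") + str(m) for m, s in self.segment)
        if self.placement is None:
            where = "new"
        elif self.placement == "circular":
            where = "new circular"
        elif self.placement[0] == "adjacency":
            where = "at {%s}" % ",".join(sorted(map(str, self.placement[1])))
        else:
            where = f"telomere {self.placement[1]}"
        return f"INS {seg} {where}"


def apply_operation(genome: Genome, op: Operation) -> Genome:
    """Apply ``op`` to ``genome`` and return the transformed genome.

    The adjacency-matching invariant is preserved; the marker count changes
    only for indels (by the segment length).
    """
    if op.kind == "dcj":
        return _apply_dcj(genome, op)
    if op.kind == "deletion":
        return _apply_deletion(genome, op)
    if op.kind == "insertion":
        return _apply_insertion(genome, op)
    raise OperationError(f"unknown operation kind {op.kind!r}")


def _apply_dcj(genome: Genome, op: Operation) -> Genome:
    adj = genome.adjacencies()
    tel = genome.telomeres()
    for c in op.cuts:
        if c not in adj:
            raise OperationError(f"adjacency {set(c)} not present")
        adj.discard(c)
    freed = {e for c in op.cuts for e in c} | tel
    sites = len(op.cuts) + len({e for j in op.joins for e in j if e in tel})
    if sites > 2 or len(op.joins) > 2:
        raise OperationError("a DCJ transforms at most two adjacencies/telomeres")
    used = set()
    for j in op.joins:
        if len(j) != 2:
            raise OperationError("a join must connect two distinct extremities")
        for e in j:
            if e not in freed or e in used:
                raise OperationError(f"extremity {e} not available for joining")
            used.add(e)
        adj.add(frozenset(j))
    return Genome.from_adjacencies(genome.markers(), adj, name=genome.name)


def _locate_segment(genome: Genome, segment: tuple):
    """Find ``segment`` as a contiguous run; return (chromosome index, start)."""
    seg = tuple(segment)
    for ci, chrom in enumerate(genome.chromosomes):
        ms = [m for m, _ in chrom.content]
        k = len(chrom.content)
        n = len(seg)
        if n > k:
            continue
        positions = range(k) if chrom.circular else range(k - n + 1)
        for start in positions:
            if all(ms[(start + i) % k] == seg[i] for i in range(n)):
                return ci, start
            if all(ms[(start + i) % k] == seg[n - 1 - i] for i in range(n)):
                return ci, start
    raise OperationError("deletion segment not found as a contiguous run")


def _apply_deletion(genome: Genome, op: Operation) -> Genome:
    ci, start = _locate_segment(genome, op.segment)
    chrom = genome.chromosomes[ci]
    k = len(chrom.content)
    n = len(op.segment)
    keep_idx = [(start + n + i) % k for i in range(k - n)] if chrom.circular else [
        i for i in range(k) if not start <= i < start + n
    ]
    removed = set(op.segment)
    adj = genome.adjacencies()
    markers = [m for m in genome.markers() if m not in removed]
    # drop adjacencies touching the segment; join the flanks if both exist
    flanks = []
    for a in sorted(adj, key=lambda s: sorted(map(str, s))):
        ends = [e for e in a if e.marker in removed]
        if ends:
            adj.discard(a)
            flanks.extend(e for e in a if e.marker not in removed)
    if chrom.circular and len(flanks) == 2:
        adj.add(adjacency(*flanks))
    elif not chrom.circular and len(flanks) == 2 and 0 < start and start + n < k:
        adj.add(adjacency(*flanks))
    return Genome.from_adjacencies(markers, adj, name=genome.name)


def _apply_insertion(genome: Genome, op: Operation) -> Genome:
    existing = set(genome.markers())
    for m, _ in op.segment:
        if m in existing:
            raise OperationError(f"inserted marker {m} already present")
    if not op.segment:
        raise OperationError("empty insertion segment")
    markers = genome.markers() + [m for m, _ in op.segment]
    adj = genome.adjacencies()
    ext = []
    for m, sign in op.segment:
        ext.append((m.tail, m.head) if sign > 0 else (m.head, m.tail))
    for i in range(len(ext) - 1):
        adj.add(adjacency(ext[i][1], ext[i + 1][0]))
    left, right = ext[0][0], ext[-1][1]
    place = op.placement
    if place == "circular":
        if len(op.segment) == 1:
            raise OperationError("a 1-marker circular chromosome has no adjacency")
        adj.add(adjacency(right, left))
    elif place is not None:
        where, site = place
        if where == "adjacency":
            site = frozenset(site)
            if site not in adj:
                raise OperationError(f"attachment adjacency {set(site)} not present")
            a, b = sorted(site, key=str)
            adj.discard(site)
            adj.add(adjacency(a, left))
            adj.add(adjacency(right, b))
        elif where == "telomere":
            if site not in genome.telomeres():
                raise OperationError(f"attachment telomere {site} not present")
            adj.add(adjacency(site, left))
        else:
            raise OperationError(f"unknown placement {place!r}")
    return Genome.from_adjacencies(markers, adj, name=genome.name)


# ---------------------------------------------------------------------------
# structural doubling (SD) test and circular singletons
# ---------------------------------------------------------------------------


def _pair_key(m: Marker, matching: Matching):
    p = matching.partner(m)
    if p is None:
        return None
    return (m, p) if m <= p else (p, m)


def is_sd(genome: Genome, matching: Matching) -> bool:
    """Is the genome structurally doubled under ``matching``?

    True iff every marker is paired and the matching-induced equivalence
    partitions the adjacencies into classes of size exactly two.  The empty
    genome is SD.
    """
    markers = genome.markers()
    if any(matching.is_singular(m) for m in markers):
        return False
    classes: dict = {}
    for a in genome.adjacencies():
        label = tuple(sorted(((str(_pair_key(e.marker, matching)), e.side) for e in a)))
        classes[label] = classes.get(label, 0) + 1
    return all(v == 2 for v in classes.values())


def find_circular_singletons(genome: Genome, matching: Matching) -> list:
    """Circular chromosomes all of whose markers are singular under ``matching``."""
    return [
        c
        for c in genome.chromosomes
        if c.circular and all(matching.is_singular(m) for m in c.markers())
    ]


# ---------------------------------------------------------------------------
# file format (UniMoG dialect)
# ---------------------------------------------------------------------------


def parse_genomes(text: str) -> list:
    """Parse a UniMoG-dialect genome file.

    Lines ``>name`` start a genome; whitespace-separated signed marker tokens
    follow; ``|`` ends a linear chromosome and ``)`` a circular one; ``#``
    starts a comment line.  Marker tokens with the same name receive
    consecutive occurrence numbers in file order.
    """
    genomes: list = []
    names: set = set()
    current: Optional[Genome] = None
    counters: dict = {}
    buffer: list = []

    def finish_chromosome(circular: bool) -> None:
        if current is None:
            raise GenomeFormatError("chromosome outside of a genome (missing '>name')")
        if not buffer:
            raise GenomeFormatError(f"empty chromosome in genome {current.name!r}")
        content = []
        for tok in buffer:
            sign = 1
            if tok.startswith("-"):
                sign, tok = -1, tok[1:]
            elif tok.startswith("+"):
                tok = tok[1:]
            if not tok:
                raise GenomeFormatError("empty marker token")
            occ = counters.get(tok, 0) + 1
            counters[tok] = occ
            content.append((Marker(tok, occ), sign))
        current.chromosomes.append(Chromosome(tuple(content), circular=circular))
        buffer.clear()

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            if buffer:
                raise GenomeFormatError(
                    f"chromosome not terminated by '|' or ')' in genome {current.name!r}"
                )
            name = line[1:].strip()
            if name in names:
                raise GenomeFormatError(f"duplicate genome name {name!r}")
            names.add(name)
            current = Genome(name=name)
            counters = {}
            genomes.append(current)
            continue
        for tok in line.split():
            if tok in ("|", ")"):
                finish_chromosome(circular=(tok == ")"))
            else:
                buffer.append(tok)
    if buffer:
        raise GenomeFormatError(
            f"chromosome not terminated by '|' or ')' in genome {current.name!r}"
        )
    return genomes


def _chromosome_key(content: tuple) -> tuple:
    # positive orientation sorts before negative so "1 2 3" beats "-3 -2 -1"
    return tuple((m.family, 0 if sign > 0 else 1) for m, sign in content)


def _reverse(content: tuple) -> tuple:
    return tuple((m, -s) for m, s in reversed(content))


def canonicalize_chromosome(chrom: Chromosome) -> Chromosome:
    """Deterministic representative among rotations/reflections of a chromosome."""
    if not chrom.content:
        return chrom
    if chrom.circular:
        candidates = []
        for seq in (chrom.content, _reverse(chrom.content)):
            for i in range(len(seq)):
                candidates.append(seq[i:] + seq[:i])
        best = min(candidates, key=_chromosome_key)
        return Chromosome(best, circular=True)
    fwd, rev = chrom.content, _reverse(chrom.content)
    best = min((fwd, rev), key=_chromosome_key)
    return Chromosome(best, circular=False)


def canonicalize(genome: Genome) -> Genome:
    chroms = [canonicalize_chromosome(c) for c in genome.chromosomes]
    chroms.sort(key=lambda c: (c.circular, _chromosome_key(c.content)))
    return Genome(name=genome.name, chromosomes=chroms)


def write_genomes(genomes: Sequence[Genome]) -> str:
    """Emit genomes in the UniMoG dialect, canonically ordered.

    Round trip: ``parse_genomes(write_genomes(gs))`` reproduces ``gs`` up to
    chromosome rotation/reflection canonicalization.
    """
    out = []
    for g in genomes:
        out.append(f">{g.name}")
        for chrom in canonicalize(g).chromosomes:
            toks = [("-" if s < 0 else "") + m.family for m, s in chrom.content]
            toks.append(")" if chrom.circular else "|")
            out.append(" ".join(toks))
    return "\n".join(out) + ("\n" if out else "")
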