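"""Genome data model: parsing, writing, operations, SD test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcjhalving.genome_model import (
    Chromosome,
    Genome,
    GenomeFormatError,
    Homology,
    Marker,
    Matching,
    Operation,
    OperationError,
    adjacency,
    apply_operation,
    find_circular_singletons,
    is_sd,
    parse_genomes,
    write_genomes,
)

from .conftest import genome, random_dcj, resolved_matching


class TestParsing:
    def test_linear_and_circular_chromosomes(self):
        g = parse_genomes(">A\n1 -2 |\n3 )")[0]
        assert [c.circular for c in g.chromosomes] == [False, True]
        adj = {tuple(sorted(map(str, a))) for a in g.adjacencies()}
        assert adj == {("h1.1", "h2.1"), ("h3.1", "t3.1")}

    def test_empty_genome_has_zero_chromosomes(self):
        g = parse_genomes(">A\n")[0]
        assert g.name == "A" and g.chromosomes == []

    def test_occurrence_numbering_is_file_order(self):
        g = parse_genomes(">A\n1 2 3 1 |")[0]
        markers = g.markers()
        assert markers == [Marker("1", 1), Marker("2", 1), Marker("3", 1), Marker("1", 2)]
        assert len(Homology.of(g).families["1"]) == 2

    def test_comments_and_multiple_genomes(self):
        gs = parse_genomes("# a comment\n>A\n1 | # trailing\n>B\n2 )")
        assert [g.name for g in gs] == ["A", "B"]

    @pytest.mark.parametrize(
        "text",
        [">A\n1 2\n>B\n3 |", ">A\n1 |\n>A\n2 |", ">A\n|", ">A\n1 2 3"],
        ids=["unterminated", "duplicate-name", "empty-chromosome", "eof"],
    )
    def test_malformed_input_raises(self, text):
        with pytest.raises(GenomeFormatError):
            parse_genomes(text)


class TestWriting:
    def test_empty_list_gives_empty_text(self):
        assert write_genomes([]) == ""

    def test_circular_emitted_from_smallest_rotation(self):
        g = parse_genomes(">A\n3 1 2 )")[0]
        assert write_genomes([g]) == ">A\n1 2 3 )\n"

    def test_round_trip_is_canonical_form(self):
        text = ">A\n-3 1 |\n2 4 -2 )\n>B\n5 |"
        gs = parse_genomes(text)
        once = write_genomes(gs)
        assert write_genomes(parse_genomes(once)) == once

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_round_trip_random_genomes(self, data):
        names = st.sampled_from(["1", "2", "3", "4"])
        chrom = st.tuples(
            st.booleans(), st.lists(st.tuples(names, st.sampled_from([1, -1])), min_size=1, max_size=5)
        )
        chroms = data.draw(st.lists(chrom, min_size=0, max_size=3))
        lines = [">G"]
        for circ, content in chroms:
            toks = [("-" if s < 0 else "") + f for f, s in content]
            lines.append(" ".join(toks) + (" )" if circ else " |"))
        g = parse_genomes("\n".join(lines))[0]
        once = write_genomes([g])
        assert write_genomes(parse_genomes(once)) == once
        # marker multiset is preserved
        assert sorted(m.family for m in parse_genomes(once)[0].markers()) == sorted(
            m.family for m in g.markers()
        )


class TestOperations:
    def test_dcj_splits_circular_chromosome(self):
        # circular (1 2 4 3): cut {h1,t2} and {h4,t3}, rejoin {h1,t3} and
        # {t2,h4}: the remaining adjacencies {h3,t1} and {h2,t4} close two
        # circles (1 3) and (2 4)
        g = genome("c:1 2 4 3")
        a1, a2, a3, a4 = (Marker(str(i), 1) for i in "1234")
        op = Operation.dcj(
            [adjacency(a1.head, a2.tail), adjacency(a4.head, a3.tail)],
            [adjacency(a1.head, a3.tail), adjacency(a2.tail, a4.head)],
        )
        g2 = apply_operation(g, op)
        from dcjhalving.oracle import state_of_genome

        assert state_of_genome(g2) == (
            (True, (("1", 1), ("3", 1))),
            (True, (("2", 1), ("4", 1))),
        )

    def test_deletion_joins_flanks(self):
        g = genome("c:1 2 3")
        g2 = apply_operation(g, Operation.deletion([Marker("2", 1)]))
        assert {tuple(sorted(map(str, a))) for a in g2.adjacencies()} == {
            ("h1.1", "t3.1"),
            ("h3.1", "t1.1"),
        }

    def test_insertion_as_new_chromosome(self):
        g = genome("l:1")
        g2 = apply_operation(g, Operation.insertion([(Marker("1", 2), 1)]))
        assert len(g2.chromosomes) == 2
        assert sorted(str(m) for m in g2.markers()) == ["1.1", "1.2"]

    def test_insertion_into_adjacency(self):
        g = genome("c:1 2")
        site = next(iter(g.adjacencies()))
        g2 = apply_operation(g, Operation.insertion([(Marker("9", 1), 1)], ("adjacency", site)))
        assert len(g2.markers()) == 3 and len(g2.adjacencies()) == 3

    def test_dcj_followed_by_inverse_is_identity(self):
        rng = np.random.default_rng(7)
        g = genome("l:1 2 3; c:4 5")
        for _ in range(25):
            op = random_dcj(g, rng)
            g2 = apply_operation(g, op)
            inverse = Operation.dcj(op.joins, op.cuts)
            g3 = apply_operation(g2, inverse)
            assert g3.adjacencies() == g.adjacencies()
            g = g2

    def test_indels_change_marker_count_by_segment_length(self):
        g = genome("l:1 2 3 4")
        g2 = apply_operation(g, Operation.deletion([Marker("2", 1), Marker("3", 1)]))
        assert len(g2.markers()) == 2
        g3 = apply_operation(g2, Operation.insertion([(Marker("7", 1), 1), (Marker("8", 1), 1)]))
        assert len(g3.markers()) == 4

    def test_operand_errors(self):
        g = genome("l:1 2 3")
        with pytest.raises(OperationError):
            apply_operation(g, Operation.deletion([Marker("9", 1)]))
        bogus = adjacency(Marker("1", 1).tail, Marker("3", 1).head)
        with pytest.raises(OperationError):
            apply_operation(g, Operation.dcj([bogus], []))

    def test_adjacency_matching_preserved_under_random_dcjs(self):
        rng = np.random.default_rng(11)
        g = genome("l:1 2 3; l:4 5; c:6 7 8")
        for _ in range(40):
            op = random_dcj(g, rng)
            g = apply_operation(g, op)
            g.validate()


class TestSDAndSingletons:
    def test_sd_circular_interleaved_pairs(self):
        g = genome("c:1 2 1 2")  # pairs {1,1'},{2,2'}: adjacencies doubled
        assert is_sd(g, resolved_matching(g))

    def test_non_sd_ordering(self):
        g = genome("c:1 2 2 1")
        m = resolved_matching(g)
        assert not is_sd(g, m)

    def test_empty_genome_is_sd(self):
        g = Genome("E", [])
        assert is_sd(g, Matching(frozenset(), frozenset()))

    def test_singular_marker_breaks_sd(self):
        g = genome("c:1 3 1")
        assert not is_sd(g, resolved_matching(g))

    def test_circular_singletons_found(self):
        g = genome("l:1 2; c:3")
        m = resolved_matching(g)
        found = find_circular_singletons(g, m)
        assert len(found) == 1 and [mm.family for mm in found[0].markers()] == ["3"]

    def test_no_circular_chromosomes_no_singletons(self):
        g = genome("l:1 2")
        assert find_circular_singletons(g, resolved_matching(g)) == []

    def test_partly_matched_circular_is_not_singleton(self):
        g = genome("c:3 4; l:4")
        m = resolved_matching(g)  # family 4 has two copies: matched
        assert find_circular_singletons(g, m) == []
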