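"""Anchor indexing, maximal-run block detection, and the block file format."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import blocks_by_oracle, permutation_features
from syntenykit.errors import ParseError, ValidationError
from syntenykit.fixtures import EXAMPLE_BLOCK_RECORD
from syntenykit.genome_model import GeneFeature
from syntenykit.synteny_blocks import (
    OrthologPair,
    SyntenyBlock,
    compute_blocks,
    index_anchors,
    read_block_file,
    read_ortholog_pairs,
    write_block_file,
    write_ortholog_pairs,
)


def blocks_for(perm, min_anchors=2, **kwargs):
    ref, comp, pairs = permutation_features(list(perm))
    return compute_blocks(index_anchors(ref, comp, pairs), min_anchors=min_anchors, **kwargs)


class TestIndexAnchors:
    def test_one_to_one_ordinals(self):
        ref, comp, pairs = permutation_features([0, 1, 2, 3, 4])
        idx = index_anchors(ref, comp, pairs)
        assert [a.ref_ordinal for a in idx.anchors] == [1, 2, 3, 4, 5]
        assert sorted(a.comp_ordinal for a in idx.anchors) == [1, 2, 3, 4, 5]

    def test_drop_ambiguous_removes_multi_mapped_gene(self):
        ref, comp, pairs = permutation_features([0, 1, 2])
        pairs = list(pairs) + [OrthologPair("a000", "b002")]  # a000 now 1-to-2
        idx = index_anchors(ref, comp, pairs, multi_policy="drop_ambiguous")
        ids = {a.ref.feature_id for a in idx.anchors}
        assert "a000" not in ids and "a002" not in ids  # b002 ambiguous too
        assert ids == {"a001"}

    def test_unknown_feature_ids_listed(self):
        ref, comp, pairs = permutation_features([0, 1])
        with pytest.raises(ValidationError, match="ghost1.*ghost2|ghost"):
            index_anchors(ref, comp, list(pairs) + [OrthologPair("ghost1", "ghost2")])

    def test_keep_first_by_position_yields_bijection(self):
        rng = random.Random(7)
        perm = list(range(30))
        rng.shuffle(perm)
        ref, comp, pairs = permutation_features(perm)
        pairs = list(pairs)
        for _ in range(3):  # plant 10% multi-mappings
            a = rng.choice(ref).feature_id
            b = rng.choice(comp).feature_id
            pairs.append(OrthologPair(a, b))
        idx = index_anchors(ref, comp, pairs, multi_policy="keep_first_by_position")
        surviving = [(a.ref.feature_id, a.comp.feature_id) for a in idx.anchors]
        # brute-force injectivity check on both sides
        refs = [r for r, _ in surviving]
        comps = [c for _, c in surviving]
        assert len(refs) == len(set(refs)) and len(comps) == len(set(comps))
        # ordinals consecutive from 1 on each side
        assert sorted(a.ref_ordinal for a in idx.anchors) == list(range(1, len(surviving) + 1))
        assert sorted(a.comp_ordinal for a in idx.anchors) == list(range(1, len(surviving) + 1))


class TestComputeBlocks:
    @pytest.mark.parametrize(
        "comp_ordinals, expected",
        [
            # (run lengths, orientations); ordinals are the 1-based B indices
            ((1, 2, 3, 4, 5), [(5, "+")]),
            ((1, 2, 3, 5, 4), [(3, "+"), (2, "-")]),
            ((5, 4, 3, 2, 1), [(5, "-")]),
            ((1, 3, 5, 2, 4), []),
        ],
    )
    def test_worked_permutations(self, comp_ordinals, expected):
        perm = [o - 1 for o in comp_ordinals]
        got = blocks_for(perm, min_anchors=2)
        assert [(len(b.anchors), b.orientation) for b in got] == expected

    def test_block_spans_are_outer_gene_limits(self):
        got = blocks_for([2, 1, 0], min_anchors=2)
        (b,) = got
        # genes at 1000,1100,1200 each 51 bp long, both genomes
        assert (b.ref_start, b.ref_end) == (1000, 1250)
        assert (b.comp_start, b.comp_end) == (1000, 1250)

    def test_chromosome_change_breaks_run(self):
        ref = [GeneFeature(f"a{i}", f"a{i}", 1, "1", 100 + i * 10, 105 + i * 10) for i in range(4)]
        comp = [
            GeneFeature("b0", "b0", 2, "1", 100, 105),
            GeneFeature("b1", "b1", 2, "1", 110, 115),
            GeneFeature("b2", "b2", 2, "2", 100, 105),
            GeneFeature("b3", "b3", 2, "2", 110, 115),
        ]
        pairs = [OrthologPair(f"a{i}", f"b{i}") for i in range(4)]
        got = compute_blocks(index_anchors(ref, comp, pairs), min_anchors=2)
        assert [(b.comp_chromosome, len(b.anchors)) for b in got] == [("1", 2), ("2", 2)]

    def test_empty_anchor_set_is_empty_list(self):
        ref, comp, _ = permutation_features([0, 1])
        assert compute_blocks(index_anchors(ref, comp, [])) == []

    def test_block_ids_sequential_with_taxon_tag(self):
        got = blocks_for([0, 1, 4, 3, 2], min_anchors=2)
        assert [b.block_id for b in got] == ["SynBlock:9000190002:1", "SynBlock:9000190002:2"]
        got = blocks_for([0, 1, 4, 3, 2], min_anchors=2, id_tag="mmhs")
        assert got[0].block_id == "SynBlock:mmhs:1"

    def test_oracle_equivalence_random_permutations(self):
        rng = random.Random(11)
        for _ in range(150):
            n = rng.randrange(1, 40)
            perm = list(range(n))
            rng.shuffle(perm)
            for min_anchors in (1, 2, 3):
                got = blocks_for(perm, min_anchors=min_anchors)
                want = blocks_by_oracle(perm, min_anchors=min_anchors)
                assert [
                    {"ref_span": (b.ref_start, b.ref_end),
                     "comp_span": (b.comp_start, b.comp_end),
                     "orientation": b.orientation,
                     "anchor_ids": tuple(a.ref_feature_id for a in b.anchors)}
                    for b in got
                ] == want, f"mismatch on perm={perm} min_anchors={min_anchors}"

    def test_monotonic_mode_merges_gapped_runs(self):
        # ordinals 1,3,5 ascend with gaps: no consecutive blocks, one monotonic block
        perm = [0, 2, 4, 1, 3]
        assert blocks_for(perm, min_anchors=2) == []
        got = blocks_for(perm, min_anchors=2, mode="monotonic")
        assert [(len(b.anchors), b.orientation) for b in got] == [(3, "+"), (2, "+")]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.permutations(list(range(12))))
    def test_partition_and_monotonicity_properties(self, perm):
        """min_anchors=1 partitions anchors; raising min_anchors only removes blocks."""
        all_blocks = blocks_for(perm, min_anchors=1)
        anchor_ids = [a.ref_feature_id for b in all_blocks for a in b.anchors]
        assert sorted(anchor_ids) == sorted(f"a{i:03d}" for i in range(len(perm)))
        assert len(anchor_ids) == len(set(anchor_ids))
        prev = {tuple(b.anchors) for b in all_blocks}
        for k in (2, 3, 4):
            cur = {tuple(b.anchors) for b in blocks_for(perm, min_anchors=k)}
            assert cur <= prev
            prev = cur

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.permutations(list(range(10))))
    def test_reversal_flips_orientation_preserves_membership(self, perm):
        n = len(perm)
        fwd = blocks_for(perm, min_anchors=2)
        rev = blocks_for([n - 1 - p for p in perm], min_anchors=2)
        key = lambda bs: sorted(tuple(sorted(a.ref_feature_id for a in b.anchors)) for b in bs)
        assert key(fwd) == key(rev)
        fwd_by_members = {tuple(sorted(a.ref_feature_id for a in b.anchors)): b.orientation for b in fwd}
        for b in rev:
            members = tuple(sorted(a.ref_feature_id for a in b.anchors))
            assert b.orientation != fwd_by_members[members]


class TestBlockFile:
    def test_paper_example_record(self, tmp_path):
        p = tmp_path / "example.tsv"
        p.write_text(EXAMPLE_BLOCK_RECORD + "\n")
        (b,) = read_block_file(p)
        assert b.comp_chromosome == "8"
        assert b.comp_taxon_id == 9606
        assert (b.comp_start, b.comp_end) == (49909789, 55526155)
        assert b.orientation == "-"
        assert b.block_id == "SynBlock:mmhs:1"
        assert (b.ref_chromosome, b.ref_taxon_id) == ("1", 10090)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert read_block_file(p) == []

    def test_random_roundtrip(self, tmp_path):
        rng = random.Random(5)
        blocks = []
        for i in range(50):
            rs, cs = rng.randrange(1, 10**8), rng.randrange(1, 10**8)
            blocks.append(
                SyntenyBlock(str(rng.randrange(1, 20)), 10090, rs, rs + rng.randrange(1, 10**6),
                             str(rng.randrange(1, 23)), 9606, cs, cs + rng.randrange(1, 10**6),
                             rng.choice("+-"), f"SynBlock:mmhs:{i + 1}")
            )
        p = tmp_path / "blocks.tsv"
        write_block_file(blocks, p)
        assert read_block_file(p) == blocks

    def test_bare_ids_accepted(self, tmp_path):
        p = tmp_path / "bare.tsv"
        p.write_text("1\t10090\t1\t2\t8\t9606\t3\t4\t+\tblk1\n")
        assert read_block_file(p)[0].block_id == "blk1"

    @pytest.mark.parametrize(
        "line, match",
        [
            ("1\t10090\t1\t2\t8\t9606\t3\t4\t+\n", "columns"),
            ("1\t10090\t1\t2\t8\t9606\t3\t4\t?\tID=x\n", "orientation"),
            ("1\t10090\t1\t2\t8\t9606\t3\t4\t+\tID=x\n" * 2, "duplicate"),
        ],
    )
    def test_malformed_lines_rejected(self, tmp_path, line, match):
        p = tmp_path / "bad.tsv"
        p.write_text(line)
        with pytest.raises(ParseError, match=match):
            read_block_file(p)

    def test_duplicate_id_on_write_rejected(self, tmp_path):
        b = SyntenyBlock("1", 1, 1, 2, "2", 2, 3, 4, "+", "dup")
        with pytest.raises(ValidationError, match="dup"):
            write_block_file([b, b], tmp_path / "x.tsv")


class TestOrthologFile:
    def test_roundtrip_with_comments(self, tmp_path):
        pairs = [OrthologPair("a1", "b1"), OrthologPair("a2", "b2")]
        p = tmp_path / "pairs.tsv"
        write_ortholog_pairs(pairs, p)
        assert read_ortholog_pairs(p) == pairs

    def test_wrong_columns_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a1\tb1\nc1\n")
        with pytest.raises(ParseError) as err:
            read_ortholog_pairs(p)
        assert err.value.line_number == 2
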