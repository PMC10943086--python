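import numpy as np
import pytest

from ncgseek.corpus import corpus_fragments, pair_to_fragment
from ncgseek.grouping import build_group_table
from ncgseek.strands import (
    DataStrand,
    ReferenceStrand,
    assemble_data,
    assemble_reference,
    build_data_strands,
    build_data_unit,
    build_reference_matrix,
    decode_fragment,
    decode_group_index,
    decode_pool,
    encode_corpus,
    encode_group_index,
    matrix_from_strands,
    parse_data,
    parse_reference,
    pool_stats,
    section_reference,
)
from ncgseek.synthetic import FixturePlan, generate_corpus


def base3_digits(value, n=6):
    """Independent base-3 conversion oracle."""
    digits = []
    for _ in range(n):
        digits.append(value % 3)
        value //= 3
    return digits[::-1]


class TestGroupIndexCoding:
    def test_716_trit_string(self):
        assert base3_digits(716) == [2, 2, 2, 1, 1, 2]
        # the rotating mapping renders those trits deterministically
        seq = encode_group_index(716)
        assert decode_group_index(seq) == 716

    def test_zero_alternates_two_bases(self):
        seq = encode_group_index(0)
        assert len(set(seq)) == 2
        assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_exhaustive_round_trip_and_no_homopolymer(self):
        seen = set()
        for i in range(729):
            seq = encode_group_index(i)
            assert len(seq) == 6
            assert decode_group_index(seq) == i
            # rotation forbids even two consecutive identical bases
            assert all(a != b for a, b in zip(seq, seq[1:]))
            assert seq[0] != "T"  # fields are seeded as if preceded by 'T'
            seen.add(seq)
        assert len(seen) == 729

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            encode_group_index(729)


class TestDataUnit:
    def test_unit_is_seven_nt_ending_in_pointer(self):
        table = build_group_table([pair_to_fragment("CR")])
        unit = build_data_unit(pair_to_fragment("CR"), table)
        assert len(unit) == 7
        assert unit[6] == table.dictionary[pair_to_fragment("CR")][1]

    def test_absent_fragment_errors(self):
        table = build_group_table([pair_to_fragment("CR")])
        with pytest.raises(KeyError, match="absent"):
            build_data_unit(pair_to_fragment("XX"), table)


class TestReferenceMatrix:
    def test_single_group_column(self):
        table = build_group_table([0x8000])
        matrix = build_reference_matrix(table)
        assert matrix.columns[0] == "A" + "C" * 15

    def test_column_count_equals_groups(self):
        table = build_group_table([0x8000, 0x4001, 0x00F0])
        matrix = build_reference_matrix(table)
        assert matrix.n_groups == len(table)

    def test_member_round_trip_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            frags = [int(x) for x in rng.integers(1, 0xFFFF, 25)]
            table = build_group_table(frags)
            matrix = build_reference_matrix(table)
            for frag in set(frags):
                g, p = table.dictionary[frag]
                assert decode_fragment(matrix.columns[g], p) == frag

    def test_pointer_absent_gives_zero(self):
        table = build_group_table([0x8000])  # pointer A, filler C
        matrix = build_reference_matrix(table)
        assert decode_fragment(matrix.columns[0], "T") == 0


class TestSectioning:
    @pytest.mark.parametrize("n_groups,expected", [
        (717, 144),
        (80, 16),
        (81, 32),
    ])
    def test_strand_counts(self, n_groups, expected):
        # mutually colliding printable fragments: one group each
        frags = []
        letters = [c for c in map(chr, range(0x41, 0x7B)) if c.isalpha()]
        for a in letters:
            for b in letters:
                frags.append(pair_to_fragment(a + b))
                if len(frags) == n_groups:
                    break
            if len(frags) == n_groups:
                break
        table = build_group_table(frags)
        assert len(table) == n_groups  # letters always share bit 0x40
        strands = section_reference(build_reference_matrix(table))
        assert len(strands) == expected

    def test_padding_columns_use_virtual_filler(self):
        table = build_group_table([0x8000])
        strands = section_reference(build_reference_matrix(table))
        row0 = next(s for s in strands if s.ref_index == 0)
        # columns 1.. are padding: cyclic ACGT pattern of the empty group
        assert row0.payload[1:5] == "CGTA"

    def test_matrix_round_trip_through_strands(self):
        table = build_group_table([0x8000, 0x4001, 0x00F0, 0x0F00])
        matrix = build_reference_matrix(table)
        strands = section_reference(matrix)
        rebuilt = matrix_from_strands(strands, matrix.n_groups)
        assert rebuilt.columns == matrix.columns


class TestAssembly:
    @pytest.fixture()
    def primers(self):
        return ("ACGTGACTGACTGACTGACTG", "CAGTCAGTCAGTCAGTCAGTA")

    def test_reference_length_142(self, primers):
        strand = ReferenceStrand(0, 0, "ACGT" * 20)
        assert len(assemble_reference(strand, primers)) == 142

    def test_data_lengths_142_to_170(self, primers, small_setup):
        table = small_setup["table"]
        frag = next(iter(table.dictionary))
        unit = build_data_unit(frag, table)
        for n_units, expected in ((12, 142), (16, 170)):
            strand = DataStrand(0, 0, unit * n_units)
            assert len(assemble_data(strand, primers)) == expected

    def test_bad_primer_length_named(self, primers):
        strand = ReferenceStrand(0, 0, "ACGT" * 20)
        with pytest.raises(ValueError, match="forward primer"):
            assemble_reference(strand, ("ACGT", primers[1]))

    def test_parse_inverts_assemble(self, primers, small_setup):
        table = small_setup["table"]
        ref = ReferenceStrand(3, 1, "ACGT" * 20)
        parsed, status = parse_reference(assemble_reference(ref, primers))
        assert (parsed.ref_index, parsed.seg_index, parsed.payload) == (3, 1, ref.payload)
        frag = next(iter(table.dictionary))
        data = DataStrand(0, 5, build_data_unit(frag, table) * 13)
        parsed2, _ = parse_data(assemble_data(data, primers))
        assert (parsed2.seg_index, parsed2.payload) == (5, data.payload)


class TestPoolRoundTrip:
    def test_worked_keyword_decodes_through_groups(self, small_setup):
        """Every pair of a keyword decodes through its own group, mirroring
        how 'CRISPR' routes through the groups of 'CR', 'IS', 'PR'."""
        table = small_setup["table"]
        matrix = build_reference_matrix(table)
        for pair in ("st", "or", "ag"):
            frag = pair_to_fragment(pair)
            g, p = table.dictionary[frag]
            assert decode_fragment(matrix.columns[g], p) == frag

    def test_full_round_trip_synthetic_corpus(self, small_setup):
        pool, corpus = small_setup["pool"], small_setup["corpus"]
        matrix = build_reference_matrix(small_setup["table"])
        decoded, report = decode_pool(pool.data_strands, matrix)
        assert decoded.files == corpus.files
        assert not report.missing_segments and not report.invalid_units

    def test_deleted_strand_loses_only_its_segment(self, small_setup):
        pool = small_setup["pool"]
        matrix = build_reference_matrix(small_setup["table"])
        clipped = {fid: list(ss) for fid, ss in pool.data_strands.items()}
        removed = clipped[0].pop(1)
        decoded, report = decode_pool(clipped, matrix)
        assert (0, removed.seg_index) in report.missing_segments
        # other files untouched
        assert decoded.files[1][1] == small_setup["corpus"].files[1][1]

    def test_no_ttt_in_any_data_payload(self, small_setup):
        for strands in small_setup["pool"].data_strands.values():
            for s in strands:
                assert "TTT" not in s.payload

    def test_round_trip_100_random_corpora(self, primer_map3):
        """Lossless encode->decode over many random corpora (with mixed
        capitalization, so multi-member groups occur)."""
        from ncgseek.synthetic import WORDS

        vocab = WORDS + [w.upper() for w in WORDS[:40]] + \
            [w.capitalize() for w in WORDS[40:80]]
        for seed in range(100):
            plan = FixturePlan(n_files=2, words_per_file=30,
                               vocabulary=vocab, seed=seed)
            corpus, _ = generate_corpus(plan)
            table = build_group_table(corpus_fragments(corpus))
            pool = encode_corpus(corpus, table, primer_map3)
            decoded, report = decode_pool(
                pool.data_strands, build_reference_matrix(table))
            assert decoded.files == corpus.files
            assert not report.missing_segments


class TestPoolStats:
    def test_density_accounting(self, small_setup):
        stats = pool_stats(small_setup["pool"], small_setup["corpus"])
        assert stats["net_density"] < stats["coding_potential"]
        assert stats["coding_potential"] < stats["coding_potential_payload_only"]
        assert stats["n_reference_strands"] == 16 * np.ceil(
            len(small_setup["table"]) / 80)
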