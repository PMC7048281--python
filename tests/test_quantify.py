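"""Exact/1-mismatch read assignment and isomiR counting."""

from collections import Counter

import numpy as np
import pytest

from isomirseq.quantify import (
    assign_read,
    build_count_matrix,
    build_index,
    quantify_library,
    rollup_canonical,
    split_key,
)
from isomirseq.reference import (
    EnumerationParams,
    IsomirVariant,
    enumerate_isomir_space,
    variants_by_id,
)

from conftest import make_reference

MATURE = "TGAGGTAGTAGGTTGTATAGTT"


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_assign(insert, variants):
    """Oracle: full scan over variants with the same stratum/tie-break rules."""
    exact = [v for v in variants if v.sequence == insert]
    if exact:
        return exact[0], 0
    near = [
        v
        for v in variants
        if len(v.sequence) == len(insert) and hamming(v.sequence, insert) == 1
    ]
    if not near:
        return None
    best = min(near, key=lambda v: (v.min_offset_magnitude(), v.variant_id))
    return best, 1


class TestMatchIndex:
    def test_every_variant_self_lookup(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        for v in single_mirna_variants:
            assert index.lookup_exact(v.sequence).variant_id == v.variant_id

    def test_query_shorter_than_all_indexed_lengths(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        assert index.lookup_exact("ACGTACGTACGT") is None
        assert index.lookup_distance1("ACGTACGTACGT") == []

    def test_distance1_lookup_matches_brute_force(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        rng = np.random.default_rng(5)
        for _ in range(200):
            v = single_mirna_variants[rng.integers(len(single_mirna_variants))]
            pos = int(rng.integers(len(v.sequence)))
            sub = "ACGT"[int(rng.integers(4))]
            query = v.sequence[:pos] + sub + v.sequence[pos + 1 :]
            got = {x.variant_id for x in index.lookup_distance1(query)}
            expected = {
                x.variant_id
                for x in single_mirna_variants
                if len(x.sequence) == len(query) and hamming(x.sequence, query) == 1
            }
            assert got == expected

    def test_duplicate_variant_sequences_rejected(self):
        dup = [
            IsomirVariant("a|+0|+0", MATURE, (("a", 0, 0),), "a"),
            IsomirVariant("b|+0|+0", MATURE, (("b", 0, 0),), "b"),
        ]
        with pytest.raises(ValueError, match="duplicate variant sequence"):
            build_index(dup)


class TestAssignRead:
    def test_canonical_insert_is_exact_stratum_zero(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        call = assign_read(MATURE, index)
        assert call.stratum == 0 and call.mismatch is None
        assert call.variant_id == "one-miR-1|+0|+0"

    def test_internal_substitution_maps_at_stratum_one_with_descriptor(
        self, single_mirna_variants
    ):
        index = build_index(single_mirna_variants)
        query = MATURE[:10] + "C" + MATURE[11:]  # ref G at position 10
        call = assign_read(query, index)
        assert call.stratum == 1
        assert (call.mismatch.position, call.mismatch.ref_base, call.mismatch.read_base) == (
            10,
            MATURE[10],
            "C",
        )
        assert call.variant_id == "one-miR-1|+0|+0"

    def test_trimmed_read_hits_trimmed_variant_not_canonical(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        call = assign_read(MATURE[:-1], index)
        assert call.stratum == 0
        assert call.variant_id == "one-miR-1|+0|-1"

    def test_exact_hit_suppresses_stratum_one(self):
        # B is at distance 1 from the query, A is exact: best-stratum wins
        a = IsomirVariant("mir-A|+0|+0", "ACGTACGTACGTACGTAC", (("mir-A", 0, 0),), "mir-A")
        b = IsomirVariant("mir-B|+0|+0", "ACGTACGTACGTACGTAG", (("mir-B", 0, 0),), "mir-B")
        call = assign_read("ACGTACGTACGTACGTAC", build_index([a, b]))
        assert (call.variant_id, call.stratum) == ("mir-A|+0|+0", 0)

    def test_tie_break_prefers_smaller_end_offsets_then_id(self):
        seq1 = "AAAACCCCGGGGTTTTAA"
        seq2 = "AAAACCCCGGGGTTTTAT"
        query = "AAAACCCCGGGGTTTTAG"  # distance 1 from both
        v1 = IsomirVariant("mir-Z|+0|+0", seq1, (("mir-Z", 0, 0),), "mir-Z")
        v2 = IsomirVariant("mir-A|-1|+0", seq2, (("mir-A", -1, 0),), "mir-A")
        call = assign_read(query, build_index([v1, v2]))
        assert call.variant_id == "mir-Z|+0|+0"  # |e5|+|e3| = 0 beats 1
        v1b = IsomirVariant("mir-Z|-1|+0", seq1, (("mir-Z", -1, 0),), "mir-Z")
        call = assign_read(query, build_index([v1b, v2]))
        assert call.variant_id == "mir-A|-1|+0"  # equal offsets: smaller id

    def test_agreement_with_brute_force_oracle_on_random_queries(
        self, single_mirna_variants
    ):
        index = build_index(single_mirna_variants)
        rng = np.random.default_rng(99)
        lengths = sorted({len(v.sequence) for v in single_mirna_variants})
        for _ in range(10_000):
            if rng.random() < 0.7:  # mutated variant
                v = single_mirna_variants[rng.integers(len(single_mirna_variants))]
                seq = list(v.sequence)
                for _ in range(int(rng.integers(0, 3))):
                    seq[int(rng.integers(len(seq)))] = "ACGT"[int(rng.integers(4))]
                query = "".join(seq)
            else:  # random sequence
                L = int(rng.choice(lengths))
                query = "".join(rng.choice(list("ACGT"), size=L))
            call = assign_read(query, index)
            oracle = brute_force_assign(query, single_mirna_variants)
            if oracle is None:
                assert call is None
            else:
                assert call is not None
                assert (call.variant_id, call.stratum) == (
                    oracle[0].variant_id,
                    oracle[1],
                )


class TestQuantifyLibrary:
    def test_exact_copies_accumulate_under_one_key(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        quant = quantify_library([(f"r{i}", MATURE) for i in range(10)], index)
        assert quant.key_counts == Counter({"one-miR-1|+0|+0": 10})
        assert quant.unmapped == 0

    def test_mismatch_reads_get_their_own_key(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        mutated = MATURE[:10] + "C" + MATURE[11:]
        inserts = [(f"e{i}", MATURE) for i in range(3)] + [
            (f"m{i}", mutated) for i in range(2)
        ]
        quant = quantify_library(inserts, index)
        assert quant.key_counts["one-miR-1|+0|+0"] == 3
        assert quant.key_counts[f"one-miR-1|+0|+0|m10{MATURE[10]}>C"] == 2

    def test_unmapped_inserts_counted_but_not_in_matrix(self, single_mirna_variants):
        index = build_index(single_mirna_variants)
        quant = quantify_library([(f"u{i}", "ACGT" * 5) for i in range(5)], index)
        assert quant.unmapped == 5 and not quant.key_counts

    def test_counts_conserve_and_ignore_input_order(self, small_bundle):
        rng = np.random.default_rng(3)
        variants = small_bundle.variants
        inserts = [
            (f"r{i}", variants[int(rng.integers(len(variants)))].sequence)
            for i in range(500)
        ] + [(f"u{i}", "".join(rng.choice(list("ACGT"), size=20))) for i in range(20)]
        quant = quantify_library(inserts, small_bundle.index)
        assert sum(quant.key_counts.values()) + quant.unmapped == len(inserts)
        shuffled = [inserts[i] for i in rng.permutation(len(inserts))]
        assert quantify_library(shuffled, small_bundle.index).key_counts == quant.key_counts


class TestRollup:
    def test_rollup_sums_keys_of_the_same_mirna(self, single_mirna_variants):
        vmap = variants_by_id(single_mirna_variants)
        counts = build_count_matrix(
            {"s1": Counter({"one-miR-1|+0|+0": 3, "one-miR-1|+0|-1": 2})}
        )
        rolled = rollup_canonical(counts, vmap)
        assert rolled.loc["one-miR-1", "s1"] == 5

    def test_rollup_with_one_key_per_mirna_is_a_rename(self, small_bundle):
        canon = [
            v
            for v in small_bundle.variants
            if any(e5 == 0 and e3 == 0 for _, e5, e3 in v.parents)
        ]
        vmap = variants_by_id(small_bundle.variants)
        counts = build_count_matrix(
            {"s1": Counter({v.variant_id: i + 1 for i, v in enumerate(canon)})}
        )
        rolled = rollup_canonical(counts, vmap)
        assert sorted(rolled["s1"]) == sorted(counts["s1"])

    def test_shared_sequence_counts_go_to_lexicographic_parent(self):
        ref = make_reference(
            [("z-miR-200c", MATURE, "AA", "TT"), ("z-miR-200b", MATURE, "GG", "CC")]
        )
        variants = enumerate_isomir_space(ref, EnumerationParams(max_trim=0, max_add=0))
        vmap = variants_by_id(variants)
        counts = build_count_matrix({"s1": Counter({variants[0].variant_id: 7})})
        rolled = rollup_canonical(counts, vmap)
        assert list(rolled.index) == ["z-miR-200b"]
        assert rolled.loc["z-miR-200b", "s1"] == 7

    def test_unknown_variant_id_is_an_error(self, single_mirna_variants):
        vmap = variants_by_id(single_mirna_variants)
        counts = build_count_matrix({"s1": Counter({"ghost|+0|+0": 1})})
        with pytest.raises(KeyError, match="ghost"):
            rollup_canonical(counts, vmap)


def test_split_key_round_trip():
    assert split_key("syn-miR-001|+0|+0") == ("syn-miR-001|+0|+0", "")
    assert split_key("syn-miR-001|-2|+1|m10G>C") == ("syn-miR-001|-2|+1", "10G>C")
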