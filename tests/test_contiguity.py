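import random

import pytest
from hypothesis import given, settings, strategies as st_strat

from simpletigs import (AlignmentRecord, eaxmax, eaxmax_bruteforce,
                        eaxmax_genome_wide, hpc_compress, hpc_coordinate_map,
                        merge_misassemblies)


def rec(start, end, ref="r", query="q"):
    return AlignmentRecord(query, ref, start, end)


class TestHpc:
    @pytest.mark.parametrize("raw,compressed", [
        ("AAATTTGGGC", "ATGC"),
        ("ACGT", "ACGT"),
        ("", ""),
        ("AAAA", "A"),
    ])
    def test_examples(self, raw, compressed):
        assert hpc_compress(raw) == compressed

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st_strat.text(alphabet="ACGT", max_size=200))
    def test_idempotent_and_non_lengthening(self, s):
        once = hpc_compress(s)
        assert hpc_compress(once) == once
        assert len(once) <= len(s)
        # no two adjacent equal characters remain
        assert all(a != b for a, b in zip(once, once[1:]))

    def test_coordinate_map_example(self):
        cmap = hpc_coordinate_map("AAATTG")
        assert cmap.compressed == "ATG"
        assert cmap.to_raw(1) == 3
        assert cmap.to_compressed(3) == 1

    def test_coordinate_map_identity_on_compressed(self):
        cmap = hpc_coordinate_map("ACGT")
        assert cmap.run_starts == (0, 1, 2, 3)

    def test_coordinate_map_empty(self):
        assert len(hpc_coordinate_map("")) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st_strat.text(alphabet="ACG", min_size=1, max_size=100))
    def test_round_trip_on_compressed_coordinates(self, s):
        cmap = hpc_coordinate_map(s)
        for ci in range(len(cmap)):
            assert cmap.to_compressed(cmap.to_raw(ci)) == ci


class TestEaxmax:
    def test_hand_worked_example(self):
        profile = eaxmax([rec(0, 8), rec(5, 10)], 10, [50, 75, 90])
        assert list(profile.per_base) == [8] * 8 + [5, 5]
        assert (profile[50], profile[75], profile[90]) == (8, 8, 5)

    def test_full_length_alignment(self):
        G = 37
        profile = eaxmax([rec(0, G)], G, [0, 25, 50, 75, 99])
        assert all(v == G for v in profile.values.values())

    def test_no_alignments(self):
        profile = eaxmax([], 10, [0, 50, 100])
        assert all(v == 0 for v in profile.values.values())

    def test_out_of_range_record_rejected(self):
        with pytest.raises(ValueError):
            eaxmax([rec(0, 11)], 10, [50])
        with pytest.raises(ValueError):
            eaxmax([], 0, [50])
        with pytest.raises(ValueError):
            AlignmentRecord("q", "r", 5, 5)

    def test_single_base_reference(self):
        assert eaxmax_bruteforce([rec(0, 1)], 1, 50) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce(self, seed):
        r = random.Random(seed)
        G = r.randint(1, 500)
        records = []
        for _ in range(r.randint(0, 20)):
            start = r.randrange(G)
            end = r.randint(start + 1, G)
            records.append(rec(start, end))
        xs = [0, 10, 50, 75, 90, 100]
        profile = eaxmax(records, G, xs)
        for x in xs:
            assert profile[x] == eaxmax_bruteforce(records, G, x)
        # monotone non-increasing in x
        values = [profile[x] for x in xs]
        assert values == sorted(values, reverse=True)

    def test_duplication_robustness(self):
        """Shorter fully-overlapped alignments never lower EAxmax."""
        r = random.Random(99)
        for _ in range(20):
            G = r.randint(10, 300)
            base = []
            for _ in range(r.randint(1, 10)):
                s = r.randrange(G)
                base.append(rec(s, r.randint(s + 1, G)))
            extra = list(base)
            for b in r.sample(base, k=min(3, len(base))):
                s = r.randint(b.start, b.end - 1)
                extra.append(rec(s, r.randint(s + 1, b.end)))
            xs = [25, 50, 75]
            before = eaxmax(base, G, xs)
            after = eaxmax(extra, G, xs)
            assert all(after[x] >= before[x] for x in xs)

    def test_index_mode_ceil(self):
        profile = eaxmax([rec(0, 8), rec(5, 10)], 10, [75], index_mode="ceil")
        assert profile[75] == 5  # ceil(7.5) = 8 -> value 5

    def test_genome_wide_concatenates_references(self):
        records = [rec(0, 10, ref="A"), rec(0, 4, ref="B")]
        profile = eaxmax_genome_wide(records, {"A": 10, "B": 10}, [50, 90])
        assert profile.G == 20
        # ranked per-base maxima: ten 10s, four 4s, six 0s
        assert profile[50] == 4
        assert profile[90] == 0

    def test_genome_wide_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            eaxmax_genome_wide([rec(0, 5, ref="Z")], {"A": 10}, [50])


class TestMergeMisassemblies:
    @pytest.mark.parametrize("positions,X,expected_clusters", [
        ([100, 2000, 5000, 5100], 3000, [(100, 2000), (5000, 5100)]),
        ([0, 2000, 4000], 3000, [(0, 2000), (4000,)]),
        ([0, 3000], 3000, [(0,), (3000,)]),
        ([], 3000, []),
        ([42], 3000, [(42,)]),
    ])
    def test_examples(self, positions, X, expected_clusters):
        got = [c.positions for c in merge_misassemblies(positions, X)]
        assert got == expected_clusters

    def test_unsorted_input_sorted_internally(self):
        got = merge_misassemblies([5000, 100, 5100, 2000], 3000)
        assert [c.positions for c in got] == [(100, 2000), (5000, 5100)]

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            merge_misassemblies([-1, 5], 3000)
        with pytest.raises(ValueError):
            merge_misassemblies([1, 2], 0)

    @pytest.mark.parametrize("seed", range(15))
    def test_cluster_invariants(self, seed):
        r = random.Random(seed)
        X = r.choice([100, 1000, 3000])
        positions = sorted(r.randrange(50_000) for _ in range(r.randint(0, 60)))
        clusters = merge_misassemblies(positions, X)
        assert sum(len(c.positions) for c in clusters) == len(positions)
        for c in clusters:
            assert c.span < X
            assert all(b - a < X for a, b in zip(c.positions, c.positions[1:]))
        for prev, nxt in zip(clusters, clusters[1:]):
            gap_break = nxt.positions[0] - prev.positions[-1] >= X
            span_break = nxt.positions[0] - prev.positions[0] >= X
            assert gap_break or span_break
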