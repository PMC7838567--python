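"""Key-set algebra across classes, feature statistics, tolerant motif search."""

from itertools import product

import numpy as np
import pytest

from tsrkeys import (
    MotifQuery,
    build_keyset_report,
    common_keys_every_protein,
    encode_key,
    key_feature_stats,
    match_motif,
    mirror_pair_analysis,
)
from tsrkeys.keygen import KeyVector


def kv(pid, keys_or_counts):
    counts = (
        dict(keys_or_counts)
        if isinstance(keys_or_counts, dict)
        else {k: 1 for k in keys_or_counts}
    )
    return KeyVector(pid, counts, sum(counts.values()))


class TestKeySetReport:
    def test_two_singleton_classes(self):
        rep = build_keyset_report(
            [kv("p1", [1, 2, 3]), kv("p2", [3, 4])], {"p1": "A", "p2": "B"}
        )
        assert rep.common_all_classes == {3}
        assert rep.specific["A"] == {1, 2}
        assert rep.specific["B"] == {4}
        assert rep.venn_count("A") == 2
        assert rep.venn_count("B") == 1
        assert rep.venn_count("A", "B") == 1

    def test_single_class_degenerate(self):
        rep = build_keyset_report([kv("p1", [1, 2]), kv("p2", [2, 5])], {"p1": "A", "p2": "A"})
        assert rep.specific["A"] == rep.distinct_keys["A"] == {1, 2, 5}
        assert rep.common_all_classes == {1, 2, 5}
        assert rep.common_every_protein["A"] == {2}

    def test_venn_regions_match_set_oracle(self, rng):
        vectors, class_map = [], {}
        for c in "ABC":
            for i in range(4):
                pid = f"{c}{i}"
                vectors.append(kv(pid, set(rng.integers(0, 120, 40).tolist())))
                class_map[pid] = c
        rep = build_keyset_report(vectors, class_map)
        union = {c: set().union(*(v.key_set() for v in vectors
                                  if class_map[v.protein_id] == c)) for c in "ABC"}
        # oracle: classify every key by its exact membership pattern
        for region, count in rep.venn_counts.items():
            members = [k for k in set().union(*union.values())
                       if {c for c in "ABC" if k in union[c]} == set(region)]
            assert count == len(members)
        assert sum(rep.venn_counts.values()) == len(set().union(*union.values()))
        # specific sets pairwise disjoint and disjoint from the common core
        for c in "ABC":
            assert not rep.specific[c] & rep.common_all_classes
            for o in "ABC":
                if o != c:
                    assert not rep.specific[c] & rep.distinct_keys[o]

    def test_unassigned_protein_rejected(self):
        with pytest.raises(KeyError):
            build_keyset_report([kv("p1", [1])], {})


class TestCommonKeysEveryProtein:
    def test_identical_vectors_full_coverage(self):
        vs = [kv(f"p{i}", {1: 2, 7: 3}) for i in range(4)]
        common, cov_d, cov_f = common_keys_every_protein(vs)
        assert common == {1, 7}
        assert all(v == 1.0 for v in cov_d.values())
        assert all(v == 1.0 for v in cov_f.values())

    def test_disjoint_member_empties_the_core(self):
        vs = [kv("p1", [1, 2]), kv("p2", [3, 4])]
        assert common_keys_every_protein(vs)[0] == frozenset()

    def test_planted_core_recovered_exactly(self, rng):
        core = set(range(1000, 1010))
        vs = []
        for i in range(5):
            noise = set(rng.integers(0, 900, 50).tolist())
            vs.append(kv(f"p{i}", core | noise))
        common, _, _ = common_keys_every_protein(vs)
        extra = set.intersection(*(set(v.key_set()) for v in vs)) - core
        assert common == core | extra  # exactly the intersection
        assert core <= common


class TestKeyFeatureStats:
    def test_single_key_uses_bin_midpoints(self, scheme):
        k = encode_key(5, 4, 4, 2, 5, scheme)
        st = key_feature_stats([k], scheme)
        assert st.mean_theta == pytest.approx(scheme.bin_midpoints("theta")[4])
        assert st.mean_maxdist == pytest.approx(scheme.bin_midpoints("maxdist")[1])
        assert st.n_keys == 1

    def test_partition_weighted_mean_identity(self, scheme, rng):
        keys = [int(k) for k in rng.integers(0, scheme.n_codes, 30)]
        all_st = key_feature_stats(keys, scheme)
        half = len(set(keys)) // 2
        uniq = sorted(set(keys))
        s1 = key_feature_stats(uniq[:half], scheme)
        s2 = key_feature_stats(uniq[half:], scheme)
        combined = (s1.mean_theta * s1.n_keys + s2.mean_theta * s2.n_keys) / (
            s1.n_keys + s2.n_keys
        )
        assert all_st.mean_theta == pytest.approx(combined)

    def test_constructed_ordering_respected(self, scheme):
        hi = [encode_key(4, 4, 4, 1, scheme.theta_T, scheme)]
        lo = [encode_key(4, 4, 4, 1, 1, scheme)]
        assert (
            key_feature_stats(hi, scheme).mean_theta
            > key_feature_stats(lo, scheme).mean_theta
        )

    def test_raw_triangle_records_mode(self, scheme):
        from tsrkeys.keygen import triangle_table
        from tsrkeys.fixtures import make_coil

        s = make_coil(8, seed=3)
        tt = triangle_table(s, scheme)
        k = int(tt["key"].iloc[0])
        st = key_feature_stats([k], scheme, triangle_records=tt)
        sub = tt[tt["key"] == k]
        assert st.mean_theta == pytest.approx(sub["theta"].mean())
        assert st.mean_maxdist == pytest.approx(sub["maxdist"].mean())


class TestMatchMotif:
    def test_adjacent_theta_bin_matches(self, scheme):
        v = kv("p", [1_683_886])  # theta_bin 2
        hits, ok = match_motif(v, MotifQuery(frozenset([1_683_885]), 1), scheme)
        assert ok and hits[1_683_885]

    def test_tolerance_exceeded(self, scheme):
        q = encode_key(4, 4, 4, 1, 1, scheme)
        stored = encode_key(4, 4, 4, 1, 3, scheme)
        hits, ok = match_motif(kv("p", [stored]), MotifQuery(frozenset([q]), 1), scheme)
        assert not ok

    def test_zero_tolerance_is_exact_membership(self, scheme, rng):
        keys = [int(k) for k in rng.integers(0, scheme.n_codes, 20)]
        v = kv("p", keys)
        for q in keys[:5] + [int(k) for k in rng.integers(0, scheme.n_codes, 5)]:
            hits, _ = match_motif(v, MotifQuery(frozenset([q]), 0), scheme)
            assert hits[q] == (q in v.counts)

    def test_sign_must_match(self, scheme):
        v = kv("p", [-1_683_885])
        hits, _ = match_motif(v, MotifQuery(frozenset([1_683_885]), 1), scheme)
        assert not hits[1_683_885]

    def test_raw_mode_agrees_except_at_theta_digit_wrap(self, small_scheme):
        """Exhaustive digit-space comparison of raw ±1 and decoded ±1 matching."""
        tT, dT = small_scheme.theta_T, small_scheme.d_T
        disagreements = []
        for l1, dq, tb_q, dv, tb_v in product(
            (1, 3), range(1, dT + 1), range(1, tT + 1), range(1, dT + 1), range(1, tT + 1)
        ):
            q = encode_key(l1, 1, 1, dq, tb_q, small_scheme)
            v = kv("p", [encode_key(l1, 1, 1, dv, tb_v, small_scheme)])
            mq = MotifQuery(frozenset([q]), 1)
            dec = match_motif(v, mq, small_scheme)[0][q]
            raw = match_motif(v, mq, small_scheme, mode="raw")[0][q]
            if dec != raw:
                disagreements.append((tb_q, tb_v))
            if tb_q not in (1, tT) and tb_v not in (1, tT):
                assert dec == raw
        # literal key±1 crosses into a neighbouring MaxDist bin exactly at
        # the theta-digit wrap; the decoded rule does not
        assert disagreements
        assert all(a in (1, tT) or b in (1, tT) for a, b in disagreements)


class TestMirrorPairAnalysis:
    def test_sign_partition_flagged(self):
        vs = [kv("a1", [100]), kv("a2", [100]), kv("b1", [-100]), kv("b2", [-100])]
        cm = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = mirror_pair_analysis(vs, cm)
        assert out[100]["separates"]
        assert out[100]["positive_classes"] == ["A"]
        assert out[100]["negative_classes"] == ["B"]

    def test_mixed_signs_in_one_class_not_flagged(self):
        vs = [kv("a1", [100, -100]), kv("b1", [-100])]
        out = mirror_pair_analysis(vs, {"a1": "A", "b1": "B"})
        assert not out[100]["separates"]

    def test_unsigned_vectors_rejected(self):
        with pytest.raises(ValueError, match="mirror"):
            mirror_pair_analysis([kv("a", [1]), kv("b", [2])], {"a": "A", "b": "B"})
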