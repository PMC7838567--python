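"""Vertex ordering, triangle geometry, key encoding and whole-structure keys."""

import math
from itertools import product

import numpy as np
import pytest

from tsrkeys import (
    BinScheme,
    decode_key,
    encode_key,
    keys_of_structure,
    order_vertices,
    triangle_geometry,
)
from tsrkeys.keygen import decode_keys, describe_triangle, encode_keys, merge_key_vector
from tsrkeys.fixtures import make_coil, make_helix, perturb, rearrange, reflect, rigid_move


class TestOrderVertices:
    def test_distinct_labels_sorted_descending(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float)
        order = order_vertices([7, 19, 12], coords, [0, 1, 2])
        labels = [[7, 19, 12][v] for v in order]
        assert labels == [19, 12, 7]

    def test_tied_pair_ranked_by_distance_to_remaining_vertex(self):
        # A and B share a label; dist(A, C)=6 > dist(B, C)=4 so A is first
        coords = np.array([[0, 0, 0], [10, 0, 0], [6, 0, 0]], dtype=float)
        coords[1] = [10.0, 0.0, 0.0]
        a, b, c = [0, 0, 0], [10, 0, 0], [6, 0, 0]
        order = order_vertices([12, 12, 7], np.array([a, b, c], dtype=float), [0, 1, 2])
        assert order == (0, 1, 2)
        # swap the geometry: now B is farther from C
        order = order_vertices([12, 12, 7], np.array([b, a, c], dtype=float), [0, 1, 2])
        assert order == (1, 0, 2)

    def test_all_equal_labels_equilateral_falls_back_to_seq_index(self):
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]], dtype=float
        )
        assert order_vertices([9, 9, 9], coords, [5, 2, 8]) == (1, 0, 2)

    def test_frame_independence(self, rng):
        coords = rng.uniform(-5, 5, size=(3, 3))
        labels = [4, 4, 17]
        ref = order_vertices(labels, coords, [0, 1, 2])
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(rng=rng).as_matrix()
        assert order_vertices(labels, coords @ rot.T + 3.0, [0, 1, 2]) == ref


class TestTriangleGeometry:
    def test_right_angle_at_midpoint(self):
        c = np.array([[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]], dtype=float)
        d12, d13, d23, d3, maxdist, theta1, theta = triangle_geometry(c)
        assert (d12, maxdist) == (2.0, 2.0)
        assert theta1 == pytest.approx(90.0, abs=1e-9)
        assert theta == pytest.approx(90.0, abs=1e-9)

    def test_obtuse_angle_folds(self):
        c = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0]], dtype=float)
        *_, maxdist, theta1, theta = triangle_geometry(c)
        assert theta1 == pytest.approx(135.0, abs=1e-9)
        assert theta == pytest.approx(45.0, abs=1e-9)
        assert maxdist == pytest.approx(math.sqrt(5.0))  # longest edge is l2-l3

    def test_agrees_with_vector_angle_oracle(self, rng):
        for _ in range(500):
            c = rng.uniform(-10, 10, size=(3, 3))
            try:
                *_, theta1, theta = triangle_geometry(c)
            except ValueError:
                continue
            mid = (c[0] + c[1]) / 2
            u, v = c[2] - mid, c[1] - mid
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            oracle = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            assert theta1 == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_rejected(self):
        collinear = np.array([[0, 0, 0], [2, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            triangle_geometry(collinear)


class TestEncodeDecode:
    def test_printed_formula_value(self, scheme):
        # theta_T=29, d_T=35, m=23: (4,4,4,1,1) -> 1015 * 3 * (529+23+1)
        assert encode_key(4, 4, 4, 1, 1, scheme) == 1_683_885

    def test_lowest_digit_increments_key_by_one(self, scheme):
        assert encode_key(4, 4, 4, 1, 2, scheme) == 1_683_886

    def test_zero_case(self, scheme):
        assert encode_key(1, 1, 1, 1, 1, scheme) == 0
        assert decode_key(0, scheme) == (1, 1, 1, 1, 1)

    def test_decode_inverts_printed_value(self, scheme):
        assert decode_key(1_683_885, scheme) == (4, 4, 4, 1, 1)

    def test_out_of_range_digits(self, scheme):
        with pytest.raises(ValueError):
            encode_key(0, 1, 1, 1, 1, scheme)
        with pytest.raises(ValueError):
            encode_key(1, 1, 1, 99, 1, scheme)
        with pytest.raises(ValueError):
            decode_key(scheme.n_codes, scheme)

    def test_round_trip_exhaustive_on_small_scheme(self, small_scheme):
        digits = list(
            product(
                range(1, small_scheme.m + 1),
                range(1, small_scheme.m + 1),
                range(1, small_scheme.m + 1),
                range(1, small_scheme.d_T + 1),
                range(1, small_scheme.theta_T + 1),
            )
        )
        keys = {encode_key(*d, small_scheme) for d in digits}
        assert len(keys) == small_scheme.n_codes  # one-to-one
        assert keys == set(range(small_scheme.n_codes))  # onto
        for d in digits[:: 37]:
            assert decode_key(encode_key(*d, small_scheme), small_scheme) == d

    def test_vectorized_matches_scalar(self, scheme, rng):
        ks = rng.integers(0, scheme.n_codes, size=200)
        l1, l2, l3, db, tb = decode_keys(ks, scheme)
        for i, k in enumerate(ks):
            assert decode_key(int(k), scheme) == (l1[i], l2[i], l3[i], db[i], tb[i])
        assert np.array_equal(encode_keys(l1, l2, l3, db, tb, scheme), ks)


class TestKeysOfStructure:
    def test_triangle_count_is_n_choose_3(self, scheme):
        s = make_coil(5, seed=3)
        kv = keys_of_structure(s, scheme)
        assert kv.total_triangles == 10
        assert sum(kv.counts.values()) == 10
        assert kv.skipped_degenerate == 0

    def test_collinear_triple_skipped(self, scheme, label_table):
        from tsrkeys.structure_io import CaStructure, Residue

        coords = [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (2.0, 0.0, 0.0)]
        rs = [
            Residue(i, (i + 1, ""), "ALA", label_table.label_of("ALA"), c)
            for i, c in enumerate(coords)
        ]
        kv = keys_of_structure(CaStructure("line", rs), scheme)
        assert kv.counts == {}
        assert kv.skipped_degenerate == 1

    def test_rigid_motion_invariance(self, scheme):
        s = make_coil(15, seed=11)
        assert keys_of_structure(s, scheme).counts == \
            keys_of_structure(rigid_move(s, seed=12), scheme).counts

    def test_rearrangement_invariance(self, scheme):
        s = make_coil(15, seed=13)
        assert keys_of_structure(s, scheme).counts == \
            keys_of_structure(rearrange(s, 6), scheme).counts

    def test_scale_sensitivity_hits_maxdist_not_theta(self, scheme):
        """Doubling coordinates changes MaxDist bins but no Theta value."""
        from tsrkeys.keygen import triangle_table

        s = make_coil(10, seed=17)
        t1 = triangle_table(s, scheme)
        t2 = triangle_table(s.with_coords(s.coords * 2.0), scheme)
        assert np.allclose(t1["theta"], t2["theta"], atol=1e-9)
        assert np.allclose(t2["maxdist"], 2 * t1["maxdist"], atol=1e-9)
        assert (t1["d_bin"] != t2["d_bin"]).any()

    def test_mirror_sign_follows_unfolded_angle(self, scheme):
        from tsrkeys.keygen import triangle_table

        s = make_coil(12, seed=19)
        tt = triangle_table(s, scheme, mirror=True)
        obtuse = tt["theta1"] > 90.0
        assert (tt.loc[obtuse, "key"] < 0).all()
        assert (tt.loc[~obtuse, "key"] >= 0).all()

    def test_mirror_right_angle_is_positive(self, scheme):
        c = np.array([[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]], dtype=float)
        d = describe_triangle([4, 11, 19], c, [0, 1, 2], scheme, mirror=True)
        assert d.theta1 == pytest.approx(90.0, abs=1e-9)
        assert d.key > 0

    def test_too_few_residues(self, scheme, label_table):
        from tsrkeys.structure_io import CaStructure, Residue

        rs = [
            Residue(0, (1, ""), "ALA", label_table.label_of("ALA"), (0.0, 0.0, 0.0)),
            Residue(1, (2, ""), "GLY", label_table.label_of("GLY"), (3.8, 0.0, 0.0)),
        ]
        with pytest.raises(ValueError, match="at least 3"):
            keys_of_structure(CaStructure("tiny", rs), scheme)


class TestMergeKeyVector:
    def test_identity_merge_is_noop(self, scheme):
        kv = keys_of_structure(make_coil(10, seed=23), scheme)
        assert merge_key_vector(kv, scheme).counts == kv.counts

    def test_grouping_never_increases_distinct_count(self, scheme):
        from tsrkeys.feature_select import default_grouping

        kv = keys_of_structure(make_coil(14, seed=29), scheme)
        merged = merge_key_vector(kv, scheme, label_map=default_grouping())
        assert merged.n_distinct <= kv.n_distinct
        assert merged.total_triangles == kv.total_triangles

    def test_non_nested_coarsening_rejected(self, scheme):
        kv = keys_of_structure(make_coil(6, seed=31), scheme)
        bad = BinScheme(theta_boundaries=(33.333,), maxdist_boundaries=(), m=scheme.m)
        with pytest.raises(ValueError, match="nested"):
            merge_key_vector(kv, scheme, out_scheme=bad)
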