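"""Triangle enumeration and integer key encoding.

Every unordered triple of Cα atoms is reduced to five digits — three
amino-acid labels in a canonical order, a MaxDist bin and a Theta bin —
and packed into one integer by a positional number system:

    key = theta_T * d_T * ((l1-1)*m**2 + (l2-1)*m + (l3-1))
        + theta_T * (d_bin - 1) + (theta_bin - 1)

The encoding is bijective on its digit space, so a key decodes uniquely
back to its digits.  Geometry digits come from the triangle's longest
edge (MaxDist, the scale factor) and from the angle at the midpoint of
the l1–l2 edge, folded to at most 90° (Theta).  In mirror mode the fold
is made chirality-aware: a triangle whose unfolded angle exceeds 90°
gets a negative key, its reflection a positive one.

Canonical vertex ordering (``order_vertices``) depends only on labels
and pairwise distances — never on the coordinate frame or on residue
record order — which is what makes keys invariant under rigid motion
and insensitive to chain rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discretize import BinScheme, assign_bin
from .structure_io import CaStructure

__all__ = [
    "TriangleDescriptor",
    "KeyVector",
    "order_vertices",
    "triangle_geometry",
    "encode_key",
    "decode_key",
    "keys_of_structure",
    "triangle_table",
]

#: edges/heights shorter than this (Å) make a triangle degenerate
DEGENERACY_EPS = 1e-9


@dataclass(frozen=True)
class TriangleDescriptor:
    """One triangle after canonical ordering, with geometry, bins and key."""

    vertex_indices: tuple[int, int, int]  # seq_indices at pos0/pos1/pos2
    labels: tuple[int, int, int]  # (l1, l2, l3)
    d12: float
    d13: float
    d23: float
    d3: float
    maxdist: float
    theta1: float
    theta: float
    d_bin: int
    theta_bin: int
    key: int


@dataclass
class KeyVector:
    """Multiset of keys representing one protein chain."""

    protein_id: str
    counts: dict[int, int]
    total_triangles: int  # sum of counts (kept, non-degenerate triangles)
    skipped_degenerate: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("key counts must be positive")
        if sum(self.counts.values()) != self.total_triangles:
            raise ValueError("total_triangles must equal the sum of counts")

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def key_set(self) -> frozenset[int]:
        return frozenset(self.counts)


# ---------------------------------------------------------------------------
# canonical vertex ordering


def order_vertices(
    labels: Sequence[int],
    coords: np.ndarray,
    seq_indices: Sequence[int],
) -> tuple[int, int, int]:
    """Return the permutation placing the three vertices at pos0/pos1/pos2.

    Ranking rules, applied in order:

    1. larger label first (distinct labels fully decide the order);
    2. a vertex tied by label with exactly one other is ranked by its
       distance to the remaining vertex, greater distance first;
    3. with all three labels equal, by the vertex's longest incident
       edge, then by its other incident edge, both descending;
    4. any residual tie by ascending ``seq_index``.

    The result depends only on labels and pairwise distances (plus
    sequence index for exact geometric ties), never on the frame.  A
    residual geometric tie implies an isosceles symmetry under which the
    competing orderings produce the same key digits, so the seq_index
    fallback never leaks record order into keys.
    """
    coords = np.asarray(coords, dtype=float)
    lab = np.asarray(labels, dtype=np.int64)
    seq = np.asarray(seq_indices, dtype=np.int64)
    d = np.array(
        [
            [0.0, _dist(coords[0], coords[1]), _dist(coords[0], coords[2])],
            [0.0, 0.0, _dist(coords[1], coords[2])],
            [0.0, 0.0, 0.0],
        ]
    )
    d = d + d.T
    if min(d[0, 1], d[0, 2], d[1, 2]) < DEGENERACY_EPS:
        raise ValueError("degenerate triangle: coincident vertices")

    t1 = np.zeros(3)
    t2 = np.zeros(3)
    for v in range(3):
        u, w = [x for x in range(3) if x != v]
        if lab[v] == lab[u] and lab[v] == lab[w]:
            t1[v] = max(d[v, u], d[v, w])
            t2[v] = min(d[v, u], d[v, w])
        elif lab[v] == lab[u]:
            t1[v] = d[v, w]
        elif lab[v] == lab[w]:
            t1[v] = d[v, u]
    order = sorted(range(3), key=lambda v: (-lab[v], -t1[v], -t2[v], seq[v]))
    return tuple(order)


def _dist(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


# ---------------------------------------------------------------------------
# geometry


def triangle_geometry(ordered_coords: np.ndarray):
    """Geometry digits for vertices already in (l1, l2, l3) order.

    Returns ``(d12, d13, d23, d3, maxdist, theta1, theta)`` where
    ``theta1`` is the angle (degrees) subtended at the midpoint of the
    l1–l2 edge between that edge and the segment to the l3 vertex, via
    the law of cosines with the arccos argument clamped to [-1, 1], and
    ``theta`` is its fold to at most 90°.
    """
    c = np.asarray(ordered_coords, dtype=float)
    d12 = _dist(c[0], c[1])
    d13 = _dist(c[0], c[2])
    d23 = _dist(c[1], c[2])
    mid = (c[0] + c[1]) / 2
    d3 = _dist(c[2], mid)
    if d12 < DEGENERACY_EPS or d3 < DEGENERACY_EPS:
        raise ValueError("degenerate triangle: zero base edge or zero midpoint height")
    arg = (d13**2 - (d12 / 2) ** 2 - d3**2) / (2 * (d12 / 2) * d3)
    theta1 = float(np.degrees(np.arccos(np.clip(arg, -1.0, 1.0))))
    theta = theta1 if theta1 <= 90.0 else 180.0 - theta1
    maxdist = max(d12, d13, d23)
    return d12, d13, d23, d3, maxdist, theta1, theta


# ---------------------------------------------------------------------------
# integer encoding


def encode_key(l1: int, l2: int, l3: int, d_bin: int, theta_bin: int, scheme: BinScheme) -> int:
    """Pack the five digits into one non-negative integer (exact arithmetic)."""
    m, tT, dT = scheme.m, scheme.theta_T, scheme.d_T
    for lab in (l1, l2, l3):
        if not 1 <= lab <= m:
            raise ValueError(f"label {lab} outside 1..{m}")
    if not 1 <= d_bin <= dT:
        raise ValueError(f"d_bin {d_bin} outside 1..{dT}")
    if not 1 <= theta_bin <= tT:
        raise ValueError(f"theta_bin {theta_bin} outside 1..{tT}")
    return (
        tT * dT * ((l1 - 1) * m * m + (l2 - 1) * m + (l3 - 1))
        + tT * (d_bin - 1)
        + (theta_bin - 1)
    )


def encode_keys(
    l1: np.ndarray, l2: np.ndarray, l3: np.ndarray,
    d_bin: np.ndarray, theta_bin: np.ndarray, scheme: BinScheme,
) -> np.ndarray:
    """Vectorized :func:`encode_key` over integer digit arrays."""
    m, tT, dT = scheme.m, scheme.theta_T, scheme.d_T
    l1 = np.asarray(l1, dtype=np.int64)
    l2 = np.asarray(l2, dtype=np.int64)
    l3 = np.asarray(l3, dtype=np.int64)
    d_bin = np.asarray(d_bin, dtype=np.int64)
    theta_bin = np.asarray(theta_bin, dtype=np.int64)
    for arr, hi in ((l1, m), (l2, m), (l3, m), (d_bin, dT), (theta_bin, tT)):
        if arr.size and (arr.min() < 1 or arr.max() > hi):
            raise ValueError("digit out of range")
    return (
        tT * dT * ((l1 - 1) * m * m + (l2 - 1) * m + (l3 - 1))
        + tT * (d_bin - 1)
        + (theta_bin - 1)
    )


def decode_keys(keys: np.ndarray, scheme: BinScheme) -> tuple[np.ndarray, ...]:
    """Vectorized :func:`decode_key`; returns (l1, l2, l3, d_bin, theta_bin)."""
    k = np.asarray(keys, dtype=np.int64)
    if k.size and (k.min() < 0 or k.max() >= scheme.n_codes):
        raise ValueError("key outside the encodable range")
    m, tT, dT = scheme.m, scheme.theta_T, scheme.d_T
    theta_bin = k % tT + 1
    q = k // tT
    d_bin = q % dT + 1
    q //= dT
    l3 = q % m + 1
    q //= m
    l2 = q % m + 1
    l1 = q // m + 1
    return l1, l2, l3, d_bin, theta_bin


def decode_key(k: int, scheme: BinScheme) -> tuple[int, int, int, int, int]:
    """Invert :func:`encode_key` by successive modulo/quotient."""
    if k < 0 or k >= scheme.n_codes:
        raise ValueError(f"key {k} outside the encodable range [0, {scheme.n_codes})")
    m, tT, dT = scheme.m, scheme.theta_T, scheme.d_T
    theta_bin = k % tT + 1
    q = k // tT
    d_bin = q % dT + 1
    q //= dT
    l3 = q % m + 1
    q //= m
    l2 = q % m + 1
    l1 = q // m + 1
    return l1, l2, l3, d_bin, theta_bin


# ---------------------------------------------------------------------------
# whole-structure enumeration (vectorized)


def _triangle_digits(
    s: CaStructure,
    scheme: BinScheme,
    grouping: Mapping[int, int] | None = None,
    triple_mask: np.ndarray | None = None,
):
    """Digits, geometry and degeneracy mask for every enumerated triple.

    Internal workhorse shared by :func:`keys_of_structure` and
    :func:`triangle_table`.  Returns a dict of per-triangle arrays over
    the kept (non-degenerate) triples plus the degenerate count.
    """
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 residues to form a triangle")
    coords = s.coords
    labels = s.labels
    if grouping:
        lut = np.arange(labels.max() + 1, dtype=np.int64)
        for src, dst in grouping.items():
            if src < lut.size:
                lut[src] = dst
        labels = lut[labels]
    if labels.max() > scheme.m:
        raise ValueError(f"label {labels.max()} exceeds scheme alphabet m={scheme.m}")

    triples = np.fromiter(
        (i for tri in combinations(range(n), 3) for i in tri), dtype=np.int64
    ).reshape(-1, 3)
    if triple_mask is not None:
        triples = triples[triple_mask]
    if triples.shape[0] == 0:
        empty = np.array([], dtype=np.int64)
        return {
            "triples": triples, "lab": np.empty((0, 3), dtype=np.int64),
            "d12": empty.astype(float), "d13": empty.astype(float),
            "d23": empty.astype(float), "d3": empty.astype(float),
            "maxdist": empty.astype(float), "theta1": empty.astype(float),
            "theta": empty.astype(float), "d_bin": empty, "theta_bin": empty,
            "negative": np.array([], dtype=bool),
        }, 0

    p = coords[triples]  # (T, 3, 3)
    lab = labels[triples]  # (T, 3)
    seq = triples.copy()

    dAB = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    dAC = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    dBC = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    # distance from vertex row v to the other two, per slot
    d_off = np.stack([
        np.stack([dAB, dAC], axis=1),  # slot 0 -> (to 1, to 2)
        np.stack([dAB, dBC], axis=1),  # slot 1 -> (to 0, to 2)
        np.stack([dAC, dBC], axis=1),  # slot 2 -> (to 0, to 1)
    ], axis=1)  # (T, 3, 2)
    others = np.array([[1, 2], [0, 2], [0, 1]])

    # per-vertex tie-break values, matching order_vertices
    t1 = np.zeros_like(d_off[:, :, 0])
    t2 = np.zeros_like(t1)
    for v in range(3):
        u, w = others[v]
        eq_u = lab[:, v] == lab[:, u]
        eq_w = lab[:, v] == lab[:, w]
        all_eq = eq_u & eq_w
        d_vu, d_vw = d_off[:, v, 0], d_off[:, v, 1]
        t1[:, v] = np.where(
            all_eq,
            np.maximum(d_vu, d_vw),
            np.where(eq_u, d_vw, np.where(eq_w, d_vu, 0.0)),
        )
        t2[:, v] = np.where(all_eq, np.minimum(d_vu, d_vw), 0.0)

    # sort the three slots by (-label, -t1, -t2, seq) with a 3-element network
    slot = np.tile(np.arange(3), (triples.shape[0], 1))

    def take(arr, idx):
        return np.take_along_axis(arr, idx[:, None], 1)[:, 0]

    def before(a, b):
        la, lb = take(lab, a), take(lab, b)
        t1a, t1b = take(t1, a), take(t1, b)
        t2a, t2b = take(t2, a), take(t2, b)
        sa, sb = take(seq, a), take(seq, b)
        return (la > lb) | (
            (la == lb)
            & (
                (t1a > t1b)
                | ((t1a == t1b) & ((t2a > t2b) | ((t2a == t2b) & (sa < sb))))
            )
        )

    for i, j in ((0, 1), (1, 2), (0, 1)):
        swap = ~before(slot[:, i], slot[:, j])
        si, sj = slot[:, i].copy(), slot[:, j].copy()
        slot[:, i] = np.where(swap, sj, si)
        slot[:, j] = np.where(swap, si, sj)

    ordered = np.take_along_axis(triples, slot, axis=1)
    olab = np.take_along_axis(lab, slot, axis=1)
    oc = coords[ordered]  # (T, 3, 3) in (l1, l2, l3) slot order

    d12 = np.linalg.norm(oc[:, 0] - oc[:, 1], axis=1)
    d13 = np.linalg.norm(oc[:, 0] - oc[:, 2], axis=1)
    d23 = np.linalg.norm(oc[:, 1] - oc[:, 2], axis=1)
    mid = (oc[:, 0] + oc[:, 1]) / 2
    d3 = np.linalg.norm(oc[:, 2] - mid, axis=1)

    degenerate = (
        (d12 < DEGENERACY_EPS)
        | (d13 < DEGENERACY_EPS)
        | (d23 < DEGENERACY_EPS)
        | (d3 < DEGENERACY_EPS)
    )
    keep = ~degenerate
    n_skipped = int(degenerate.sum())

    d12, d13, d23, d3 = d12[keep], d13[keep], d23[keep], d3[keep]
    ordered, olab = ordered[keep], olab[keep]

    with np.errstate(invalid="ignore"):
        arg = (d13**2 - (d12 / 2) ** 2 - d3**2) / (2 * (d12 / 2) * d3)
    arg = np.clip(arg, -1.0, 1.0)
    theta1 = np.degrees(np.arccos(arg))
    theta = np.where(theta1 <= 90.0, theta1, 180.0 - theta1)
    maxdist = np.maximum(np.maximum(d12, d13), d23)

    d_bin = assign_bin(maxdist, scheme.maxdist_boundaries)
    theta_bin = assign_bin(theta, scheme.theta_boundaries)
    # theta1 > 90°; a tolerance keeps exact right angles (arg == 0 up to
    # rounding) on the positive branch
    negative = arg < -1e-12

    return {
        "triples": ordered, "lab": olab,
        "d12": d12, "d13": d13, "d23": d23, "d3": d3,
        "maxdist": maxdist, "theta1": theta1, "theta": theta,
        "d_bin": d_bin, "theta_bin": theta_bin, "negative": negative,
    }, n_skipped


def _pack_keys(lab: np.ndarray, d_bin: np.ndarray, theta_bin: np.ndarray,
               negative: np.ndarray, scheme: BinScheme, mirror: bool) -> np.ndarray:
    m, tT, dT = scheme.m, scheme.theta_T, scheme.d_T
    keys = (
        tT * dT * ((lab[:, 0] - 1) * m * m + (lab[:, 1] - 1) * m + (lab[:, 2] - 1))
        + tT * (d_bin - 1)
        + (theta_bin - 1)
    ).astype(np.int64)
    if mirror:
        keys = np.where(negative, -keys, keys)
    return keys


def keys_of_structure(
    s: CaStructure,
    scheme: BinScheme,
    mirror: bool = False,
    grouping: Mapping[int, int] | None = None,
    triple_mask: np.ndarray | None = None,
) -> KeyVector:
    """Key multiset over all C(n, 3) Cα triples of a structure.

    With ``mirror`` on, keys of triangles whose unfolded angle exceeds
    90° are negated, so a structure and its mirror image no longer share
    chirality-sensitive keys.  ``grouping`` (label → group label) is
    applied before vertex ordering.  ``triple_mask`` restricts the
    enumeration to a boolean subset of the lexicographic triples —
    secondary-structure feature selection plugs in here.
    """
    arrs, n_skipped = _triangle_digits(s, scheme, grouping, triple_mask)
    keys = _pack_keys(arrs["lab"], arrs["d_bin"], arrs["theta_bin"],
                      arrs["negative"], scheme, mirror)
    uniq, counts = np.unique(keys, return_counts=True)
    return KeyVector(
        protein_id=s.id,
        counts={int(k): int(c) for k, c in zip(uniq, counts)},
        total_triangles=int(counts.sum()),
        skipped_degenerate=n_skipped,
    )


def triangle_table(
    s: CaStructure,
    scheme: BinScheme,
    mirror: bool = False,
    grouping: Mapping[int, int] | None = None,
    triple_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-triangle records: key, digits, vertex positions and raw geometry.

    The verbose companion of :func:`keys_of_structure`; one row per kept
    triangle with columns ``key, l1, l2, l3, d_bin, theta_bin, pos0,
    pos1, pos2, theta1, theta, maxdist``.
    """
    arrs, _ = _triangle_digits(s, scheme, grouping, triple_mask)
    keys = _pack_keys(arrs["lab"], arrs["d_bin"], arrs["theta_bin"],
                      arrs["negative"], scheme, mirror)
    return pd.DataFrame(
        {
            "key": keys,
            "l1": arrs["lab"][:, 0],
            "l2": arrs["lab"][:, 1],
            "l3": arrs["lab"][:, 2],
            "d_bin": arrs["d_bin"],
            "theta_bin": arrs["theta_bin"],
            "pos0": arrs["triples"][:, 0],
            "pos1": arrs["triples"][:, 1],
            "pos2": arrs["triples"][:, 2],
            "theta1": arrs["theta1"],
            "theta": arrs["theta"],
            "maxdist": arrs["maxdist"],
        }
    )


def merge_key_vector(
    kv: KeyVector,
    scheme: BinScheme,
    label_map: Mapping[int, int] | None = None,
    out_scheme: BinScheme | None = None,
) -> KeyVector:
    """Coarsen a key multiset by label grouping and/or nested bin coarsening.

    Each key is decoded, its labels mapped through ``label_map`` and
    re-sorted into canonical (descending) positions, and its bin digits
    re-assigned under ``out_scheme`` — whose boundaries must be a subset
    of ``scheme``'s, so every fine bin maps into exactly one coarse bin.
    Counts of keys that collapse together are summed.  Because this is a
    surjection on key space, generalized Jaccard between two vectors can
    only grow (or stay) under the same merge.
    """
    out = out_scheme or scheme
    for fine, coarse, name in (
        (scheme.theta_boundaries, out.theta_boundaries, "theta"),
        (scheme.maxdist_boundaries, out.maxdist_boundaries, "maxdist"),
    ):
        if not set(np.round(coarse, 9)).issubset(set(np.round(fine, 9))):
            raise ValueError(f"{name} boundaries of out_scheme are not nested in scheme's")

    def bin_map(fine, coarse) -> np.ndarray:
        fine = np.asarray(fine, dtype=float)
        reps = np.append(fine, (fine[-1] + 1.0) if fine.size else 1.0)
        return np.asarray(assign_bin(reps, coarse), dtype=np.int64).reshape(-1)

    tmap = bin_map(scheme.theta_boundaries, out.theta_boundaries)
    dmap = bin_map(scheme.maxdist_boundaries, out.maxdist_boundaries)

    keys = np.fromiter(kv.counts.keys(), dtype=np.int64, count=len(kv.counts))
    cnts = np.fromiter(kv.counts.values(), dtype=np.int64, count=len(kv.counts))
    sign = np.where(keys < 0, -1, 1)
    l1, l2, l3, d_bin, theta_bin = decode_keys(np.abs(keys), scheme)
    labs = np.stack([l1, l2, l3], axis=1)
    if label_map:
        lut = np.arange(scheme.m + 1, dtype=np.int64)
        for src, dst in label_map.items():
            lut[src] = dst
        labs = lut[labs]
    labs = -np.sort(-labs, axis=1)  # canonical descending label order
    merged = sign * encode_keys(
        labs[:, 0], labs[:, 1], labs[:, 2], dmap[d_bin - 1], tmap[theta_bin - 1], out
    )
    counts: dict[int, int] = {}
    for k, c in zip(merged, cnts):
        counts[int(k)] = counts.get(int(k), 0) + int(c)
    return KeyVector(
        protein_id=kv.protein_id,
        counts=counts,
        total_triangles=kv.total_triangles,
        skipped_degenerate=kv.skipped_degenerate,
    )


def describe_triangle(
    labels: Sequence[int],
    coords: np.ndarray,
    seq_indices: Sequence[int],
    scheme: BinScheme,
    mirror: bool = False,
) -> TriangleDescriptor:
    """Full descriptor for a single triangle (scalar reference path)."""
    order = order_vertices(labels, coords, seq_indices)
    oc = np.asarray(coords, dtype=float)[list(order)]
    olab = tuple(int(np.asarray(labels)[v]) for v in order)
    d12, d13, d23, d3, maxdist, theta1, theta = triangle_geometry(oc)
    d_bin = int(assign_bin(maxdist, scheme.maxdist_boundaries))
    theta_bin = int(assign_bin(theta, scheme.theta_boundaries))
    key = encode_key(*olab, d_bin, theta_bin, scheme)
    if mirror and theta1 > 90.0 + 1e-10:  # right angles stay positive
        key = -key
    return TriangleDescriptor(
        vertex_indices=tuple(int(np.asarray(seq_indices)[v]) for v in order),
        labels=olab,
        d12=d12, d13=d13, d23=d23, d3=d3,
        maxdist=maxdist, theta1=theta1, theta=theta,
        d_bin=d_bin, theta_bin=theta_bin, key=key,
    )
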