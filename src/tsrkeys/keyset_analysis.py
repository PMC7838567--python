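"""Class-level key-set algebra, feature statistics and motif matching.

Terminology used throughout (capitalization is deliberate and follows
field usage):

* *common* keys of a set of classes: present in every class's union;
* *specific* keys of a class: in that class's union and in no other;
* *Common* keys of one class: present in **every member protein** of
  the class — a much stronger condition than class-level commonality,
  and the basis for motif discovery.

All set computations ignore key frequencies (sets of distinct keys);
frequency-aware coverage is reported separately where stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .discretize import BinScheme
from .keygen import KeyVector, decode_key

__all__ = [
    "KeySetReport",
    "KeyFeatureStats",
    "MotifQuery",
    "build_keyset_report",
    "common_keys_every_protein",
    "key_feature_stats",
    "match_motif",
    "mirror_pair_analysis",
]

#: full Venn-region enumeration is exponential; cap it
MAX_VENN_CLASSES = 6


@dataclass
class KeySetReport:
    classes: dict[str, list[str]]
    distinct_keys: dict[str, frozenset[int]]
    common_all_classes: frozenset[int]
    specific: dict[str, frozenset[int]]
    common_every_protein: dict[str, frozenset[int]]
    venn_counts: dict[frozenset, int]  # region (frozenset of class labels) -> count

    def venn_count(self, *classes: str) -> int:
        return self.venn_counts.get(frozenset(classes), 0)


@dataclass(frozen=True)
class KeyFeatureStats:
    mean_theta: float
    mean_maxdist: float
    mean_frequency: float
    n_keys: int


@dataclass(frozen=True)
class MotifQuery:
    keys: frozenset[int]
    tolerance: int = 1

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


def build_keyset_report(
    vectors: Sequence[KeyVector], class_map: Mapping[str, str]
) -> KeySetReport:
    """Common / specific / per-protein-Common key sets over labeled classes.

    Every vector must appear in ``class_map`` (protein id → class
    label).  Venn regions are enumerated exhaustively for up to
    ``MAX_VENN_CLASSES`` classes; beyond that only the all-common region
    and pairwise intersections are reported.
    """
    by_class: dict[str, list[KeyVector]] = {}
    for v in vectors:
        if v.protein_id not in class_map:
            raise KeyError(f"protein {v.protein_id!r} missing from class map")
        by_class.setdefault(class_map[v.protein_id], []).append(v)

    classes = {c: [v.protein_id for v in vs] for c, vs in by_class.items()}
    distinct = {
        c: frozenset().union(*(v.key_set() for v in vs)) for c, vs in by_class.items()
    }
    names = sorted(distinct)
    common_all = frozenset.intersection(*(distinct[c] for c in names))
    specific = {
        c: distinct[c].difference(*(distinct[o] for o in names if o != c))
        if len(names) > 1
        else distinct[c]
        for c in names
    }
    common_every = {
        c: frozenset.intersection(*(v.key_set() for v in vs))
        for c, vs in by_class.items()
    }

    venn: dict[frozenset, int] = {}
    if len(names) <= MAX_VENN_CLASSES:
        union_all = frozenset().union(*distinct.values())
        membership: dict[int, frozenset] = {}
        for key in union_all:
            region = frozenset(c for c in names if key in distinct[c])
            membership[key] = region
        for region in map(frozenset, _powerset(names)):
            if region:
                venn[region] = 0
        for region in membership.values():
            venn[region] += 1
    else:
        for c1, c2 in combinations(names, 2):
            venn[frozenset((c1, c2))] = len(distinct[c1] & distinct[c2])
        venn[frozenset(names)] = len(common_all)

    return KeySetReport(
        classes=classes,
        distinct_keys=distinct,
        common_all_classes=common_all,
        specific=specific,
        common_every_protein=common_every,
        venn_counts=venn,
    )


def _powerset(items):
    for r in range(1, len(items) + 1):
        yield from combinations(items, r)


def common_keys_every_protein(
    vectors: Sequence[KeyVector],
) -> tuple[frozenset[int], dict[str, float], dict[str, float]]:
    """Keys present in every member of one class, with per-protein coverage.

    Returns ``(common, coverage_distinct, coverage_frequency)`` where
    the coverage dicts give, per protein, the fraction of its distinct
    keys (respectively of its total key count, frequency-weighted) that
    are Common.
    """
    if not vectors:
        raise ValueError("need at least one key vector")
    common = frozenset.intersection(*(v.key_set() for v in vectors))
    cov_distinct = {}
    cov_freq = {}
    for v in vectors:
        cov_distinct[v.protein_id] = (
            len(common) / v.n_distinct if v.n_distinct else 0.0
        )
        in_common = sum(c for k, c in v.counts.items() if k in common)
        cov_freq[v.protein_id] = in_common / v.total_triangles if v.total_triangles else 0.0
    return common, cov_distinct, cov_freq


def key_feature_stats(
    keys: Iterable[int],
    scheme: BinScheme,
    vectors: Sequence[KeyVector] = (),
    triangle_records=None,
) -> KeyFeatureStats:
    """Mean Theta, MaxDist and occurrence frequency over a key set.

    With only keys available, Theta/MaxDist are decoded bin midpoints;
    when ``triangle_records`` (a per-triangle table from
    :func:`tsrkeys.keygen.triangle_table`) is given, raw per-triangle
    values are averaged instead.  Mean frequency is the average of the
    per-protein occurrence counts of the keys over ``vectors`` (keys a
    protein lacks contribute nothing).
    """
    keyset = set(keys)
    if not keyset:
        raise ValueError("empty key set")

    if triangle_records is not None:
        rec = triangle_records[triangle_records["key"].isin(keyset)]
        if len(rec) == 0:
            raise ValueError("no triangle records for the requested keys")
        mean_theta = float(rec["theta"].mean())
        mean_maxdist = float(rec["maxdist"].mean())
    else:
        theta_mid = scheme.bin_midpoints("theta")
        maxd_mid = scheme.bin_midpoints("maxdist")
        thetas, maxds = [], []
        for k in keyset:
            _, _, _, d_bin, theta_bin = decode_key(abs(k), scheme)
            thetas.append(theta_mid[theta_bin - 1])
            maxds.append(maxd_mid[d_bin - 1])
        mean_theta = float(np.mean(thetas))
        mean_maxdist = float(np.mean(maxds))

    freqs = [v.counts[k] for v in vectors for k in keyset if k in v.counts]
    mean_freq = float(np.mean(freqs)) if freqs else float("nan")
    return KeyFeatureStats(
        mean_theta=mean_theta,
        mean_maxdist=mean_maxdist,
        mean_frequency=mean_freq,
        n_keys=len(keyset),
    )


def match_motif(
    v: KeyVector,
    q: MotifQuery,
    scheme: BinScheme,
    mode: str = "decoded",
) -> tuple[dict[int, bool], bool]:
    """Tolerant presence test for a set of query keys in one vector.

    A query key matches when the vector holds a key with the same sign
    and the same decoded ``(l1, l2, l3, d_bin)`` whose Theta bin differs
    by at most ``q.tolerance`` — the ±1 flexibility used for motif
    searches.  ``mode="raw"`` instead accepts any stored key within
    ``±tolerance`` of the query integer, which coincides with the
    decoded rule except where the Theta digit would wrap past bin 1 or
    bin theta_T.  Returns per-key hits and an all-present flag.
    """
    hits: dict[int, bool] = {}
    if mode == "raw":
        stored = v.key_set()
        for k in q.keys:
            hits[k] = any(
                (k + delta) in stored and (k + delta) * k >= 0
                for delta in range(-q.tolerance, q.tolerance + 1)
            )
    elif mode == "decoded":
        tT = scheme.theta_T
        for k in q.keys:
            sign = -1 if k < 0 else 1
            l1, l2, l3, d_bin, theta_bin = decode_key(abs(k), scheme)
            found = False
            for tb in range(
                max(1, theta_bin - q.tolerance), min(tT, theta_bin + q.tolerance) + 1
            ):
                cand = abs(k) + (tb - theta_bin)  # same digits, shifted theta bin
                if sign * cand in v.counts:
                    found = True
                    break
            hits[k] = found
    else:
        raise ValueError(f"unknown match mode {mode!r}")
    return hits, all(hits.values())


def mirror_pair_analysis(
    vectors: Sequence[KeyVector], class_map: Mapping[str, str]
) -> dict[int, dict]:
    """Chirality splits: which classes carry +k versus -k, per |key|.

    Input vectors must come from mirror-mode key generation (signed
    keys).  For every magnitude present with at least one sign, reports
    the classes whose members carry the positive and the negative form,
    and flags magnitudes where the sign perfectly separates classes:
    both signs occur, and no class contains both.
    """
    if all(k >= 0 for v in vectors for k in v.counts):
        raise ValueError("vectors carry no negative keys; mirror mode required")
    pos: dict[int, set[str]] = {}
    neg: dict[int, set[str]] = {}
    for v in vectors:
        if v.protein_id not in class_map:
            raise KeyError(f"protein {v.protein_id!r} missing from class map")
        c = class_map[v.protein_id]
        for k in v.counts:
            (pos if k >= 0 else neg).setdefault(abs(k), set()).add(c)
    out: dict[int, dict] = {}
    for mag in set(pos) | set(neg):
        p, n = pos.get(mag, set()), neg.get(mag, set())
        out[mag] = {
            "positive_classes": sorted(p),
            "negative_classes": sorted(n),
            "separates": bool(p) and bool(n) and not (p & n),
        }
    return out
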