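"""Adaptive unsupervised discretization of Theta and MaxDist.

Triangle geometry enters the key formula through two discretized digits:
the folded mid-edge angle Theta (degrees, (0, 90]) and the longest-edge
length MaxDist (Å).  Bin boundaries are fitted so that (a) bins hold as
close to equal numbers of observations as achievable and (b) tied values
never straddle a cut; cuts are then iteratively relocated to the
inter-value gap that minimizes the total within-bin variance.

The shipped presets cover the candidate bin counts surveyed for the
method — Theta in {7, 15, 21, 29} and MaxDist in {12, 26, 35}, with
29/35 as the default pairing — fitted on the packaged synthetic Cα
sample (see ``tsrkeys.fixtures``).  User-supplied boundary files can be
dropped in wherever a preset is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinScheme",
    "BinCountCandidate",
    "assign_bin",
    "fit_bin_boundaries",
    "within_bin_variance",
    "select_bin_counts",
    "read_boundaries",
    "write_boundaries",
    "preset_scheme",
    "default_scheme",
    "THETA_BIN_CANDIDATES",
    "MAXDIST_BIN_CANDIDATES",
]

THETA_BIN_CANDIDATES = (7, 15, 21, 29)
MAXDIST_BIN_CANDIDATES = (12, 26, 35)
DEFAULT_THETA_BINS = 29
DEFAULT_MAXDIST_BINS = 35

_MAX_RELOCATION_PASSES = 100


@dataclass(frozen=True)
class BinScheme:
    """Discretization boundaries plus the label-alphabet size m.

    ``theta_boundaries`` / ``maxdist_boundaries`` are ascending interior
    cut-points; a value falls in bin ``i`` (1-based) when it lies in
    ``(boundaries[i-2], boundaries[i-1]]``, with values beyond the last
    cut clamped into the final (open-ended) bin.
    """

    theta_boundaries: tuple[float, ...]
    maxdist_boundaries: tuple[float, ...]
    m: int

    def __post_init__(self) -> None:
        for name, b in (("theta", self.theta_boundaries), ("maxdist", self.maxdist_boundaries)):
            arr = np.asarray(b, dtype=float)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} boundaries must be strictly increasing")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def theta_T(self) -> int:
        return len(self.theta_boundaries) + 1

    @property
    def d_T(self) -> int:
        return len(self.maxdist_boundaries) + 1

    @property
    def n_codes(self) -> int:
        """Size of the full digit space theta_T * d_T * m**3."""
        return self.theta_T * self.d_T * self.m**3

    def theta_bin(self, value) -> np.ndarray | int:
        return assign_bin(value, self.theta_boundaries)

    def maxdist_bin(self, value) -> np.ndarray | int:
        return assign_bin(value, self.maxdist_boundaries)

    def bin_midpoints(self, which: str) -> np.ndarray:
        """Representative (midpoint) value per bin, used when only keys are known.

        The first bin spans (0, b1]; the open-ended last bin is given the
        width of its left neighbour (Theta's last bin is capped at 90°).
        """
        b = np.asarray(
            self.theta_boundaries if which == "theta" else self.maxdist_boundaries, dtype=float
        )
        if b.size == 0:
            return np.array([45.0 if which == "theta" else 1.0])
        edges = np.concatenate([[0.0], b])
        mids = (edges[:-1] + edges[1:]) / 2
        if which == "theta":
            last = (b[-1] + 90.0) / 2
        else:
            width = b[-1] - edges[-2]
            last = b[-1] + width / 2
        return np.concatenate([mids, [last]])


@dataclass(frozen=True)
class BinCountCandidate:
    n_bins: int
    within_bin_variance: float


def assign_bin(value, boundaries) -> np.ndarray | int:
    """1-based bin index under the right-closed convention ``(lo, hi]``.

    Values above the last cut fall in the last bin; negative values are
    rejected (both Theta and MaxDist are non-negative quantities).
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("cannot bin negative values")
    b = np.asarray(boundaries, dtype=float)
    idx = np.searchsorted(b, v, side="left") + 1
    return int(idx) if np.isscalar(value) or v.ndim == 0 else idx


def _prefix_stats(u: np.ndarray, c: np.ndarray):
    """Prefix count/sum/sum-of-squares over sorted unique values."""
    n = np.concatenate([[0], np.cumsum(c)])
    s1 = np.concatenate([[0.0], np.cumsum(u * c)])
    s2 = np.concatenate([[0.0], np.cumsum(u * u * c)])
    return n, s1, s2


def _bin_variance(n, s1, s2, lo: int, hi: int) -> float:
    """Population variance of the values in uniques (lo, hi] (prefix indices)."""
    cnt = n[hi] - n[lo]
    if cnt == 0:
        return 0.0
    mean = (s1[hi] - s1[lo]) / cnt
    return max((s2[hi] - s2[lo]) / cnt - mean * mean, 0.0)


def fit_bin_boundaries(values: Iterable[float], n_bins: int) -> np.ndarray:
    """Fit ``n_bins - 1`` interior cut-points on a sample.

    Cuts are restricted to the gaps between distinct values, so tied
    values can never be split.  Each cut targets its equal-frequency
    position; because a gap exactly at the target may not exist (tied
    runs), the cut snaps to the *nearest* admissible gap by cumulative
    count, and ties between equally-near gaps are broken by the lower
    total within-bin variance of the two adjacent bins.  Cuts are then
    revisited iteratively — each re-balancing the two bins around it —
    until no cut moves or a pass limit is reached.  On all-distinct
    values this reduces to equal-frequency binning (deviation at most
    one element per bin).
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ValueError("cannot fit boundaries on an empty sample")
    u, c = np.unique(v, return_counts=True)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > u.size:
        raise ValueError(f"n_bins={n_bins} exceeds the {u.size} distinct values")
    if n_bins == 1:
        return np.array([])

    gaps = (u[:-1] + u[1:]) / 2  # candidate cut positions
    n, s1, s2 = _prefix_stats(u, c)
    total = n[-1]

    def snap(target: float, lo: int, hi: int, bin_lo: int, bin_hi: int) -> int:
        """Gap in [lo, hi) nearest to the target count; variance breaks ties.

        ``bin_lo``/``bin_hi`` are the prefix bounds of the two bins the
        cut separates, used for the variance tie-break.
        """
        cand = np.arange(lo, hi)
        dev = np.abs(n[cand + 1] - target)
        nearest = cand[dev == dev.min()]
        if nearest.size == 1:
            return int(nearest[0])
        cost = [
            _bin_variance(n, s1, s2, bin_lo, g + 1) + _bin_variance(n, s1, s2, g + 1, bin_hi)
            for g in nearest
        ]
        return int(nearest[int(np.argmin(cost))])

    # equal-frequency seed: cut j targets cumulative count j*total/n_bins
    cuts: list[int] = []  # gap indices; cut at gap g separates uniques <=g from >g
    for j in range(1, n_bins):
        lo = cuts[-1] + 1 if cuts else 0
        hi = gaps.size - (n_bins - 1 - j)  # leave room for remaining cuts
        cuts.append(snap(j * total / n_bins, lo, hi, lo, u.size))

    # iterative refinement: re-balance each cut between its neighbours
    for _ in range(_MAX_RELOCATION_PASSES):
        moved = False
        for j in range(len(cuts)):
            left = cuts[j - 1] if j > 0 else -1
            right = cuts[j + 1] if j + 1 < len(cuts) else u.size - 1
            target = (n[left + 1] + n[right + 1]) / 2  # balance the two bins
            g = snap(target, left + 1, right if right < u.size - 1 else gaps.size,
                     left + 1, right + 1)
            if g != cuts[j]:
                cuts[j] = g
                moved = True
        if not moved:
            break
    return gaps[np.array(cuts)]


def within_bin_variance(values: Iterable[float], boundaries) -> float:
    """Sum over bins of the population variance of the values in the bin."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return 0.0
    bins = assign_bin(v, boundaries)
    k = len(np.asarray(boundaries)) + 1
    cnt = np.bincount(bins, minlength=k + 1).astype(float)
    s1 = np.bincount(bins, weights=v, minlength=k + 1)
    s2 = np.bincount(bins, weights=v * v, minlength=k + 1)
    nz = cnt > 0
    mean = np.zeros_like(cnt)
    mean[nz] = s1[nz] / cnt[nz]
    var = np.zeros_like(cnt)
    var[nz] = np.maximum(s2[nz] / cnt[nz] - mean[nz] ** 2, 0.0)
    return float(var.sum())


@dataclass
class BinCountSelection:
    """Outcome of the bin-count survey across sample sets."""

    per_sample: list[list[BinCountCandidate]]  # all candidates, each sample
    top_five: list[list[int]]  # five smallest-variance counts per sample
    selected: list[list[int]]  # the two largest among the top five
    minimum: int
    median: float
    maximum: int
    mode: int


def select_bin_counts(
    sample_sets: Sequence[Iterable[float]], candidate_range: Iterable[int]
) -> BinCountSelection:
    """Survey candidate bin counts by within-bin variance.

    Per sample set: fit boundaries for every candidate count, rank by
    variance (ties broken toward the larger count), keep the five
    smallest, then retain the two largest counts among those five.  The
    pooled retained counts are summarized by min / median / max / mode
    (modal ties also resolve toward the larger count, matching the
    preference for finer discretization).
    """
    candidates = sorted(set(int(k) for k in candidate_range))
    if not candidates:
        raise ValueError("empty candidate range")
    if not sample_sets:
        raise ValueError("need at least one sample set")

    per_sample, top_five, selected = [], [], []
    for sample in sample_sets:
        v = np.asarray(list(sample), dtype=float)
        n_distinct = np.unique(v).size
        cands = []
        for k in candidates:
            if k > n_distinct:
                continue
            b = fit_bin_boundaries(v, k)
            cands.append(BinCountCandidate(k, within_bin_variance(v, b)))
        if not cands:
            raise ValueError("no feasible candidate bin count for a sample set")
        per_sample.append(cands)
        ranked = sorted(cands, key=lambda c: (c.within_bin_variance, -c.n_bins))
        five = [c.n_bins for c in ranked[:5]]
        top_five.append(five)
        selected.append(sorted(five, reverse=True)[:2])

    pooled = np.array([k for sel in selected for k in sel])
    counts = {k: int((pooled == k).sum()) for k in set(pooled.tolist())}
    mode = max(counts, key=lambda k: (counts[k], k))
    return BinCountSelection(
        per_sample=per_sample,
        top_five=top_five,
        selected=selected,
        minimum=int(pooled.min()),
        median=float(np.median(pooled)),
        maximum=int(pooled.max()),
        mode=int(mode),
    )


def read_boundaries(path) -> np.ndarray:
    """Read one ascending cut-point per line; '#' lines are comments."""
    vals = []
    for line in Path(str(path)).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals.append(float(line))
    arr = np.asarray(vals, dtype=float)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError(f"boundaries in {path} are not strictly increasing")
    return arr


def write_boundaries(boundaries, path, header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(repr(float(b)) for b in boundaries)
    Path(path).write_text("\n".join(lines) + "\n")


def preset_scheme(theta_bins: int = DEFAULT_THETA_BINS,
                  maxdist_bins: int = DEFAULT_MAXDIST_BINS,
                  m: int = 23) -> BinScheme:
    """A shipped boundary preset (fitted on the packaged synthetic sample)."""
    if theta_bins not in THETA_BIN_CANDIDATES:
        raise ValueError(f"no theta preset for {theta_bins} bins; have {THETA_BIN_CANDIDATES}")
    if maxdist_bins not in MAXDIST_BIN_CANDIDATES:
        raise ValueError(f"no maxdist preset for {maxdist_bins} bins; have {MAXDIST_BIN_CANDIDATES}")
    data = resources.files("tsrkeys.data")
    return BinScheme(
        theta_boundaries=tuple(read_boundaries(data / f"theta_{theta_bins}.txt")),
        maxdist_boundaries=tuple(read_boundaries(data / f"maxdist_{maxdist_bins}.txt")),
        m=m,
    )


def default_scheme(m: int = 23) -> BinScheme:
    """The default 29-bin Theta / 35-bin MaxDist scheme."""
    return preset_scheme(DEFAULT_THETA_BINS, DEFAULT_MAXDIST_BINS, m)
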