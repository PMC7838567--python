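"""Synthetic Cα traces and structure transformations.

Generators for ideal secondary-structure geometry and random coil
traces, plus the transformations the method's invariants are stated
over: Gaussian perturbation, reflection, rigid motion, chain
rearrangement and rigid three-residue motif planting.  Everything is
deterministic given its seed, so fixtures ship as code.

Geometry emulated: an ideal α-helix Cα spiral (1.5 Å rise, 100° twist,
2.3 Å radius, consecutive Cα ≈ 3.8 Å apart), an extended β-strand zigzag
(3.3 Å axial step) and a self-avoiding random walk with 3.8 Å virtual
bonds for coil.  These reproduce realistic Cα–Cα distance and triangle
distributions but none of the side-chain packing, loop closure or
hydrogen-bond constraints of real proteins.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import CaStructure, LabelTable, Residue

__all__ = [
    "AA3",
    "random_sequence",
    "make_helix",
    "make_strand",
    "make_coil",
    "perturb",
    "reflect",
    "rigid_move",
    "plant_motif",
    "rearrange",
    "motif_coords",
]

#: the 20 standard residues, alphabetical (matches the default label table)
AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å
STRAND_STEP = 3.3  # Å axial rise per residue
COIL_BOND = 3.8  # Å virtual Cα-Cα bond
COIL_CLASH = 3.0  # Å minimum non-bonded separation


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(n: int, seed) -> list[str]:
    """n residue names drawn i.i.d. uniformly from the 20 standard types."""
    rng = _rng(seed)
    return [AA3[i] for i in rng.integers(0, len(AA3), size=n)]


def _build(structure_id: str, sequence: Sequence[str], coords: np.ndarray,
           ss_segments=None, label_table: LabelTable | None = None) -> CaStructure:
    if label_table is None:
        label_table = LabelTable.default()
    residues = []
    for i, (aa3, c) in enumerate(zip(sequence, coords)):
        label = label_table.label_of(aa3)
        if label is None:
            raise ValueError(f"residue {aa3!r} not in label table")
        residues.append(
            Residue(seq_index=i, auth_pos=(i + 1, ""), aa3=aa3, label=label,
                    coord=(float(c[0]), float(c[1]), float(c[2])))
        )
    return CaStructure(structure_id, residues, list(ss_segments or []))


def make_helix(n: int, seed, structure_id: str | None = None,
               sequence: Sequence[str] | None = None) -> CaStructure:
    """Ideal α-helical Cα trace annotated as one helix segment."""
    if n < 3:
        raise ValueError("need n >= 3")
    i = np.arange(n)
    ang = np.radians(HELIX_TWIST) * i
    coords = np.stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i], axis=1
    )
    seq = list(sequence) if sequence is not None else random_sequence(n, seed)
    return _build(structure_id or f"helix{n}_s{seed}", seq, coords,
                  ss_segments=[("helix", 0, n - 1)])


def make_strand(n: int, seed, structure_id: str | None = None,
                sequence: Sequence[str] | None = None) -> CaStructure:
    """Extended β-strand-like zigzag trace annotated as one strand segment."""
    if n < 3:
        raise ValueError("need n >= 3")
    i = np.arange(n)
    zig = np.where(i % 2 == 0, 0.95, -0.95)
    coords = np.stack([STRAND_STEP * i, zig, np.zeros(n)], axis=1)
    seq = list(sequence) if sequence is not None else random_sequence(n, seed)
    return _build(structure_id or f"strand{n}_s{seed}", seq, coords,
                  ss_segments=[("strand", 0, n - 1)])


def make_coil(n: int, seed, structure_id: str | None = None,
              sequence: Sequence[str] | None = None,
              max_tries: int = 200) -> CaStructure:
    """Self-avoiding random walk with fixed 3.8 Å virtual bonds.

    Steps are rejected while any non-bonded pair comes closer than
    3.0 Å, which keeps the MaxDist distribution protein-like for
    binning experiments.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rng = _rng(seed)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(max_tries):
            step = rng.normal(size=3)
            step *= COIL_BOND / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i < 2 or np.linalg.norm(coords[: i - 1] - cand, axis=1).min() >= COIL_CLASH:
                coords[i] = cand
                break
        else:  # pragma: no cover - rejection nearly never exhausts
            raise RuntimeError("self-avoiding walk failed to extend")
    seq = list(sequence) if sequence is not None else random_sequence(n, rng.integers(2**31))
    return _build(structure_id or f"coil{n}_s{seed}", seq, coords)


def perturb(s: CaStructure, sigma: float, seed) -> CaStructure:
    """I.i.d. Gaussian coordinate noise of the given σ (Å); σ=0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return s.with_coords(s.coords)
    rng = _rng(seed)
    return s.with_coords(s.coords + rng.normal(scale=sigma, size=(len(s), 3)),
                         suffix=f"_p{sigma}")


def reflect(s: CaStructure) -> CaStructure:
    """Mirror image: x-coordinate negation (an involution)."""
    coords = s.coords
    coords[:, 0] *= -1
    return s.with_coords(coords, suffix="_mirror")


def rigid_move(s: CaStructure, seed) -> CaStructure:
    """Uniformly random proper rotation plus a random translation."""
    rng = _rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-50, 50, size=3)
    return s.with_coords(s.coords @ rot.T + trans, suffix="_moved")


def motif_coords(maxdist: float, theta_deg: float, d3_frac: float = 0.25) -> np.ndarray:
    """A planar triangle with prescribed MaxDist and mid-edge angle.

    Vertices: L1 at the origin, L2 at ``(maxdist, 0, 0)``, L3 placed at
    distance ``d3 = d3_frac * maxdist`` from the edge midpoint so that
    the mid-edge angle equals ``theta_deg``.  With ``d3_frac < 0.5`` the
    L1–L2 edge stays the longest, so MaxDist is exactly ``maxdist``.
    """
    if not 0 < d3_frac < 0.5:
        raise ValueError("d3_frac must lie in (0, 0.5) to keep the base edge longest")
    mid = np.array([maxdist / 2, 0.0, 0.0])
    th = math.radians(theta_deg)
    d3 = d3_frac * maxdist
    # angle is measured at the midpoint against the (unit) direction to L2
    l3 = mid + d3 * np.array([math.cos(th), math.sin(th), 0.0])
    return np.array([[0.0, 0.0, 0.0], [maxdist, 0.0, 0.0], l3])


def stable_motif_geometry(
    scheme,
    theta_range: tuple[float, float] = (20.0, 70.0),
    maxdist_range: tuple[float, float] = (5.0, 40.0),
) -> tuple[float, float]:
    """(MaxDist, Theta) at the midpoints of the widest in-range bins.

    A recurring structural motif is only recoverable as a shared key if
    its geometry sits away from bin boundaries; this picks, for a given
    scheme, the widest Theta and MaxDist bins whose midpoints fall in
    the requested physical ranges and returns their midpoints.
    """
    best = {}
    for which, (lo, hi) in (("theta", theta_range), ("maxdist", maxdist_range)):
        b = np.asarray(
            scheme.theta_boundaries if which == "theta" else scheme.maxdist_boundaries
        )
        edges = np.concatenate([[0.0], b])  # interior bins only
        widths = np.diff(edges)
        mids = (edges[:-1] + edges[1:]) / 2
        ok = (mids >= lo) & (mids <= hi)
        if not ok.any():
            raise ValueError(f"no {which} bin midpoint inside {lo}..{hi}")
        best[which] = float(mids[ok][np.argmax(widths[ok])])
    return best["maxdist"], best["theta"]


def plant_motif(
    s: CaStructure,
    coords3: np.ndarray,
    labels3: Sequence[str],
    positions: Sequence[int],
    jitter: float = 0.0,
    seed=0,
) -> CaStructure:
    """Overwrite three residues with a rigid motif (optionally jittered).

    ``coords3`` are the motif's three Cα positions (any frame: a random
    rigid motion is applied so the planted copy sits in a generic
    orientation near the structure's centroid), ``labels3`` the residue
    names, ``positions`` the seq_indices to overwrite.  ``jitter`` adds
    uniform noise in ``[-jitter, +jitter]`` Å per coordinate, emulating
    the structural flexibility of a real recurring motif.
    """
    if len(positions) != 3 or len(set(positions)) != 3:
        raise ValueError("need three distinct positions")
    if any(not 0 <= p < len(s) for p in positions):
        raise IndexError("motif position out of range")
    rng = _rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    placed = np.asarray(coords3, dtype=float) @ rot.T + s.coords.mean(axis=0)
    if jitter:
        placed = placed + rng.uniform(-jitter, jitter, size=(3, 3))

    table = LabelTable.default()
    coords = s.coords
    sequence = [r.aa3 for r in s.residues]
    for pos, aa3, c in zip(positions, labels3, placed):
        sequence[pos] = aa3
        coords[pos] = c
    return _build(s.id + "_motif", sequence, coords, ss_segments=s.ss_segments,
                  label_table=table)


def rearrange(s: CaStructure, cut: int) -> CaStructure:
    """Move residues [0, cut) to the C-terminal end, coordinates untouched.

    Emulates covalently re-joining an N-terminal block after the last
    residue: record order changes, geometry does not, so the key
    multiset is unchanged.
    """
    if not 0 < cut < len(s):
        raise ValueError("cut must be inside the chain")
    reordered = s.residues[cut:] + s.residues[:cut]
    residues = [
        Residue(seq_index=i, auth_pos=(i + 1, ""), aa3=r.aa3, label=r.label, coord=r.coord)
        for i, r in enumerate(reordered)
    ]
    return CaStructure(s.id + f"_rearr{cut}", residues, [])
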