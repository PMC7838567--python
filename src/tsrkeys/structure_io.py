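"""Read and write Cα traces from PDB files.

The comparison method works on one chain at a time: a structure is an
ordered list of Cα points, each carrying an integer amino-acid label used
as a digit of the triangle key.  Parsing is delegated to :mod:`gemmi`;
this module only selects Cα atoms, resolves altlocs, maps residue names
to integer labels and lifts HELIX/SHEET records onto internal indices.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "CaStructure",
    "LabelTable",
    "read_pdb_ca",
    "trim_structure",
    "write_pdb",
]

#: default aliases for common modified residues; overridable per call
DEFAULT_ALIASES: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "TPO": "THR",  # phosphothreonine
    "SEP": "SER",  # phosphoserine
    "PTR": "TYR",  # phosphotyrosine
    "TYS": "TYR",  # sulfotyrosine
    "TYN": "TYR",  # nitrotyrosine (naming as used for modified ERK1 Tyr)
    "CSO": "CYS",
    "MLY": "LYS",
    "HYP": "PRO",
}


@dataclass(frozen=True)
class Residue:
    """One Cα point: internal index, author numbering, name, label, coordinate."""

    seq_index: int
    auth_pos: tuple[int, str]  # author residue number, insertion code ('' if none)
    aa3: str
    label: int
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for residue {self.aa3} {self.auth_pos}")


@dataclass
class CaStructure:
    """An ordered, single-chain Cα trace with optional secondary-structure segments.

    ``ss_segments`` holds ``(kind, start, end)`` with ``kind`` in
    ``{"helix", "strand"}`` and *closed* 0-based ``seq_index`` bounds.
    """

    id: str
    residues: list[Residue]
    ss_segments: list[tuple[str, int, int]] = field(default_factory=list)
    n_skipped_residues: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for i, r in enumerate(self.residues):
            if r.seq_index != i:
                raise ValueError("residues must be indexed 0..n-1 in order")
            if r.auth_pos in seen:
                raise ValueError(f"duplicate residue position {r.auth_pos}")
            seen.add(r.auth_pos)
        n = len(self.residues)
        for kind, start, end in self.ss_segments:
            if kind not in ("helix", "strand"):
                raise ValueError(f"unknown secondary-structure kind {kind!r}")
            if not (0 <= start <= end < n):
                raise ValueError(f"ss segment ({kind}, {start}, {end}) out of range")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of Cα coordinates in Å."""
        return np.array([r.coord for r in self.residues], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """(n,) integer array of amino-acid labels."""
        return np.array([r.label for r in self.residues], dtype=np.int64)

    def with_coords(self, coords: np.ndarray, suffix: str = "") -> "CaStructure":
        """Copy of the structure with replaced coordinates (same labels/annotation)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError("coordinate array shape mismatch")
        residues = [replace(r, coord=tuple(c)) for r, c in zip(self.residues, coords)]
        return CaStructure(self.id + suffix, residues, list(self.ss_segments))


class LabelTable:
    """Amino-acid 3-letter code → integer label, with optional grouping.

    ``m`` is the size of the label alphabet used as the radix of the key
    formula; every label satisfies ``1 <= label <= m`` so the encoding
    stays bijective.  The shipped default maps the 20 standard amino
    acids, sorted alphabetically by 3-letter code, to 4..23 with m = 23.
    """

    def __init__(
        self,
        mapping: Mapping[str, int],
        m: int | None = None,
        grouping: Mapping[int, int] | None = None,
    ) -> None:
        self.mapping = dict(mapping)
        if not self.mapping:
            raise ValueError("empty label mapping")
        labels = list(self.mapping.values())
        self.m = int(m) if m is not None else max(labels)
        if min(labels) < 1 or max(labels) > self.m:
            raise ValueError(f"labels must lie in 1..m (m={self.m})")
        if grouping is None and len(set(labels)) != len(labels):
            raise ValueError("label mapping must be injective when no grouping is applied")
        self.grouping = dict(grouping) if grouping else None
        if self.grouping:
            for src, dst in self.grouping.items():
                if not (1 <= dst <= self.m):
                    raise ValueError(f"group label {dst} out of range 1..{self.m}")

    @classmethod
    def default(cls) -> "LabelTable":
        return cls.from_tsv(resources.files("tsrkeys.data") / "aa_labels.tsv")

    @classmethod
    def from_tsv(cls, path) -> "LabelTable":
        """Load ``aa3<TAB>label`` rows; '#' lines are comments."""
        mapping = {}
        for line in Path(str(path)).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa3, lab = line.split("\t")[:2]
            mapping[aa3.upper()] = int(lab)
        return cls(mapping)

    def label_of(self, aa3: str, aliases: Mapping[str, str] | None = None) -> int | None:
        """Resolve a residue name to its (possibly grouped) label, or None."""
        aa3 = aa3.upper()
        if aa3 not in self.mapping and aliases and aa3 in aliases:
            aa3 = aliases[aa3]
        lab = self.mapping.get(aa3)
        if lab is not None and self.grouping:
            lab = self.grouping.get(lab, lab)
        return lab

    def label_array(self) -> np.ndarray:
        """Lookup table old-label -> effective label (identity without grouping)."""
        arr = np.arange(self.m + 1, dtype=np.int64)
        if self.grouping:
            for src, dst in self.grouping.items():
                arr[src] = dst
        return arr

    def fingerprint(self) -> str:
        payload = repr(sorted(self.mapping.items())) + repr(
            sorted(self.grouping.items()) if self.grouping else None
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_pdb_ca(
    path,
    chain: str = "first",
    model: int = 1,
    label_table: LabelTable | None = None,
    aliases: Mapping[str, str] | None = None,
) -> CaStructure:
    """Extract one chain's Cα trace from a PDB file.

    Parameters
    ----------
    path : str or Path
        PDB file.
    chain : str
        Chain identifier, or ``"first"`` for the first chain in the file.
    model : int
        1-based model index (NMR/multi-model files); default first model.
    label_table : LabelTable, optional
        Amino-acid labelling; default table if omitted.
    aliases : mapping, optional
        Modified-residue aliases (e.g. ``MSE → MET``); defaults to
        :data:`DEFAULT_ALIASES`.  Residues with no label after aliasing
        are skipped with a warning and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if label_table is None:
        label_table = LabelTable.default()
    if aliases is None:
        aliases = DEFAULT_ALIASES

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if not (1 <= model <= len(st)):
        raise ValueError(f"model {model} not in file with {len(st)} model(s)")
    mdl = st[model - 1]
    if len(mdl) == 0:
        raise ValueError(f"no chains in model {model} of {path}")
    if chain == "first":
        ch = mdl[0]
    else:
        ch = mdl.find_chain(chain)
        if ch is None:
            raise ValueError(f"chain {chain!r} not found in {path}")

    residues: list[Residue] = []
    pos_to_index: dict[tuple[int, str], int] = {}
    n_skipped = 0
    for res in ch:
        # collect CA candidates; pick highest occupancy, first-in-file on ties
        best = None
        for atom in res:
            if atom.name.strip() != "CA" or atom.element.name != "C":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        label = label_table.label_of(res.name, aliases)
        if label is None:
            warnings.warn(f"{path.name}: residue {res.name} {res.seqid.num} has no label; skipped")
            n_skipped += 1
            continue
        auth = (res.seqid.num, res.seqid.icode.strip())
        if auth in pos_to_index:  # duplicate residue record (altloc split across residues)
            continue
        pos_to_index[auth] = len(residues)
        residues.append(
            Residue(
                seq_index=len(residues),
                auth_pos=auth,
                aa3=res.name,
                label=label,
                coord=(best.pos.x, best.pos.y, best.pos.z),
            )
        )
    if not residues:
        raise ValueError(f"no Cα atoms found in chain {ch.name!r} of {path}")

    ss_segments = _collect_ss_segments(st, ch.name, residues)
    return CaStructure(
        id=f"{path.stem}_{ch.name}",
        residues=residues,
        ss_segments=ss_segments,
        n_skipped_residues=n_skipped,
    )


def _collect_ss_segments(
    st: gemmi.Structure, chain_name: str, residues: Sequence[Residue]
) -> list[tuple[str, int, int]]:
    """Map HELIX/SHEET author ranges onto internal seq_index intervals."""
    segments: list[tuple[str, int, int]] = []

    def add(kind: str, start_addr, end_addr) -> None:
        if start_addr.chain_name != chain_name or end_addr.chain_name != chain_name:
            return
        lo, hi = start_addr.res_id.seqid.num, end_addr.res_id.seqid.num
        if lo > hi:
            lo, hi = hi, lo
        idx = [r.seq_index for r in residues if lo <= r.auth_pos[0] <= hi]
        if idx:
            segments.append((kind, min(idx), max(idx)))

    for h in st.helices:
        add("helix", h.start, h.end)
    for sheet in st.sheets:
        for strand in sheet.strands:
            add("strand", strand.start, strand.end)
    segments.sort(key=lambda t: (t[1], t[2]))
    return segments


def trim_structure(s: CaStructure, start: int, end: int) -> CaStructure:
    """Sub-structure over the closed seq_index window ``[start, end]``.

    Mimics trimming a deposited structure from the N- or C-terminus so
    that chains under comparison carry identical sequences.  Residues are
    re-indexed from 0 and secondary-structure segments are clipped to the
    window (segments falling entirely outside are dropped).
    """
    if not (0 <= start <= end < len(s)):
        raise IndexError(f"trim window [{start}, {end}] out of range for {len(s)} residues")
    residues = [
        replace(r, seq_index=i) for i, r in enumerate(s.residues[start : end + 1])
    ]
    segments = []
    for kind, lo, hi in s.ss_segments:
        lo2, hi2 = max(lo, start), min(hi, end)
        if lo2 <= hi2:
            segments.append((kind, lo2 - start, hi2 - start))
    return CaStructure(s.id, residues, segments, s.n_skipped_residues)


def write_pdb(s: CaStructure, path, chain: str = "A") -> None:
    """Write a minimal single-chain PDB file (ATOM + HELIX/SHEET records).

    Intended for synthetic fixtures and round-trip checks, not as a
    general PDB writer; coordinates are emitted at the format's native
    3-decimal precision.
    """
    lines: list[str] = []
    helix_no = strand_no = 0
    for kind, lo, hi in s.ss_segments:
        r1, r2 = s.residues[lo], s.residues[hi]
        ic1 = r1.auth_pos[1] or " "
        ic2 = r2.auth_pos[1] or " "
        if kind == "helix":
            helix_no += 1
            lines.append(
                "HELIX  %3d %3d %3s %1s %4d%1s %3s %1s %4d%1s%2d"
                % (helix_no, helix_no, r1.aa3, chain, r1.auth_pos[0], ic1,
                   r2.aa3, chain, r2.auth_pos[0], ic2, 1)
            )
        else:
            strand_no += 1
            lines.append(
                "SHEET  %3d %3s%2d %3s %1s%4d%1s %3s %1s%4d%1s %2d"
                % (strand_no, "A", 1, r1.aa3, chain, r1.auth_pos[0], ic1,
                   r2.aa3, chain, r2.auth_pos[0], ic2, 0)
            )
    for i, r in enumerate(s.residues, start=1):
        x, y, z = r.coord
        lines.append(
            "ATOM  %5d  CA  %3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f           C"
            % (i, r.aa3, chain, r.auth_pos[0], r.auth_pos[1] or " ", x, y, z, 1.0, 0.0)
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
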