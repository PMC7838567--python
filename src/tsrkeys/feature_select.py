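"""Secondary-structure feature selection and amino-acid grouping.

Restricting the triangle enumeration to annotated secondary structure
separates helical from strand architecture that whole-chain key sets
blur: *IESS* keys come from triangles whose three residues all sit in
some helix or strand segment (segments and types may differ), *IASS*
keys from triangles confined to a single segment.  IASS keys are by
construction a subset of IESS keys, which are a subset of all keys.

Amino-acid grouping coarsens the label alphabet (e.g. Ser and Thr share
one label) so that chemically similar substitutions stop splitting
keys; the grouped key space is strictly coarser, which can only merge
key classes and therefore never decreases generalized Jaccard
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np

from .structure_io import CaStructure, LabelTable

__all__ = [
    "SSAnnotation",
    "annotate_ss",
    "iess_filter",
    "iass_filter",
    "apply_grouping",
    "load_grouping",
    "default_grouping",
]


@dataclass
class SSAnnotation:
    """Per-residue secondary-structure tags and segment ids.

    ``tag[i]`` is ``"helix"``, ``"strand"`` or ``"none"``; ``segment[i]``
    is a unique id per annotated segment, -1 outside any segment.
    """

    tag: np.ndarray  # dtype object/str
    segment: np.ndarray  # int, -1 = unannotated

    def __len__(self) -> int:
        return len(self.tag)


def annotate_ss(s: CaStructure) -> SSAnnotation:
    """Expand a structure's segment list into per-residue annotation.

    Overlapping segments are resolved first-come (segments are sorted by
    start in the structure).
    """
    n = len(s)
    tag = np.array(["none"] * n, dtype=object)
    segment = np.full(n, -1, dtype=np.int64)
    for seg_id, (kind, lo, hi) in enumerate(s.ss_segments):
        for i in range(lo, hi + 1):
            if segment[i] == -1:
                tag[i] = kind
                segment[i] = seg_id
    return SSAnnotation(tag=tag, segment=segment)


def _triple_index_arrays(n: int) -> np.ndarray:
    return np.array(list(combinations(range(n), 3)), dtype=np.int64).reshape(-1, 3)


def iess_filter(s: CaStructure) -> np.ndarray:
    """Boolean mask over lexicographic triples: inter-secondary-structure keys.

    A triangle passes when all three residues are annotated helix or
    strand — within one segment or spanning several, of either type.
    """
    ann = _require_annotation(s)
    triples = _triple_index_arrays(len(s))
    tagged = ann.segment >= 0
    return tagged[triples].all(axis=1)


def iass_filter(s: CaStructure, mode: str = "segment") -> np.ndarray:
    """Boolean mask over triples: intra-secondary-structure keys.

    ``mode="segment"`` (default): all three residues lie in one single
    helix or strand segment.  ``mode="type"``: all three share the same
    secondary-structure type, segments free.  Either way the selection
    is a subset of :func:`iess_filter`.
    """
    ann = _require_annotation(s)
    triples = _triple_index_arrays(len(s))
    tagged = (ann.segment >= 0)[triples].all(axis=1)
    if mode == "segment":
        seg = ann.segment[triples]
        same = (seg[:, 0] == seg[:, 1]) & (seg[:, 1] == seg[:, 2])
    elif mode == "type":
        t = ann.tag[triples]
        same = (t[:, 0] == t[:, 1]) & (t[:, 1] == t[:, 2])
    else:
        raise ValueError(f"unknown IASS mode {mode!r}")
    return tagged & same


def _require_annotation(s: CaStructure) -> SSAnnotation:
    if not s.ss_segments:
        raise ValueError(f"structure {s.id!r} has no secondary-structure annotation")
    return annotate_ss(s)


def apply_grouping(table: LabelTable, groups: Mapping[int, int]) -> LabelTable:
    """New label table whose mapping composes an existing one with a grouping.

    ``groups`` maps original labels to group labels (both within 1..m).
    Key generation under the grouped table produces a coarser key space:
    the distinct key count can only stay equal or shrink.
    """
    for src, dst in groups.items():
        if not (1 <= dst <= table.m):
            raise ValueError(f"group label {dst} outside 1..{table.m}")
    return LabelTable(table.mapping, m=table.m, grouping=dict(groups))


def load_grouping(path, table: LabelTable) -> dict[int, int]:
    """Read ``aa3<TAB>group_label`` rows into an original-label → group map."""
    groups: dict[int, int] = {}
    for line in Path(str(path)).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa3, grp = line.split("\t")[:2]
        src = table.mapping.get(aa3.upper())
        if src is None:
            raise ValueError(f"grouping file references unknown residue {aa3!r}")
        groups[src] = int(grp)
    return groups


def default_grouping(table: LabelTable | None = None) -> dict[int, int]:
    """The shipped grouping: {S,T} {D,E} {N,Q} {K,R} {I,L,V} {F,Y,W}."""
    from importlib import resources

    if table is None:
        table = LabelTable.default()
    return load_grouping(resources.files("tsrkeys.data") / "grouping_default.tsv", table)
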