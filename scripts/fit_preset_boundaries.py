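#!/usr/bin/env python
"""Regenerate the shipped boundary presets from the packaged synthetic sample.

The presets under ``src/tsrkeys/data`` are fitted on a fixed synthetic
Ca sample (4 helices + 4 strands + 4 coils, 40 residues each, fixed
seeds). Run from the repository root after changing the fixture
geometry or the discretization algorithm:

    python scripts/fit_preset_boundaries.py
"""
import numpy as np

from tsrkeys import fixtures
from tsrkeys.discretize import (
    MAXDIST_BIN_CANDIDATES,
    THETA_BIN_CANDIDATES,
    BinScheme,
    fit_bin_boundaries,
    write_boundaries,
)
from tsrkeys.keygen import triangle_table


def main() -> None:
    raw = BinScheme(theta_boundaries=(), maxdist_boundaries=(), m=23)
    thetas, maxds = [], []
    for i in range(4):
        for maker, base in (
            (fixtures.make_helix, 100),
            (fixtures.make_strand, 200),
            (fixtures.make_coil, 300),
        ):
            tt = triangle_table(maker(40, seed=base + i), raw)
            thetas.append(tt["theta"].to_numpy())
            maxds.append(tt["maxdist"].to_numpy())
    theta = np.concatenate(thetas)
    maxd = np.concatenate(maxds)
    print(f"sample: {theta.size} triangles")

    hdr = ("Fitted on the packaged synthetic Ca sample "
           "(4 helices + 4 strands + 4 coils, 40 residues, fixed seeds).")
    for k in THETA_BIN_CANDIDATES:
        write_boundaries(fit_bin_boundaries(theta, k), f"src/tsrkeys/data/theta_{k}.txt",
                         header=f"Theta bin boundaries, {k} bins (degrees). {hdr}")
    for k in MAXDIST_BIN_CANDIDATES:
        write_boundaries(fit_bin_boundaries(maxd, k), f"src/tsrkeys/data/maxdist_{k}.txt",
                         header=f"MaxDist bin boundaries, {k} bins (Angstrom). {hdr}")
    print("presets rewritten")


if __name__ == "__main__":
    main()
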