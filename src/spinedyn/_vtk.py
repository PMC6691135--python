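"""Minimal legacy-VTK (ASCII) export for meridian triangle meshes.

Writes the (r, z) mesh as 3D points with y=0 plus optional point-data
scalar fields — enough for ParaView inspection of a run without binary
dependencies.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np


def write_vtk(
    path: str,
    nodes: np.ndarray,
    tris: np.ndarray,
    point_data: Optional[Mapping[str, np.ndarray]] = None,
) -> None:
    n, nt = len(nodes), len(tris)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspinedyn meridian mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for r, z in nodes:
            fh.write(f"{r:.9g} 0 {z:.9g}\n")
        fh.write(f"\nCELLS {nt} {4 * nt}\n")
        for a, b, c in tris:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"\nCELL_TYPES {nt}\n")
        fh.write("\n".join(["5"] * nt) + "\n")
        if point_data:
            fh.write(f"\nPOINT_DATA {n}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in np.asarray(vals)) + "\n")
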