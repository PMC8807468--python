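"""Output writers: legacy ASCII VTK unstructured grids and CSV traces."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Mesh


def write_vtk(path: str | os.PathLike, mesh: Mesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and optional nodal/cell fields as a legacy ASCII VTK
    unstructured grid (readable by ParaView and friends)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n, m = mesh.n_nodes, mesh.n_cells
    lines = [
        "# vtk DataFile Version 3.0",
        "dissectsim snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9e} {y:.9e} 0.0")
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.tris:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)  # VTK_TRIANGLE

    def emit_fields(data: dict[str, np.ndarray]) -> None:
        for name, f in data.items():
            f = np.asarray(f)
            if f.ndim == 2 and f.shape[1] == 2:
                lines.append(f"VECTORS {name} double")
                for vx, vy in f:
                    lines.append(f"{vx:.9e} {vy:.9e} 0.0")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9e}" for v in f)

    if point_data:
        lines.append(f"POINT_DATA {n}")
        emit_fields(point_data)
    if cell_data:
        lines.append(f"CELL_DATA {m}")
        emit_fields(cell_data)
    path.write_text("\n".join(lines) + "\n")


def write_csv(path: str | os.PathLike, rows: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
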