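"""Plain-text exports: scalar time series CSV and legacy-VTK snapshots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .solver import SimulationResult

__all__ = ["write_series_csv", "write_vtk_series"]


def write_series_csv(result: SimulationResult, path: str | Path) -> None:
    """Scalar summaries (time, volume, radii, wall pressures) as CSV."""
    result.series.to_csv(path, index=False)


def write_vtk_series(result: SimulationResult, directory: str | Path,
                     basename: str = "snapshot") -> list[Path]:
    """Write each snapshot as a legacy-ASCII VTK polyline along the radius.

    One file per snapshot (``<basename>_NNN.vtk``) with all nodal scalar
    fields as point data; viewable in ParaView as a time series.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, snap in enumerate(result.snapshots):
        r = snap["r_m"]
        n = len(r)
        lines = [
            "# vtk DataFile Version 3.0",
            f"radial snapshot t={snap['time_s']:.1f}s",
            "ASCII",
            "DATASET POLYDATA",
            f"POINTS {n} double",
        ]
        lines += [f"{x:.9e} 0 0" for x in r]
        lines.append(f"LINES 1 {n + 1}")
        lines.append(" ".join([str(n)] + [str(j) for j in range(n)]))
        lines.append(f"POINT_DATA {n}")
        for name in ("p_l", "p_tl", "omega_nl", "S_t", "omega_Nt",
                     "omega_grow", "eps"):
            vals = np.asarray(snap[name])
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9e}" for v in vals]
        path = directory / f"{basename}_{i:03d}.vtk"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
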