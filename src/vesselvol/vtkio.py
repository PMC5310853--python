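"""Minimal VTK legacy ASCII polydata writer/reader for centerline export.

Only the subset needed for polylines with point scalars (POINTS, LINES,
POINT_DATA/SCALARS) is supported — enough for any VTK-aware viewer
(ParaView, 3D Slicer) to render color-coded centerlines.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError


def write_vtk_polylines(path, points: np.ndarray, lines: list[list[int]], scalars: dict) -> None:
    """Write polylines as VTK legacy ASCII polydata.

    Parameters
    ----------
    points : (N, 3) array of physical coordinates.
    lines : list of point-index sequences, one per polyline.
    scalars : mapping of scalar name -> (N,) per-point values.
    """
    points = np.asarray(points, float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("vesselvol centerline export\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(i) for i in [len(l), *l]) + "\n")
        if scalars:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, values in scalars.items():
                values = np.asarray(values, float)
                if len(values) != len(points):
                    raise FormatError(f"scalar {name!r} length {len(values)} != {len(points)} points")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in values:
                    fh.write(f"{v:.9g}\n")


def read_vtk_polylines(path):
    """Parse a file written by :func:`write_vtk_polylines`.

    Returns (points, lines, scalars) with the same shapes as the writer's
    arguments. Intended for round-trip checks, not as a general VTK reader.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    points, lines, scalars = None, [], {}
    try:
        for line in it:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "POINTS":
                n = int(parts[1])
                points = np.array([next(it).split() for _ in range(n)], dtype=float)
            elif parts[0] == "LINES":
                n_lines = int(parts[1])
                for _ in range(n_lines):
                    row = [int(t) for t in next(it).split()]
                    if row[0] != len(row) - 1:
                        raise FormatError("malformed LINES row")
                    lines.append(row[1:])
            elif parts[0] == "SCALARS":
                name = parts[1]
                next(it)  # LOOKUP_TABLE line
                scalars[name] = np.array([float(next(it)) for _ in range(len(points))])
    except (StopIteration, ValueError, IndexError) as exc:
        raise FormatError(f"cannot parse VTK polydata {path}: {exc}") from exc
    if points is None:
        raise FormatError(f"no POINTS section in {path}")
    return points, lines, scalars
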