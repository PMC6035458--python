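"""Readers/writers for the plain-text interchange formats.

Slice-contour format (one slice per block)::

    # rsdmtox contours v1
    spacing 2.5
    z 0.0
    12.0 -3.5
    ...
    z 2.5
    ...

PLY (ASCII) carries meshes, with per-vertex dose and slice index stored as
named scalar properties. Dose grids are a JSON header (shape/origin/spacing)
next to a whitespace-separated value file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import ContourError, ContourStack, DoseGrid, Slice, SurfaceMesh

_FMT = "%.9g"


def write_contours(stack: ContourStack, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# rsdmtox contours v1\n")
        fh.write(f"spacing {_FMT % stack.slice_spacing}\n")
        for s in stack.slices:
            fh.write(f"z {_FMT % s.z}\n")
            for x, y in s.points:
                fh.write(f"{_FMT % x} {_FMT % y}\n")


def read_contours(path: str | Path) -> ContourStack:
    path = Path(path)
    spacing = None
    slices: list[Slice] = []
    z, pts = None, []

    def flush() -> None:
        if z is not None:
            if len(pts) < 3:
                raise ContourError(
                    f"{path.name}: slice at z={z} has <3 points")
            slices.append(Slice(z, np.asarray(pts)))

    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if tok[0] == "spacing":
            spacing = float(tok[1])
        elif tok[0] == "z":
            flush()
            z, pts = float(tok[1]), []
        else:
            if z is None:
                raise ContourError(f"{path.name}:{lineno}: point before z")
            if len(tok) != 2:
                raise ContourError(f"{path.name}:{lineno}: expected 'x y'")
            pts.append([float(tok[0]), float(tok[1])])
    flush()
    if not slices:
        raise ContourError(f"{path.name}: no slices found")
    if spacing is None:
        zs = [s.z for s in slices]
        spacing = float(np.median(np.diff(zs))) if len(zs) > 1 else 1.0
    return ContourStack(slices, spacing)


# ---------------------------------------------------------------------------
# PLY


def write_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    has_dose = mesh.vertex_dose is not None
    has_slice = mesh.vertex_slice is not None
    with path.open("w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if has_dose:
            fh.write("property double dose\n")
        if has_slice:
            fh.write("property int slice\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i in range(mesh.n_vertices):
            row = [_FMT % v for v in mesh.vertices[i]]
            if has_dose:
                row.append(_FMT % mesh.vertex_dose[i])
            if has_slice:
                row.append(str(int(mesh.vertex_slice[i])))
            fh.write(" ".join(row) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path: str | Path) -> SurfaceMesh:
    lines = Path(path).read_text().splitlines()
    if lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    props: list[str] = []
    i = 1
    element = None
    while lines[i].strip() != "end_header":
        tok = lines[i].split()
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex":
            props.append(tok[-1])
        i += 1
    i += 1
    data = np.array([lines[i + k].split() for k in range(n_vert)], dtype=float)
    cols = {p: j for j, p in enumerate(props)}
    vertices = data[:, [cols["x"], cols["y"], cols["z"]]]
    dose = data[:, cols["dose"]] if "dose" in cols else None
    vslice = data[:, cols["slice"]].astype(int) if "slice" in cols else None
    i += n_vert
    faces = []
    for k in range(n_face):
        tok = lines[i + k].split()
        if tok[0] != "3":
            raise ValueError(f"{path}: only triangle faces supported")
        faces.append([int(t) for t in tok[1:4]])
    return SurfaceMesh(vertices, np.asarray(faces, dtype=int),
                       vertex_dose=dose, vertex_slice=vslice)


def write_obj(mesh: SurfaceMesh, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {_FMT % v[0]} {_FMT % v[1]} {_FMT % v[2]}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# dose grids


def write_dose_grid(grid: DoseGrid, base: str | Path) -> None:
    base = Path(base)
    header = {
        "shape": list(grid.values.shape),
        "origin": grid.origin.tolist(),
        "spacing": grid.spacing.tolist(),
        "is_eqd2": grid.is_eqd2,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(base.with_suffix(".txt"), grid.values.ravel(), fmt=_FMT)


def read_dose_grid(base: str | Path) -> DoseGrid:
    base = Path(base)
    header = json.loads(base.with_suffix(".json").read_text())
    values = np.loadtxt(base.with_suffix(".txt")).reshape(header["shape"])
    return DoseGrid(values, np.asarray(header["origin"]),
                    np.asarray(header["spacing"]),
                    is_eqd2=header.get("is_eqd2", False))
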