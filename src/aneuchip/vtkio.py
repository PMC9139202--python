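"""Legacy-VTK rectilinear-grid I/O (ASCII).

Fields live on uniform Cartesian grids, so the natural interchange
format is a VTK ``RECTILINEAR_GRID`` dataset with cell data, which
ParaView and VisIt open directly.  Only the small subset needed by this
pipeline is implemented: ASCII files, cell-centered SCALARS/VECTORS,
2-D grids written as single-cell-thick 3-D grids.  Files written by
:func:`write_rectilinear` are re-read losslessly (up to float formatting)
by :func:`read_rectilinear`.
"""

from __future__ import annotations

import numpy as np

from .errors import UsageError

__all__ = ["write_rectilinear", "read_rectilinear"]

_FMT = "%.9e"


def write_rectilinear(
    path: str,
    spacing: float,
    origin: tuple,
    cell_data: dict[str, np.ndarray],
    title: str = "aneuchip field",
) -> None:
    """Write cell-centered fields on a uniform grid.

    Scalar fields have the grid's shape; vector fields have one extra
    trailing axis of length 2 or 3 (2-D vectors are padded with a zero
    z component).
    """
    if not cell_data:
        raise UsageError("cell_data must contain at least one field")
    first = np.asarray(next(iter(cell_data.values())))
    shape = _grid_shape(first)
    dim = len(shape)
    if dim not in (2, 3):
        raise UsageError("only 2-D and 3-D grids are supported")
    full = tuple(shape) + (1,) * (3 - dim)
    origin3 = tuple(origin) + (0.0,) * (3 - dim)

    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {full[0] + 1} {full[1] + 1} {full[2] + 1}",
    ]
    for ax, name in enumerate(("X", "Y", "Z")):
        coords = origin3[ax] + np.arange(full[ax] + 1) * spacing
        lines.append(f"{name}_COORDINATES {full[ax] + 1} double")
        lines.append(" ".join(_FMT % c for c in coords))
    ncell = int(np.prod(full))
    lines.append(f"CELL_DATA {ncell}")
    for name, arr in cell_data.items():
        arr = np.asarray(arr, dtype=float)
        if _grid_shape(arr) != tuple(shape):
            raise UsageError(f"field '{name}' does not match the grid shape")
        if arr.ndim == dim:  # scalar
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.reshape(full, order="C").ravel(order="F")
            lines.append("\n".join(_FMT % v for v in flat))
        else:  # vector
            ncomp = arr.shape[-1]
            vec = np.zeros(tuple(shape) + (3,))
            vec[..., :ncomp] = arr
            lines.append(f"VECTORS {name} double")
            # rows must be in VTK's x-fastest cell order
            flat = vec.reshape((-1, 3), order="C")[_fortran_order_index(full)]
            lines.append("\n".join(" ".join(_FMT % c for c in row) for row in flat))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _grid_shape(arr: np.ndarray) -> tuple:
    """Grid shape of a scalar (ndim axes) or vector (ndim+1 axes, last
    axis length 2 or 3) cell array."""
    if arr.ndim in (2, 3) and (arr.ndim == 2 or arr.shape[-1] not in (2, 3)):
        return tuple(arr.shape)
    if arr.ndim in (3, 4) and arr.shape[-1] in (2, 3):
        return tuple(arr.shape[:-1])
    raise UsageError(f"cannot infer grid shape from array of shape {arr.shape}")


def _fortran_order_index(full: tuple) -> np.ndarray:
    """Row order mapping C-ravelled cells to VTK's x-fastest ordering."""
    idx = np.arange(int(np.prod(full))).reshape(full, order="C")
    return idx.ravel(order="F")


def read_rectilinear(path: str) -> dict:
    """Read a file written by :func:`write_rectilinear`.

    Returns ``{"spacing", "origin", "shape", "cell_data"}`` with arrays
    restored to their original (2-D or 3-D, scalar or vector) shapes.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(tokens)

    def until(word):
        for tok in it:
            if tok == word:
                return
        raise UsageError(f"malformed VTK file: '{word}' not found")

    until("DIMENSIONS")
    npts = [int(next(it)) for _ in range(3)]
    full = tuple(n - 1 for n in npts)
    coords = []
    for name in ("X", "Y", "Z"):
        until(f"{name}_COORDINATES")
        n = int(next(it))
        next(it)  # dtype
        coords.append(np.array([float(next(it)) for _ in range(n)]))
    spacing = float(coords[0][1] - coords[0][0]) if len(coords[0]) > 1 else 1.0
    dim = 3 if full[2] > 1 else 2
    origin = tuple(c[0] for c in coords[:dim])
    shape = full[:dim]

    until("CELL_DATA")
    ncell = int(next(it))
    cell_data = {}
    rev = _fortran_order_index(full)
    inv = np.empty_like(rev)
    inv[rev] = np.arange(len(rev))
    while True:
        try:
            kind = next(it)
        except StopIteration:
            break
        if kind == "SCALARS":
            name = next(it)
            next(it)  # dtype
            next(it)  # ncomp
            next(it), next(it)  # LOOKUP_TABLE default
            vals = np.array([float(next(it)) for _ in range(ncell)])
            arr = vals[inv].reshape(full, order="C").reshape(shape)
            cell_data[name] = arr
        elif kind == "VECTORS":
            name = next(it)
            next(it)  # dtype
            vals = np.array([float(next(it)) for _ in range(3 * ncell)]).reshape(-1, 3)
            arr = vals[inv].reshape(full + (3,), order="C").reshape(shape + (3,))
            cell_data[name] = arr[..., :dim] if dim == 2 else arr
        else:
            continue
    return {"spacing": spacing, "origin": origin, "shape": shape, "cell_data": cell_data}
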