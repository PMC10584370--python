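"""File formats: parameter JSON, grid CSV/JSON bundles, images, traces.

Grids travel as a JSON manifest plus CSV matrices (labels, fiber angles,
region map) so every artifact stays plain text; images are accepted as
NIfTI (via nibabel), PNG (via imageio) or CSV matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .tissue import TissueGrid

__all__ = [
    "save_grid", "load_grid", "load_image", "save_csv_matrix",
    "load_csv_matrix", "save_trace_csv",
]


def save_csv_matrix(path, arr, fmt="%.6g", header: str = "") -> None:
    np.savetxt(path, np.asarray(arr), delimiter=",", fmt=fmt,
               header=header, comments="# ")


def load_csv_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def save_grid(grid: TissueGrid, path) -> None:
    """Write a grid as <path>.json plus CSV matrices next to it."""
    path = Path(path)
    stem = path.with_suffix("")
    files = {}
    for name, arr, fmt in (("labels", grid.labels, "%d"),
                           ("fiber_angle", grid.fiber_angle, "%.6g"),
                           ("region_map", grid.region_map, "%d")):
        if arr is None:
            continue
        f = f"{stem.name}_{name}.csv"
        save_csv_matrix(stem.parent / f, arr, fmt=fmt,
                        header=f"{name}; spacing_um={grid.dx}")
        files[name] = f
    manifest = {
        "dx_um": grid.dx,
        "shape": list(grid.shape),
        "files": files,
        "pacing_sites": {k: list(v) for k, v in grid.pacing_sites.items()},
    }
    path.write_text(json.dumps(manifest, indent=1))


def load_grid(path) -> TissueGrid:
    path = Path(path)
    manifest = json.loads(path.read_text())
    base = path.parent
    labels = load_csv_matrix(base / manifest["files"]["labels"])
    fiber = load_csv_matrix(base / manifest["files"]["fiber_angle"])
    region = None
    if "region_map" in manifest["files"]:
        region = load_csv_matrix(base / manifest["files"]["region_map"])
    g = TissueGrid(labels, fiber, manifest["dx_um"], region_map=region)
    g.pacing_sites = {k: tuple(v) for k, v in manifest["pacing_sites"].items()}
    return g


def load_image(path) -> np.ndarray:
    """Grayscale image from NIfTI, PNG/TIFF or CSV."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64).squeeze()
    if suffix.endswith(".csv"):
        return load_csv_matrix(path)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.float64)


def save_trace_csv(path, t, V, Cai=None, currents=None,
                   current_names=None) -> None:
    """Single-cell trace CSV with units in the header."""
    cols = [("t_ms", t), ("V_mV", V)]
    if Cai is not None:
        cols.append(("Cai_mM", Cai))
    if currents is not None and current_names:
        for i, n in enumerate(current_names):
            cols.append((f"{n}_pApF", currents[:, i]))
    header = ",".join(n for n, _ in cols)
    data = np.column_stack([c for _, c in cols])
    np.savetxt(path, data, delimiter=",", header=header, comments="")
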