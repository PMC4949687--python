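"""File I/O: GIFTI surfaces and functional maps, label masks, sidecars.

Surfaces and per-vertex maps travel as GIFTI (ASCII encoding, so files
stay plain text); vertex masks as label files with one 0-based vertex
index per line, or a JSON dialect carrying a name plus indices; run
metadata as JSON sidecars next to the functional file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .mesh import TriangleMesh
from .phase import ComplexMap, PhaseEncodedDesign, VertexTimeSeries

_ASCII = "ASCII"


def save_mesh_gifti(mesh: TriangleMesh, path) -> None:
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET",
        encoding=_ASCII,
    )
    faces = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE",
        encoding=_ASCII,
    )
    nib.gifti.GiftiImage(darrays=[coords, faces]).to_filename(str(path))


def load_mesh_gifti(path) -> TriangleMesh:
    img = nib.load(str(path))
    coords = faces = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = da.data
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = da.data
    if coords is None or faces is None:
        raise ValueError(f"{path} lacks pointset/triangle arrays")
    return TriangleMesh(coords, faces)


def save_scalar_gifti(values: np.ndarray, path) -> None:
    """Per-vertex map(s); a 2-D array becomes one data array per column."""
    values = np.asarray(values, dtype=np.float32)
    cols = values[:, None] if values.ndim == 1 else values
    darrays = [
        nib.gifti.GiftiDataArray(
            np.ascontiguousarray(cols[:, i]), intent="NIFTI_INTENT_NONE",
            encoding=_ASCII,
        )
        for i in range(cols.shape[1])
    ]
    nib.gifti.GiftiImage(darrays=darrays).to_filename(str(path))


def load_scalar_gifti(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.column_stack([da.data for da in img.darrays])
    return data[:, 0] if data.shape[1] == 1 else data


def save_complex_map_gifti(cmap: ComplexMap, path) -> None:
    """Complex map as two GIFTI arrays: real then imaginary."""
    save_scalar_gifti(
        np.column_stack([cmap.values.real, cmap.values.imag]), path
    )


def load_complex_map_gifti(path) -> ComplexMap:
    data = load_scalar_gifti(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path} is not a two-array (real, imag) file")
    return ComplexMap(data[:, 0] + 1j * data[:, 1])


def save_timeseries_gifti(ts: VertexTimeSeries, path) -> None:
    """Run data as a GIFTI (one array per time point) + JSON sidecar."""
    save_scalar_gifti(ts.data.T.astype(np.float32).T, path)
    d = ts.design
    sidecar = {
        "tr": d.tr, "cycles_per_run": d.cycles_per_run,
        "direction": d.direction, "modality": d.modality,
        "n_samples": d.n_samples,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_timeseries_gifti(path) -> VertexTimeSeries:
    data = load_scalar_gifti(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    design = PhaseEncodedDesign(
        meta["n_samples"], meta["tr"], meta["cycles_per_run"],
        meta["direction"], meta["modality"],
    )
    return VertexTimeSeries(data, design)


def save_label(mask, path, name: str | None = None) -> None:
    """Vertex mask: plain text (one index per line) or JSON when named."""
    idx = sorted(int(i) for i in mask)
    if name is None:
        Path(path).write_text("\n".join(str(i) for i in idx) + "\n")
    else:
        Path(path).write_text(json.dumps({"name": name, "indices": idx}, indent=1))


def load_label(path) -> set[int]:
    text = Path(path).read_text().strip()
    if text.startswith("{"):
        return set(int(i) for i in json.loads(text)["indices"])
    return set(int(line) for line in text.splitlines() if line.strip())
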