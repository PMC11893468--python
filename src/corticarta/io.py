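"""Reading and writing the pipeline's on-disk formats.

Surfaces go to GIFTI (one ``.surf.gii`` per hemisphere and surface, via
nibabel); matrices — profiles, connectomes, timeseries, embeddings — go to
TSV; ground truth and run configuration go to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import CorticalSheet
from .synthetic import GroundTruth

__all__ = [
    "save_sheet",
    "load_sheet",
    "save_matrix_tsv",
    "load_matrix_tsv",
    "save_ground_truth",
    "load_ground_truth",
]


def _gifti_surface(vertices: np.ndarray, faces: np.ndarray) -> nib.gifti.GiftiImage:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
    )
    return img


def save_sheet(sheet: CorticalSheet, directory) -> None:
    """Write a cortical sheet as per-hemisphere GIFTI surfaces plus JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for label in ("L", "R"):
        idx = np.flatnonzero(sheet.hemisphere == label)
        pos = np.full(sheet.n_vertices, -1, dtype=int)
        pos[idx] = np.arange(idx.size)
        in_hemi = np.all(np.isin(sheet.faces, idx), axis=1)
        faces = pos[sheet.faces[in_hemi]]
        for name, verts in (
            ("outer", sheet.outer_vertices[idx]),
            ("inner", sheet.inner_vertices[idx]),
            ("sphere", sheet.sphere_coordinates[idx]),
        ):
            nib.save(_gifti_surface(verts, faces), directory / f"{label}.{name}.surf.gii")
    meta = {
        "hemisphere_counts": {
            "L": int((sheet.hemisphere == "L").sum()),
            "R": int((sheet.hemisphere == "R").sum()),
        },
        "hemisphere_centers": {k: list(map(float, v)) for k, v in sheet.hemisphere_centers.items()},
    }
    (directory / "sheet.json").write_text(json.dumps(meta))


def load_sheet(directory) -> CorticalSheet:
    directory = Path(directory)
    meta = json.loads((directory / "sheet.json").read_text())
    outer, inner, sphere, hemis, faces = [], [], [], [], []
    offset = 0
    for label in ("L", "R"):
        parts = {}
        for name in ("outer", "inner", "sphere"):
            img = nib.load(directory / f"{label}.{name}.surf.gii")
            parts[name] = (
                img.darrays[0].data.astype(float),
                img.darrays[1].data.astype(int),
            )
        n = parts["outer"][0].shape[0]
        outer.append(parts["outer"][0])
        inner.append(parts["inner"][0])
        sphere.append(parts["sphere"][0])
        hemis.append(np.full(n, label))
        faces.append(parts["outer"][1] + offset)
        offset += n
    centers = {k: np.asarray(v) for k, v in meta["hemisphere_centers"].items()}
    sph = np.vstack(sphere)
    sph /= np.linalg.norm(sph, axis=1, keepdims=True)  # undo float32 rounding
    return CorticalSheet(
        outer_vertices=np.vstack(outer),
        inner_vertices=np.vstack(inner),
        faces=np.vstack(faces),
        sphere_coordinates=sph,
        hemisphere=np.concatenate(hemis),
        hemisphere_centers=centers,
    )


def save_matrix_tsv(matrix: np.ndarray, path, index=None, columns=None) -> None:
    """Write a 2D array as TSV (rows x columns, e.g. depths x vertices)."""
    df = pd.DataFrame(np.asarray(matrix), index=index, columns=columns)
    df.to_csv(path, sep="\t", index=index is not None)


def load_matrix_tsv(path, has_index: bool = False) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0 if has_index else None)
    return df.to_numpy(dtype=float)


def save_ground_truth(gt: GroundTruth, path) -> None:
    Path(path).write_text(gt.to_json())


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
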