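"""Reading and writing the pipeline's on-disk formats.

Volumes travel as NIfTI-1 with the voxel spacing in the affine (written
as a diagonal scaling plus origin translation) and the frame interval in
a JSON sidecar; masks as uint8 NIfTI; markers as a small JSON file of
voxel indices; paths, delays and ground truth as CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import CenterlinePath, MarkerSet, VesselMask
from .preprocess import DynamicCTA, Volume3D


def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_dynamic(dyn: DynamicCTA, path, sidecar_path=None) -> None:
    img = nib.Nifti1Image(dyn.data.astype(np.float32),
                          _affine(dyn.spacing, dyn.origin))
    img.header.set_zooms(dyn.spacing + (dyn.dt,))
    nib.save(img, str(path))
    if sidecar_path is None:
        sidecar_path = Path(str(path).replace(".nii.gz", "").replace(".nii", "")
                            + ".json")
    with open(sidecar_path, "w") as fh:
        json.dump({"dt_s": dyn.dt, "origin_mm": list(dyn.origin)}, fh,
                  indent=2, sort_keys=True)


def load_dynamic(path, sidecar_path=None, dt=None) -> DynamicCTA:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if dt is None:
        if sidecar_path is None:
            cand = Path(str(path).replace(".nii.gz", "").replace(".nii", "")
                        + ".json")
            sidecar_path = cand if cand.exists() else None
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta = json.load(fh)
            dt = float(meta["dt_s"])
            origin = tuple(meta.get("origin_mm", origin))
        elif len(zooms) > 3 and zooms[3] > 0:
            dt = float(zooms[3])
        else:
            raise ValueError(f"{path}: frame interval unknown; provide a "
                             "sidecar JSON with 'dt_s' or pass dt")
    return DynamicCTA(data, spacing, dt, origin)


def save_mask(mask: VesselMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def load_mask(path) -> VesselMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VesselMask(data > 0, tuple(float(z) for z in zooms[:3]), origin)


def save_volume(vol: Volume3D, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32),
                          _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def load_markers(path) -> MarkerSet:
    with open(path) as fh:
        d = json.load(fh)
    try:
        return MarkerSet(d["proximal"], d["thrombus"], d["distal"])
    except KeyError as exc:
        raise ValueError(f"{path}: markers file is missing key {exc}")


def save_markers(markers: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(markers, fh, indent=2, sort_keys=True)


def paths_to_frame(paths) -> pd.DataFrame:
    rows = []
    for p in paths:
        for ordinal, (voxel, arc, label, seg) in enumerate(
                zip(p.voxels, p.arclength_mm, p.labels, p.segment_ids)):
            rows.append({"path_id": p.path_id, "ordinal": ordinal,
                         "i": voxel[0], "j": voxel[1], "k": voxel[2],
                         "arclength_mm": arc, "label": label,
                         "segment_id": seg})
    return pd.DataFrame(rows)


def truth_to_frame(truth) -> pd.DataFrame:
    rows = []
    for entry in truth:
        for p, arc, root, arr in zip(entry["points_mm"],
                                     entry["arclength_mm"],
                                     entry["root_mm"], entry["arrival_s"]):
            rows.append({"segment": entry["segment"],
                         "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                         "arclength_mm": arc, "root_mm": root,
                         "arrival_s": arr,
                         "velocity_mm_s": entry["velocity_mm_s"]})
    return pd.DataFrame(rows)
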