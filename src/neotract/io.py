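"""File I/O: NIfTI volumes, FSL gradient tables, .trk/.tck streamlines,
YAML protocol files, and machine-readable run logs.

Volumes are NIfTI-1 via nibabel and are reoriented to the closest canonical
(RAS-like) axis layout on load, with the reorientation logged, so the
plane conventions of the ROI module (sagittal = axis 0, coronal = axis 1,
axial = axis 2) hold regardless of on-disk orientation.  Streamlines go
through nibabel's TrackVis (.trk) and MRtrix (.tck) writers; .tck
round-trips bit-identically at float32 storage precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .roi import Roi, TractProtocol
from .tensor import DiffusionTensorVolume, DwiVolume, GradientScheme
from .tracking import Streamline, Tractogram, TrackingParams

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- gradients

def load_gradients(bvec_path, bval_path, dialect: str = "fsl"
                   ) -> GradientScheme:
    """Read a gradient table.

    ``fsl`` dialect: bvec is 3 rows x n columns, bval one row of n values.
    ``columns`` dialect: bvec is n rows x 3 columns, bval one value per line.
    """
    bvec = np.loadtxt(bvec_path)
    bval = np.loadtxt(bval_path).ravel()
    if dialect == "fsl":
        if bvec.shape[0] != 3:
            raise ValueError(f"FSL bvec must have 3 rows, got {bvec.shape}")
        directions = bvec.T
    elif dialect == "columns":
        if bvec.ndim != 2 or bvec.shape[1] != 3:
            raise ValueError(f"columns bvec must be (n, 3), got {bvec.shape}")
        directions = bvec
    else:
        raise ValueError(f"unknown gradient dialect {dialect!r}")
    return GradientScheme(directions=directions, b_values=bval)


def save_gradients(scheme: GradientScheme, bvec_path, bval_path,
                   dialect: str = "fsl") -> None:
    if dialect == "fsl":
        np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")
    elif dialect == "columns":
        np.savetxt(bvec_path, scheme.directions, fmt="%.8f")
    else:
        raise ValueError(f"unknown gradient dialect {dialect!r}")
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.1f")


# ------------------------------------------------------------------ volumes

def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    canonical = nib.as_closest_canonical(img)
    if canonical is not img:
        ornt = "".join(nib.aff2axcodes(img.affine))
        log.info("reoriented volume from %s to canonical RAS", ornt)
    return canonical


def load_dwi(path, scheme: GradientScheme) -> DwiVolume:
    """Load a 4-D DWI NIfTI and bind it to its gradient scheme."""
    img = _canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D DWI, got shape {data.shape}")
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"DWI has {data.shape[3]} volumes but gradient table has "
            f"{len(scheme)} entries")
    return DwiVolume(signal=data, affine=img.affine, scheme=scheme)


def load_tensor(path, mask_path=None) -> DiffusionTensorVolume:
    """Load a 6-volume tensor NIfTI (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)."""
    img = _canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError(
            f"expected a 6-volume tensor image, got shape {data.shape}")
    if mask_path is not None:
        mimg = _canonical(nib.load(str(mask_path)))
        mask = np.asarray(mimg.dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return DiffusionTensorVolume(tensor=data, affine=img.affine, mask=mask)


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def load_scalar(path) -> tuple[np.ndarray, np.ndarray]:
    img = _canonical(nib.load(str(path)))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_tensor(vol: DiffusionTensorVolume, path, mask_path=None) -> None:
    save_volume(vol.tensor, vol.affine, path)
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine),
                 str(mask_path))


# -------------------------------------------------------------- streamlines

def save_tractogram(tractogram: Tractogram, path) -> None:
    """Write streamlines as .trk or .tck (by extension) in world mm."""
    path = str(path)
    sls = [sl.points for sl in tractogram.streamlines]
    t = nib.streamlines.Tractogram(sls, affine_to_rasmm=np.eye(4))
    if path.endswith(".trk"):
        header = {
            "voxel_to_rasmm": tractogram.affine.astype(np.float32),
            "voxel_sizes": np.linalg.norm(tractogram.affine[:3, :3],
                                          axis=0).astype(np.float32),
            "dimensions": np.asarray(tractogram.shape, dtype=np.int16),
        }
        nib.streamlines.save(t, path, header=header)
    elif path.endswith(".tck"):
        nib.streamlines.save(t, path)
    else:
        raise ValueError(f"unknown tractogram format for {path!r} "
                         "(use .trk or .tck)")


def load_streamlines(path) -> list[np.ndarray]:
    """Read a .trk/.tck file back to world-mm point arrays."""
    tfile = nib.streamlines.load(str(path))
    return [np.asarray(s) for s in tfile.tractogram.streamlines]


# ---------------------------------------------------------------- protocols

def _roi_from_dict(d: dict, where: str) -> Roi:
    try:
        kwargs = dict(
            shape=d["shape"], plane=d["plane"],
            slice_index=int(d["slice"]), op=d["op"],
            label=d.get("label", ""))
        if d["shape"] == "polygon":
            kwargs["vertices"] = np.asarray(d["vertices"], dtype=float)
        else:
            kwargs["center"] = tuple(d["center"])
            kwargs["width"] = float(d["width"])
            kwargs["height"] = float(d["height"])
        return Roi(**kwargs)
    except KeyError as e:
        raise ValueError(f"{where}: missing required ROI key {e}") from None


def protocol_from_dict(d: dict, where: str = "protocol") -> TractProtocol:
    for key in ("tract", "fa_start", "fa_stop", "max_angle", "rois"):
        if key not in d:
            raise ValueError(f"{where}: missing required key {key!r}")
    rois = [_roi_from_dict(r, f"{where}.rois[{i}]")
            for i, r in enumerate(d["rois"])]
    return TractProtocol(
        tract_name=d["tract"], fa_start=float(d["fa_start"]),
        fa_stop=float(d["fa_stop"]), max_angle=float(d["max_angle"]),
        rois=rois, min_points=int(d.get("min_points", 2)))


def load_protocol(path) -> TractProtocol:
    """Load one tract protocol from a YAML/JSON file, with validation."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return protocol_from_dict(d, where=str(path))


def default_registry_path() -> Path:
    return Path(__file__).parent / "data" / "tract_registry.yaml"


def load_registry_file(path=None) -> dict:
    """The shipped per-tract thresholds/angles/ROI-plan YAML."""
    with open(path or default_registry_path()) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------- run logs

def write_run_log(path, *, command: str, params: dict, seed=None) -> None:
    """Machine-readable sidecar: toolkit version, command, parameters."""
    record = {"tool": "neotract", "version": __version__,
              "command": command, "seed": seed, "params": params}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
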