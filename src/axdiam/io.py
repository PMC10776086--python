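"""NIfTI and sidecar I/O for diffusion volumes and parameter maps."""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np

from .scheme import AcquisitionScheme, read_scheme, scheme_paths, write_scheme


def read_dwi(path_nifti, path_bval, path_bvec, path_bdelta):
    """Load a 4D diffusion volume plus its acquisition scheme.

    b-values are converted from s/mm^2 to the internal ms/um^2; the b0 mask
    uses the 50 s/mm^2 threshold.  Gradient directions are taken to be in the
    image frame.  Returns (data 4D array, scheme, nibabel image).
    """
    for p in (path_nifti, path_bval, path_bvec, path_bdelta):
        if not os.path.exists(p):
            raise FileNotFoundError(f"input file not found: {p}")
    img = nib.load(path_nifti)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    scheme = read_scheme(path_bval, path_bvec, path_bdelta)
    if scheme.n_meas != data.shape[3]:
        raise ValueError(
            f"scheme lists {scheme.n_meas} measurements but volume has "
            f"{data.shape[3]} frames"
        )
    dw = ~scheme.b0_mask
    zero = np.linalg.norm(scheme.bvecs, axis=1) < 1e-12
    bad = np.nonzero(dw & zero)[0]
    if bad.size:
        raise ValueError(f"zero gradient vector at diffusion-weighted index {bad[0]}")
    return data, scheme, img


def write_dwi(data, scheme: AcquisitionScheme, out_prefix, affine=None):
    """Write a 4D volume with bval/bvec/bdelta sidecars next to it."""
    affine = np.eye(4) if affine is None else affine
    nii_path = os.fspath(out_prefix) + ".nii"
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), nii_path)
    write_scheme(scheme, *scheme_paths(out_prefix))
    return nii_path


def write_maps(maps: dict, reference_img, out_dir, prefix="axdiam"):
    """Write one NIfTI per parameter map, copying the reference affine.

    ``maps`` is a name -> 3D array dict (NaN marks masked voxels).  Returns
    the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    if reference_img is not None:
        affine = reference_img.affine
        ref_shape = reference_img.shape[:3]
    else:
        affine, ref_shape = np.eye(4), None
    paths = {}
    for name, vol in maps.items():
        vol = np.asarray(vol, dtype=np.float32)
        if ref_shape is not None and vol.shape != tuple(ref_shape):
            raise ValueError(
                f"map {name!r} shape {vol.shape} does not match reference {ref_shape}"
            )
        path = os.path.join(out_dir, f"{prefix}_{name}.nii")
        nib.save(nib.Nifti1Image(vol, affine), path)
        paths[name] = path
    return paths


def write_provenance(out_dir, config: dict, seed=None):
    """Record the run configuration next to the outputs."""
    from . import __version__

    os.makedirs(out_dir, exist_ok=True)
    record = {"package": "axdiam", "version": __version__, "seed": seed, "config": config}
    path = os.path.join(out_dir, "provenance.json")
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return path
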