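"""NIfTI and delimited-text I/O with a fixed, documented voxel order.

Voxels are always extracted in ascending Fortran linear index order (i
fastest, then j, then k), and coordinates are voxel-centre world coordinates
in millimetres obtained through the image affine.  Matrices and tables are
read and written as UTF-8 delimited text with a header row; reports and
configurations as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .domain import VoxelDomain

__all__ = [
    "read_masked_volume",
    "domain_to_label_image",
    "write_label_volume",
    "write_matrix",
    "read_matrix",
    "write_json",
]


def _mask_order(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ijk indices of nonzero voxels in ascending Fortran linear order."""
    ijk = np.column_stack(np.nonzero(mask))
    lin = np.ravel_multi_index(ijk.T, mask.shape, order="F")
    order = np.argsort(lin, kind="stable")
    return ijk[order], lin[order]


def read_masked_volume(
    volume: str | Path,
    mask: str | Path,
) -> tuple[np.ndarray, VoxelDomain]:
    """Extract masked voxel values (or series) and build a VoxelDomain.

    The mask is read as a label volume: nonzero entries select voxels and
    their integer values become nucleus labels.  Hemisphere is assigned by
    the sign of the world x coordinate (negative = left).  For a 4-D volume
    the result is (n_voxels, n_volumes); for 3-D, (n_voxels,).
    """
    vol = nib.load(str(volume))
    msk = nib.load(str(mask))
    if vol.shape[:3] != msk.shape[:3]:
        raise ValueError("volume and mask grids differ")
    if not np.allclose(vol.affine, msk.affine, atol=1e-4):
        raise ValueError("volume and mask affines differ")
    mdata = np.asanyarray(msk.dataobj)
    if mdata.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not np.any(mdata):
        raise ValueError("mask is empty")
    ijk, _ = _mask_order(mdata != 0)
    vdata = np.asanyarray(vol.dataobj)
    if vdata.ndim == 3:
        values = vdata[ijk[:, 0], ijk[:, 1], ijk[:, 2]].astype(float)
    elif vdata.ndim == 4:
        values = vdata[ijk[:, 0], ijk[:, 1], ijk[:, 2], :].astype(float)
    else:
        raise ValueError("volume must be 3-D or 4-D")
    coords = nib.affines.apply_affine(msk.affine, ijk)
    labels = mdata[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    hemisphere = np.where(coords[:, 0] < 0, "left", "right")
    zooms = msk.header.get_zooms()[:3]
    domain = VoxelDomain(
        coords=coords,
        hemisphere=hemisphere,
        nucleus_label=np.array([str(int(v)) for v in labels]),
        voxel_size=float(zooms[0]),
    )
    return values, domain


def domain_to_label_image(
    domain: VoxelDomain,
    values: np.ndarray | None = None,
) -> nib.Nifti1Image:
    """Paint per-voxel values (default: nucleus index) into a NIfTI image.

    The grid is the tight bounding box of the domain at its voxel size, with
    an affine mapping voxel indices to the original world coordinates.
    """
    vs = domain.voxel_size
    ijk_f = (domain.coords - domain.coords.min(axis=0)) / vs
    ijk = np.rint(ijk_f).astype(int)
    if not np.allclose(ijk_f, ijk, atol=1e-6):
        raise ValueError("domain coordinates are not on a regular grid")
    shape = tuple(ijk.max(axis=0) + 1)
    if values is None:
        nuclei = domain.nuclei()
        lut = {name: i + 1 for i, name in enumerate(nuclei)}
        values = np.array([lut[n] for n in domain.nucleus_label], dtype=float)
    data = np.zeros(shape)
    data[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = values
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = domain.coords.min(axis=0)
    return nib.Nifti1Image(data, affine)


def write_label_volume(
    domain: VoxelDomain,
    path: str | Path,
    values: np.ndarray | None = None,
) -> None:
    nib.save(domain_to_label_image(domain, values), str(path))


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    columns: list | None = None,
    index_name: str = "voxel_id",
) -> None:
    """Write a matrix as tab-delimited text with a header row of feature ids."""
    values = np.atleast_2d(np.asarray(values))
    if columns is None:
        columns = [str(j + 1) for j in range(values.shape[1])]
    df = pd.DataFrame(values, columns=[str(c) for c in columns])
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
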