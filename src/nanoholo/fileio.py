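"""Volume readers/writers: multi-page TIFF and MHD/RAW.

TIFF stacks carry one slice per page and a JSON description tag with the
spacing (nm) and origin; MHD headers store the same in their native
key-value format (``ElementSpacing`` is written in nanometres).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import tifffile

from .volume import Volume3D

__all__ = ["FormatError", "read_volume", "write_volume"]


class FormatError(ValueError):
    """Unreadable, unsupported, or truncated volume file."""


_MHD_DTYPES = {
    "MET_UCHAR": np.uint8, "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16, "MET_SHORT": np.int16,
    "MET_UINT": np.uint32, "MET_INT": np.int32,
    "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
}
_MHD_NAMES = {np.dtype(v): k for k, v in _MHD_DTYPES.items()}


def write_volume(v: Volume3D, path) -> None:
    """Write a volume as ``.tif``/``.tiff`` stack or ``.mhd`` + ``.raw`` pair."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        meta = {"spacing_nm": v.spacing, "origin_nm": list(v.origin)}
        tifffile.imwrite(path, v.voxels, description=json.dumps(meta),
                         photometric="minisblack")
    elif suffix == ".mhd":
        dtype = np.dtype(v.voxels.dtype)
        if dtype not in _MHD_NAMES:
            raise FormatError(f"dtype {dtype} not supported by the MHD writer")
        raw_name = path.with_suffix(".raw").name
        nz, ny, nx = v.shape
        header = (
            "ObjectType = Image\n"
            "NDims = 3\n"
            "BinaryData = True\n"
            "BinaryDataByteOrderMSB = False\n"
            f"DimSize = {nx} {ny} {nz}\n"
            f"ElementSpacing = {v.spacing} {v.spacing} {v.spacing}\n"
            f"Offset = {v.origin[2]} {v.origin[1]} {v.origin[0]}\n"
            f"ElementType = {_MHD_NAMES[dtype]}\n"
            f"ElementDataFile = {raw_name}\n"
        )
        path.write_text(header)
        v.voxels.astype(dtype).tofile(path.with_suffix(".raw"))
    else:
        raise FormatError(f"unsupported volume format: {path.suffix!r}")


def _read_tiff(path: Path) -> Volume3D:
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    spacing, origin = 1.0, (0.0, 0.0, 0.0)
    try:
        meta = json.loads(desc)
        spacing = float(meta.get("spacing_nm", 1.0))
        origin = tuple(meta.get("origin_nm", origin))
    except (json.JSONDecodeError, TypeError, ValueError):
        pass  # foreign TIFF without our side-car metadata
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2D/3D TIFF, got ndim={data.ndim}")
    return Volume3D(data, spacing=spacing, origin=origin)


def _read_mhd(path: Path) -> Volume3D:
    try:
        fields = {}
        for line in path.read_text().splitlines():
            if "=" in line:
                key, val = line.split("=", 1)
                fields[key.strip()] = val.strip()
        dims = [int(x) for x in fields["DimSize"].split()]
        dtype = _MHD_DTYPES[fields["ElementType"]]
        spacing = float(fields["ElementSpacing"].split()[0])
        offset = [float(x) for x in fields.get("Offset", "0 0 0").split()]
        raw_path = path.parent / fields["ElementDataFile"]
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed MHD header {path}: {exc}") from exc
    expected = int(np.prod(dims)) * np.dtype(dtype).itemsize
    if not raw_path.exists():
        raise FormatError(f"raw file missing: {raw_path}")
    if os.path.getsize(raw_path) != expected:
        raise FormatError(
            f"raw file {raw_path} has {os.path.getsize(raw_path)} bytes, "
            f"expected {expected} (truncated or corrupt)")
    nx, ny, nz = dims
    data = np.fromfile(raw_path, dtype=dtype).reshape(nz, ny, nx)
    return Volume3D(data, spacing=spacing, origin=(offset[2], offset[1], offset[0]))


def read_volume(path) -> Volume3D:
    """Read a ``.tif``/``.tiff`` stack or ``.mhd``/``.raw`` pair losslessly."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path)
    if suffix == ".mhd":
        return _read_mhd(path)
    raise FormatError(f"unsupported volume format: {path.suffix!r}")
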