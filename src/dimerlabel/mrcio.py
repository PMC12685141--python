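"""Minimal MRC2014 volume/stack reader and writer.

Supports reading modes 0 (int8), 1 (int16) and 2 (float32) with byte-order
normalization, and writing mode 2 with the voxel size recorded in the cell
dimensions. Only the header fields the pipeline needs are interpreted; the
full 1024-byte header is preserved structurally on write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

HEADER_BYTES = 1024
_MODES = {0: np.int8, 1: np.int16, 2: np.float32}

_HEADER_DTYPE = np.dtype(
    [
        ("nx", "i4"), ("ny", "i4"), ("nz", "i4"),
        ("mode", "i4"),
        ("nxstart", "i4"), ("nystart", "i4"), ("nzstart", "i4"),
        ("mx", "i4"), ("my", "i4"), ("mz", "i4"),
        ("cella", "f4", 3), ("cellb", "f4", 3),
        ("mapc", "i4"), ("mapr", "i4"), ("maps", "i4"),
        ("dmin", "f4"), ("dmax", "f4"), ("dmean", "f4"),
        ("ispg", "i4"), ("nsymbt", "i4"),
        ("extra", "V100"),
        ("origin", "f4", 3),
        ("map", "S4"), ("machst", "u1", 4),
        ("rms", "f4"), ("nlabl", "i4"), ("labels", "S800"),
    ]
)
assert _HEADER_DTYPE.itemsize == HEADER_BYTES


class MRCParseError(ValueError):
    pass


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC2014 file; returns (data as (nz, ny, nx), voxel size A)."""
    raw = Path(path).read_bytes()
    if len(raw) < HEADER_BYTES:
        raise MRCParseError("file shorter than the 1024-byte MRC header")
    header = np.frombuffer(raw[:HEADER_BYTES], dtype=_HEADER_DTYPE)[0]
    if header["map"] not in (b"MAP ", b"MAP\x00"):
        raise MRCParseError(f"bad MAP identifier {header['map']!r}")
    swapped = False
    if not 0 <= int(header["mode"]) <= 101:
        header = header.byteswap()
        swapped = True
    mode = int(header["mode"])
    if mode not in _MODES:
        raise MRCParseError(f"unsupported mode {mode} (modes 0/1/2 are readable)")
    nx, ny, nz = (int(header[k]) for k in ("nx", "ny", "nz"))
    if min(nx, ny, nz) < 1:
        raise MRCParseError(f"non-positive dimensions nx={nx} ny={ny} nz={nz}")
    dtype = np.dtype(_MODES[mode])
    if swapped:
        dtype = dtype.newbyteorder()
    n_expected = nx * ny * nz
    offset = HEADER_BYTES + int(header["nsymbt"])
    n_available = (len(raw) - offset) // dtype.itemsize
    if n_available < n_expected:
        raise MRCParseError(
            f"truncated data block: expected {n_expected} voxels, found {n_available}"
        )
    data = np.frombuffer(raw, dtype=dtype, count=n_expected, offset=offset)
    data = data.reshape(nz, ny, nx)
    mx = int(header["mx"]) or nx
    voxel = float(header["cella"][0]) / mx if header["cella"][0] > 0 else 1.0
    return np.ascontiguousarray(data), voxel


def write_mrc(path: str | Path, data: np.ndarray, voxel_size: float) -> None:
    """Write a 2D image, 2D stack or 3D volume as MRC2014 mode 2 (float32)."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    nz, ny, nx = arr.shape
    header = np.zeros(1, dtype=_HEADER_DTYPE)[0]
    header["nx"], header["ny"], header["nz"] = nx, ny, nz
    header["mode"] = 2
    header["mx"], header["my"], header["mz"] = nx, ny, nz
    header["cella"] = np.array([nx, ny, nz], np.float32) * voxel_size
    header["cellb"] = (90.0, 90.0, 90.0)
    header["mapc"], header["mapr"], header["maps"] = 1, 2, 3
    header["dmin"], header["dmax"], header["dmean"] = (
        float(arr.min()),
        float(arr.max()),
        float(arr.mean()),
    )
    header["map"] = b"MAP "
    header["machst"] = (0x44, 0x44, 0x00, 0x00)  # little-endian stamp
    header["rms"] = float(arr.std())
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(arr).tobytes())
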