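"""Minimal MRC/MRCS reader and writer.

Implements the classic 1024-byte MRC2014-style header with no extended
header.  Movie stacks are stored as 3D volumes with frames along the
slowest (z) axis, column-fastest within each section.  Read supports
modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16); writing always
emits mode 2 so downstream consumers see a single float representation.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Tuple, Union

import numpy as np

__all__ = ["MRCFormatError", "read_mrc", "write_mrc"]

_HEADER_SIZE = 1024
_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


class MRCFormatError(IOError):
    """Raised when an MRC file cannot be parsed."""


def read_mrc(path: Union[str, Path]) -> Tuple[np.ndarray, float]:
    """Read an MRC/MRCS file.

    Returns ``(data, pixel_size)`` where ``data`` has shape (nz, ny, nx)
    (nz = 1 for single images is squeezed by callers as needed) and
    ``pixel_size`` is in Angstroms (0.0 if the header does not define
    a cell).  Raises :class:`MRCFormatError` on malformed or truncated
    files, reporting the byte offset at which parsing failed.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MRCFormatError(
            f"{path}: truncated header, {len(raw)} < {_HEADER_SIZE} bytes "
            f"(failed at byte offset {len(raw)})"
        )
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if min(nx, ny, nz) <= 0:
        raise MRCFormatError(
            f"{path}: non-positive dimensions ({nx}, {ny}, {nz}) in header "
            "(byte offset 0)"
        )
    dtype = _MODE_DTYPES.get(mode)
    if dtype is None:
        raise MRCFormatError(
            f"{path}: unsupported mode {mode} (byte offset 12); "
            f"supported modes are {sorted(_MODE_DTYPES)}"
        )
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if nsymbt < 0:
        raise MRCFormatError(f"{path}: negative nsymbt (byte offset 92)")
    data_offset = _HEADER_SIZE + nsymbt
    count = nx * ny * nz
    expected_end = data_offset + count * dtype.itemsize
    if len(raw) < expected_end:
        raise MRCFormatError(
            f"{path}: truncated data, file ends at byte {len(raw)} but "
            f"{nx}x{ny}x{nz} mode-{mode} sections require {expected_end} bytes"
        )
    data = np.frombuffer(
        raw, dtype=dtype, count=count, offset=data_offset
    ).reshape(nz, ny, nx)
    pixel_size = float(cella[0] / mx) if mx > 0 and cella[0] > 0 else 0.0
    return data.astype(np.float32), pixel_size


def write_mrc(
    path: Union[str, Path], data: np.ndarray, pixel_size: float
) -> None:
    """Write ``data`` as a mode-2 (float32) MRC file.

    2D input is written as a single section; 3D input as a stack with
    the first axis slowest.  ``pixel_size`` (A) defines the cell so a
    round trip through :func:`read_mrc` preserves both data and pixel
    size bit-exactly for float32 input.
    """
    arr = np.asarray(data, dtype="<f4")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D data, got shape {data.shape}")
    nz, ny, nx = arr.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    finite = arr[np.isfinite(arr)]
    dmin = float(finite.min()) if finite.size else 0.0
    dmax = float(finite.max()) if finite.size else 0.0
    dmean = float(finite.mean()) if finite.size else 0.0
    rms = float(finite.std()) if finite.size else 0.0
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<i", header, 88, 1 if nz == 1 else 0)  # ispg: image/stack
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, rms)
    struct.pack_into("<i", header, 220, 1)  # nlabl
    header[224:224 + 10] = b"doseweight"
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.tobytes())
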