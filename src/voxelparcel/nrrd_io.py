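"""Minimal NRRD reader/writer for integer label volumes.

Supports the subset of the NRRD format the package emits: 3-D integer
arrays stored with ``encoding: ascii`` (plain text, whitespace-separated
values in C order). This keeps label volumes human-readable and
diff-friendly while remaining loadable by standard NRRD tooling.
"""

from __future__ import annotations

import os

import numpy as np

_NRRD_MAGIC = "NRRD0004"

# NRRD type strings for the integer dtypes we write.
_DTYPE_TO_NRRD = {
    np.dtype(np.int8): "int8",
    np.dtype(np.int16): "int16",
    np.dtype(np.int32): "int32",
    np.dtype(np.int64): "int64",
    np.dtype(np.uint8): "uint8",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.uint32): "uint32",
    np.dtype(np.uint64): "uint64",
}
_NRRD_TO_DTYPE = {v: k for k, v in _DTYPE_TO_NRRD.items()}
# Common aliases permitted by the NRRD spec.
_NRRD_TO_DTYPE.update(
    {
        "signed char": np.dtype(np.int8),
        "uchar": np.dtype(np.uint8),
        "unsigned char": np.dtype(np.uint8),
        "short": np.dtype(np.int16),
        "unsigned short": np.dtype(np.uint16),
        "int": np.dtype(np.int32),
        "unsigned int": np.dtype(np.uint32),
        "long long": np.dtype(np.int64),
        "unsigned long long": np.dtype(np.uint64),
    }
)


def write_nrrd(path: str | os.PathLike, volume: np.ndarray) -> None:
    """Write an integer array as an ASCII-encoded NRRD file."""
    volume = np.asarray(volume)
    if volume.dtype not in _DTYPE_TO_NRRD:
        raise ValueError(f"unsupported dtype for NRRD label volume: {volume.dtype}")
    header = [
        _NRRD_MAGIC,
        "# label volume written by voxelparcel",
        f"type: {_DTYPE_TO_NRRD[volume.dtype]}",
        f"dimension: {volume.ndim}",
        "sizes: " + " ".join(str(s) for s in volume.shape),
        "encoding: ascii",
    ]
    flat = volume.ravel(order="C")
    with open(path, "w") as fh:
        fh.write("\n".join(header))
        fh.write("\n\n")
        # one row of values per line of the fastest axis for readability
        ncol = volume.shape[-1] if volume.ndim else 1
        for i in range(0, flat.size, ncol):
            fh.write(" ".join(str(v) for v in flat[i : i + ncol]))
            fh.write("\n")


def read_nrrd(path: str | os.PathLike) -> np.ndarray:
    """Read an ASCII-encoded NRRD file written by :func:`write_nrrd`."""
    with open(path) as fh:
        magic = fh.readline().strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file (bad magic {magic!r})")
        fields: dict[str, str] = {}
        for line in fh:
            line = line.rstrip("\n")
            if line == "":
                break  # blank line separates header from data
            if line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}: malformed NRRD header line {line!r}")
            key, _, value = line.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding", "").lower() not in ("ascii", "txt", "text"):
            raise ValueError(
                f"{path}: only ascii-encoded NRRD is supported "
                f"(got encoding {fields.get('encoding')!r})"
            )
        type_str = fields.get("type", "")
        if type_str not in _NRRD_TO_DTYPE:
            raise ValueError(f"{path}: unsupported NRRD type {type_str!r}")
        sizes = tuple(int(s) for s in fields["sizes"].split())
        if len(sizes) != int(fields["dimension"]):
            raise ValueError(f"{path}: sizes/dimension mismatch in header")
        data = np.array(fh.read().split(), dtype=_NRRD_TO_DTYPE[type_str])
    expected = int(np.prod(sizes)) if sizes else 1
    if data.size != expected:
        raise ValueError(
            f"{path}: expected {expected} values for sizes {sizes}, got {data.size}"
        )
    return data.reshape(sizes, order="C")
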