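"""TIFF and sidecar I/O helpers.

Raw frames are 8-bit (LSI) or 16-bit (SFDI) grayscale TIFFs named
``<stream>_<cycle:06d>_<index:02d>.tiff``; derived maps are written as
32-bit float TIFFs with a JSON sidecar carrying wavelength, units and
invalid-pixel bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "frame_name",
    "write_frame",
    "read_frame",
    "write_map",
    "read_map",
    "dataset_hash",
]


def frame_name(stream: str, cycle: int, index: int) -> str:
    return f"{stream}_{cycle:06d}_{index:02d}.tiff"


def write_frame(path, frame: np.ndarray, bit_depth: int) -> None:
    """Quantize a float frame to the given bit depth and write it."""
    full = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    if frame.dtype == dtype:
        data = frame
    else:
        data = np.clip(np.rint(frame), 0, full).astype(dtype)
    tifffile.imwrite(str(path), data)


def read_frame(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_map(path, arr: np.ndarray, **sidecar) -> None:
    """Write a float32 map plus a JSON sidecar of metadata.

    The sidecar always records the NaN (invalid) pixel count.
    """
    path = Path(path)
    arr = np.asarray(arr, dtype=np.float32)
    tifffile.imwrite(str(path), arr)
    meta = dict(sidecar)
    meta.setdefault("shape", list(arr.shape))
    meta["invalid_pixels"] = int(np.count_nonzero(~np.isfinite(arr)))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_map(path):
    path = Path(path)
    arr = tifffile.imread(str(path))
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta


def dataset_hash(data_dir) -> str:
    """SHA-256 over all frame files and the manifest, in sorted path order."""
    h = hashlib.sha256()
    for p in sorted(Path(data_dir).rglob("*")):
        if p.is_file() and p.suffix in {".tiff", ".tif", ".csv"}:
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
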