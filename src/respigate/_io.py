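"""Deterministic array persistence.

Arrays are stored as ``.npy`` members of an uncompressed zip with fixed
timestamps, so that identical content yields byte-identical files and
rerun manifests hash equal.  ``numpy.load`` reads the result directly.
JSON string attributes travel in a reserved ``__attrs__`` member.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path
from typing import Any, Mapping

import numpy as np

_EPOCH = (1980, 1, 1, 0, 0, 0)  # earliest timestamp zip supports


def save_arrays(
    path: str | Path,
    arrays: Mapping[str, np.ndarray],
    attrs: Mapping[str, Any] | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.ascontiguousarray(arrays[name]))
            zf.writestr(zipfile.ZipInfo(f"{name}.npy", date_time=_EPOCH), buf.getvalue())
        if attrs is not None:
            payload = json.dumps(dict(attrs), sort_keys=True)
            zf.writestr(zipfile.ZipInfo("__attrs__", date_time=_EPOCH), payload)
    return path


def load_arrays(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, Any]]:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    attrs: dict[str, Any] = {}
    with zipfile.ZipFile(path, "r") as zf:
        for name in zf.namelist():
            if name == "__attrs__":
                attrs = json.loads(zf.read(name).decode())
            elif name.endswith(".npy"):
                arrays[name[: -len(".npy")]] = np.lib.format.read_array(
                    io.BytesIO(zf.read(name))
                )
    return arrays, attrs
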