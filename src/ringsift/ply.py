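"""Minimal deterministic PLY point-cloud I/O (binary little-endian).

Writes x, y, z as float32 plus optional red/green/blue uchar per vertex.
The byte stream is a pure function of the inputs, so identical clouds give
identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InputError


def write_ply(path, points: np.ndarray, colors: np.ndarray | None = None) -> None:
    points = np.asarray(points, dtype="<f4").reshape(-1, 3)
    header = [
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {points.shape[0]}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8).reshape(-1, 3)
        if colors.shape[0] != points.shape[0]:
            raise InputError("colors and points must have the same length")
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if colors is None:
            fh.write(points.tobytes())
        else:
            rec = np.empty(points.shape[0],
                           dtype=[("xyz", "<f4", 3), ("rgb", "u1", 3)])
            rec["xyz"] = points
            rec["rgb"] = colors
            fh.write(rec.tobytes())


def read_ply(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read back a PLY written by :func:`write_ply`. Returns (points, colors)."""
    path = Path(path)
    data = path.read_bytes()
    end = data.find(b"end_header\n")
    if not data.startswith(b"ply") or end < 0:
        raise InputError(f"not a PLY file: {path}")
    header = data[:end].decode("ascii").splitlines()
    body = data[end + len(b"end_header\n"):]

    n = 0
    props: list[str] = []
    for line in header:
        if line.startswith("element vertex"):
            n = int(line.split()[-1])
        elif line.startswith("property"):
            props.append(line.split()[-1])
        elif line.startswith("format") and "binary_little_endian" not in line:
            raise InputError(f"unsupported PLY format in {path}: {line}")
    has_color = "red" in props
    dtype = [("xyz", "<f4", 3)] + ([("rgb", "u1", 3)] if has_color else [])
    rec = np.frombuffer(body, dtype=dtype, count=n)
    points = rec["xyz"].astype(np.float64)
    colors = rec["rgb"].copy() if has_color else None
    return points, colors
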