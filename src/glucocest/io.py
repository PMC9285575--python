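"""Reading and writing stacks, offset sidecars, maps and tables.

Stacks are stored as NIfTI volumes (rows x cols x offsets) with a
plain-text offsets sidecar (one ppm per line; blank lines and ``#``
comments ignored) and a small JSON sidecar for frame time and the S0
reference offset.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import ZSpectrumStack

__all__ = ["read_offsets", "write_offsets", "read_stack", "write_stack", "write_map", "read_map"]


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.parent / f"{stem}.offsets.txt", path.parent / f"{stem}.meta.json"


def read_offsets(path: str | Path) -> np.ndarray:
    """Parse an offsets sidecar: one ppm per line, '#' comments allowed."""
    vals = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            vals.append(float(line))
    if not vals:
        raise ValueError(f"no offsets found in {path}")
    return np.array(vals)


def write_offsets(offsets: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("".join(f"{o:.6g}\n" for o in offsets))


def write_stack(stack: ZSpectrumStack, path: str | Path) -> Path:
    """Write a stack as NIfTI plus offsets and metadata sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(stack.data.astype(np.float64), np.eye(4)), str(path))
    off_p, meta_p = _sidecar_paths(path)
    write_offsets(stack.offsets, off_p)
    meta_p.write_text(
        json.dumps({"frame_time_min": stack.frame_time, "s0_offset_ppm": stack.s0_offset})
    )
    return path


def read_stack(path: str | Path, offsets_path: str | Path | None = None) -> ZSpectrumStack:
    """Read a NIfTI stack and its sidecars back into a ZSpectrumStack."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[2] == 1:  # reserved slice axis
        data = data[:, :, 0, :]
    off_p, meta_p = _sidecar_paths(path)
    if offsets_path is not None:
        off_p = Path(offsets_path)
    if not off_p.exists():
        raise FileNotFoundError(f"missing offsets sidecar {off_p}")
    offsets = read_offsets(off_p)
    if data.shape[-1] != len(offsets):
        raise ValueError(
            f"offset count mismatch: stack {path.name} has {data.shape[-1]} volumes "
            f"but sidecar lists {len(offsets)} offsets"
        )
    frame_time, s0 = None, -10.0
    if meta_p.exists():
        meta = json.loads(meta_p.read_text())
        frame_time = meta.get("frame_time_min")
        s0 = meta.get("s0_offset_ppm", -10.0)
    return ZSpectrumStack(data, offsets, frame_time=frame_time, s0_offset=s0)


def write_map(values: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D parametric map (NaN-padded) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), np.eye(4)), str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)
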