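"""NIfTI and sidecar I/O for echo stacks, label masks and T2 maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import EchoStack, T2Map

__all__ = [
    "write_echo_stack", "read_echo_stack",
    "write_labels", "read_labels",
    "write_t2map", "read_t2map",
]


def _affine(pixel_spacing, slice_step) -> np.ndarray:
    # axes: (slice, row, col) -> voxel sizes (slice step, row spacing, col spacing)
    return np.diag([slice_step, pixel_spacing[0], pixel_spacing[1], 1.0])


def write_echo_stack(stack: EchoStack, path: str | Path) -> Path:
    """4D NIfTI (slice, row, col, echo) plus a ``*.json`` sidecar with echo times."""
    path = Path(path)
    aff = _affine(stack.pixel_spacing, stack.slice_thickness + stack.slice_gap)
    nib.save(nib.Nifti1Image(stack.data.astype(np.float32), aff), path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(json.dumps({
        "echo_times_ms": list(map(float, stack.echo_times)),
        "pixel_spacing_mm": list(map(float, stack.pixel_spacing)),
        "slice_thickness_mm": float(stack.slice_thickness),
        "slice_gap_mm": float(stack.slice_gap),
    }, indent=1))
    return path


def read_echo_stack(path: str | Path) -> EchoStack:
    path = Path(path)
    img = nib.load(path)
    sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    meta = json.loads(sidecar.read_text())
    return EchoStack(
        data=np.asarray(img.dataobj, dtype=float),
        echo_times=np.asarray(meta["echo_times_ms"], dtype=float),
        pixel_spacing=tuple(meta.get("pixel_spacing_mm", (1.0, 1.0))),
        slice_thickness=float(meta.get("slice_thickness_mm", 1.0)),
        slice_gap=float(meta.get("slice_gap_mm", 0.0)),
    )


def write_labels(labels: np.ndarray, path: str | Path,
                 pixel_spacing=(1.0, 1.0), slice_step: float = 1.0) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16),
                             _affine(pixel_spacing, slice_step)), path)
    return path


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj).astype(np.int16)


def write_t2map(t2map: T2Map, prefix: str | Path) -> dict[str, Path]:
    """Write T2, S0, B, validity and RSS volumes as ``<prefix>_<name>.nii.gz``."""
    prefix = Path(prefix)
    aff = np.eye(4)
    out = {}
    for name, arr, dt in (("t2", t2map.t2, np.float32), ("s0", t2map.s0, np.float32),
                          ("b", t2map.b, np.float32),
                          ("valid", t2map.valid, np.uint8),
                          ("rss", t2map.residual_rss, np.float32)):
        p = Path(f"{prefix}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(arr).astype(dt), aff), p)
        out[name] = p
    return out


def read_t2map(prefix: str | Path) -> T2Map:
    def load(name):
        return np.asarray(nib.load(Path(f"{prefix}_{name}.nii.gz")).dataobj)

    return T2Map(t2=load("t2").astype(float), s0=load("s0").astype(float),
                 b=load("b").astype(float), valid=load("valid").astype(bool),
                 residual_rss=load("rss").astype(float))
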