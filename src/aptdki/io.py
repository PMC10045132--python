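"""File I/O: NIfTI-1 images, offset sidecars, b-value files.

NIfTI is the canonical image format throughout; frame metadata travels in
plain-text sidecars (JSON offset lists for CEST, FSL-style ``.bval`` for
diffusion) so a stack on disk is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .offsets import OffsetScheme, parse_offset_scheme

__all__ = [
    "save_nifti", "load_nifti",
    "save_offsets_json", "load_offsets_json",
    "save_bvals", "load_bvals",
]


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return path


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_offsets_json(scheme: OffsetScheme, path) -> Path:
    """Write the per-frame offset labels ("S0" marks the reference frame)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = ["S0" if w is None else w for w in scheme.frame_offsets()]
    path.write_text(json.dumps({"frame_offsets_ppm": labels}, indent=1))
    return path


def load_offsets_json(path) -> OffsetScheme:
    labels = json.loads(Path(path).read_text())["frame_offsets_ppm"]
    return parse_offset_scheme(labels)


def save_bvals(b_values, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(" ".join(f"{float(b):g}" for b in b_values) + "\n")
    return path


def load_bvals(path) -> np.ndarray:
    """Read b-values from an FSL-style whitespace file or a JSON list."""
    text = Path(path).read_text().strip()
    if text.startswith("["):
        return np.asarray(json.loads(text), dtype=float)
    return np.asarray(text.split(), dtype=float)
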