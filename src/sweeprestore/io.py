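"""TIFF and sidecar-metadata I/O.

Z-stacks are written as multi-page TIFF (one page per plane); sweep and
projection images as single-page 32-bit float TIFF.  A plain-text key-value
sidecar records the acquisition parameters and seed next to each simulated
image set.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Dict, Union

import numpy as np
import tifffile

from .optics import AcquisitionSpec, ZStack

__all__ = ["write_stack", "read_stack", "write_image", "read_image",
           "write_sidecar", "read_sidecar"]

PathLike = Union[str, Path]


def write_stack(path: PathLike, stack: ZStack) -> None:
    """(h, w, n_planes) stack -> multi-page TIFF, one page per plane."""
    pages = np.moveaxis(stack.frames, 2, 0).astype(np.float32)
    tifffile.imwrite(str(path), pages)


def read_stack(path: PathLike) -> np.ndarray:
    """Multi-page TIFF -> (h, w, n_planes) float array."""
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    return np.moveaxis(pages.astype(float), 0, 2)


def write_image(path: PathLike, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_sidecar(path: PathLike, spec: AcquisitionSpec, seed, **extra) -> None:
    lines = [f"{k} = {v}" for k, v in asdict(spec).items()]
    lines.append(f"seed = {seed}")
    lines += [f"{k} = {v}" for k, v in extra.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: PathLike) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
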