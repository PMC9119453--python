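"""Synthetic paired-acquisition datasets.

Builds the supervised training unit of the restoration workflow: for each
phantom, a z-stack is acquired, texture-projected into the ground-truth
z-projection P, and a continuous z-sweep is acquired as the degraded input S.
Both are normalized by effective exposure time so they share one ADU/s scale.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from .optics import (AcquisitionSpec, ImagePair, Phantom, PhantomParams,
                     exposure_normalize, generate_phantom, render_zstack,
                     render_zsweep)
from .zproject import DEFAULT_SMOOTH_RADIUS, DEFAULT_WINDOW, texture_project

__all__ = ["simulate_pair", "generate_dataset", "default_spec_for_size"]

_SEED_MOD = 2**31 - 1


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + k * 7919 + 17) % _SEED_MOD


def simulate_pair(phantom: Phantom, spec: AcquisitionSpec, seed: Optional[int],
                  window: int = DEFAULT_WINDOW,
                  smooth_radius: int = DEFAULT_SMOOTH_RADIUS,
                  noise: bool = True) -> ImagePair:
    """Acquire both paradigms on one phantom and return the normalized pair."""
    stack_seed = _child_seed(seed, 0) if (noise and seed is not None) else None
    sweep_seed = _child_seed(seed, 1) if (noise and seed is not None) else None
    stack = render_zstack(phantom, spec, seed=stack_seed)
    projection = texture_project(stack.frames, window=window,
                                 smooth_radius=smooth_radius)
    sweep = render_zsweep(phantom, spec, seed=sweep_seed)
    pair = ImagePair(
        S=exposure_normalize(sweep.pixels, sweep.effective_exposure),
        P=exposure_normalize(projection.image, stack.effective_exposure_per_plane),
        metadata={
            "layout_kind": phantom.layout_kind,
            "seed": seed,
            "log_domain": False,
            "n_exposures": sweep.n_exposures,
            "acquisition": spec,
        },
    )
    return pair


def default_spec_for_size(size: Tuple[int, int],
                          pixel_size: float = 4.0,
                          z_range: float = 750.0) -> AcquisitionSpec:
    """Acquisition spec whose field of view renders to `size` pixels.

    The 4 um desk-scale pixel keeps small synthetic fields covering a
    physically plausible lateral extent; the full-resolution instrument scale
    (1.39 um/px) remains the AcquisitionSpec default.
    """
    return AcquisitionSpec(z_range=z_range, pixel_size=pixel_size)


def generate_dataset(layout_kind: str, n_pairs: int, size: Tuple[int, int],
                     seed: int, spec: Optional[AcquisitionSpec] = None,
                     params: Optional[PhantomParams] = None,
                     noise: bool = True) -> Tuple[List[ImagePair], List[Phantom]]:
    """Generate n_pairs phantoms of one layout and their (S, P) image pairs."""
    spec = spec or default_spec_for_size(size)
    h, w = size
    volume = (w * spec.pixel_size, h * spec.pixel_size, spec.z_range)
    if params is None:
        params = PhantomParams(volume_size=volume)
    else:
        from dataclasses import replace
        params = replace(params, volume_size=volume)
    pairs, phantoms = [], []
    for i in range(n_pairs):
        phantom = generate_phantom(layout_kind, params, seed=_child_seed(seed, 100 + i))
        pair = simulate_pair(phantom, spec, seed=_child_seed(seed, 200 + i), noise=noise)
        pair.metadata["index"] = i
        pairs.append(pair)
        phantoms.append(phantom)
    return pairs, phantoms
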