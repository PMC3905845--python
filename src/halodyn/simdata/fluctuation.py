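"""Fluctuation (N&B) stack simulator in the fast-diffusion limit.

Per pixel and frame, the occupancy is Poisson(n_true) and the detected
photon count Poisson(occupancy * epsilon + background); frames are
independent. The resulting counts follow a compound distribution with

    mean     = n * eps + background
    variance = n * eps * (1 + eps) + background

so at zero background the apparent brightness is exactly 1 + eps.
"""

from __future__ import annotations

import numpy as np

from halodyn.stack import ImageStack
from halodyn.simdata.config import SimConfig, GroundTruth, NandbTruth

__all__ = ["simulate_nandb_stack"]

_CHUNK_FRAMES = 500  # cap transient memory for very long stacks


def simulate_nandb_stack(
    n_true,
    epsilon_true: float,
    n_frames: int,
    config: SimConfig,
    background_counts: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a photon-counting fluctuation stack with known n and epsilon.

    Parameters
    ----------
    n_true : float or 2-D array
        True mean number of molecules per pixel; a map enables spatial
        contrast (e.g. focus vs pool regions).
    epsilon_true : float
        True molecular brightness in counts/molecule/frame.
    n_frames : int
        Number of frames; must be >= 2 (variance undefined otherwise).
    background_counts : float, optional
        Overrides ``config.background_counts``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (variance undefined)")
    if epsilon_true < 0:
        raise ValueError("epsilon_true must be >= 0")
    background = (
        config.background_counts if background_counts is None else background_counts
    )
    if background < 0:
        raise ValueError("background must be >= 0")

    shape = tuple(config.image_shape)
    n_map = np.broadcast_to(np.asarray(n_true, dtype=float), shape).copy()
    if np.any(n_map < 0):
        raise ValueError("n_true must be >= 0")

    rng = np.random.default_rng(config.rng_seed + 3) if rng is None else rng
    data = np.empty((n_frames, *shape), dtype=np.uint16)
    for start in range(0, n_frames, _CHUNK_FRAMES):
        stop = min(start + _CHUNK_FRAMES, n_frames)
        block = (stop - start, *shape)
        occupancy = rng.poisson(np.broadcast_to(n_map, block))
        counts = rng.poisson(occupancy * epsilon_true + background)
        data[start:stop] = counts.astype(np.uint16)

    stack = ImageStack(
        data=data,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        meta={"seed": config.rng_seed},
    )
    truth = GroundTruth(
        seed=config.rng_seed,
        config=config,
        nandb=NandbTruth(
            n_true=n_map,
            epsilon_true=float(epsilon_true),
            background_counts=float(background),
        ),
    )
    return stack, truth
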