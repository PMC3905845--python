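"""Photon-counting time-lapse rendering over a simulated cell field.

Imaging model per frame: a diffusing pool of point emitters inside each
cell (Brownian steps of per-axis variance 2*D*dt, reflected at the cell
boundary), immobile sub-resolution foci, Gaussian PSF blur, a constant
background, and Poisson shot noise. The noiseless expected frame conserves
photons exactly: sum = background * n_px + total emission rate.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from halodyn.stack import ImageStack
from halodyn.simdata.config import SimConfig, GroundTruth

__all__ = ["simulate_timelapse", "render_frame"]


def _deposit_bilinear(image: np.ndarray, rc: np.ndarray, weights: np.ndarray) -> None:
    """Spread point emissions onto the pixel grid with bilinear weights."""
    if len(rc) == 0:
        return
    h, w = image.shape
    r = np.clip(rc[:, 0], 0.0, h - 1.0 - 1e-9)
    c = np.clip(rc[:, 1], 0.0, w - 1.0 - 1e-9)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    np.add.at(image, (r0, c0), weights * (1 - fr) * (1 - fc))
    np.add.at(image, (r0, c1), weights * (1 - fr) * fc)
    np.add.at(image, (r1, c0), weights * fr * (1 - fc))
    np.add.at(image, (r1, c1), weights * fr * fc)


def render_frame(
    shape: tuple[int, int],
    emitter_rc: np.ndarray,
    emitter_rates: np.ndarray,
    psf_sigma_px: float,
    background: float,
) -> np.ndarray:
    """Noiseless expected photon image for one frame (photon-conserving)."""
    image = np.zeros(shape, dtype=np.float64)
    _deposit_bilinear(image, emitter_rc, emitter_rates)
    if psf_sigma_px > 0:
        # 'reflect' boundary keeps the total photon budget exact
        image = ndimage.gaussian_filter(image, psf_sigma_px, mode="reflect")
    return image + background


def _reflect_steps(
    pos: np.ndarray,
    steps: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Brownian update with reflection at the cell boundary.

    A step landing outside the mask is mirrored about the current
    position; if the mirrored point is also outside, the molecule stays
    put for this frame (rare for physically sensible step sizes).
    """
    h, w = mask.shape

    def inside(p: np.ndarray) -> np.ndarray:
        r = np.floor(p[:, 0]).astype(int)
        c = np.floor(p[:, 1]).astype(int)
        ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        res = np.zeros(len(p), dtype=bool)
        res[ok] = mask[r[ok], c[ok]]
        return res

    proposed = pos + steps
    good = inside(proposed)
    out = np.where(good[:, None], proposed, pos)
    bad = ~good
    if bad.any():
        mirrored = pos[bad] - steps[bad]
        ok2 = inside(mirrored)
        sel = np.flatnonzero(bad)[ok2]
        out[sel] = mirrored[ok2]
    return out


def simulate_timelapse(
    labels: np.ndarray,
    truth: GroundTruth,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Render a photon-counting time-lapse over a cell field.

    Parameters
    ----------
    labels, truth
        Output of :func:`make_cell_geometry`.
    noise : bool
        If False the stack holds the noiseless expected photon images
        (float); if True, Poisson draws (integer counts).

    Returns the stack and the same GroundTruth with rendering parameters
    appended under ``truth.extras``.
    """
    config = truth.config if config is None else config
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    shape = tuple(config.image_shape)
    if labels.shape != shape:
        raise ValueError("label image does not match config.image_shape")
    px = config.pixel_size_um
    psf_sigma_px = config.psf_sigma_um / px
    eps = config.molecular_brightness_counts
    dt = config.frame_interval_s
    step_sd_px = np.sqrt(2.0 * config.diffusion_um2_s * dt) / px

    # undersampling check: rms step vs typical cell diameter
    if truth.cells:
        mean_area_px = np.mean([c.area_um2 for c in truth.cells]) / px ** 2
        diameter_px = 2.0 * np.sqrt(mean_area_px / np.pi)
        if step_sd_px * np.sqrt(2.0) > diameter_px:
            warnings.warn(
                "diffusion step exceeds the cell diameter per frame "
                "(motion is undersampled)",
                stacklevel=2,
            )

    # initialize pool molecules uniformly inside each cell
    masks: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for cell in truth.cells:
        mask = labels == cell.cell_id
        masks.append(mask)
        px_inside = np.argwhere(mask)
        n_pool = config.pool_molecules_per_cell
        if n_pool > 0 and len(px_inside):
            picks = px_inside[rng.integers(0, len(px_inside), size=n_pool)]
            pos = picks + rng.uniform(0.0, 1.0, size=(n_pool, 2))
        else:
            pos = np.zeros((0, 2))
        positions.append(pos)

    # immobile foci: row/col positions and emission rates
    foci_rc = []
    for cell in truth.cells:
        if cell.n_foci:
            xy = np.asarray(cell.focus_centroids_um) / px
            foci_rc.append(xy[:, ::-1])  # (x, y) um -> (row, col) px
    foci_rc = np.vstack(foci_rc) if foci_rc else np.zeros((0, 2))
    focus_rate = config.focus_brightness_multiple * eps

    frames = np.empty((config.n_frames, *shape), dtype=np.float64)
    for f in range(config.n_frames):
        if f > 0:
            for i, mask in enumerate(masks):
                if len(positions[i]) == 0:
                    continue
                steps = rng.normal(0.0, step_sd_px, size=positions[i].shape)
                positions[i] = _reflect_steps(positions[i], steps, mask)
        emitters = [p for p in positions if len(p)]
        rc = np.vstack(emitters + [foci_rc]) if (emitters or len(foci_rc)) else np.zeros((0, 2))
        rates = np.concatenate(
            [np.full(sum(len(p) for p in emitters), eps),
             np.full(len(foci_rc), focus_rate)]
        )
        frames[f] = render_frame(shape, rc, rates, psf_sigma_px, config.background_counts)

    if noise:
        data = rng.poisson(frames).astype(np.uint16)
    else:
        data = frames

    stack = ImageStack(
        data=data,
        pixel_size_um=px,
        frame_interval_s=dt,
        meta={"seed": config.rng_seed, "noise": noise},
    )
    n_pool_total = sum(len(p) for p in positions)
    truth.extras.update(
        {
            "molecular_brightness_counts": eps,
            "focus_rate_counts": focus_rate,
            "background_counts": config.background_counts,
            "expected_photons_per_frame": config.background_counts * labels.size
            + n_pool_total * eps
            + len(foci_rc) * focus_rate,
            "diffusion_um2_s": config.diffusion_um2_s,
        }
    )
    return stack, truth
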