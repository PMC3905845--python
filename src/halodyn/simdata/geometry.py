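"""Random pleiomorphic cell fields as label images with exact true areas."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label

from halodyn.simdata.config import SimConfig, GroundTruth, CellTruth

__all__ = ["make_cell_geometry", "CrowdedFieldError"]

# Fourier boundary perturbation: harmonics 2..5, per-harmonic relative sd
_BOUNDARY_HARMONICS = (2, 3, 4, 5)
_BOUNDARY_SD = 0.06
_PLACEMENT_ATTEMPTS = 200
_CELL_GAP_PX = 2  # minimum empty pixels between neighboring cells


class CrowdedFieldError(RuntimeError):
    """No requested cell could be placed in the field."""


def _cell_mask(n_target_px: int, rng: np.random.Generator) -> np.ndarray:
    """Rasterize a randomly deformed ellipse holding exactly n_target_px pixels."""
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    r = np.ones_like(theta)
    for m in _BOUNDARY_HARMONICS:
        c = rng.normal(0.0, _BOUNDARY_SD)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        r += c * np.cos(m * theta + phi)
    # mild ellipticity
    ecc = rng.uniform(0.0, 0.35)
    phi0 = rng.uniform(0.0, np.pi)
    r *= 1.0 + ecc * np.cos(2.0 * (theta - phi0))
    r = np.clip(r, 0.3, None)

    # scale so the polygon area (shoelace in polar form) matches the target
    poly_area = 0.5 * np.sum(r ** 2) * (2.0 * np.pi / theta.size)
    r *= np.sqrt(n_target_px / poly_area)

    r_max = r.max()
    size = int(np.ceil(2 * r_max)) + 5
    cy = cx = size / 2.0
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    mask = ndimage.binary_fill_holes(mask)
    return _match_pixel_count(mask, n_target_px)


def _match_pixel_count(mask: np.ndarray, n_target: int) -> np.ndarray:
    """Add/remove boundary pixels until the mask holds exactly n_target pixels.

    Pixels are added where they touch the most mask neighbors (keeps the
    boundary smooth) and removed from the thinnest parts of the rim while
    preserving 8-connectivity.
    """
    mask = mask.copy()
    structure = np.ones((3, 3), bool)
    count = int(mask.sum())
    guard = 0
    while count != n_target:
        guard += 1
        if guard > 10000:
            raise RuntimeError("area matching did not converge")
        if count < n_target:
            ring = ndimage.binary_dilation(mask, structure) & ~mask
            if not ring.any():
                raise RuntimeError("cannot grow mask further")
            neighbor_count = ndimage.convolve(
                mask.astype(np.int8), structure.astype(np.int8), mode="constant"
            )
            cand = np.argwhere(ring)
            scores = neighbor_count[cand[:, 0], cand[:, 1]]
            order = np.argsort(-scores)
            take = min(n_target - count, len(cand))
            for idx in order[:take]:
                mask[cand[idx, 0], cand[idx, 1]] = True
            count = int(mask.sum())
        else:
            edt = ndimage.distance_transform_edt(mask)
            rim = np.argwhere((edt > 0) & (edt <= np.sqrt(2) + 1e-9))
            order = np.argsort(edt[rim[:, 0], rim[:, 1]])
            removed = 0
            need = count - n_target
            for idx in order:
                r0, c0 = rim[idx]
                mask[r0, c0] = False
                # reject removals that disconnect the cell
                if cc_label(mask, connectivity=2).max() != 1:
                    mask[r0, c0] = True
                    continue
                removed += 1
                if removed == need:
                    break
            count = int(mask.sum())
    return mask


def _crop_to_content(mask: np.ndarray) -> np.ndarray:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    return mask[r0:r1 + 1, c0:c1 + 1]


def _sample_focus_positions(
    mask: np.ndarray, n_foci: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sub-pixel focus positions (row, col) inside the eroded mask."""
    if n_foci == 0:
        return np.zeros((0, 2))
    interior = ndimage.binary_erosion(mask, np.ones((3, 3), bool), iterations=2)
    if not interior.any():
        interior = mask
    candidates = np.argwhere(interior)
    picks = candidates[rng.integers(0, len(candidates), size=n_foci)]
    jitter = rng.uniform(-0.4, 0.4, size=(n_foci, 2))
    return picks + jitter


def make_cell_geometry(
    config: SimConfig,
    n_cells: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Place non-overlapping deformed-ellipse cells in the field.

    Cell areas are drawn from Normal(mean_cell_area_um2, cell_area_sd_um2)
    truncated at a minimal size; the rasterized pixel count matches the
    recorded true area exactly (true area = pixel count x pixel area).
    Each cell receives Poisson(foci_per_cell_mean) sub-resolution foci at
    uniform positions inside the cell.

    Returns
    -------
    labels : ndarray of int32
        0 = background, 1..n = cell labels.
    truth : GroundTruth
        Per-cell true areas, focus counts/centroids (um, x-y order) and
        the focus intensity fraction implied by the config brightness model.

    Raises
    ------
    CrowdedFieldError
        If n_cells > 0 and not a single cell could be placed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = config.rng() if rng is None else rng
    shape = tuple(config.image_shape)
    labels = np.zeros(shape, dtype=np.int32)
    blocked = np.zeros(shape, dtype=bool)  # occupied + gap margin
    px_area = config.pixel_area_um2
    min_area_px = 9

    truth = GroundTruth(seed=config.rng_seed, config=config, n_requested=n_cells)
    gap = np.ones((2 * _CELL_GAP_PX + 1,) * 2, bool)
    next_id = 1
    for _ in range(n_cells):
        area_um2 = rng.normal(config.mean_cell_area_um2, config.cell_area_sd_um2)
        n_px = max(min_area_px, int(round(area_um2 / px_area)))
        mask = _crop_to_content(_cell_mask(n_px, rng))
        h, w = mask.shape
        if h >= shape[0] or w >= shape[1]:
            continue
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            r0 = rng.integers(1, shape[0] - h)
            c0 = rng.integers(1, shape[1] - w)
            window = blocked[r0:r0 + h, c0:c0 + w]
            if not (window & mask).any():
                labels[r0:r0 + h, c0:c0 + w][mask] = next_id
                region = np.zeros(shape, bool)
                region[r0:r0 + h, c0:c0 + w] = mask
                blocked |= ndimage.binary_dilation(region, gap)
                n_foci = int(rng.poisson(config.foci_per_cell_mean))
                foci_rc = _sample_focus_positions(mask, n_foci, rng)
                foci_rc += np.array([r0, c0])
                foci_xy_um = foci_rc[:, ::-1] * config.pixel_size_um
                com = ndimage.center_of_mass(region)
                m = config.focus_brightness_multiple
                pool = config.pool_molecules_per_cell
                total = n_foci * m + pool
                frac = (n_foci * m / total) if total > 0 else 0.0
                truth.cells.append(
                    CellTruth(
                        cell_id=next_id,
                        area_um2=n_px * px_area,
                        centroid_um=(com[1] * config.pixel_size_um,
                                     com[0] * config.pixel_size_um),
                        focus_centroids_um=foci_xy_um,
                        focus_intensity_fraction=frac,
                    )
                )
                next_id += 1
                placed = True
                break
        if not placed:
            continue

    truth.n_placed = len(truth.cells)
    if n_cells > 0 and truth.n_placed == 0:
        raise CrowdedFieldError(
            "field too crowded: could not place any cell "
            f"(requested {n_cells} in {shape})"
        )
    if truth.n_placed < n_cells:
        warnings.warn(
            f"placed only {truth.n_placed}/{n_cells} cells (field too crowded)",
            stacklevel=2,
        )
    return labels, truth
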