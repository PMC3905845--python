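"""Per-pixel number-and-brightness (N&B) fluctuation analysis.

Photon-counting formulation: for each pixel with temporal mean <I> and
population variance s2 over the time stack,

    apparent number      N = <I>^2 / s2
    apparent brightness  B = s2 / <I>
    molecular number     n = <I>^2 / (s2 - <I>)
    molecular brightness e = (s2 - <I>) / <I>

The shot-noise term <I> is removed in the molecular quantities; pixels
with s2 <= <I> carry no detectable molecular fluctuation signal and are
masked (NaN sentinel, never silently zero).

Hazard: apparent brightness scales with detector gain — counts must be
true photon counts for e to be interpretable as counts/molecule/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from halodyn.stack import ImageStack

__all__ = ["NBMap", "RoiStats", "pixel_moments", "nb_maps", "roi_stats", "motion_filter"]

MIN_ROI_PIXELS = 4


@dataclass
class NBMap:
    """Per-pixel moment and number/brightness maps.

    Invalid pixels (zero mean, or variance not exceeding the shot-noise
    floor) are NaN in the four derived maps and False in ``valid_mask``.
    """

    mean_map: np.ndarray
    variance_map: np.ndarray
    apparent_number: np.ndarray
    apparent_brightness: np.ndarray
    molecular_number: np.ndarray
    molecular_brightness: np.ndarray
    valid_mask: np.ndarray


@dataclass
class RoiStats:
    roi_id: int
    n_pixels: int
    mean_molecular_number: float
    sem_molecular_number: float
    mean_molecular_brightness: float
    sem_molecular_brightness: float
    normalized_brightness: float | None = None
    excluded: bool = False
    flags: list[str] = field(default_factory=list)


def pixel_moments(stack: ImageStack | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Temporal mean and population variance (ddof=0) per pixel."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim != 3:
        raise ValueError("stack must be 3-D (time, y, x)")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames for a variance")
    mean = data.mean(axis=0, dtype=np.float64)
    var = data.var(axis=0, dtype=np.float64, ddof=0)
    return mean, var


def nb_maps(
    mean_map: np.ndarray,
    variance_map: np.ndarray,
    background: float = 0.0,
) -> NBMap:
    """Derive the apparent and molecular N&B maps from per-pixel moments.

    Parameters
    ----------
    background : float
        Optional constant background subtracted from the mean before the
        molecular maps are computed (off by default).
    """
    mean_map = np.asarray(mean_map, dtype=float)
    variance_map = np.asarray(variance_map, dtype=float)
    if mean_map.shape != variance_map.shape:
        raise ValueError("mean and variance maps must share a shape")
    signal = mean_map - background

    with np.errstate(divide="ignore", invalid="ignore"):
        apparent_number = np.where(variance_map > 0, signal ** 2 / variance_map, np.nan)
        apparent_brightness = np.where(signal > 0, variance_map / signal, np.nan)
        excess = variance_map - signal
        valid = (signal > 0) & (excess > 0)
        molecular_number = np.where(valid, signal ** 2 / excess, np.nan)
        molecular_brightness = np.where(valid, excess / signal, np.nan)

    return NBMap(
        mean_map=mean_map,
        variance_map=variance_map,
        apparent_number=apparent_number,
        apparent_brightness=apparent_brightness,
        molecular_number=molecular_number,
        molecular_brightness=molecular_brightness,
        valid_mask=valid,
    )


def roi_stats(
    nbmap: NBMap,
    rois: np.ndarray,
    reference_roi: int | None = None,
) -> list[RoiStats]:
    """Mean +/- SEM of molecular number and brightness per labeled ROI.

    ``normalized_brightness`` is each ROI's mean molecular brightness
    divided by the reference ROI's; ROIs with fewer than 4 valid pixels are
    flagged and excluded from normalization.
    """
    rois = np.asarray(rois)
    if rois.shape != nbmap.mean_map.shape:
        raise ValueError("ROI label image must match the map shape")
    labels = np.unique(rois)
    labels = labels[labels > 0]

    out: list[RoiStats] = []
    by_id: dict[int, RoiStats] = {}
    for lab in labels:
        sel = (rois == lab) & nbmap.valid_mask
        n = int(sel.sum())
        if n < MIN_ROI_PIXELS:
            st = RoiStats(
                roi_id=int(lab), n_pixels=n,
                mean_molecular_number=float("nan"), sem_molecular_number=float("nan"),
                mean_molecular_brightness=float("nan"),
                sem_molecular_brightness=float("nan"),
                excluded=True,
                flags=[f"only {n} valid pixels (< {MIN_ROI_PIXELS}): excluded"],
            )
        else:
            num = nbmap.molecular_number[sel]
            bri = nbmap.molecular_brightness[sel]
            st = RoiStats(
                roi_id=int(lab), n_pixels=n,
                mean_molecular_number=float(num.mean()),
                sem_molecular_number=float(num.std(ddof=1) / np.sqrt(n)),
                mean_molecular_brightness=float(bri.mean()),
                sem_molecular_brightness=float(bri.std(ddof=1) / np.sqrt(n)),
            )
        out.append(st)
        by_id[st.roi_id] = st

    if reference_roi is not None:
        ref = by_id.get(int(reference_roi))
        if ref is None:
            raise ValueError(f"reference ROI {reference_roi} not present")
        if ref.excluded:
            raise ValueError(f"reference ROI {reference_roi} has too few valid pixels")
        for st in out:
            if not st.excluded:
                st.normalized_brightness = (
                    st.mean_molecular_brightness / ref.mean_molecular_brightness
                )
    return out


def motion_filter(
    stack: ImageStack | np.ndarray,
    max_shift_px: float,
) -> tuple[bool, float, bool]:
    """Global drift check between the first and last quartile of frames.

    Returns ``(passed, shift_px, low_confidence)``. Drift is estimated by
    phase cross-correlation between the temporal means of the first and
    last quarter of the stack. Featureless stacks pass with shift 0 and a
    low-confidence flag.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("need a 3-D stack with at least 2 frames")
    if max_shift_px <= 0:
        raise ValueError("max_shift_px must be positive")
    q = max(1, data.shape[0] // 4)
    first = data[:q].mean(axis=0)
    last = data[-q:].mean(axis=0)

    # structure check: contrast of the averaged images vs their noise floor
    contrast = min(first.std(), last.std())
    scale = max(first.mean(), last.mean(), 1e-12)
    n_avg = q
    shot_floor = np.sqrt(scale / n_avg)  # Poisson noise left after averaging
    low_confidence = contrast <= 2.0 * shot_floor

    if first.std() == 0 or last.std() == 0:
        return True, 0.0, True

    shift, error, _ = phase_cross_correlation(first, last, upsample_factor=10)
    shift_px = float(np.hypot(*shift))
    if low_confidence:
        return True, 0.0, True
    return shift_px <= max_shift_px, shift_px, False
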