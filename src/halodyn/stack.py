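"""Calibrated image-stack container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A (time, y, x) intensity or photon-count array with physical calibration.

    Parameters
    ----------
    data : ndarray
        3-D array ordered (time, y, x). A 2-D array is promoted to a
        single-frame stack.
    pixel_size_um : float
        Lateral pixel size in micrometres. Required; no silent default.
    frame_interval_s : float, optional
        Time between consecutive frames in seconds. Required by
        time-resolved analyses only.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(
                f"stack must be 2-D or 3-D (time, y, x); got ndim={self.data.ndim}"
            )
        if not (self.pixel_size_um and self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be a positive number")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive when given")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def frame(self, i: int) -> np.ndarray:
        return self.data[i]

    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def max_image(self) -> np.ndarray:
        return self.data.max(axis=0)
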