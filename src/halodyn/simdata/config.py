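"""Simulation configuration and ground-truth records."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class SimConfig:
    """Parameters shared by the synthetic-data generators.

    Defaults mirror a typical confocal photon-counting acquisition:
    207 nm pixels, 0.272 s frame interval, 128 x 128 frames, cells of
    28 +/- 6 um^2 carrying on average 2 sub-resolution foci.
    """

    pixel_size_um: float = 0.207
    frame_interval_s: float = 0.272
    n_frames: int = 100
    image_shape: tuple[int, int] = (128, 128)
    mean_cell_area_um2: float = 28.0
    cell_area_sd_um2: float = 6.0
    foci_per_cell_mean: float = 2.0
    focus_brightness_multiple: float = 25.0
    pool_molecules_per_cell: int = 300
    molecular_brightness_counts: float = 4.0
    background_counts: float = 1.0
    psf_sigma_um: float = 0.15
    diffusion_um2_s: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pixel_size_um",
            "frame_interval_s",
            "mean_cell_area_um2",
            "psf_sigma_um",
            "diffusion_um2_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        nonneg = (
            "cell_area_sd_um2",
            "foci_per_cell_mean",
            "pool_molecules_per_cell",
            "molecular_brightness_counts",
            "background_counts",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if len(self.image_shape) != 2 or min(self.image_shape) < 16:
            raise ValueError("image_shape must be 2-D with each dim >= 16")
        if self.focus_brightness_multiple < 1:
            raise ValueError("focus_brightness_multiple must be >= 1")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d


@dataclass
class CellTruth:
    """True geometry and focus content of one simulated cell."""

    cell_id: int
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y)
    focus_centroids_um: np.ndarray    # (k, 2) in (x, y)
    focus_intensity_fraction: float

    @property
    def n_foci(self) -> int:
        return int(len(self.focus_centroids_um))


@dataclass
class FrapTruth:
    """True kinetics behind a simulated recovery-trace ensemble."""

    k_values: np.ndarray
    amplitudes: np.ndarray
    immobile_fraction: float
    bleach_depth: float
    plateau: float
    noise_sd: float
    acquisition_bleach_rate: float
    mobile_fraction: float


@dataclass
class NandbTruth:
    """True molecular parameters behind a simulated fluctuation stack."""

    n_true: np.ndarray          # molecules per pixel (map)
    epsilon_true: float         # counts/molecule/frame
    background_counts: float


@dataclass
class GroundTruth:
    """Container for whatever true parameters a generator emitted."""

    seed: int
    config: SimConfig
    cells: list[CellTruth] = field(default_factory=list)
    n_requested: int | None = None
    n_placed: int | None = None
    frap: FrapTruth | None = None
    nandb: NandbTruth | None = None
    extras: dict = field(default_factory=dict)

    @property
    def mean_area_um2(self) -> float:
        return float(np.mean([c.area_um2 for c in self.cells])) if self.cells else float("nan")

    @property
    def mean_foci_per_cell(self) -> float:
        return float(np.mean([c.n_foci for c in self.cells])) if self.cells else float("nan")
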