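"""Reproducible synthetic-recovery benchmarks.

Each benchmark regenerates synthetic data at reference parameters taken
from the study being reproduced, runs the corresponding analysis chain
end to end, and returns the recovered quantities. Used by the acceptance
suite and the ``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from halodyn import frap, nandb, segquant
from halodyn.simdata import (
    SimConfig,
    make_cell_geometry,
    simulate_frap_traces,
    simulate_nandb_stack,
    simulate_timelapse,
)

__all__ = [
    "frap_mono_benchmark",
    "frap_bi_benchmark",
    "nb_contrast_benchmark",
    "calibrate_quality_threshold",
    "foci_pipeline_benchmark",
]

# Reference acquisition grid: 150 frames (50 pre-bleach) at 0.272 s/frame
FRAP_CONFIG = SimConfig(n_frames=150)
N_PREBLEACH = 50
BLEACH_AREA_UM2 = 3.72

# control-condition recovery: one mobile component, ~35% recovery at 5 s
CONTROL_K = 1.15
CONTROL_AMPLITUDE = 0.35
CONTROL_N_TRACES = 17
CONTROL_RMSE = 0.0300

# replication-arrest recovery: two mobile components, ~44% recovery
ARREST_K_FAST = 2.75
ARREST_K_SLOW = 0.24
ARREST_SLOW_FRACTION = 0.347
ARREST_RECOVERY = 0.44
ARREST_N_TRACES = 26
ARREST_RMSE = 0.0155

# per-pixel molecule counts: diffuse pool vs focus regions
POOL_MOLECULES_PER_PIXEL = 27.0
FOCUS_MOLECULES_PER_PIXEL = 38.0

# control-condition focus content
CONTROL_FOCI_PER_CELL = 2.0


def _fit_ensemble(
    k_values, amplitudes, immobile_fraction, noise_sd, n_traces, model, rng
):
    """Simulate one trace ensemble, normalize, average and fit."""
    traces, _ = simulate_frap_traces(
        k_values, amplitudes, immobile_fraction,
        noise_sd=noise_sd, n_traces=n_traces,
        config=FRAP_CONFIG, n_prebleach=N_PREBLEACH,
        bleach_area_um2=BLEACH_AREA_UM2, rng=rng,
    )
    normalized = [
        frap.normalize_trace(
            tr.t, tr.i_raw, tr.i_b,
            n_prebleach=N_PREBLEACH, bleach_area_um2=BLEACH_AREA_UM2,
        )
        for tr in traces
    ]
    return frap.fit_recovery(frap.average_traces(normalized), model=model)


def frap_mono_benchmark(seed: int, n_replicates: int = 20) -> dict:
    """Mono-exponential recovery on control-like ensembles.

    Per replicate: 17 traces with noise matched to the reference ensemble
    RMSE of 0.0300, averaged and fitted. Returns all rate estimates.
    """
    rng = np.random.default_rng(seed)
    noise_sd = CONTROL_RMSE * np.sqrt(CONTROL_N_TRACES)
    ks = []
    for _ in range(n_replicates):
        fit = _fit_ensemble(
            [CONTROL_K], [CONTROL_AMPLITUDE], 1.0 - CONTROL_AMPLITUDE,
            noise_sd, CONTROL_N_TRACES, "mono", rng,
        )
        ks.append(float(fit.k[0]))
    return {"k": np.array(ks), "n_traces_total": n_replicates * CONTROL_N_TRACES}


def frap_bi_benchmark(seed: int, n_replicates: int = 20) -> dict:
    """Bi-exponential recovery on replication-arrest-like ensembles.

    Per replicate: 26 traces at the reference two-component kinetics
    (fast 2.75 1/s, slow 0.24 1/s, slow fraction 34.7% of the mobile
    amplitude), noise matched to ensemble RMSE 0.0155.
    """
    rng = np.random.default_rng(seed)
    amplitudes = (
        np.array([1.0 - ARREST_SLOW_FRACTION, ARREST_SLOW_FRACTION])
        * ARREST_RECOVERY
    )
    noise_sd = ARREST_RMSE * np.sqrt(ARREST_N_TRACES)
    k_fast, k_slow, slow_frac = [], [], []
    for _ in range(n_replicates):
        fit = _fit_ensemble(
            [ARREST_K_FAST, ARREST_K_SLOW], amplitudes, 1.0 - ARREST_RECOVERY,
            noise_sd, ARREST_N_TRACES, "bi", rng,
        )
        k_fast.append(float(fit.k[0]))
        k_slow.append(float(fit.k[1]))
        slow_frac.append(float(fit.slow_fraction))
    return {
        "k_fast": np.array(k_fast),
        "k_slow": np.array(k_slow),
        "slow_fraction": np.array(slow_frac),
        "n_traces_total": n_replicates * ARREST_N_TRACES,
    }


def nb_contrast_benchmark(
    seed: int,
    n_frames: int = 5000,
    epsilon: float = 0.2,
    shape: tuple[int, int] = (32, 32),
) -> dict:
    """Focus-vs-pool molecule-number contrast via the full N&B chain.

    Simulates a photon-counting stack whose central block holds the
    focus-level molecule density, recovers per-pixel molecular numbers,
    and reports the ROI contrast in percent.
    """
    config = SimConfig(image_shape=shape, rng_seed=seed, background_counts=0.0)
    n_map = np.full(shape, POOL_MOLECULES_PER_PIXEL)
    h, w = shape
    n_map[h // 4: h // 2 + h // 4, w // 4: w // 2 + w // 4] = FOCUS_MOLECULES_PER_PIXEL
    stack, _ = simulate_nandb_stack(
        n_map, epsilon, n_frames, config,
        rng=np.random.default_rng(seed),
    )
    maps = nandb.nb_maps(*nandb.pixel_moments(stack))
    rois = np.ones(shape, int)
    rois[n_map == FOCUS_MOLECULES_PER_PIXEL] = 2
    stats = {s.roi_id: s for s in nandb.roi_stats(maps, rois, reference_roi=1)}
    pool = stats[1].mean_molecular_number
    focus = stats[2].mean_molecular_number
    return {
        "pool_n": pool,
        "focus_n": focus,
        "percent_increase": 100.0 * (focus - pool) / pool,
    }


def _field_config(seed: int, shape=(512, 512)) -> SimConfig:
    return SimConfig(
        image_shape=shape, rng_seed=seed, n_frames=8,
        foci_per_cell_mean=CONTROL_FOCI_PER_CELL,
    )


def calibrate_quality_threshold(seed: int, n_cells: int = 25) -> float:
    """Calibrate the manual focus-quality threshold on a held-out field.

    Measures the band-pass response at each true focus position of a
    dedicated calibration field and returns 40% of the median response —
    well above the noise floor, well below typical focus responses.
    """
    config = _field_config(seed)
    labels, truth = make_cell_geometry(config, n_cells)
    stack, truth = simulate_timelapse(labels, truth)
    image = stack.mean_image()
    px = config.pixel_size_um
    response = segquant._spot_band_pass(image, 0.75 / px)
    values = []
    for cell in truth.cells:
        for x_um, y_um in np.atleast_2d(cell.focus_centroids_um):
            r, c = int(round(y_um / px)), int(round(x_um / px))
            r0, r1 = max(r - 2, 0), min(r + 3, response.shape[0])
            c0, c1 = max(c - 2, 0), min(c + 3, response.shape[1])
            values.append(response[r0:r1, c0:c1].max())
    if not values:
        raise RuntimeError("calibration field contains no foci")
    return 0.4 * float(np.median(values))


def foci_pipeline_benchmark(
    seed: int,
    n_cells: int = 500,
    cells_per_field: int = 25,
) -> dict:
    """End-to-end focus pipeline on simulated control-condition fields.

    Generates fields totalling ``n_cells`` cells with Poisson-distributed
    foci at the control-condition mean, segments, detects foci with a
    threshold calibrated on a held-out field, and compares the detected
    mean foci per cell against the generator's.
    """
    threshold = calibrate_quality_threshold(seed + 10_000)
    records: list[segquant.CellRecord] = []
    true_foci = 0
    true_cells = 0
    field_seed = seed
    while true_cells < n_cells:
        want = min(cells_per_field, n_cells - true_cells)
        config = _field_config(field_seed)
        labels, truth = make_cell_geometry(config, want)
        stack, truth = simulate_timelapse(labels, truth)
        image = stack.mean_image()
        px = config.pixel_size_um
        seg = segquant.segment_cells(image, pixel_size_um=px)
        foci = segquant.detect_foci(
            image, seg, quality_threshold=threshold, pixel_size_um=px
        )
        records.extend(segquant.per_cell_metrics(image, seg, foci, pixel_size_um=px))
        true_foci += sum(c.n_foci for c in truth.cells)
        true_cells += truth.n_placed
        field_seed += 1
    summary = segquant.population_summary(records)
    return {
        "detected_mean_foci_per_cell": summary.mean_foci_per_cell,
        "true_mean_foci_per_cell": true_foci / true_cells,
        "generator_mean": CONTROL_FOCI_PER_CELL,
        "n_cells_true": true_cells,
        "n_cells_detected": summary.n_cells,
        "quality_threshold": threshold,
        "summary": dataclasses.asdict(summary),
    }
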