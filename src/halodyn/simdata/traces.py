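"""Synthetic photobleaching-recovery traces with known kinetics.

Normalized recovery state: unity before the bleach; after the bleach

    F(t) = F_inf - sum_i a_i * exp(-k_i * t),  t = 0 at first post-bleach frame

with F_inf = (1 - depth) + sum_i a_i, where the bleach depth follows from
the amplitudes and the immobile fraction (depth * (1 - immobile) = sum a_i).
Raw traces add an intensity scale, an optional slow acquisition-bleaching
decay, a constant background and i.i.d. Gaussian noise.
"""

from __future__ import annotations

import numpy as np

from halodyn.frap import FrapTrace
from halodyn.simdata.config import SimConfig, GroundTruth, FrapTruth

__all__ = ["simulate_frap_traces", "recovery_curve"]

DEFAULT_BLEACH_AREA_UM2 = 3.72


def recovery_curve(
    t_post: np.ndarray,
    k_values: np.ndarray,
    amplitudes: np.ndarray,
    plateau: float,
) -> np.ndarray:
    """Closed-form multi-exponential recovery F(t) = plateau - sum a_i e^(-k_i t)."""
    t_post = np.asarray(t_post, dtype=float)
    out = np.full_like(t_post, plateau)
    for a, k in zip(amplitudes, k_values):
        out -= a * np.exp(-k * t_post)
    return out


def simulate_frap_traces(
    k_values,
    amplitudes,
    immobile_fraction: float,
    noise_sd: float,
    n_traces: int,
    config: SimConfig,
    n_prebleach: int = 50,
    acquisition_bleach_rate: float = 0.0,
    intensity_scale: float = 1000.0,
    background_level: float = 100.0,
    bleach_area_um2: float = DEFAULT_BLEACH_AREA_UM2,
    rng: np.random.Generator | None = None,
) -> tuple[list[FrapTrace], GroundTruth]:
    """Generate raw recovery traces for a known multi-exponential model.

    Parameters
    ----------
    k_values, amplitudes
        Recovery rate constants (1/s) and their amplitudes on the
        normalized scale. Must be positive / non-negative.
    immobile_fraction
        Fraction of the bleached signal that never recovers; together with
        the amplitudes it sets the bleach depth
        (depth = sum(a) / (1 - immobile)).
    noise_sd
        Gaussian noise sd on the normalized scale.
    acquisition_bleach_rate
        Optional slow mono-exponential decay (1/s) applied to the whole
        acquisition, emulating bleaching by the imaging beam itself.

    Returns the raw traces (``i_raw``/``i_b`` channels populated,
    normalization left to the analysis side) and the ground truth.
    """
    k_values = np.atleast_1d(np.asarray(k_values, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if k_values.shape != amplitudes.shape:
        raise ValueError("k_values and amplitudes must have the same length")
    if np.any(k_values <= 0):
        raise ValueError("rate constants must be positive")
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")
    if not 0.0 <= immobile_fraction <= 1.0:
        raise ValueError("immobile_fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if not 0 < n_prebleach < config.n_frames:
        raise ValueError("n_prebleach must be within n_frames")

    mobile_amp = float(amplitudes.sum())
    if immobile_fraction >= 1.0:
        if mobile_amp > 0:
            raise ValueError("immobile_fraction=1 requires zero amplitudes")
        depth = 1.0
    else:
        depth = mobile_amp / (1.0 - immobile_fraction)
    if depth > 1.0 + 1e-9:
        raise ValueError(
            f"amplitudes and immobile fraction imply bleach depth {depth:.3f} > 1"
        )
    plateau = (1.0 - depth) + mobile_amp

    rng = np.random.default_rng(config.rng_seed + 2) if rng is None else rng
    dt = config.frame_interval_s
    t = np.arange(config.n_frames) * dt
    t_post = t[n_prebleach:] - t[n_prebleach]

    state = np.ones(config.n_frames)
    state[n_prebleach:] = recovery_curve(t_post, k_values, amplitudes, plateau)
    decay = np.exp(-acquisition_bleach_rate * t)

    traces: list[FrapTrace] = []
    for _ in range(n_traces):
        noisy = state + rng.normal(0.0, noise_sd, size=state.shape)
        i_raw = intensity_scale * decay * noisy + background_level
        i_b = np.full_like(t, background_level)
        traces.append(
            FrapTrace(
                t=t,
                i_raw=i_raw,
                i_b=i_b,
                n_prebleach=n_prebleach,
                bleach_area_um2=bleach_area_um2,
            )
        )

    truth = GroundTruth(
        seed=config.rng_seed,
        config=config,
        frap=FrapTruth(
            k_values=k_values,
            amplitudes=amplitudes,
            immobile_fraction=immobile_fraction,
            bleach_depth=depth,
            plateau=plateau,
            noise_sd=noise_sd,
            acquisition_bleach_rate=acquisition_bleach_rate,
            mobile_fraction=1.0 - immobile_fraction,
        ),
    )
    return traces, truth
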