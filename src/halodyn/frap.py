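"""Photobleaching-recovery trace normalization and kinetic fitting.

Workflow: raw ROI and background intensity traces are normalized against
an exponential reference fitted to the background-corrected pre-bleach
frames, averaged across experiments, and the post-bleach segment is fitted
with a mono- or bi-exponential recovery model

    F(t) = plateau - sum_i a_i * exp(-k_i * t),   t = 0 at first post-bleach frame.

Rate constants convert to half-times tau_1/2 = ln(2)/k and to apparent 2-D
diffusion coefficients D = beta * A / (4 * tau_1/2) for a bleached area A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "FrapTrace",
    "FrapFit",
    "normalize_trace",
    "average_traces",
    "fit_recovery",
    "half_time",
    "diffusion_coefficient",
    "FitError",
]

LN2 = float(np.log(2.0))


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge."""


@dataclass
class FrapTrace:
    """A single recovery trace with raw, reference and normalized channels.

    ``t`` is the absolute acquisition time grid (s); the first
    ``n_prebleach`` samples precede the bleach.
    """

    t: np.ndarray
    i_raw: np.ndarray
    i_b: np.ndarray
    n_prebleach: int = 50
    bleach_area_um2: float | None = None
    i_sb: np.ndarray | None = None
    i_norm: np.ndarray | None = None
    reference_fallback: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i_raw = np.asarray(self.i_raw, dtype=float)
        self.i_b = np.asarray(self.i_b, dtype=float)
        if not (self.t.shape == self.i_raw.shape == self.i_b.shape):
            raise ValueError("t, i_raw and i_b must have identical shapes")
        if self.t.ndim != 1:
            raise ValueError("traces must be 1-D")
        if not 0 < self.n_prebleach < self.t.size:
            raise ValueError("n_prebleach must be within the trace length")
        if self.bleach_area_um2 is not None and self.bleach_area_um2 <= 0:
            raise ValueError("bleach_area_um2 must be positive")

    @property
    def t_post(self) -> np.ndarray:
        """Post-bleach time grid re-zeroed at the first post-bleach frame."""
        return self.t[self.n_prebleach:] - self.t[self.n_prebleach]

    @property
    def f_post(self) -> np.ndarray:
        if self.i_norm is None:
            raise ValueError("trace is not normalized yet")
        return self.i_norm[self.n_prebleach:]


@dataclass
class FrapFit:
    """Result of a mono- or bi-exponential recovery fit.

    Components are ordered fast-then-slow. Confidence intervals are 95%,
    from the asymptotic covariance unless a residual bootstrap was used.
    """

    model: str
    k: np.ndarray
    k_ci: np.ndarray          # shape (n_comp, 2)
    amplitudes: np.ndarray
    amplitude_ci: np.ndarray  # shape (n_comp, 2)
    plateau: float
    rmse: float
    tau_half: np.ndarray
    beta: float = 1.0
    bleach_area_um2: float | None = None
    diffusion_um2_s: np.ndarray | None = None
    slow_fraction: float | None = None
    slow_fraction_ci: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)
    ci_method: str = "covariance"

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "k_per_s": self.k.tolist(),
            "k_ci95": self.k_ci.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "amplitude_ci95": self.amplitude_ci.tolist(),
            "plateau": self.plateau,
            "rmse": self.rmse,
            "tau_half_s": self.tau_half.tolist(),
            "beta": self.beta,
            "bleach_area_um2": self.bleach_area_um2,
            "flags": self.flags,
            "ci_method": self.ci_method,
        }
        if self.diffusion_um2_s is not None:
            d["diffusion_um2_s"] = self.diffusion_um2_s.tolist()
        if self.slow_fraction is not None:
            d["slow_fraction"] = self.slow_fraction
            d["slow_fraction_ci95"] = list(self.slow_fraction_ci)
        return d


def half_time(k: float) -> float:
    """Recovery half-time tau_1/2 = ln(2)/k for rate constant k (1/s)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return LN2 / k


def diffusion_coefficient(k: float, bleach_area_um2: float, beta: float = 1.0) -> float:
    """Apparent 2-D diffusion coefficient D = beta*A/(4*tau_1/2) in um^2/s.

    Equivalent to beta * A * k / (4 ln 2).
    """
    if k <= 0 or bleach_area_um2 <= 0 or beta <= 0:
        raise ValueError("k, bleach area and beta must be positive")
    return beta * bleach_area_um2 / (4.0 * half_time(k))


def _fit_prebleach_reference(
    t_pre: np.ndarray, i_pre: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Fit offset + amplitude*exp(-lam*t) to the pre-bleach samples.

    Returns the parameter triple and a fallback flag. On fit failure the
    reference degenerates to the pre-bleach mean (amplitude 0).
    """
    mean = float(i_pre.mean())

    def model(t, offset, amp, lam):
        return offset + amp * np.exp(-lam * t)

    # initial guess: linear drift fraction over the pre-bleach window
    slope = np.polyfit(t_pre, i_pre, 1)[0]
    span = t_pre[-1] - t_pre[0] if t_pre[-1] > t_pre[0] else 1.0
    amp0 = max(-slope * span, 1e-6 * abs(mean) + 1e-12)
    lam0 = 1.0 / span
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model,
                t_pre,
                i_pre,
                p0=[mean, amp0, lam0],
                bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        return np.asarray(popt), False
    except (RuntimeError, ValueError):
        return np.array([mean, 0.0, 0.0]), True


def normalize_trace(
    t: np.ndarray,
    i_raw: np.ndarray,
    i_b: np.ndarray,
    n_prebleach: int = 50,
    bleach_area_um2: float | None = None,
) -> FrapTrace:
    """Normalize a raw recovery trace so pre-bleach intensity equals unity.

    The reference I_sb(t) is an exponential (offset + amp*exp(-lam t))
    fitted to the background-corrected pre-bleach samples and extrapolated
    over the whole acquisition; I_norm = (I_raw - I_b) / I_sb. This removes
    both the static background and any slow acquisition-bleaching decay.

    Raises
    ------
    ValueError
        If the extrapolated reference is non-positive anywhere (degenerate
        input such as I_raw == I_b).
    """
    trace = FrapTrace(
        t=t, i_raw=i_raw, i_b=i_b,
        n_prebleach=n_prebleach, bleach_area_um2=bleach_area_um2,
    )
    if n_prebleach < 3:
        raise ValueError("need at least 3 pre-bleach samples to fit a reference")
    corrected = trace.i_raw - trace.i_b
    t_pre = trace.t[:n_prebleach]
    pre_mean = corrected[:n_prebleach].mean()
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach mean; cannot normalize")
    # fit on the unit scale so normalization is exactly scale-invariant
    params, fallback = _fit_prebleach_reference(
        t_pre, corrected[:n_prebleach] / pre_mean
    )
    offset, amp, lam = params
    i_sb = pre_mean * (offset + amp * np.exp(-lam * trace.t))
    if np.any(i_sb <= 0):
        raise ValueError(
            "non-positive reference trace; cannot normalize (check background ROI)"
        )
    trace.i_sb = i_sb
    trace.i_norm = corrected / i_sb
    trace.reference_fallback = fallback
    pre_mean = float(trace.i_norm[:n_prebleach].mean())
    if abs(pre_mean - 1.0) > 0.02:
        trace.reference_fallback = True
        # fall back to plain pre-bleach mean normalization, flagged
        mean = corrected[:n_prebleach].mean()
        if mean <= 0:
            raise ValueError("non-positive pre-bleach mean; cannot normalize")
        trace.i_sb = np.full_like(trace.t, mean)
        trace.i_norm = corrected / mean
    return trace


def average_traces(traces: list[FrapTrace]) -> FrapTrace:
    """Pointwise mean of normalized traces sharing a common time grid."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
            raise ValueError("traces do not share a common time grid")
        if tr.n_prebleach != traces[0].n_prebleach:
            raise ValueError("traces disagree on n_prebleach")
    for tr in traces:
        if tr.i_norm is None:
            raise ValueError("all traces must be normalized before averaging")
    i_norm = np.mean([tr.i_norm for tr in traces], axis=0)
    out = FrapTrace(
        t=t0.copy(),
        i_raw=i_norm.copy(),
        i_b=np.zeros_like(t0),
        n_prebleach=traces[0].n_prebleach,
        bleach_area_um2=traces[0].bleach_area_um2,
    )
    out.i_norm = i_norm
    out.i_sb = np.ones_like(t0)
    return out


def _recovery_model(n_comp: int):
    if n_comp == 1:
        def model(t, plateau, a1, k1):
            return plateau - a1 * np.exp(-k1 * t)
    else:
        def model(t, plateau, a1, k1, a2, k2):
            return plateau - a1 * np.exp(-k1 * t) - a2 * np.exp(-k2 * t)
    return model


def fit_recovery(
    trace: FrapTrace,
    model: str = "mono",
    beta: float = 1.0,
    bootstrap: int = 0,
    rng: np.random.Generator | int | None = None,
) -> FrapFit:
    """Least-squares fit of the post-bleach recovery segment.

    Parameters
    ----------
    trace : FrapTrace
        Normalized trace; the post-bleach segment must hold >= 10 samples.
    model : {"mono", "bi"}
    beta : float
        Geometry factor for the diffusion-coefficient conversion.
    bootstrap : int
        If > 0, number of residual-bootstrap resamples used for the 95% CIs
        instead of the asymptotic covariance.
    """
    if model not in ("mono", "bi"):
        raise ValueError("model must be 'mono' or 'bi'")
    if trace.i_norm is None:
        raise ValueError("trace must be normalized before fitting")
    t_post = trace.t_post
    f_post = trace.f_post
    if t_post.size < 10:
        raise ValueError("post-bleach segment must hold at least 10 samples")

    n_comp = 1 if model == "mono" else 2
    func = _recovery_model(n_comp)
    f0, f_end = float(f_post[0]), float(f_post[-1])
    depth = max(f_end - f0, 0.05)
    span = t_post[-1] if t_post[-1] > 0 else 1.0
    if n_comp == 1:
        p0 = [f_end, depth, 2.0 / span * 5]
        lower = [-np.inf, 0.0, 1e-9]
        upper = [np.inf, np.inf, np.inf]
    else:
        p0 = [f_end, depth * 0.6, 20.0 / span, depth * 0.4, 2.0 / span]
        lower = [-np.inf, 0.0, 1e-9, 0.0, 1e-9]
        upper = [np.inf, np.inf, np.inf, np.inf, np.inf]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                func, t_post, f_post, p0=p0, bounds=(lower, upper), maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{model}-exponential recovery fit failed: {exc}") from exc

    resid = f_post - func(t_post, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))

    if bootstrap and bootstrap > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        samples = []
        fitted = func(t_post, *popt)
        for _ in range(bootstrap):
            resampled = fitted + gen.choice(resid, size=resid.size, replace=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    p_b, _ = optimize.curve_fit(
                        func, t_post, resampled, p0=popt,
                        bounds=(lower, upper), maxfev=20000,
                    )
                samples.append(p_b)
            except (RuntimeError, ValueError):
                continue
        if len(samples) < bootstrap // 2:
            raise FitError("residual bootstrap failed on most resamples")
        samples = np.asarray(samples)
        ci_lo = np.percentile(samples, 2.5, axis=0)
        ci_hi = np.percentile(samples, 97.5, axis=0)
        param_ci = np.stack([ci_lo, ci_hi], axis=1)
        ci_method = "bootstrap"
        boot_samples = samples
    else:
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        param_ci = np.stack([popt - 1.96 * perr, popt + 1.96 * perr], axis=1)
        ci_method = "covariance"
        boot_samples = None

    plateau = float(popt[0])
    amps = popt[1::2]
    ks = popt[2::2]
    amp_ci = param_ci[1::2]
    k_ci = param_ci[2::2]

    # order components fast-then-slow
    order = np.argsort(ks)[::-1]
    ks, amps, k_ci, amp_ci = ks[order], amps[order], k_ci[order], amp_ci[order]

    flags: list[str] = []
    slow_fraction = None
    slow_fraction_ci = None
    if n_comp == 2:
        total = amps.sum()
        slow_fraction = float(amps[1] / total) if total > 0 else float("nan")
        if boot_samples is not None:
            fr = []
            for p_b in boot_samples:
                a = p_b[1::2]
                k = p_b[2::2]
                a = a[np.argsort(k)[::-1]]
                s = a.sum()
                if s > 0:
                    fr.append(a[1] / s)
            slow_fraction_ci = (
                float(np.percentile(fr, 2.5)),
                float(np.percentile(fr, 97.5)),
            )
        else:
            # delta method on f = a_slow/(a_fast + a_slow)
            ia_fast, ia_slow = 1 + 2 * order[0], 1 + 2 * order[1]
            a_f, a_s = amps[0], amps[1]
            total2 = (a_f + a_s) ** 2
            grad = np.zeros(len(popt))
            grad[ia_fast] = -a_s / total2
            grad[ia_slow] = a_f / total2
            var = float(grad @ pcov @ grad)
            se = np.sqrt(max(var, 0.0))
            slow_fraction_ci = (
                slow_fraction - 1.96 * se,
                slow_fraction + 1.96 * se,
            )
        if np.any(amp_ci[:, 0] < 0):
            flags.append("amplitude CI crosses zero: bi model may be over-specified")
        if ks[1] > 0 and ks[0] / ks[1] < 3:
            flags.append("rate constants within 3x: components weakly identifiable")

    tau = LN2 / ks
    diffusion = None
    if trace.bleach_area_um2 is not None:
        diffusion = np.array(
            [diffusion_coefficient(k, trace.bleach_area_um2, beta) for k in ks]
        )

    return FrapFit(
        model=model,
        k=ks,
        k_ci=k_ci,
        amplitudes=amps,
        amplitude_ci=amp_ci,
        plateau=plateau,
        rmse=rmse,
        tau_half=tau,
        beta=beta,
        bleach_area_um2=trace.bleach_area_um2,
        diffusion_um2_s=diffusion,
        slow_fraction=slow_fraction,
        slow_fraction_ci=slow_fraction_ci,
        flags=flags,
        ci_method=ci_method,
    )
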