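"""Pixel-wise noise-corrected T2 relaxometry for multi-echo spin-echo magnitude data.

Magnitude MR images carry Rician noise: each pixel is the modulus of two
independent Gaussian channels, so its expected *squared* intensity is the
squared noise-free signal plus a constant offset ``B^2 = 2 sigma^2``. The
three-parameter model fitted here,

    S(TE)^2 = S0^2 exp(-2 TE / T2) + B^2,

is therefore unbiased in squared-signal space, unlike the traditional
two-parameter log-linear magnitude fit whose T2 estimate is inflated at low
SNR. The first echo is excluded by default to avoid stimulated-echo
contamination in multi-echo CPMG trains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import FitConfig
from .exceptions import InputError

__all__ = [
    "EchoStack",
    "T2Map",
    "model_signal_squared",
    "fit_pixel",
    "fit_pixel_loglinear",
    "fit_map",
]


@dataclass
class EchoStack:
    """4D multi-echo magnitude stack: (slice, row, col, echo) plus echo times (ms)."""

    data: np.ndarray
    echo_times: np.ndarray
    pixel_spacing: tuple[float, float] = (0.313, 0.446)
    slice_gap: float = 0.5
    slice_thickness: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise InputError("EchoStack data must be 4D (slice, row, col, echo)")
        if self.data.shape[-1] != self.echo_times.size:
            raise InputError(
                f"number of echoes ({self.data.shape[-1]}) does not match "
                f"echo_times length ({self.echo_times.size})"
            )
        if np.any(np.diff(self.echo_times) <= 0):
            raise InputError("echo_times must be strictly increasing")
        if np.any(self.data < 0):
            raise InputError("magnitude intensities must be >= 0")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class T2Map:
    """Per-pixel fit results: T2 (ms), S0, noise term B, validity and residual RSS."""

    t2: np.ndarray
    s0: np.ndarray
    b: np.ndarray
    valid: np.ndarray
    residual_rss: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t2.shape


class PixelFit(NamedTuple):
    s0: float
    t2: float
    b: float
    rss: float
    valid: bool


def model_signal_squared(s0: float, t2: float, b: float, te) -> float | np.ndarray:
    """Expected squared magnitude ``S0^2 exp(-2 TE/T2) + B^2`` at echo time ``te`` (ms)."""
    if np.any(np.asarray(t2) <= 0):
        raise InputError("t2 must be > 0")
    te = np.asarray(te, dtype=float)
    out = s0 * s0 * np.exp(-2.0 * te / t2) + b * b
    return float(out) if out.ndim == 0 else out


def _included(signals: np.ndarray, echo_times: np.ndarray, config: FitConfig):
    keep = np.array([i not in config.excluded_echoes for i in range(echo_times.size)])
    sig, te = signals[keep], echo_times[keep]
    if sig.size < 4:
        raise InputError(
            f"need >= 4 usable echoes for a three-parameter fit, got {sig.size}"
        )
    return sig, te


def _initial_guess(sig: np.ndarray, te: np.ndarray, config: FitConfig):
    """Log-linear start from the two smallest-TE included echoes.

    The noise term starts at the part of the smallest measured signal that the
    log-linear decay cannot explain (its full value when the decay predicts
    essentially zero, near zero when the decay already accounts for it).
    """
    lo_t2, hi_t2 = config.t2_bounds
    s1, s2 = sig[0], sig[1]
    t1, t2_ = te[0], te[1]
    if s1 > 0 and s2 > 0 and s1 > s2:
        t2_init = (t2_ - t1) / np.log(s1 / s2)
        s0_init = s1 * np.exp(t1 / t2_init)
    else:  # non-decaying start: fall back to mid-range decay
        t2_init = np.sqrt(lo_t2 * hi_t2)
        s0_init = max(sig.max(), 1.0)
    eps = 1e-6
    t2_init = float(np.clip(t2_init, lo_t2 * (1 + eps), hi_t2 * (1 - eps)))
    s0_init = float(np.clip(s0_init, config.s0_bounds[0] + eps,
                            min(config.s0_bounds[1], 1e12)))
    pred_min = s0_init * np.exp(-te[np.argmin(sig)] / t2_init)
    b_init = float(np.sqrt(max(float(sig.min()) ** 2 - pred_min ** 2, 0.0)))
    b_init = float(np.clip(b_init, config.b_bounds[0],
                           min(config.b_bounds[1], 1e12)))
    return s0_init, t2_init, b_init


def fit_pixel(signals: Sequence[float], echo_times: Sequence[float],
              config: FitConfig | None = None) -> PixelFit:
    """Fit (S0, T2, B) to one pixel's per-echo magnitudes by bounded least squares.

    Minimizes ``sum_TE (S_meas^2 - model_signal_squared)^2`` over the included
    echoes with a trust-region-reflective solver. Non-convergent or
    out-of-bounds solutions are handled per ``config.fallback_policy``.
    """
    config = (config or FitConfig()).validate()
    signals = np.asarray(signals, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    if signals.shape != echo_times.shape:
        raise InputError("signals and echo_times must have equal length")
    sig, te = _included(signals, echo_times, config)
    if np.all(sig == 0):
        return PixelFit(0.0, np.nan, 0.0, np.nan, False)

    sq = sig * sig
    lo = np.array([config.s0_bounds[0], config.t2_bounds[0], config.b_bounds[0]])
    hi = np.array([config.s0_bounds[1], config.t2_bounds[1], config.b_bounds[1]])

    def resid(x):
        s0, t2v, bv = x
        return s0 * s0 * np.exp(-2.0 * te / t2v) + bv * bv - sq

    def jac(x):
        s0, t2v, bv = x
        e = np.exp(-2.0 * te / t2v)
        return np.column_stack([
            2.0 * s0 * e,
            s0 * s0 * e * (2.0 * te / (t2v * t2v)),
            np.full_like(te, 2.0 * bv),
        ])

    x0 = np.array(_initial_guess(sig, te, config))

    # S0 and B enter the objective only squared, so in (s0, rate, b) with
    # rate = 1/T2 the problem is smooth and sign-symmetric: solve it first
    # with unbounded Levenberg-Marquardt (fast), and accept |s0|, |b| when
    # the implied T2 lands inside its bounds -- the unconstrained optimum is
    # then also the bounded one. Fall back to bounded TRF otherwise.
    def resid_rate(x):
        s0, rate, bv = x
        with np.errstate(over="ignore"):
            out = s0 * s0 * np.exp(np.clip(-2.0 * te * rate, -700, 700)) + bv * bv - sq
        return np.nan_to_num(out, posinf=1e300)

    def jac_rate(x):
        s0, rate, bv = x
        e = np.exp(np.clip(-2.0 * te * rate, -350, 350))
        return np.column_stack([
            2.0 * s0 * e,
            -2.0 * te * s0 * s0 * e,
            np.full_like(te, 2.0 * bv),
        ])

    sol = least_squares(
        resid_rate, np.array([x0[0], 1.0 / x0[1], x0[2]]),
        jac=jac_rate, method="lm",
        ftol=config.tolerance, xtol=config.tolerance, gtol=config.tolerance,
        max_nfev=config.max_iterations * 4,
    )
    s0_hat, rate_hat, b_hat = sol.x
    s0_hat, b_hat = abs(s0_hat), abs(b_hat)
    t2_hat = 1.0 / rate_hat if rate_hat > 0 else np.inf
    feasible = (sol.success
                and lo[0] <= s0_hat <= hi[0]
                and lo[1] <= t2_hat <= hi[1]
                and lo[2] <= b_hat <= hi[2])
    if not feasible:
        sol = least_squares(
            resid, x0, jac=jac, bounds=(lo, hi), method="trf",
            ftol=config.tolerance, xtol=config.tolerance, gtol=config.tolerance,
            max_nfev=config.max_iterations * 4,
        )
        s0_hat, t2_hat, b_hat = sol.x
    rss = float(np.sum(sol.fun ** 2))
    # Solutions pinned at the T2 bounds are non-physiologic (fluid, artifact,
    # pure noise); mark them invalid unless the policy says clamp.
    edge = (t2_hat >= config.t2_bounds[1] * (1 - 1e-9)
            or t2_hat <= config.t2_bounds[0] * (1 + 1e-9))
    ok = bool(sol.success)
    if config.fallback_policy == "mark_invalid":
        valid = ok and not edge
    else:  # clamp
        valid = ok
        t2_hat = float(np.clip(t2_hat, *config.t2_bounds))
    return PixelFit(float(s0_hat), float(t2_hat), float(b_hat), rss, valid)


def fit_pixel_loglinear(signals: Sequence[float], echo_times: Sequence[float],
                        config: FitConfig | None = None) -> tuple[float, float]:
    """Traditional uncorrected two-parameter fit: linear regression of ln S on TE.

    Returns (s0, t2). Serves as the biased baseline against which the
    noise-corrected fit is compared; positive magnitudes required.
    """
    config = (config or FitConfig()).validate()
    signals = np.asarray(signals, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    sig, te = _included(signals, echo_times, config)
    if np.any(sig <= 0):
        raise InputError("log-linear fit requires strictly positive magnitudes")
    slope, intercept = np.polyfit(te, np.log(sig), 1)
    if slope >= 0:
        return float(np.exp(intercept)), float("inf")
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_map(stack: EchoStack, mask: np.ndarray, config: FitConfig | None = None) -> T2Map:
    """Apply :func:`fit_pixel` to every masked pixel of a 4D echo stack.

    ``mask`` may be boolean or an integer label image (any nonzero label is
    fitted). Unmasked pixels are marked invalid with NaN parameters. The
    result is independent of pixel iteration order.
    """
    config = (config or FitConfig()).validate()
    mask = np.asarray(mask)
    if mask.shape != stack.spatial_shape:
        raise InputError(
            f"mask shape {mask.shape} does not match stack spatial shape "
            f"{stack.spatial_shape}"
        )
    mbool = mask.astype(bool)
    shape = stack.spatial_shape
    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    b = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    tes = stack.echo_times
    for idx in zip(*np.nonzero(mbool)):
        f = fit_pixel(stack.data[idx], tes, config)
        s0[idx], t2[idx], b[idx], rss[idx], valid[idx] = f.s0, f.t2, f.b, f.rss, f.valid
    return T2Map(t2=t2, s0=s0, b=b, valid=valid, residual_rss=rss)
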