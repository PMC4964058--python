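"""Mono-exponential T2*/R2* decay fitting.

The signal model throughout is

    S(TE) = S0 * exp(-TE / T2*) [+ C]

with TE and T2* in milliseconds; R2* = 1000 / T2* in s^-1.  Four fitting
routes are provided:

``fit_loglinear``
    Ordinary (optionally weighted) least squares of ln(S) on TE; the
    workhorse, closed form.
``fit_nls``
    Nonlinear least squares in signal space, optionally with a constant
    background-noise offset C.
``fit_truncation``
    Log-linear fit after excluding echoes that have decayed to the
    background-noise floor (the standard remedy for very short T2*).
``compute_map``
    Per-pixel mapping with an r-squared quality gate.

Goodness of fit (r-squared) is always evaluated in signal space over the
echoes actually used, so the quality gate means the same thing for every
method.  Degenerate inputs yield fits with ``valid=False`` and a reason
code, never exceptions, so per-pixel mapping cannot abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .phantom import MultiEchoImage
from .tissues import DEFAULT_MIN_ECHOES, DEFAULT_R2_GATE

RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # mean magnitude of pure noise / sigma

METHODS = ("loglinear", "nls", "nls_offset", "truncation")


@dataclass(frozen=True)
class EchoSeries:
    """One decay sample: echo times (ms) with magnitude signal values."""

    echo_times_ms: np.ndarray
    signal: np.ndarray
    background_sigma: float | None = None

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "echo_times_ms", te)
        object.__setattr__(self, "signal", sig)
        if te.size < 2 or sig.size != te.size:
            raise ValueError("need >= 2 echoes and matching signal length")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(sig < 0):
            raise ValueError("magnitude signal must be non-negative")
        if self.background_sigma is not None and self.background_sigma < 0:
            raise ValueError("background_sigma must be >= 0")

    def __len__(self) -> int:
        return int(self.echo_times_ms.size)


@dataclass(frozen=True)
class DecayFit:
    """Result of one decay-curve fit.

    ``t2star_ms`` and ``r2star`` always satisfy r2star * t2star = 1000
    when valid; both are NaN otherwise.  ``used_echoes`` marks the echoes
    that entered the fit.
    """

    s0: float
    t2star_ms: float
    offset: float
    r_squared: float
    used_echoes: np.ndarray
    method: str
    valid: bool
    reason: str = ""

    @property
    def r2star(self) -> float:
        """Relaxation rate in s^-1 (1000 / T2*[ms])."""
        return 1000.0 / self.t2star_ms

    @property
    def n_used(self) -> int:
        return int(np.count_nonzero(self.used_echoes))


def _invalid(series: EchoSeries, method: str, reason: str,
             used: np.ndarray | None = None) -> DecayFit:
    mask = np.zeros(len(series), bool) if used is None else used
    return DecayFit(np.nan, np.nan, 0.0, np.nan, mask, method, False, reason)


def _signal_space_r2(series: EchoSeries, pred: np.ndarray, used: np.ndarray) -> float:
    obs = series.signal[used]
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - pred[used]) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def fit_loglinear(series: EchoSeries,
                  min_echoes: int = DEFAULT_MIN_ECHOES,
                  use_echoes: np.ndarray | None = None,
                  weights: np.ndarray | None = None,
                  method_label: str = "loglinear") -> DecayFit:
    """Closed-form log-linear fit: OLS of ln(signal) against echo time.

    Non-positive signals are dropped automatically (ln undefined); if
    fewer than ``min_echoes`` usable echoes remain, or the fitted slope
    is not a decay, the result carries ``valid=False`` with a reason.
    ``weights`` (optional, per echo, >= 0) switch to weighted LS; zero
    weight excludes the echo.
    """
    te = series.echo_times_ms
    used = np.ones(len(series), bool) if use_echoes is None else np.asarray(use_echoes, bool).copy()
    used &= series.signal > 0
    w = np.ones(len(series)) if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    used &= w > 0
    if np.count_nonzero(used) < max(min_echoes, 2):
        return _invalid(series, method_label, "too few usable echoes", used)

    x, y, wu = te[used], np.log(series.signal[used]), w[used]
    sw = wu.sum()
    xb, yb = np.sum(wu * x) / sw, np.sum(wu * y) / sw
    sxx = np.sum(wu * (x - xb) ** 2)
    if sxx == 0.0:
        return _invalid(series, method_label, "degenerate echo times", used)
    slope = float(np.sum(wu * (x - xb) * (y - yb)) / sxx)
    intercept = float(yb - slope * xb)
    if slope >= 0.0:
        return _invalid(series, method_label, "no decay", used)

    t2star = -1.0 / slope  # ms
    s0 = float(np.exp(intercept))
    pred = s0 * np.exp(-te / t2star)
    r2 = _signal_space_r2(series, pred, used)
    return DecayFit(s0, t2star, 0.0, r2, used, method_label, True)


def fit_nls(series: EchoSeries, with_offset: bool = False,
            min_echoes: int = DEFAULT_MIN_ECHOES,
            max_nfev: int = 200) -> DecayFit:
    """Nonlinear least squares of S0*exp(-TE/T2*) (+C) in signal space.

    Initialized from the log-linear fit; the offset model needs one more
    point than ``min_echoes``.  Non-convergence returns ``valid=False``.
    """
    method = "nls_offset" if with_offset else "nls"
    needed = min_echoes + (1 if with_offset else 0)
    used = series.signal > 0
    if with_offset:
        used = np.ones(len(series), bool)  # offset model tolerates zeros
    if np.count_nonzero(used) < needed:
        return _invalid(series, method, "too few usable echoes", used)

    init = fit_loglinear(series, min_echoes=2)
    if init.valid:
        s0_0, r2_0 = init.s0, init.r2star
    else:
        s0_0 = float(max(series.signal.max(), 1e-6))
        r2_0 = 1000.0 / float(series.echo_times_ms[-1])
    te, sig = series.echo_times_ms[used], series.signal[used]

    if with_offset:
        def resid(p):
            return p[0] * np.exp(-te * p[1] / 1000.0) + p[2] - sig
        x0 = [s0_0, r2_0, 0.0]
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
    else:
        def resid(p):
            return p[0] * np.exp(-te * p[1] / 1000.0) - sig
        x0 = [s0_0, r2_0]
        bounds = ([0.0, 0.0], [np.inf, np.inf])

    sol = least_squares(resid, x0, bounds=bounds, max_nfev=max_nfev)
    if not sol.success or sol.x[1] <= 0:
        return _invalid(series, method, "no convergence", used)
    s0, r2star = float(sol.x[0]), float(sol.x[1])
    offset = float(sol.x[2]) if with_offset else 0.0
    t2star = 1000.0 / r2star
    pred = s0 * np.exp(-series.echo_times_ms / t2star) + offset
    r2 = _signal_space_r2(series, pred, used)
    return DecayFit(s0, t2star, offset, r2, used, method, True)


def noise_floor(background_sigma: float, floor_multiple: float = 2.0) -> float:
    """Signal level treated as 'decayed to background noise'.

    Pure Rician noise has mean sigma*sqrt(pi/2) (the Rayleigh mean);
    echoes below ``floor_multiple`` times that carry little decay
    information.
    """
    return floor_multiple * background_sigma * RAYLEIGH_MEAN


def fit_truncation(series: EchoSeries, floor_multiple: float = 2.0,
                   min_echoes: int = DEFAULT_MIN_ECHOES) -> DecayFit:
    """Log-linear fit after discarding echoes at the noise floor.

    Requires ``series.background_sigma``; with sigma = 0 no echo is
    excluded and the result equals the plain log-linear fit.
    """
    if series.background_sigma is None:
        raise ValueError("fit_truncation requires series.background_sigma")
    floor = noise_floor(series.background_sigma, floor_multiple)
    keep = series.signal >= floor
    if np.count_nonzero(keep & (series.signal > 0)) < min_echoes:
        return _invalid(series, "truncation", "all echoes at noise floor",
                        keep & (series.signal > 0))
    return fit_loglinear(series, min_echoes=min_echoes, use_echoes=keep,
                         method_label="truncation")


# ---------------------------------------------------------------------------
# per-pixel mapping


@dataclass
class R2StarMap:
    """Per-pixel relaxometry product.

    ``quality`` is True only where the fit is valid, r-squared exceeds
    the gate, and the pixel is above the background signal floor.
    """

    t2star_ms: np.ndarray
    r2star: np.ndarray
    r_squared: np.ndarray
    quality: np.ndarray
    valid: np.ndarray
    method: str
    echo_times_ms: np.ndarray
    gate: float = DEFAULT_R2_GATE


def _map_loglinear_vectorized(image: MultiEchoImage, min_echoes: int,
                              foreground: np.ndarray) -> tuple[np.ndarray, ...]:
    """Closed-form per-pixel log-linear fit over a whole stack at once."""
    te = image.echo_times_ms
    sig = image.echo_images  # (n_echo, ny, nx)
    w = (sig > 0) & foreground  # usable echoes per pixel
    n_used = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(w, np.log(np.where(sig > 0, sig, 1.0)), 0.0)
    x = te.reshape(-1, 1, 1) * w
    sw = n_used.astype(float)
    safe = sw >= max(min_echoes, 2)
    sw_safe = np.where(sw > 0, sw, 1.0)
    xb = x.sum(axis=0) / sw_safe
    yb = y.sum(axis=0) / sw_safe
    sxx = ((te.reshape(-1, 1, 1) - xb) ** 2 * w).sum(axis=0)
    sxy = ((te.reshape(-1, 1, 1) - xb) * (y - yb) * w).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    intercept = yb - slope * xb
    valid = safe & (slope < 0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t2 = np.where(valid, -1.0 / slope, np.nan)
        r2star = np.where(valid, -1000.0 * slope, np.nan)
        pred = np.exp(intercept) * np.exp(te.reshape(-1, 1, 1) * slope)
        ss_res = (((sig - pred) * w) ** 2).sum(axis=0)
        mean_sig = (sig * w).sum(axis=0) / sw_safe
        ss_tot = (((sig - mean_sig) * w) ** 2).sum(axis=0)
        rsq = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), np.nan)
    rsq = np.where(valid, rsq, np.nan)
    return t2, r2star, rsq, valid


def compute_map(image: MultiEchoImage, method: str = "loglinear",
                gate: float = DEFAULT_R2_GATE,
                min_echoes: int = DEFAULT_MIN_ECHOES,
                background_sigma: float | None = None,
                signal_floor: float | None = None,
                floor_multiple: float = 2.0) -> R2StarMap:
    """Fit every pixel of a multi-echo stack and gate on fit quality.

    Background pixels (first-echo signal below ``signal_floor``, default
    3x ``background_sigma`` when known else 1 % of the image maximum) are
    excluded up front.  The quality mask requires a valid fit with
    r-squared strictly above ``gate``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "truncation" and background_sigma is None:
        raise ValueError("truncation mapping requires background_sigma")
    first = image.echo_images[0]
    if signal_floor is None:
        if background_sigma is not None and background_sigma > 0:
            signal_floor = 3.0 * background_sigma
        else:
            signal_floor = 0.01 * float(image.echo_images.max())
    foreground = first >= signal_floor

    if method == "loglinear":
        t2, r2s, rsq, valid = _map_loglinear_vectorized(image, min_echoes, foreground)
        valid = valid & foreground
    else:
        shape = first.shape
        t2 = np.full(shape, np.nan)
        r2s = np.full(shape, np.nan)
        rsq = np.full(shape, np.nan)
        valid = np.zeros(shape, bool)
        for idx in np.argwhere(foreground):
            series = EchoSeries(image.echo_times_ms,
                                image.echo_images[:, idx[0], idx[1]],
                                background_sigma=background_sigma)
            if method == "nls":
                f = fit_nls(series, with_offset=False, min_echoes=min_echoes)
            elif method == "nls_offset":
                f = fit_nls(series, with_offset=True, min_echoes=min_echoes)
            else:
                f = fit_truncation(series, floor_multiple, min_echoes)
            if f.valid:
                t2[idx[0], idx[1]] = f.t2star_ms
                r2s[idx[0], idx[1]] = f.r2star
                rsq[idx[0], idx[1]] = f.r_squared
                valid[idx[0], idx[1]] = True
    quality = valid & (rsq > gate)
    return R2StarMap(t2, r2s, rsq, quality, valid, method, image.echo_times_ms, gate)
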