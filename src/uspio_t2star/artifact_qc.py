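"""Detection and handling of artifact-corrupted late echoes.

Susceptibility ("blooming") artifacts from nearby iron-rich structures
attenuate later echoes of a decay curve while leaving early echoes
intact.  The workflow here mirrors the manual remedy of inspecting the
decay curve, removing artifact-influenced late echoes and refitting —
automated as: fit the initial trajectory from the first few echoes,
flag later echoes that fall far from its prediction, and refit without
them.  A down-weighting variant is provided as a softer alternative to
outright exclusion.

Departure from the trajectory is judged on log-signal residuals with
the usual linear-regression prediction leverage 1 + 1/m + (x-xbar)^2/Sxx,
so that the growing extrapolation uncertainty of the short initial fit
does not masquerade as artifact on clean noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relaxometry import DecayFit, EchoSeries, fit_loglinear
from .tissues import DEFAULT_MIN_ECHOES

WEIGHT_RULES = ("uniform", "late_downweight", "residual_downweight")


@dataclass
class ArtifactReport:
    """Outcome of artifact-echo detection and refit for one series."""

    flagged_echoes: np.ndarray      # bool, True = artifact-suspect
    initial_fit: DecayFit           # early-echo trajectory
    refit: DecayFit                 # fit excluding flagged echoes
    r_squared_before: float
    r_squared_after: float
    n_testable: int                 # echoes beyond the initial window
    rule_params: tuple[int, float]  # (m_init, k_sigma)

    @property
    def any_flagged(self) -> bool:
        return bool(self.flagged_echoes.any())


def _standardized_residuals(series: EchoSeries, init_fit: DecayFit,
                            init_mask: np.ndarray) -> np.ndarray:
    """|log-residual| of each echo vs the initial trajectory, in units of
    its leverage-adjusted noise scale (NaN inside the initial window,
    +inf for unloggable zero signals)."""
    te = series.echo_times_ms
    m = int(init_mask.sum())
    x = te[init_mask]
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    pred_ln = np.log(init_fit.s0) - te / init_fit.t2star_ms
    pred_sig = np.exp(pred_ln)

    with np.errstate(divide="ignore"):
        obs_ln = np.where(series.signal > 0, np.log(np.maximum(series.signal, 1e-300)), -np.inf)
    resid = np.abs(obs_ln - pred_ln)

    # per-echo log-noise scale: initial-window rms residual, floored by the
    # propagated background noise (sigma/S) and a machine-epsilon guard
    init_rms = float(np.sqrt(np.mean((obs_ln[init_mask] - pred_ln[init_mask]) ** 2)))
    sigma = series.background_sigma or 0.0
    eps_floor = float(np.finfo(float).eps * 100)
    with np.errstate(divide="ignore"):
        sigma_ln = np.where(pred_sig > 0, sigma / np.maximum(pred_sig, 1e-300), np.inf)
    scale = np.maximum.reduce([np.full_like(resid, init_rms), sigma_ln,
                               np.full_like(resid, eps_floor)])
    leverage = 1.0 + 1.0 / m + (te - xbar) ** 2 / sxx
    z = resid / (scale * np.sqrt(leverage))
    z[init_mask] = np.nan
    return z


def detect_artifact_echoes(series: EchoSeries, m_init: int = 3,
                           k_sigma: float = 3.0,
                           min_echoes: int = DEFAULT_MIN_ECHOES,
                           allow_relaxed: bool = False) -> ArtifactReport:
    """Flag late echoes far from the initial decay trajectory.

    The first ``m_init`` echoes define the trajectory (log-linear fit
    with the echo floor relaxed to ``m_init`` for this internal step);
    every later echo is tested independently against its prediction and
    flagged when its leverage-standardized log residual exceeds
    ``k_sigma``.  Flags do not cascade: each echo is judged on its own
    departure from the same trajectory.
    """
    if m_init < 2:
        raise ValueError("m_init must be >= 2")
    n = len(series)
    if n < m_init + 1:
        raise ValueError(f"series of length {n} leaves no echo to test after "
                         f"the {m_init}-echo initial window")
    init_mask = np.zeros(n, bool)
    init_mask[:m_init] = True
    init_fit = fit_loglinear(series, min_echoes=m_init, use_echoes=init_mask)

    flagged = np.zeros(n, bool)
    if init_fit.valid:
        z = _standardized_residuals(series, init_fit, init_mask)
        late = ~init_mask
        flagged[late] = z[late] > k_sigma

    before = fit_loglinear(series, min_echoes=min_echoes)
    after = refit_excluding(series, flagged, min_echoes=min_echoes,
                            allow_relaxed=allow_relaxed)
    return ArtifactReport(
        flagged_echoes=flagged,
        initial_fit=init_fit,
        refit=after,
        r_squared_before=before.r_squared if before.valid else np.nan,
        r_squared_after=after.r_squared if after.valid else np.nan,
        n_testable=n - m_init,
        rule_params=(m_init, k_sigma),
    )


def refit_excluding(series: EchoSeries, flagged: np.ndarray,
                    min_echoes: int = DEFAULT_MIN_ECHOES,
                    allow_relaxed: bool = False) -> DecayFit:
    """Refit using only unflagged echoes.

    Dropping echoes trades artifact robustness for sampling accuracy, so
    when fewer than ``min_echoes`` would remain the fit is invalid by
    default; ``allow_relaxed`` opts in to a 3-echo floor.
    """
    flagged = np.asarray(flagged, bool)
    if flagged.shape != (len(series),):
        raise ValueError("flagged mask does not align with series")
    keep = ~flagged
    floor = min_echoes
    if np.count_nonzero(keep & (series.signal > 0)) < min_echoes and allow_relaxed:
        floor = 3
    return fit_loglinear(series, min_echoes=floor, use_echoes=keep)


def weighted_fit(series: EchoSeries, weight_rule: str = "uniform",
                 decay_ratio: float = 0.7, m_init: int = 3,
                 k_sigma: float = 3.0,
                 min_echoes: int = DEFAULT_MIN_ECHOES) -> DecayFit:
    """Weighted log-linear fit with a named late-echo weighting rule.

    ``uniform`` reproduces the plain fit; ``late_downweight`` decays the
    weights geometrically with echo index (ratio ``decay_ratio``);
    ``residual_downweight`` performs one reweighting pass from the
    artifact-detection residuals, w = 1 / (1 + (z / k_sigma)^2) with z
    the leverage-standardized log residual.
    """
    if weight_rule not in WEIGHT_RULES:
        raise ValueError(f"unknown weight_rule {weight_rule!r}; choose from {WEIGHT_RULES}")
    n = len(series)
    if weight_rule == "uniform":
        weights = np.ones(n)
    elif weight_rule == "late_downweight":
        weights = decay_ratio ** np.arange(n)
    else:
        init_mask = np.zeros(n, bool)
        init_mask[:m_init] = True
        init_fit = fit_loglinear(series, min_echoes=m_init, use_echoes=init_mask)
        if not init_fit.valid:
            weights = np.ones(n)
        else:
            z = _standardized_residuals(series, init_fit, init_mask)
            weights = np.ones(n)
            late = ~init_mask
            with np.errstate(over="ignore", invalid="ignore"):
                weights[late] = 1.0 / (1.0 + (z[late] / k_sigma) ** 2)
            weights[~np.isfinite(weights)] = 0.0
    return fit_loglinear(series, min_echoes=min_echoes, weights=weights,
                         method_label="loglinear")
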