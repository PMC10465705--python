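"""Per-replica rupture-time and energy extraction.

Rupture of the residual contact interface is treated as a two-state
process.  Two independent criteria frame the event on each replica:

1. a sigmoidal fit of the (smoothed) internal-energy profile,

       E_fit(t) = E_min + (E_max - E_min) / (1 + 10^(m (t50 - t))),

   whose flex t50 is the rupture time and whose value at the flex minus
   the bound plateau, (E_max - E_min)/2, is the internal-energy
   contribution deltaU;

2. a geometric heuristic: the first time the minimum distance between
   the broken moieties exceeds a threshold and stays there for a number
   of consecutive frames.

The two are cross-validated per replica; disagreement is reported as a
fraction of the trace span.  Replicas without a detectable transition
(amplitude below 3x the residual noise, or a non-convergent fit) are
flagged censored, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .synthetic import DistanceTrace, EnergyTrace, sigmoid_mean_path


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with truncated edge windows.

    ``window`` must be odd and within the series length; window=1 is the
    identity.  Length is preserved: near the edges the window shrinks to
    the available samples.
    """
    x = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not 1 <= window <= x.size:
        raise ValueError("window must lie in [1, len(series)]")
    if window == 1:
        return x.copy()
    return (pd.Series(x)
            .rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def default_window(n_samples: int, fraction: float = 0.01) -> int:
    """Smoothing window: ``fraction`` of the trace length, forced odd."""
    w = max(int(round(fraction * n_samples)), 1)
    return w if w % 2 == 1 else w + 1


class SigmoidTransitionFit(BaseEstimator):
    """Nonlinear least-squares fit of a two-state base-10 logistic.

    Parameters
    ----------
    smoothing_window : int or "auto"
        Centred moving-average window applied before fitting; "auto"
        takes 1% of the trace length (odd).
    min_amplitude_sigma : float
        A fitted amplitude below this multiple of the residual s.d. is
        treated as "no detectable transition" (censored), not an error.
    maxfev : int
        Function-evaluation budget of the Levenberg-Marquardt solver.

    Attributes (after ``fit``)
    --------------------------
    E_min_, E_max_ : bound / broken plateau energies (kT)
    m_ : steepness (decades per time unit)
    t50_ : flex time = rupture time
    pcov_ : 4x4 parameter covariance estimate
    residual_sd_ : s.d. of the smoothed-trace residuals
    converged_ : True when the fit converged with a detectable transition
    """

    def __init__(self, smoothing_window: Union[int, str] = "auto",
                 min_amplitude_sigma: float = 3.0, maxfev: int = 20000):
        self.smoothing_window = smoothing_window
        self.min_amplitude_sigma = min_amplitude_sigma
        self.maxfev = maxfev

    @staticmethod
    def _initial_guess(t: np.ndarray, y: np.ndarray):
        n = t.size
        dec = max(n // 10, 1)
        e_lo = float(np.mean(y[:dec]))
        e_hi = float(np.mean(y[-dec:]))
        mid = 0.5 * (e_lo + e_hi)
        above = np.nonzero(y >= mid)[0]
        t50 = float(t[above[0]]) if above.size else float(t[n // 2])
        q1 = e_lo + 0.25 * (e_hi - e_lo)
        q3 = e_lo + 0.75 * (e_hi - e_lo)
        i1 = np.nonzero(y >= q1)[0]
        i3 = np.nonzero(y >= q3)[0]
        span = (t[i3[0]] - t[i1[0]]) if (i1.size and i3.size
                                         and i3[0] > i1[0]) else 0.0
        # logistic 25%-75% crossing interval is 2 log10(3) / m
        dt_med = float(np.median(np.diff(t))) if n > 1 else 1.0
        m0 = 2 * np.log10(3.0) / span if span > 0 else 1.0 / (10 * dt_med)
        return e_lo, e_hi, m0, t50

    def fit(self, t, E) -> "SigmoidTransitionFit":
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(E, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("t and E must have equal length")
        if t.size < 50:
            raise ValueError("need at least 50 samples to fit")
        w = (default_window(t.size) if self.smoothing_window == "auto"
             else int(self.smoothing_window))
        ys = moving_average(y, w)
        p0 = self._initial_guess(t, ys)

        self.converged_ = False
        self.pcov_ = np.full((4, 4), np.nan)
        self.E_min_, self.E_max_, self.m_, self.t50_ = (
            p0[0], p0[1], np.nan, np.nan)
        try:
            popt, pcov = curve_fit(
                lambda tt, e0, e1, m, t50:
                    sigmoid_mean_path(tt, e0, e1, m, t50),
                t, ys, p0=p0, maxfev=self.maxfev)
        except RuntimeError:
            self.residual_sd_ = float(np.std(ys - np.mean(ys), ddof=1))
            return self
        e0, e1, m, t50 = popt
        if m < 0:     # mirrored solution: same curve with swapped plateaus
            e0, e1, m, t50 = e1, e0, -m, t50
        fitted = sigmoid_mean_path(t, e0, e1, m, t50)
        resid_s = ys - fitted
        resid_raw = y - fitted
        self.residual_sd_ = float(np.std(resid_raw, ddof=1))
        self.E_min_, self.E_max_, self.m_, self.t50_ = (
            float(e0), float(e1), float(m), float(t50))
        # curve_fit scales the covariance by the *smoothed* residual
        # variance under an iid assumption; rescale to the raw noise and
        # inflate for serial correlation (AR(1) effective sample size),
        # otherwise the reported errors are optimistic by ~sqrt(window).
        var_s = float(np.var(resid_s, ddof=1))
        if var_s > 0:
            r = resid_raw - resid_raw.mean()
            denom = float(np.dot(r, r))
            phi = float(np.dot(r[:-1], r[1:]) / denom) if denom > 0 else 0.0
            phi = min(max(phi, 0.0), 0.99)
            inflation = (self.residual_sd_ ** 2 / var_s) * (
                (1 + phi) / (1 - phi))
            pcov = pcov * inflation
        self.pcov_ = pcov
        amplitude = self.E_max_ - self.E_min_
        detectable = (amplitude >
                      self.min_amplitude_sigma * self.residual_sd_)
        in_span = t[0] <= self.t50_ <= t[-1]
        self.converged_ = bool(detectable and in_span and amplitude > 0)
        return self

    def predict(self, t) -> np.ndarray:
        """Fitted logistic evaluated at ``t``."""
        if not hasattr(self, "t50_"):
            raise RuntimeError("call fit first")
        return sigmoid_mean_path(np.asarray(t, dtype=float),
                                 self.E_min_, self.E_max_,
                                 self.m_, self.t50_)


@dataclass
class SigmoidFit:
    """Plain record of a converged (or censored) sigmoid fit."""

    E_min: float
    E_max: float
    m: float
    t50: float
    pcov: np.ndarray
    residual_sd: float
    converged: bool


def fit_sigmoid(trace: EnergyTrace,
                smoothing_window: Union[int, str] = "auto",
                min_amplitude_sigma: float = 3.0) -> SigmoidFit:
    """Fit the two-state logistic to one energy trace."""
    est = SigmoidTransitionFit(smoothing_window=smoothing_window,
                               min_amplitude_sigma=min_amplitude_sigma)
    est.fit(trace.times, trace.energies)
    return SigmoidFit(E_min=est.E_min_, E_max=est.E_max_, m=est.m_,
                      t50=est.t50_, pcov=est.pcov_,
                      residual_sd=est.residual_sd_,
                      converged=est.converged_)


def estimate_delta_U(fit: SigmoidFit, trace: Optional[EnergyTrace] = None,
                     from_smoothed: bool = False,
                     smoothing_window: Union[int, str] = "auto") -> float:
    """Internal-energy contribution: flex value minus the lower plateau.

    The logistic at its flex sits at the plateau midpoint, so the default
    (analytic) reading is (E_max - E_min)/2, which is noise-free.  With
    ``from_smoothed`` the smoothed data value at t50 is used instead.
    """
    if not fit.converged:
        raise ValueError("deltaU requires a converged fit")
    if from_smoothed:
        if trace is None:
            raise ValueError("from_smoothed needs the trace")
        w = (default_window(trace.times.size)
             if smoothing_window == "auto" else int(smoothing_window))
        ys = moving_average(trace.energies, w)
        idx = int(np.argmin(np.abs(trace.times - fit.t50)))
        return float(ys[idx] - fit.E_min)
    return 0.5 * (fit.E_max - fit.E_min)


def _bound_state_stats(d: np.ndarray) -> tuple:
    """Robust (level, s.d.) of the bound-state distance band.

    The bound state forms a narrow density peak at the contact distance
    while the post-rupture drift spreads its mass over a wide range, so
    the histogram mode of the low-distance region locates the bound
    level even when rupture happens early in the trace.  The spread is a
    MAD estimate over the lower half of the peak (1.4826 * median of
    mode - d over d <= mode equals the s.d. for a Gaussian peak).
    """
    lo, hi = float(np.min(d)), float(np.median(d))
    if hi <= lo:
        return lo, 0.0
    mode = 0.5 * (lo + hi)
    # zoom the histogram onto the mode bin: the initial range can be
    # dominated by the drift ramp, with bins far wider than the peak
    for _ in range(3):
        sel = d[(d >= lo) & (d <= hi)]
        if sel.size < 100:
            break
        counts, edges = np.histogram(sel, bins=50, range=(lo, hi))
        i = int(np.argmax(counts))
        w = edges[i + 1] - edges[i]
        mode = 0.5 * (edges[i] + edges[i + 1])
        lo, hi = max(lo, edges[i] - w), min(hi, edges[i + 1] + w)
    lower = d[d <= mode]
    sd = 1.4826 * float(np.median(mode - lower)) if lower.size else 0.0
    return float(mode), sd


def rupture_time_heuristic(trace: DistanceTrace,
                           threshold: Optional[float] = None,
                           persistence: int = 10,
                           n_sigma: float = 5.0) -> Optional[float]:
    """First time the min-distance exceeds a threshold persistently.

    With ``threshold`` None it is set to level + ``n_sigma`` * s.d. of
    the bound state, estimated robustly from the low-distance density
    peak (see :func:`_bound_state_stats`).  Returns the time at the
    start of the first run of ``persistence`` consecutive frames above
    threshold, or None (censored) if there is none.
    """
    if persistence < 1:
        raise ValueError("persistence must be at least 1")
    d = trace.min_distance
    margin = 0.0
    if threshold is None:
        level, sd = _bound_state_stats(d)
        margin = n_sigma * sd
        threshold = level + margin
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = d > threshold
    if persistence == 1:
        hits = np.nonzero(above)[0]
    else:
        run = np.convolve(above.astype(int),
                          np.ones(persistence, dtype=int), mode="valid")
        hits = np.nonzero(run == persistence)[0]
    if not hits.size:
        return None
    i0 = int(hits[0])
    # Rupture is irreversible: the trace after the crossing must sit well
    # clear of the threshold, which rejects flat noise-only traces whose
    # auto-threshold landed inside the noise band.
    if margin > 0 and float(np.mean(d[i0:])) <= threshold + margin:
        return None
    return float(trace.times[i0])


@dataclass
class RuptureEvent:
    """Per-replica outcome of the twofold rupture-framing procedure."""

    tau: Optional[float]             # flex of the energy sigmoid (ns)
    tau_heuristic: Optional[float]   # distance criterion (ns)
    delta_U: Optional[float]         # kT
    censored: bool
    agreement: Optional[float]       # |tau - tau_heuristic| / trace span
    fit: Optional[SigmoidFit] = None
    replica_id: Optional[str] = None
    true_rupture_time: Optional[float] = None


@dataclass
class DetectorSettings:
    """Knobs of both rupture criteria (defaults documented per field)."""

    smoothing_window: Union[int, str] = "auto"
    min_amplitude_sigma: float = 3.0
    distance_threshold: Optional[float] = None   # None -> bound + 5 s.d.
    persistence: int = 10
    delta_U_from_smoothed: bool = False


def analyze_replica(energy: Optional[EnergyTrace],
                    distance: Optional[DistanceTrace],
                    settings: Optional[DetectorSettings] = None
                    ) -> RuptureEvent:
    """Run both rupture criteria on one (paired) replica.

    tau is taken from the sigmoid flex; the heuristic time is recorded for
    cross-validation.  The event is censored when the energy criterion
    finds no transition and the distance criterion none either.
    """
    if energy is None and distance is None:
        raise ValueError("at least one trace is required")
    settings = settings or DetectorSettings()
    if (energy is not None and distance is not None
            and (energy.times.size != distance.times.size
                 or not np.allclose(energy.times, distance.times))):
        raise ValueError("paired traces must share the same time base")

    fit = tau = delta_U = None
    if energy is not None:
        fit = fit_sigmoid(energy, settings.smoothing_window,
                          settings.min_amplitude_sigma)
        if fit.converged:
            tau = fit.t50
            delta_U = estimate_delta_U(
                fit, energy, from_smoothed=settings.delta_U_from_smoothed,
                smoothing_window=settings.smoothing_window)

    tau_h = None
    if distance is not None:
        tau_h = rupture_time_heuristic(distance,
                                       settings.distance_threshold,
                                       settings.persistence)

    agreement = None
    if tau is not None and tau_h is not None:
        base = energy if energy is not None else distance
        span = float(base.times[-1] - base.times[0])
        agreement = abs(tau - tau_h) / span if span > 0 else None

    censored = tau is None and tau_h is None
    rid = energy.replica_id if energy is not None else distance.replica_id
    truth = (energy.true_rupture_time if energy is not None
             else distance.true_rupture_time)
    return RuptureEvent(tau=tau, tau_heuristic=tau_h, delta_U=delta_U,
                        censored=censored, agreement=agreement, fit=fit,
                        replica_id=rid, true_rupture_time=truth)
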