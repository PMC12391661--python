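"""Ensemble mean-squared displacement and its confined-diffusion fits.

The MSD here is the *displacement-from-origin* ensemble average: at elapsed
time t, MSD(t) = (1/N_t) Σ_i ‖p_i(t) − p_i(0)‖² over the N_t tracks that have
a localization at t.  This is deliberately not the lag-time-averaged MSD of
micro-rheology; for confined beads the from-origin curve saturates at a
plateau set by the cage size, and two quantities are read off it:

* the **diffusion length** — the square root of the plateau MSD, obtained by
  fitting a line along the plateau and extrapolating to t = 0 — a proxy for
  the average pore size;
* the **diffusion exponent** n in MSD = 6·D·t**n, the slope of ln MSD vs
  ln t: n = 1 for free diffusion, n < 1 for sub-diffusive (confined) motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, NonConfinedError, TrackValidationError
from .tracks import TrackSet

__all__ = [
    "MsdCurve",
    "MsdFit",
    "compute_msd",
    "fit_diffusion_length",
    "fit_diffusion_exponent",
    "classify_regime",
    "analyze_msd",
]


@dataclass
class MsdCurve:
    """Ensemble MSD on the acquisition frame grid.

    ``times`` ascends from 0 (s); ``msd`` is in µm²; ``n_beads[i]`` counts the
    tracks contributing at ``times[i]``.
    """

    times: np.ndarray
    msd: np.ndarray
    n_beads: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_beads = np.asarray(self.n_beads, dtype=int)


@dataclass
class MsdFit:
    """Results of plateau and/or power-law fits on an :class:`MsdCurve`."""

    diffusion_length: float | None = None  # µm
    plateau_intercept: float | None = None  # µm²
    plateau_window: tuple[float, float] | None = None  # s
    diffusion_exponent: float | None = None
    effective_D: float | None = None  # µm²/s, from MSD = 6 D t^n
    exponent_window: tuple[float, float] | None = None  # s


def compute_msd(trackset: TrackSet) -> MsdCurve:
    """Ensemble displacement-from-origin MSD of a track set.

    Each track is referenced to its own first localization; elapsed times must
    sit on the shared frame grid (multiples of ``frame_interval``).  Tracks of
    unequal length contribute wherever they have data, so the per-time bead
    count N_t may vary.
    """
    if len(trackset) == 0:
        raise TrackValidationError("cannot compute MSD of an empty TrackSet")
    dt = trackset.frame_interval
    per_track = []
    max_idx = 0
    for tr in trackset:
        elapsed = tr.t - tr.t[0]
        idx = np.rint(elapsed / dt).astype(int)
        if np.any(np.abs(elapsed - idx * dt) > 1e-6 * max(dt, 1.0)):
            raise TrackValidationError(
                f"track {tr.track_id!r} does not sit on the frame grid"
            )
        sq = np.sum((tr.xyz - tr.xyz[0]) ** 2, axis=1)
        per_track.append((idx, sq))
        max_idx = max(max_idx, int(idx[-1]))

    total = np.zeros(max_idx + 1)
    count = np.zeros(max_idx + 1, dtype=int)
    for idx, sq in per_track:
        total[idx] += sq
        count[idx] += 1
    have = count > 0
    msd = np.zeros(max_idx + 1)
    msd[have] = total[have] / count[have]
    times = np.arange(max_idx + 1) * dt
    return MsdCurve(times[have], msd[have], count[have])


def _detect_plateau(curve: MsdCurve, slope_tol: float = 0.1, min_frac: float = 0.2):
    """Longest trailing window of the curve whose local log-log slope stays
    below ``slope_tol``, spanning at least ``min_frac`` of the usable points.

    The local slope is measured between *octave-binned* means (mean MSD over
    [T/2, T] vs [T/4, T/2], and so on backwards), which averages out both
    point noise and the correlated wander of small-ensemble MSD curves.  The
    window extends back octave by octave while consecutive bins stay flat.
    """
    mask = (curve.times > 0) & (curve.msd > 0)
    t = curve.times[mask]
    m = curve.msd[mask]
    if t.size < 3:
        raise NonConfinedError("too few points to detect a plateau")
    T = t[-1]
    edges = [T]
    while edges[-1] / 2.0 >= t[0]:
        edges.append(edges[-1] / 2.0)
    if len(edges) < 3:
        raise NonConfinedError("too few decades of lag time to detect a plateau")
    means = []
    for hi, lo in zip(edges[:-1], edges[1:]):
        sel = (t > lo) & (t <= hi)
        if sel.sum() == 0:
            break
        means.append(float(m[sel].mean()))
    if len(means) < 2:
        raise NonConfinedError("too few points to detect a plateau")
    slopes = [np.log(a / b) / np.log(2.0) for a, b in zip(means[:-1], means[1:])]
    if slopes[0] >= slope_tol:
        raise NonConfinedError("no MSD plateau detected: curve is non-confined")
    k = 0
    while k < len(slopes) and slopes[k] < slope_tol:
        k += 1
    lo_edge = edges[k + 1]
    min_pts = max(3, int(np.ceil(min_frac * t.size)))
    window_t = t[t > lo_edge]
    if window_t.size < min_pts:
        lo_edge = t[t.size - min_pts] - 1e-12
        window_t = t[t > lo_edge]
    return float(window_t[0]), float(T)


def fit_diffusion_length(
    curve: MsdCurve, plateau_window: tuple[float, float] | None = None
) -> MsdFit:
    """Diffusion length from the MSD plateau.

    An ordinary least-squares line is fitted along the plateau region
    (auto-detected unless ``plateau_window`` is given) and extrapolated to
    t = 0; the square root of the intercept is the diffusion length.
    """
    if plateau_window is None:
        plateau_window = _detect_plateau(curve)
    lo, hi = plateau_window
    mask = (curve.times >= lo) & (curve.times <= hi)
    t = curve.times[mask]
    m = curve.msd[mask]
    if t.size < 2:
        raise FitError("plateau window contains fewer than 2 points")
    slope, intercept = np.polyfit(t, m, 1)
    if intercept <= 0:
        raise FitError(
            "negative plateau intercept; choose a later plateau window"
        )
    return MsdFit(
        diffusion_length=float(np.sqrt(intercept)),
        plateau_intercept=float(intercept),
        plateau_window=(float(lo), float(hi)),
    )


def fit_diffusion_exponent(
    curve: MsdCurve, window: tuple[float, float] | None = None
) -> MsdFit:
    """Diffusion exponent n and effective D from MSD = 6·D·t**n.

    Least-squares slope of ln MSD versus ln t over the window (default: the
    whole curve from the first frame on); t = 0 and non-positive MSD values
    are excluded.
    """
    mask = (curve.times > 0) & (curve.msd > 0)
    if window is not None:
        lo, hi = window
        mask &= (curve.times >= lo) & (curve.times <= hi)
    t = curve.times[mask]
    m = curve.msd[mask]
    if t.size < 3:
        raise FitError("need at least 3 positive-MSD points to fit the exponent")
    n, logc = np.polyfit(np.log(t), np.log(m), 1)
    return MsdFit(
        diffusion_exponent=float(n),
        effective_D=float(np.exp(logc) / 6.0),
        exponent_window=(float(t[0]), float(t[-1])),
    )


def classify_regime(fit: MsdFit, tol: float = 0.05) -> str:
    """Classify the diffusion regime from the fitted exponent.

    Returns ``"sub-diffusive"`` (n < 1 − tol), ``"free"`` (|n − 1| ≤ tol) or
    ``"super-diffusive"`` (n > 1 + tol).
    """
    if fit.diffusion_exponent is None or not np.isfinite(fit.diffusion_exponent):
        raise FitError("fit has no finite diffusion exponent")
    n = fit.diffusion_exponent
    if n < 1.0 - tol:
        return "sub-diffusive"
    if n <= 1.0 + tol:
        return "free"
    return "super-diffusive"


def analyze_msd(curve: MsdCurve) -> MsdFit:
    """Run both fits on a curve; plateau fields stay None for curves without
    a detectable plateau (freely diffusing ensembles)."""
    fit = fit_diffusion_exponent(curve)
    try:
        plat = fit_diffusion_length(curve)
    except (NonConfinedError, FitError):
        return fit
    fit.diffusion_length = plat.diffusion_length
    fit.plateau_intercept = plat.plateau_intercept
    fit.plateau_window = plat.plateau_window
    return fit
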