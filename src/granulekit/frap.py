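"""FRAP trace normalization, photobleach correction and recovery fitting.

A FRAP trace is normalized as ``nI = (I - I_bkg) / (I_i - I_bkgi)`` where
``I`` is the bleached-region intensity, ``I_bkg`` the background intensity of
the same frame, and ``I_i`` / ``I_bkgi`` their pre-bleach values (averaged
over all pre-bleach frames).  Recovery is fitted to the first-order model

    nI(t) - nI(0+) = A_rec * (1 - exp(-k * t))

with ``t`` measured from the bleach, ``A_rec`` the recovery amplitude (mobile
fraction above the bleach floor) and ``k`` the recovery rate in 1/s.  Traces
whose recovery stays in the linear regime over the acquisition window are
fitted to ``nI = k * t`` through the origin instead.

Acquisition photobleaching is corrected with a mono-exponential rate fitted to
a cytoplasm reference trace; ex-vivo granule persistence is summarized as the
bleach-corrected intensity ratio after/before eggshell puncture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .imaging import DataQualityWarning


@dataclass(frozen=True)
class FrapTrace:
    """One bleached-region time series with its per-frame background."""

    times: np.ndarray  # s, strictly increasing
    intensity: np.ndarray  # AU
    background: np.ndarray  # AU, same length
    bleach_index: int  # first post-bleach frame

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        b = np.asarray(self.background, dtype=float)
        if not (t.size == i.size == b.size):
            raise ValueError("times, intensity and background must align")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.bleach_index < t.size):
            raise ValueError("bleach index must fall inside the trace")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "background", b)

    @property
    def initial_intensity(self) -> float:
        """Mean pre-bleach intensity I_i (average over all pre-bleach frames)."""
        return float(self.intensity[: self.bleach_index].mean())

    @property
    def initial_background(self) -> float:
        """Mean pre-bleach background I_bkgi."""
        return float(self.background[: self.bleach_index].mean())


@dataclass(frozen=True)
class RecoveryFit:
    model: str  # "exponential" | "linear"
    a_rec: float  # amplitude (dimensionless); for linear fits, NaN
    k: float  # rate (1/s) or linear slope (1/s)
    rss: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class PersistenceRecord:
    """Bleach-corrected granule intensity ratio across an extrusion event.

    The ratio is a minimal estimate of the retained fraction: granules that
    drift out of the field are lost from I_A but not from I_B.
    """

    i_before: float
    i_after_raw: float
    i_after_corrected: float
    bleach_rate: float  # 1/s
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("persistence ratio must be non-negative")


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Background-corrected, pre-bleach-normalized intensity nI per frame."""
    denom = trace.initial_intensity - trace.initial_background
    if denom <= 0:
        raise ValueError(
            "pre-bleach granule intensity does not exceed background; "
            "trace cannot be normalized"
        )
    return (trace.intensity - trace.background) / denom


def fit_bleach_rate(times: np.ndarray, reference: np.ndarray) -> float:
    """Mono-exponential photobleach rate (1/s) from a reference trace.

    The reference is normalized to its first frame and fitted to
    ``exp(-lambda * (t - t0))``.  An increasing reference yields a negative
    rate, which is clamped to 0 with a warning.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(reference, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("reference must align with times and have >= 3 frames")
    y = y / y[0]
    dt = t - t[0]
    # log-linear seed, refined by nonlinear least squares
    pos = y > 0
    slope = np.polyfit(dt[pos], np.log(y[pos]), 1)[0] if pos.sum() >= 2 else 0.0
    lam0 = max(-slope, 0.0)
    try:
        (lam,), _ = curve_fit(
            lambda tt, l: np.exp(-l * tt), dt, y, p0=[lam0], maxfev=10000
        )
    except RuntimeError:
        lam = lam0
    if lam < 0:
        warnings.warn(
            "reference trace brightens over time; photobleach rate clamped to 0",
            DataQualityWarning,
            stacklevel=2,
        )
        lam = 0.0
    return float(lam)


def bleach_correct(
    times: np.ndarray,
    series: np.ndarray,
    reference: np.ndarray,
    reference_times: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Undo acquisition photobleaching using a cytoplasm reference.

    Returns ``series * exp(+lambda * (t - t0))`` and the fitted rate.
    """
    t = np.asarray(times, dtype=float)
    rt = t if reference_times is None else np.asarray(reference_times, dtype=float)
    lam = fit_bleach_rate(rt, reference)
    corrected = np.asarray(series, dtype=float) * np.exp(lam * (t - t[0]))
    return corrected, lam


def _exp_model(t: np.ndarray, a: float, k: float) -> np.ndarray:
    return a * (1.0 - np.exp(-k * t))


def fit_recovery(
    times: np.ndarray,
    n_intensity: np.ndarray,
    model: str = "auto",
) -> RecoveryFit:
    """Fit the post-bleach portion of a normalized trace.

    ``times``/``n_intensity`` are post-bleach frames only (the first entry is
    the bleach floor).  The series is differenced against its first value so
    the exponential model has no intercept; amplitudes are bounded to
    [0, 1.5] and rates to k >= 0.  Five multi-start restarts guard against
    local minima; non-convergence is reported, never silently replaced.

    ``model="auto"`` falls back to the linear fit when the fitted exponential
    satisfies ``k * t_max < 0.2``, i.e. recovery is indistinguishable from
    linear over the acquisition window.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(n_intensity, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 post-bleach frames to fit recovery")
    dt = t - t[0]
    dy = y - y[0]

    if model not in ("auto", "exponential", "linear"):
        raise ValueError(f"unknown model {model!r}")

    if model == "linear":
        return _fit_linear(dt, dy)

    if np.ptp(dy) == 0:
        # flat trace: amplitude 0, rate unidentifiable
        return RecoveryFit("exponential", 0.0, float("nan"), 0.0, True, "flat series")

    a0 = max(float(dy[-1]), 1e-6)
    half = a0 / 2.0
    above = np.flatnonzero(dy >= half)
    t_half = dt[above[0]] if above.size else dt[-1] / 2.0
    k0 = np.log(2.0) / max(t_half, dt[1] if dt.size > 1 else 1.0)

    best: tuple[float, float, float] | None = None
    for mult in (1.0, 0.2, 5.0, 0.04, 25.0):
        try:
            (a, k), _ = curve_fit(
                _exp_model,
                dt,
                dy,
                p0=[min(a0, 1.4), k0 * mult],
                bounds=([0.0, 0.0], [1.5, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((dy - _exp_model(dt, a, k)) ** 2))
        if best is None or rss < best[2]:
            best = (float(a), float(k), rss)
    if best is None:
        return RecoveryFit(
            "exponential", float("nan"), float("nan"), float("nan"), False,
            "exponential fit failed to converge after 5 restarts",
        )
    a, k, rss = best

    if model == "auto" and k * dt[-1] < 0.2:
        return _fit_linear(dt, dy)
    return RecoveryFit("exponential", a, k, rss, True)


def _fit_linear(dt: np.ndarray, dy: np.ndarray) -> RecoveryFit:
    """Slope through the origin on the differenced post-bleach series."""
    denom = float(np.sum(dt * dt))
    if denom == 0:
        return RecoveryFit("linear", float("nan"), float("nan"), float("nan"), False, "degenerate times")
    k = float(np.sum(dt * dy) / denom)
    k = max(k, 0.0)
    rss = float(np.sum((dy - k * dt) ** 2))
    return RecoveryFit("linear", float("nan"), k, rss, True)


def persistence_ratio(
    i_before: float,
    i_after: float,
    elapsed: float,
    *,
    bleach_rate: float | None = None,
    reference: np.ndarray | None = None,
    reference_times: np.ndarray | None = None,
) -> PersistenceRecord:
    """Granule intensity retained across extrusion, corrected for bleaching.

    ``i_before``/``i_after`` are total granule intensities (from
    :func:`granulekit.imaging.measure_objects`) before and after the puncture,
    ``elapsed`` the time between the two measurements in seconds.  The
    photobleach rate comes either directly (``bleach_rate``) or from a
    cytoplasm ``reference`` trace of an intact embryo.
    """
    if i_before <= 0:
        raise ValueError("pre-puncture intensity must be positive")
    if bleach_rate is None:
        if reference is None or reference_times is None:
            raise ValueError("supply bleach_rate or a reference trace with times")
        bleach_rate = fit_bleach_rate(reference_times, reference)
    corrected = float(i_after) * float(np.exp(bleach_rate * elapsed))
    return PersistenceRecord(
        i_before=float(i_before),
        i_after_raw=float(i_after),
        i_after_corrected=corrected,
        bleach_rate=float(bleach_rate),
        ratio=corrected / float(i_before),
    )
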