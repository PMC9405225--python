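"""Luminescence-trace treatment and k_L estimation from aeration curves.

Dissolved oxygen quenches the luminescence of a ruthenium dye, so the
recorded peak intensity falls as the deaerated vessel re-aerates under
agitation.  With a first-order surface-aeration model

    dC/dt = kLa (C_sat - C),   C(0) = 0
    C(t)  = C_sat (1 - exp(-kLa t))

the treated intensity I_max - I_recorded follows the same saturating
exponential, scaled to the span I_max - I_min between the fully deaerated
and the air-saturated plateaus.  ``fit_kla`` recovers kLa by a bounded
scalar least-squares search on that curve; kL = kLa / a with a = A/V the
specific interfacial area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import minimize_scalar

__all__ = [
    "SpectrumSeries",
    "IntensityTrace",
    "KLFit",
    "extract_peak",
    "concentration_profile",
    "integrate_aeration",
    "model_intensity",
    "fit_kla",
]

# bracket of the scalar search on log10(kLa), in 1/s
_KLA_BRACKET = (1e-6, 1e-1)


@dataclass(frozen=True)
class SpectrumSeries:
    """Time-stamped luminescence spectra plus the dark reference.

    ``counts`` has one row per time point, one column per wavelength.
    """

    times: np.ndarray  # s, strictly increasing
    wavelengths: np.ndarray  # nm, strictly increasing
    counts: np.ndarray  # (n_times, n_wavelengths)
    dark: np.ndarray  # (n_wavelengths,)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        wl = np.asarray(self.wavelengths, float)
        c = np.asarray(self.counts, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if c.shape != (t.size, wl.size):
            raise ValueError("counts must be (n_times, n_wavelengths)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "dark", np.asarray(self.dark, float))


@dataclass(frozen=True)
class IntensityTrace:
    """Peak-intensity trace with its deaeration/saturation plateau levels.

    ``I_max`` is the intensity at full deaeration (no quenching) and
    ``I_min`` the intensity at air saturation; both may be NaN when they
    are to be inferred or fitted.
    """

    times: np.ndarray
    I_recorded: np.ndarray
    I_max: float = float("nan")
    I_min: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        I = np.asarray(self.I_recorded, float)
        if t.shape != I.shape:
            raise ValueError("times and I_recorded must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if (
            math.isfinite(self.I_max)
            and math.isfinite(self.I_min)
            and not self.I_max > self.I_min
        ):
            raise ValueError("I_max must exceed I_min")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "I_recorded", I)

    def with_plateaus(self, I_max: float, I_min: float) -> "IntensityTrace":
        return replace(self, I_max=I_max, I_min=I_min)

    @property
    def treated(self) -> np.ndarray:
        """I_treated = I_max - I_recorded (unquenched reference minus peak)."""
        if not math.isfinite(self.I_max):
            raise ValueError("I_max is not set")
        return self.I_max - self.I_recorded


@dataclass(frozen=True)
class KLFit:
    """Result of a kLa fit: kLa (1/s), kL = kLa/a (m/s), sse (counts^2)."""

    kLa: float
    kL: float
    a: float
    sse: float
    n: int
    boundary: bool = False  # True when the optimum sat on the search bracket

    def __post_init__(self) -> None:
        if self.kLa <= 0 or self.sse < 0:
            raise ValueError("kLa must be > 0 and sse >= 0")
        if not math.isclose(self.kLa, self.kL * self.a, rel_tol=1e-9):
            raise ValueError("kLa must equal kL*a")

    @property
    def kLa_per_hour(self) -> float:
        return self.kLa * 3600.0


def extract_peak(
    series: SpectrumSeries,
    center: float = 608.0,
    halfwidth: float = 10.0,
    baseline_band: tuple[float, float] = (450.0, 500.0),
    smooth_points: int = 30,
) -> IntensityTrace:
    """Dark-subtracted, drift-corrected peak intensity per time point.

    For each spectrum: subtract the dark reference, fit a linear baseline
    on the emission-free ``baseline_band`` and remove it (the drift is an
    instrument-temperature artefact), smooth with a ``smooth_points``
    moving average, and take the maximum inside ``center +- halfwidth``.
    """
    wl = series.wavelengths
    window = (wl >= center - halfwidth) & (wl <= center + halfwidth)
    if window.sum() < 3:
        raise ValueError(
            f"peak window {center}+-{halfwidth} nm holds fewer than 3 samples"
        )
    band = (wl >= baseline_band[0]) & (wl <= baseline_band[1])
    corrected = series.counts - series.dark[None, :]
    if band.sum() >= 2:
        # per-spectrum linear baseline anchored on the emission-free band
        coefs = npoly.polyfit(wl[band], corrected[:, band].T, 1)
        corrected = corrected - npoly.polyval(wl, coefs).reshape(corrected.shape)
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        corrected = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="same"), 1, corrected
        )
    peaks = corrected[:, window].max(axis=1)
    return IntensityTrace(times=series.times, I_recorded=peaks)


def concentration_profile(
    t: np.ndarray | float, kLa: float, C_sat: float
) -> np.ndarray | float:
    """Closed-form aeration profile ``C = C_sat (1 - exp(-kLa t))``."""
    if kLa < 0:
        raise ValueError("kLa must be >= 0")
    return C_sat * -np.expm1(-kLa * np.asarray(t, float))


def integrate_aeration(
    kLa_of_t: Callable[[np.ndarray], np.ndarray] | float,
    C_sat: float,
    t_grid: Sequence[float],
) -> np.ndarray:
    """Integrate dC/dt = kLa(t)(C_sat - C), C(0)=0, on ``t_grid``.

    Uses the exact integrating factor C = C_sat(1 - exp(-int kLa dt)) with
    5-point Gauss-Legendre quadrature of kLa on each grid interval: exact
    for kLa constant (or polynomial up to degree 9) within intervals, so a
    piecewise-constant kLa whose breakpoints sit on grid nodes integrates
    to the product-of-exponentials closed form.
    """
    t = np.asarray(t_grid, float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if callable(kLa_of_t):
        f = lambda x: np.asarray(kLa_of_t(x), float)
    else:
        const = float(kLa_of_t)
        f = lambda x: np.full_like(np.asarray(x, float), const)
    nodes, weights = np.polynomial.legendre.leggauss(5)
    a, b = t[:-1], t[1:]
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    samples = f(mid[:, None] + half[:, None] * nodes[None, :])
    if np.any(samples < 0):
        raise ValueError("kLa(t) must be non-negative on the grid")
    increments = half * (samples * weights[None, :]).sum(axis=1)
    integral = np.concatenate([[0.0], np.cumsum(increments)])
    return C_sat * -np.expm1(-integral)


def model_intensity(
    t: np.ndarray | float, kLa: float, I_max: float, I_min: float
) -> np.ndarray | float:
    """Treated-intensity model ``(I_max - I_min)(1 - exp(-kLa t))``."""
    if not I_max > I_min:
        raise ValueError("I_max must exceed I_min")
    return (I_max - I_min) * -np.expm1(-kLa * np.asarray(t, float))


def _plateau_levels(trace: IntensityTrace, frac: float = 0.05) -> tuple[float, float]:
    """Infer (I_max, I_min) as medians of the first/last ``frac`` of points.

    The protocol starts from full deaeration (highest intensity) and ends
    at air saturation (lowest), so the leading plateau estimates I_max and
    the trailing one I_min.
    """
    n = trace.times.size
    k = max(3, int(round(frac * n)))
    I = trace.I_recorded
    return float(np.median(I[:k])), float(np.median(I[-k:]))


def fit_kla(
    trace: IntensityTrace,
    a: float,
    fit_span: bool = False,
    xtol: float = 1e-10,
) -> KLFit:
    """Least-squares estimate of kLa from a treated intensity trace.

    Minimises sum (I_treated - I_calculated)^2 over kLa alone (the plateau
    intensities fixed from the experiment, the protocol's reading) by a
    deterministic bounded search on log10(kLa).  With ``fit_span=True`` the
    span I_max - I_min is profiled out analytically at each kLa instead of
    being fixed, for traces whose plateaus are unreliable.
    """
    if a <= 0:
        raise ValueError("specific area a must be positive")
    if trace.times.size < 5:
        raise ValueError("need at least 5 time points to fit kLa")
    if math.isfinite(trace.I_max) and math.isfinite(trace.I_min):
        I_max, I_min = trace.I_max, trace.I_min
    else:
        I_max, I_min = _plateau_levels(trace)
    if not I_max > I_min:
        raise ValueError("trace has no dynamic range (I_max <= I_min)")
    t = trace.times - trace.times[0]
    y = I_max - trace.I_recorded  # I_treated_exp
    span = I_max - I_min
    if np.ptp(y) == 0.0:
        raise ValueError("constant trace: kLa is unidentifiable")

    def sse_at(log_kla: float) -> float:
        shape = -np.expm1(-(10.0**log_kla) * t)
        if fit_span:
            denom = float(shape @ shape)
            amp = float(shape @ y) / denom if denom > 0 else 0.0
        else:
            amp = span
        r = y - amp * shape
        return float(r @ r)

    lo, hi = math.log10(_KLA_BRACKET[0]), math.log10(_KLA_BRACKET[1])
    res = minimize_scalar(
        sse_at, bounds=(lo, hi), method="bounded", options={"xatol": xtol}
    )
    kLa = 10.0**res.x
    boundary = min(res.x - lo, hi - res.x) < 1e-6
    return KLFit(
        kLa=kLa, kL=kLa / a, a=a, sse=float(res.fun), n=int(t.size),
        boundary=boundary,
    )
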