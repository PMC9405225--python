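"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this package are instrument traces (luminescence spectra of
an oxygen-quenched dye during re-aeration), exported CFD gradient fields,
and tables of dimensionless mass-transfer records.  Each generator here
emulates one of them with the statistical structure the analysis assumes —
exponential saturation traces with additive detector noise and a linear
baseline drift; analytic flows (Taylor-Green, solid rotation, pure shear)
with closed-form dissipation; power-law Sherwood data with multiplicative
scatter — and returns the ground truth alongside the data, so every
estimator in the package can be checked for recovery.

All randomness flows through a seeded ``numpy.random.default_rng``:
identical spec + seed reproduces the output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .correlation import CorrelationDataset, SherwoodConstants
from .kinetics import IntensityTrace, SpectrumSeries
from .turbulence_post import (
    CW_DEFAULT,
    GradientField,
    SurfaceFluxField,
    wale_nut,
)

__all__ = [
    "TraceSpec",
    "FlowSpec",
    "ShDatasetSpec",
    "gen_luminescence",
    "gen_spectrum_series",
    "gen_flow",
    "gen_sherwood_dataset",
    "gen_surface_profile",
    "packaged_taylor_green",
]


@dataclass(frozen=True)
class TraceSpec:
    """Recipe for one synthetic aeration trace.

    Defaults emulate a typical run: kLa = 2 h^-1, a ~1500-count dynamic
    range on a 200-count saturated floor, 1% detector noise, a slow
    thermal baseline drift, sampled every 5 s for five time constants.
    """

    kLa_true: float | Callable[[np.ndarray], np.ndarray] = 2.0 / 3600.0  # 1/s
    I_max: float = 1700.0  # counts at full deaeration
    I_min: float = 200.0  # counts at air saturation
    noise_sigma: float = 15.0  # counts, ~1% of the span
    drift_slope: float = 0.0  # counts/s
    duration: float = 9000.0  # s  (= 5 / kLa_true at the default kLa)
    dt: float = 5.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if not self.I_max > self.I_min >= 0:
            raise ValueError("need I_max > I_min >= 0")


@dataclass(frozen=True)
class FlowSpec:
    """Recipe for an analytic flow sampled on a uniform periodic grid."""

    kind: str = "taylor_green"  # | solid_rotation | pure_shear | random_smooth
    amplitude: float = 0.1  # m/s (or rad/s, 1/s for rotation/shear rates)
    wavenumber: float | None = None  # 1/m; default 2*pi/domain_L
    grid_n: int = 16  # cells per axis
    domain_L: float = 2.0 * math.pi / 100.0  # m
    nu: float = 9.78e-7  # m^2/s
    seed: int = 0
    gradients: str = "finite_difference"  # | analytic

    def __post_init__(self) -> None:
        if self.grid_n < 8:
            raise ValueError("grid_n must be >= 8")
        if self.kind not in (
            "taylor_green", "solid_rotation", "pure_shear", "random_smooth"
        ):
            raise ValueError(f"unknown flow kind {self.kind!r}")
        if self.gradients not in ("finite_difference", "analytic"):
            raise ValueError("gradients must be finite_difference or analytic")


@dataclass(frozen=True)
class ShDatasetSpec:
    """Recipe for a synthetic Sherwood-correlation dataset.

    Default ranges are the fitted validity window of the experimental
    campaign: Re in [624, 3172], Sc in [366, 395], G in [0.651, 1.08].
    """

    constants_true: SherwoodConstants = field(
        default_factory=lambda: SherwoodConstants(
            k=1.68, alpha=0.551, gamma=1.18, provenance="experimental"
        )
    )
    Re_range: tuple[float, float] = (624.0, 3172.0)
    Sc_range: tuple[float, float] = (366.0, 395.0)
    G_range: tuple[float, float] = (0.651, 1.08)
    n_records: int = 50
    noise_cv: float = 0.0  # multiplicative scatter, relative
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.Re_range, self.Sc_range, self.G_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        if self.n_records < 1 or self.noise_cv < 0:
            raise ValueError("need n_records >= 1 and noise_cv >= 0")


def _truth_shape(spec: TraceSpec, t: np.ndarray) -> np.ndarray:
    """Saturation curve 1 - exp(-int kLa dt), handling callable kLa."""
    if callable(spec.kLa_true):
        # cumulative trapezoid of kLa(t); fine-grid free since t is the grid
        rates = np.asarray(spec.kLa_true(t), float)
        integral = np.concatenate(
            [[0.0], np.cumsum(0.5 * (rates[1:] + rates[:-1]) * np.diff(t))]
        )
        return -np.expm1(-integral)
    return -np.expm1(-float(spec.kLa_true) * t)


def gen_luminescence(spec: TraceSpec) -> tuple[IntensityTrace, dict]:
    """Synthetic peak-intensity trace plus its ground truth.

    I(t) = I_max - (I_max - I_min)(1 - e^(-kLa t)) + drift*t + noise:
    intensity starts at the deaerated maximum and is quenched toward the
    saturation floor as oxygen transfers in.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    shape = _truth_shape(spec, t)
    clean = spec.I_max - (spec.I_max - spec.I_min) * shape
    noisy = clean + spec.drift_slope * t
    if spec.noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sigma, t.size)
    trace = IntensityTrace(
        times=t, I_recorded=noisy, I_max=spec.I_max, I_min=spec.I_min
    )
    truth = {
        "kLa_true": spec.kLa_true,
        "clean": clean,
        "spec": spec,
    }
    return trace, truth


def gen_spectrum_series(
    spec: TraceSpec,
    center: float = 608.0,
    sigma_nm: float = 15.0,
    dark_floor: float = 120.0,
    wavelengths: np.ndarray | None = None,
) -> tuple[SpectrumSeries, dict]:
    """Wrap each trace point in a synthetic emission spectrum.

    A Gaussian emission band (default centre 608 nm, width 15 nm) whose
    amplitude follows the aeration trace, on a flat dark floor; the trace's
    drift enters as a wavelength-independent baseline offset, which is what
    the extraction's emission-free-band detrend removes.
    """
    trace, truth = gen_luminescence(spec)
    wl = (
        np.linspace(430.0, 750.0, 321)
        if wavelengths is None
        else np.asarray(wavelengths, float)
    )
    emission = np.exp(-0.5 * ((wl - center) / sigma_nm) ** 2)
    dark = np.full(wl.size, dark_floor)
    amp = trace.I_recorded - spec.drift_slope * trace.times  # peak amplitudes
    counts = dark[None, :] + amp[:, None] * emission[None, :]
    counts = counts + (spec.drift_slope * trace.times)[:, None]  # baseline drift
    series = SpectrumSeries(
        times=trace.times, wavelengths=wl, counts=counts, dark=dark
    )
    return series, {**truth, "trace": trace}


def _centers(n: int, L: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * (L / n)


def gen_flow(spec: FlowSpec, Cw: float = CW_DEFAULT) -> tuple[GradientField, dict]:
    """Analytic velocity-gradient field with closed-form diagnostics.

    Kinds
    -----
    taylor_green
        2-D Taylor-Green vortex u = A cos(kx) sin(ky), v = -A sin(kx)
        cos(ky) on a periodic box; volume-mean resolved dissipation
        nu A^2 k^2.  Gradients by 2nd-order central differences of the
        sampled velocities by default (``gradients="analytic"`` for exact).
    solid_rotation
        Rigid rotation at rate omega about z: zero strain, and a
        closed-form WALE viscosity (Cw Delta)^2 (2/3)^(1/4) omega.
    pure_shear
        du/dy = gamma_dot only; the WALE viscosity is identically zero.
    random_smooth
        A random trigonometric polynomial velocity field (seeded), for
        property tests; no closed-form truth beyond finiteness.
    """
    n, L, A = spec.grid_n, spec.domain_L, spec.amplitude
    kappa = spec.wavenumber if spec.wavenumber is not None else 2.0 * math.pi / L
    x = _centers(n, L)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    ncells = n**3
    vol = np.full(ncells, (L / n) ** 3)
    delta = L / n
    truth: dict = {"spec": spec}

    def stack(components: dict[tuple[int, int], np.ndarray]) -> np.ndarray:
        g = np.zeros((ncells, 3, 3))
        for (i, j), val in components.items():
            g[:, i, j] = val.ravel()
        return g

    if spec.kind == "taylor_green":
        if not math.isclose((kappa * L) % (2 * math.pi), 0.0, abs_tol=1e-9) and not math.isclose(
            (kappa * L) % (2 * math.pi), 2 * math.pi, abs_tol=1e-9
        ):
            raise ValueError("taylor_green needs kappa*L a multiple of 2*pi")
        if spec.gradients == "analytic":
            dudx = -A * kappa * np.sin(kappa * X) * np.sin(kappa * Y)
            dudy = A * kappa * np.cos(kappa * X) * np.cos(kappa * Y)
            dvdx = -A * kappa * np.cos(kappa * X) * np.cos(kappa * Y)
            dvdy = A * kappa * np.sin(kappa * X) * np.sin(kappa * Y)
        else:
            u = A * np.cos(kappa * X) * np.sin(kappa * Y)
            v = -A * np.sin(kappa * X) * np.cos(kappa * Y)
            h = L / n
            ddx = lambda f: (np.roll(f, -1, 0) - np.roll(f, 1, 0)) / (2 * h)
            ddy = lambda f: (np.roll(f, -1, 1) - np.roll(f, 1, 1)) / (2 * h)
            dudx, dudy = ddx(u), ddy(u)
            dvdx, dvdy = ddx(v), ddy(v)
        gradU = stack({(0, 0): dudx, (0, 1): dudy, (1, 0): dvdx, (1, 1): dvdy})
        truth["mean_eps_res"] = spec.nu * A**2 * kappa**2
    elif spec.kind == "solid_rotation":
        omega = A
        g = np.zeros((ncells, 3, 3))
        g[:, 0, 1] = -omega
        g[:, 1, 0] = omega
        gradU = g
        truth["mean_eps_res"] = 0.0
        truth["nu_t"] = (Cw * delta) ** 2 * (2.0 / 3.0) ** 0.25 * abs(omega)
    elif spec.kind == "pure_shear":
        g = np.zeros((ncells, 3, 3))
        g[:, 0, 1] = A  # du/dy = gamma_dot
        gradU = g
        truth["nu_t"] = 0.0
        truth["mean_eps_res"] = 2.0 * spec.nu * (A / 2.0) ** 2 * 2.0
    else:  # random_smooth
        rng = np.random.default_rng(spec.seed)
        gradU = np.zeros((ncells, 3, 3))
        base = 2.0 * math.pi / L
        for i in range(3):
            for j in range(3):
                a0, a1, ph = rng.normal(size=3)
                m = rng.integers(1, 4)
                gradU[:, i, j] = A * base * (
                    a0 + a1 * np.sin(m * base * pos[:, j] + ph)
                )
    field = GradientField(position=pos, cell_volume=vol, gradU=gradU, nu=spec.nu)
    if spec.kind == "solid_rotation":
        # sanity: attach the per-cell WALE value actually implied
        truth["nu_t_check"] = float(
            np.median(wale_nut(gradU[:2], delta, Cw))
        )
    return field, truth


def gen_sherwood_dataset(spec: ShDatasetSpec) -> tuple[CorrelationDataset, dict]:
    """Power-law Sherwood records with multiplicative Gaussian scatter.

    (Re, Sc, G) are sampled log-uniformly over the configured ranges;
    Sh = k Re^alpha Sc^beta G^gamma (1 + eps), eps ~ N(0, noise_cv).
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.constants_true

    def log_uniform(lo: float, hi: float) -> np.ndarray:
        return np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n_records))

    Re = log_uniform(*spec.Re_range)
    Sc = log_uniform(*spec.Sc_range)
    G = log_uniform(*spec.G_range)
    Sh = c.k * Re**c.alpha * Sc**c.beta * G**c.gamma
    if spec.noise_cv > 0:
        Sh = Sh * (1.0 + rng.normal(0.0, spec.noise_cv, spec.n_records))
    data = CorrelationDataset(Re=Re, Sc=Sc, G=G, Sh=Sh)
    return data, {"constants_true": c, "spec": spec}


def gen_surface_profile(
    kL_true: float,
    C_sat: float,
    C_bulk: float,
    D_AB: float,
    n_faces: int = 64,
    face_variation: float = 0.0,
    seed: int = 0,
) -> SurfaceFluxField:
    """Surface-flux field constructed so ``surface_kl`` returns ``kL_true``.

    Film theory: a boundary layer absorbing at coefficient kL carries the
    interface gradient dC/dy = kL (C_sat - C_bulk) / D_AB.  Optional
    face-to-face perturbations are applied with zero area-weighted net
    effect, leaving the area-mean flux (and hence kL) unchanged exactly.
    """
    if not C_sat > C_bulk:
        raise ValueError("need C_sat > C_bulk for an absorbing interface")
    if kL_true <= 0 or D_AB <= 0:
        raise ValueError("kL_true and D_AB must be positive")
    area = np.full(n_faces, 1.0 / n_faces)
    base = kL_true * (C_sat - C_bulk) / D_AB
    dCdy = np.full(n_faces, base)
    if face_variation > 0.0:
        rng = np.random.default_rng(seed)
        pert = rng.uniform(-face_variation, face_variation, n_faces)
        pert -= (pert * area).sum() / area.sum()  # zero area-weighted mean
        dCdy = base * (1.0 + pert)
    return SurfaceFluxField(
        area=area,
        dCdy=dCdy,
        D_ABt=np.zeros(n_faces),
        C_sat=C_sat,
        C_bulk_mean=C_bulk,
    )


def packaged_taylor_green(grid_n: int = 32) -> tuple[GradientField, dict]:
    """The package's reference Taylor-Green field (deterministic).

    Regenerated on demand instead of shipped as a table; byte-identical
    across calls for a given ``grid_n``.
    """
    return gen_flow(FlowSpec(kind="taylor_green", grid_n=grid_n, seed=0))
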