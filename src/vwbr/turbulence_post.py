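"""Post-processing of exported LES velocity-gradient fields.

Operates on flat per-cell tables (position, cell volume, the nine
components of the resolved velocity-gradient tensor, optional SGS kinetic
energy) exported from any CFD run, and computes the diagnostics a culture
engineer needs: strain rate, the WALE sub-grid eddy viscosity, resolved and
SGS energy-dissipation rates, the Kolmogorov length (a proxy bound on cell
aggregate size), shear-stress magnitude, eddy diffusivity, the resolved
kinetic-energy ratio (mesh quality), and the surface-flux mass-transfer
coefficient.

All operators accept a single 3x3 tensor or a stacked ``(n, 3, 3)`` array
and are vectorised with numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CW_DEFAULT",
    "C_EPS_DEFAULT",
    "SCT_DEFAULT",
    "KE_RATIO_THRESHOLD",
    "EDR_CULTURE_LIMIT",
    "GradientField",
    "TurbulenceDiagnostics",
    "FluctuationSeries",
    "SurfaceFluxField",
    "strain_rate",
    "wale_nut",
    "eps_total",
    "kolmogorov",
    "shear_stress",
    "turb_diffusivity",
    "ke_ratio",
    "surface_kl",
    "diagnose_field",
    "summarize_distributions",
]

#: WALE model constant (solver-standard value).
CW_DEFAULT = 0.325
#: SGS dissipation constant in eps_sgs = C_eps * k_sgs^(3/2) / Delta.
C_EPS_DEFAULT = 1.034
#: Turbulent Schmidt number for eddy diffusivity D_ABt = nu_t / Sc_t.
SCT_DEFAULT = 1.34
#: Minimum resolved fraction of turbulent kinetic energy for a good LES mesh.
KE_RATIO_THRESHOLD = 0.8
#: EDR (m^2/s^3) above which conditions are flagged as harsh for stem-cell
#: culture.
EDR_CULTURE_LIMIT = 0.5e-3


@dataclass(frozen=True)
class GradientField:
    """Per-cell velocity gradients of one exported snapshot.

    ``gradU[i, a, b]`` is d u_a / d x_b in cell ``i``; the LES filter width
    is the cube root of the cell volume.
    """

    position: np.ndarray  # (n, 3) m
    cell_volume: np.ndarray  # (n,) m^3
    gradU: np.ndarray  # (n, 3, 3) 1/s
    nu: float  # molecular kinematic viscosity, m^2/s
    k_sgs: np.ndarray | None = None  # (n,) m^2/s^2
    nu_t: np.ndarray | None = None  # (n,) m^2/s

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.position, float))
        vol = np.atleast_1d(np.asarray(self.cell_volume, float))
        g = np.asarray(self.gradU, float)
        if g.ndim == 2:
            g = g[None]
        n = vol.size
        if pos.shape != (n, 3) or g.shape != (n, 3, 3):
            raise ValueError("inconsistent field shapes")
        if np.any(vol <= 0):
            raise ValueError("cell volumes must be positive")
        if not np.all(np.isfinite(g)):
            raise ValueError("gradient tensors must be finite")
        if self.nu <= 0:
            raise ValueError("molecular viscosity must be positive")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "cell_volume", vol)
        object.__setattr__(self, "gradU", g)
        for name in ("k_sgs", "nu_t"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.atleast_1d(np.asarray(arr, float))
                if arr.size != n or np.any(arr < 0):
                    raise ValueError(f"{name} must be non-negative, length n")
                object.__setattr__(self, name, arr)

    @property
    def delta(self) -> np.ndarray:
        """Filter width per cell: cube root of the cell volume (m)."""
        return np.cbrt(self.cell_volume)

    def __len__(self) -> int:
        return int(self.cell_volume.size)


@dataclass(frozen=True)
class TurbulenceDiagnostics:
    """Per-cell derived turbulence quantities (all SI)."""

    S_dd: np.ndarray  # S:S double contraction, 1/s^2
    nu_t: np.ndarray  # m^2/s
    eps_res: np.ndarray  # m^2/s^3
    eps_sgs: np.ndarray  # m^2/s^3
    eps: np.ndarray  # m^2/s^3
    eta: np.ndarray  # m
    tau: np.ndarray  # Pa
    D_ABt: np.ndarray  # m^2/s
    cell_volume: np.ndarray  # m^3 (weights for summaries)


@dataclass(frozen=True)
class FluctuationSeries:
    """Mean-removed velocity-fluctuation samples at probes.

    ``u_prime`` has shape (n_probes, n_samples, 3); ``k_sgs`` pairs each
    sample with the modelled SGS kinetic energy, shape (n_probes,
    n_samples) or (n_probes,).
    """

    u_prime: np.ndarray
    k_sgs: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u_prime, float)
        if u.ndim == 2:
            u = u[None]
        if u.ndim != 3 or u.shape[2] != 3 or u.shape[1] < 2:
            raise ValueError("u_prime must be (n_probes, n_samples>=2, 3)")
        k = np.asarray(self.k_sgs, float)
        if k.ndim == 0:
            k = np.full(u.shape[0], float(k))
        if k.ndim == 2 and k.shape[0] != u.shape[0]:
            raise ValueError("k_sgs probe dimension mismatch")
        if np.any(k < 0):
            raise ValueError("k_sgs must be non-negative")
        object.__setattr__(self, "u_prime", u)
        object.__setattr__(self, "k_sgs", k)


@dataclass(frozen=True)
class SurfaceFluxField:
    """Per-face surface data of an absorbing gas-liquid interface.

    ``dCdy`` is the wall-normal concentration gradient at the surface,
    positive into the liquid; fluxes are reported as magnitudes.
    """

    area: np.ndarray  # (n_faces,) m^2
    dCdy: np.ndarray  # (n_faces,) mol/m^4
    D_ABt: np.ndarray  # (n_faces,) m^2/s
    C_sat: float  # mol/m^3
    C_bulk_mean: float  # mol/m^3

    def __post_init__(self) -> None:
        area = np.atleast_1d(np.asarray(self.area, float))
        if np.any(area <= 0):
            raise ValueError("face areas must be positive")
        dcdy = np.broadcast_to(
            np.asarray(self.dCdy, float), area.shape
        ).astype(float)
        dabt = np.broadcast_to(
            np.asarray(self.D_ABt, float), area.shape
        ).astype(float)
        if np.any(dabt < 0):
            raise ValueError("turbulent diffusivities must be non-negative")
        object.__setattr__(self, "area", area)
        object.__setattr__(self, "dCdy", dcdy)
        object.__setattr__(self, "D_ABt", dabt)


def _stacked(gradU: np.ndarray) -> tuple[np.ndarray, bool]:
    g = np.asarray(gradU, float)
    if g.ndim == 2:
        return g[None], True
    return g, False


def strain_rate(gradU: np.ndarray) -> np.ndarray:
    """Resolved strain-rate tensor: the symmetric part of grad u.

    Vanishes for solid-body rotation (antisymmetric gradients).
    """
    g, single = _stacked(gradU)
    S = 0.5 * (g + np.swapaxes(g, -1, -2))
    return S[0] if single else S


def _double_contraction(T: np.ndarray) -> np.ndarray:
    return np.einsum("...ij,...ij->...", T, T)


def wale_nut(
    gradU: np.ndarray, delta: float | np.ndarray, Cw: float = CW_DEFAULT
) -> np.ndarray | float:
    """WALE sub-grid eddy viscosity (m^2/s).

        nu_t = (Cw Delta)^2 (Sd:Sd)^(3/2) / [(S:S)^(5/2) + (Sd:Sd)^(5/4)]

    with Sd the traceless symmetric part of the squared gradient tensor.
    Returns 0 where both contractions vanish (quiescent cells) and — by
    construction of Sd — for any pure-shear gradient, the design property
    that distinguishes WALE from Smagorinsky.
    """
    if Cw <= 0 or np.any(np.asarray(delta) <= 0):
        raise ValueError("Cw and delta must be positive")
    g, single = _stacked(gradU)
    S = 0.5 * (g + np.swapaxes(g, -1, -2))
    g2 = np.einsum("...ik,...kj->...ij", g, g)
    Sd = 0.5 * (g2 + np.swapaxes(g2, -1, -2))
    tr = np.trace(Sd, axis1=-2, axis2=-1)
    Sd = Sd - (tr / 3.0)[..., None, None] * np.eye(3)
    ss = _double_contraction(S)
    sdsd = _double_contraction(Sd)
    denom = ss**2.5 + sdsd**1.25
    delta = np.broadcast_to(np.asarray(delta, float), sdsd.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        nut = np.where(denom > 0.0, (Cw * delta) ** 2 * sdsd**1.5 / denom, 0.0)
    return float(nut[0]) if single else nut


def eps_total(
    field: GradientField,
    include_sgs: bool = True,
    C_eps: float = C_EPS_DEFAULT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell (eps, eps_res, eps_sgs) in m^2/s^3.

    eps_res = 2 nu S:S from the resolved strain field; eps_sgs =
    C_eps k_sgs^(3/2) / Delta from the modelled SGS energy; eps is their
    sum.  Requesting the SGS part without k_sgs data is an input error.
    """
    S = strain_rate(field.gradU)
    eps_res = 2.0 * field.nu * _double_contraction(S)
    if include_sgs:
        if field.k_sgs is None:
            raise ValueError("field carries no k_sgs but the SGS term was requested")
        eps_sgs = C_eps * field.k_sgs**1.5 / field.delta
    else:
        eps_sgs = np.zeros_like(eps_res)
    return eps_res + eps_sgs, eps_res, eps_sgs


def kolmogorov(nu: float, eps: np.ndarray | float) -> np.ndarray | float:
    """Kolmogorov length scale ``eta = (nu^3 / eps)^(1/4)`` (m).

    Quiescent cells (eps = 0) map to +inf: no finite smallest eddy.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    eps_arr = np.asarray(eps, float)
    if np.any(eps_arr < 0):
        raise ValueError("eps must be non-negative")
    with np.errstate(divide="ignore"):
        eta = np.where(eps_arr > 0, (nu**3 / eps_arr) ** 0.25, np.inf)
    return float(eta) if np.isscalar(eps) else eta


def shear_stress(
    gradU: np.ndarray,
    mu: float,
    mu_t: float | np.ndarray = 0.0,
    literal: bool = False,
) -> np.ndarray | float:
    """Shear-stress estimate (Pa) felt by suspended aggregates.

    Default: the dimensionally consistent magnitude
    ``tau = (mu + mu_t) sqrt(2 S:S)``.  ``literal=True`` instead evaluates
    the plain product ``(mu + mu_t) (S:S)`` for comparison with reports
    that use that form (note its units are then Pa/s).
    """
    if mu < 0 or np.any(np.asarray(mu_t) < 0):
        raise ValueError("viscosities must be non-negative")
    S = strain_rate(gradU)
    ss = _double_contraction(S)
    if literal:
        return (mu + mu_t) * ss
    return (mu + mu_t) * np.sqrt(2.0 * ss)


def turb_diffusivity(
    nu_t: np.ndarray | float, Sc_t: float = SCT_DEFAULT
) -> np.ndarray | float:
    """Eddy diffusivity ``D_ABt = nu_t / Sc_t`` (m^2/s)."""
    if Sc_t <= 0:
        raise ValueError("turbulent Schmidt number must be positive")
    if np.any(np.asarray(nu_t) < 0):
        raise ValueError("nu_t must be non-negative")
    return nu_t / Sc_t


def ke_ratio(
    fluct: FluctuationSeries, threshold: float = KE_RATIO_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Resolved fraction of turbulent kinetic energy per probe.

    k_resolved = (1/2) sum_i mean(u'_i^2); ratio = k_res / (k_res +
    mean k_sgs), in [0, 1].  Returns (ratio, quality_flag) where the flag
    marks probes resolving less than ``threshold`` of the energy — the
    conventional 80% rule of thumb for adequate LES resolution.  Probes
    with zero total energy get NaN and are flagged.
    """
    u = fluct.u_prime
    k_res = 0.5 * (u**2).mean(axis=1).sum(axis=-1)
    k_sgs = fluct.k_sgs
    k_sgs_mean = k_sgs.mean(axis=1) if k_sgs.ndim == 2 else k_sgs
    total = k_res + k_sgs_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, k_res / total, np.nan)
    flagged = ~(ratio >= threshold)
    return ratio, flagged


def surface_kl(surface: SurfaceFluxField, D_AB: float) -> float:
    """Surface-averaged mass-transfer coefficient kL (m/s) from fluxes.

    Per face, the absorption flux is N = (D_AB + D_ABt) |dC/dy| at the
    interface; kL is the area-weighted mean flux over the driving force
    C_sat - <C_bulk>.  A vanishing driving force (saturated run) is an
    error rather than a divide-by-zero.
    """
    if D_AB <= 0:
        raise ValueError("D_AB must be positive")
    driving = surface.C_sat - surface.C_bulk_mean
    if abs(driving) < 1e-9 * abs(surface.C_sat):
        raise ValueError("driving force C_sat - <C> underflows: saturated run")
    flux = (D_AB + surface.D_ABt) * np.abs(surface.dCdy)
    mean_flux = float(flux @ surface.area) / float(surface.area.sum())
    return mean_flux / driving


def diagnose_field(
    field: GradientField,
    Cw: float = CW_DEFAULT,
    C_eps: float = C_EPS_DEFAULT,
    Sc_t: float = SCT_DEFAULT,
    literal_shear: bool = False,
) -> TurbulenceDiagnostics:
    """Run the full per-cell diagnostic chain on a gradient field.

    Uses the field's own nu_t where exported, otherwise recomputes it with
    the WALE operator; the SGS dissipation term is included only when the
    field carries k_sgs.
    """
    S = strain_rate(field.gradU)
    s_dd = _double_contraction(S)
    nu_t = (
        field.nu_t
        if field.nu_t is not None
        else wale_nut(field.gradU, field.delta, Cw)
    )
    eps, eps_res, eps_sgs = eps_total(
        field, include_sgs=field.k_sgs is not None, C_eps=C_eps
    )
    rho_ref = 998.0  # water at ~21 C; only scales mu = rho*nu in tau
    mu = rho_ref * field.nu
    mu_t = rho_ref * nu_t
    tau = shear_stress(field.gradU, mu, mu_t, literal=literal_shear)
    return TurbulenceDiagnostics(
        S_dd=s_dd,
        nu_t=np.asarray(nu_t, float),
        eps_res=eps_res,
        eps_sgs=eps_sgs,
        eps=eps,
        eta=kolmogorov(field.nu, eps),
        tau=np.asarray(tau, float),
        D_ABt=np.asarray(turb_diffusivity(nu_t, Sc_t), float),
        cell_volume=field.cell_volume,
    )


def _weighted_quantiles(
    values: np.ndarray, weights: np.ndarray, qs: np.ndarray
) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(qs, cum, v)


def summarize_distributions(
    diag: TurbulenceDiagnostics,
    bins: int = 50,
    quantiles: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
    edr_limit: float = EDR_CULTURE_LIMIT,
) -> dict:
    """Volume-weighted histograms and quantiles of eta, eps and tau.

    Mirrors the distribution summaries a culture engineer reads off field
    snapshots, plus the fraction of working volume whose energy-dissipation
    rate exceeds ``edr_limit`` (default 0.5e-3 m^2/s^3, the level above
    which conditions are considered harsh for stem-cell aggregates).
    """
    w = diag.cell_volume
    if w.size == 0:
        raise ValueError("empty diagnostics field")
    qs = np.asarray(quantiles, float)
    out: dict = {"quantile_levels": qs}
    for name in ("eta", "eps", "tau"):
        values = getattr(diag, name)
        finite = np.isfinite(values)
        v, wv = values[finite], w[finite]
        if v.size == 0:
            out[name] = {"histogram": None, "quantiles": None}
            continue
        hist, edges = np.histogram(v, bins=bins, weights=wv)
        out[name] = {
            "histogram": hist,
            "bin_edges": edges,
            "quantiles": _weighted_quantiles(v, wv, qs),
            "volume_fraction_finite": float(wv.sum() / w.sum()),
        }
    out["edr_limit"] = edr_limit
    out["volume_fraction_edr_above_limit"] = float(
        w[diag.eps > edr_limit].sum() / w.sum()
    )
    return out
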