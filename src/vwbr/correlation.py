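"""The modified Sherwood correlation and the oxygen-limited cell density.

Surface aeration of the vertical-wheel vessel is summarised by a power-law
correlation between dimensionless groups,

    Sh = k Re^alpha Sc^(1/3) G^gamma,

where G = D A / V folds the working-volume dependence into a geometric
group.  The Schmidt exponent is fixed at 1/3 (the classical boundary-layer
result) so that only (k, alpha, gamma) are fitted.  A correlation fitted to
simulation output overpredicts the measured kL by a nearly constant factor;
``adjust_linear_constant`` rescales its linear constant k against
observations and reports the correction factor.  Finally, equating oxygen
transfer to oxygen uptake bounds the supportable cell density
X = kLa C_sat / qO2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .physchem import (
    DimensionlessGroups,
    MediumProperties,
    OperatingPoint,
    dimensionless_groups,
    sherwood_to_kl,
)

__all__ = [
    "SherwoodConstants",
    "CorrelationDataset",
    "FitReport",
    "predict_sherwood",
    "fit_sherwood",
    "adjust_linear_constant",
    "predict_kla",
    "max_cell_density",
]

#: Classical boundary-layer Schmidt exponent.
BETA_DEFAULT = 1.0 / 3.0


@dataclass(frozen=True)
class SherwoodConstants:
    """Power-law constants (k, alpha, beta, gamma) with a provenance tag."""

    k: float
    alpha: float
    beta: float = BETA_DEFAULT
    gamma: float = 0.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("linear constant k must be positive")
        for name in ("alpha", "beta", "gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"exponent {name} must be finite")


@dataclass(frozen=True)
class CorrelationDataset:
    """Records of (Re, Sc, G, Sh) with optional per-record weights."""

    Re: np.ndarray
    Sc: np.ndarray
    G: np.ndarray
    Sh: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("Re", "Sc", "G", "Sh"):
            arr = np.asarray(getattr(self, name), float)
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be positive")
            n = arr.size if n is None else n
            if arr.size != n:
                raise ValueError("all columns must have equal length")
            arrays[name] = arr
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if w.size != n or np.any(w < 0):
                raise ValueError("weights must be non-negative, same length")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return int(self.Re.size)


@dataclass(frozen=True)
class FitReport:
    """Fitted constants plus per-record absolute percentage errors."""

    constants: SherwoodConstants
    ape: np.ndarray  # per-record |Sh_pred - Sh_obs| / Sh_obs * 100
    sse: float

    @property
    def mean_ape(self) -> float:
        return float(self.ape.mean())

    @property
    def max_ape(self) -> float:
        return float(self.ape.max())


def predict_sherwood(
    groups: DimensionlessGroups | CorrelationDataset, c: SherwoodConstants
):
    """Evaluate ``Sh = k Re^alpha Sc^beta G^gamma``."""
    return c.k * groups.Re**c.alpha * groups.Sc**c.beta * groups.G**c.gamma


def fit_sherwood(
    data: CorrelationDataset,
    fix_beta: bool = True,
    beta: float = BETA_DEFAULT,
    log_space: bool = False,
) -> FitReport:
    """Least-squares fit of (k, alpha, gamma) [and beta if freed].

    Minimises sum (Sh_obs - Sh_model)^2 directly on Sh (a log-space option
    exists for diagnostics).  Deterministic: fixed start (1, 0.5, 1) and
    tolerances 1e-12.  Raises if the data cannot identify the free
    constants (fewer records than constants, or no variation in Re or G).
    """
    n_free = 3 if fix_beta else 4
    if len(data) < n_free + 1:
        raise ValueError(
            f"need at least {n_free + 1} records to fit {n_free} constants"
        )
    for name in ("Re", "G") + (() if fix_beta else ("Sc",)):
        col = getattr(data, name)
        if np.ptp(col) / col.max() < 1e-12:
            raise ValueError(f"no variation in {name}: exponent unidentifiable")
    w = np.sqrt(data.weights) if data.weights is not None else 1.0
    logs = np.log(np.column_stack([data.Re, data.Sc, data.G]))
    log_obs = np.log(data.Sh)

    def model_log(theta: np.ndarray) -> np.ndarray:
        log_k, alpha, gamma = theta[0], theta[1], theta[2]
        b = theta[3] if not fix_beta else beta
        return log_k + logs @ np.array([alpha, b, gamma])

    def residuals(theta: np.ndarray) -> np.ndarray:
        if log_space:
            return w * (model_log(theta) - log_obs)
        return w * (np.exp(model_log(theta)) - data.Sh)

    x0 = [0.0, 0.5, 1.0] + ([beta] if not fix_beta else [])
    sol = least_squares(
        residuals, x0=np.array(x0), method="lm", xtol=1e-12, ftol=1e-12,
        gtol=1e-12, max_nfev=20000,
    )
    theta = sol.x
    constants = SherwoodConstants(
        k=float(np.exp(theta[0])),
        alpha=float(theta[1]),
        beta=float(theta[3]) if not fix_beta else beta,
        gamma=float(theta[2]),
        provenance="fitted",
    )
    pred = predict_sherwood(data, constants)
    ape = np.abs(pred - data.Sh) / data.Sh * 100.0
    sse = float(np.sum((pred - data.Sh) ** 2))
    return FitReport(constants=constants, ape=ape, sse=sse)


def adjust_linear_constant(
    sim: SherwoodConstants,
    observations: CorrelationDataset,
    compare: Literal["kL", "Sh"] = "kL",
    D: float | None = None,
    D_AB: float | None = None,
) -> tuple[SherwoodConstants, float]:
    """Rescale the linear constant of a correlation against observations.

    Finds the single multiplicative constant c minimising
    sum (obs - c * pred)^2, where obs/pred are Sherwood numbers or the kL
    values they imply (``compare="kL"`` needs ``D`` and ``D_AB`` to convert;
    the optimum is invariant to that common linear rescaling, so the two
    comparisons agree whenever all records share one geometry/temperature).
    Returns the adjusted constants (exponents untouched) and the correction
    factor k_adjusted / k_sim.
    """
    if len(observations) == 0:
        raise ValueError("observations must be non-empty")
    pred = np.asarray(predict_sherwood(observations, sim), float)
    obs = observations.Sh.copy()
    if compare == "kL":
        if D is None or D_AB is None:
            scale = 1.0  # single common conversion: drops out of the ratio
        else:
            scale = D_AB / D
        pred = pred * scale
        obs = obs * scale
    factor = float(obs @ pred) / float(pred @ pred)
    adjusted = replace(sim, k=sim.k * factor, provenance="adjusted")
    return adjusted, factor


def predict_kla(
    op: OperatingPoint, props: MediumProperties, c: SherwoodConstants
) -> tuple[float, float]:
    """Predict (kLa in 1/s, kL in m/s) for one operating point.

    Composes the dimensionless groups, evaluates the correlation, converts
    Sh back to kL with the wheel diameter, and multiplies by the specific
    area a = A/V.
    """
    groups = dimensionless_groups(op, props)
    Sh = predict_sherwood(groups, c)
    kL = sherwood_to_kl(Sh, op.D, props.D_AB)
    return kL * op.specific_area, kL


def max_cell_density(kLa: float, C_sat: float, qO2: float) -> float:
    """Oxygen-limited maximum cell density ``X = kLa C_sat / qO2``.

    Equates the oxygen transfer rate kLa(C_sat - 0) to the uptake X qO2 of
    a homogeneous culture driving the bulk oxygen to zero.  Units:
    kLa 1/s, C_sat mol/m^3, qO2 mol/cell/s -> X cells/m^3 (divide by 1e6
    for cells/mL).
    """
    if kLa <= 0 or C_sat <= 0:
        raise ValueError("kLa and C_sat must be positive")
    if qO2 <= 0:
        raise ValueError("qO2 must be positive")
    return kLa * C_sat / qO2
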