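"""Tables, configuration, packaged fixtures and run reports.

All on-disk formats are delimited text (comma or tab, auto-detected) with a
header row; numbers are always written with a period decimal separator,
independent of locale.  SI units internally; rpm and 1/h appear only at the
boundary because that is how operators quote agitation rates and kLa.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .correlation import CorrelationDataset, SherwoodConstants
from .kinetics import IntensityTrace, SpectrumSeries
from .physchem import DEFAULT_WHEEL_DIAMETER, O2_MOLE_FRACTION_AIR
from .turbulence_post import (
    C_EPS_DEFAULT,
    CW_DEFAULT,
    SCT_DEFAULT,
    GradientField,
    SurfaceFluxField,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "read_table",
    "write_table",
    "load_table1_areas",
    "load_table3_constants",
    "load_packaged_trace",
    "read_trace",
    "write_trace",
    "read_correlation_dataset",
    "read_gradient_field",
    "read_surface_field",
    "write_properties_report",
]

_GRADIENT_COLUMNS = [
    "dudx", "dudy", "dudz", "dvdx", "dvdy", "dvdz", "dwdx", "dwdy", "dwdz",
]


@dataclass
class RunConfig:
    """Serialisable configuration covering every tunable of the pipeline."""

    wheel_diameter: float = DEFAULT_WHEEL_DIAMETER  # m
    pO2: float = O2_MOLE_FRACTION_AIR  # atm
    diffusivity_c0: float = 1.05e-9  # m^2/s
    diffusivity_c1: float = 5.0e-11  # m^2/s/degC
    viscosity_correlation: str = "vogel-kell"
    saturation_correlation: str = "benson-krause"
    fix_beta: bool = True
    beta: float = 1.0 / 3.0
    Cw: float = CW_DEFAULT
    C_eps: float = C_EPS_DEFAULT
    Sc_t: float = SCT_DEFAULT
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Quantities (each with a unit string), warnings, and provenance."""

    stage: str
    quantities: dict[str, tuple[float, str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    inputs_digest: str = ""
    version: str = "0.1.0"

    def add(self, name: str, value: float, unit: str) -> None:
        self.quantities[name] = (float(value), unit)

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_text(self) -> str:
        lines = [f"# vwbr {self.version} :: {self.stage}"]
        if self.inputs_digest:
            lines.append(f"# inputs: {self.inputs_digest}")
        for name, (value, unit) in self.quantities.items():
            lines.append(f"{name}\t{value:.10g}\t{unit}")
        for w in self.warnings:
            lines.append(f"# WARNING: {w}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "version": self.version,
                "inputs": self.inputs_digest,
                "quantities": {
                    k: {"value": v, "unit": u}
                    for k, (v, u) in self.quantities.items()
                },
                "warnings": self.warnings,
            },
            indent=2,
        )

    def write(self, path: str | Path) -> None:
        p = Path(path)
        p.write_text(self.to_text())
        p.with_suffix(p.suffix + ".json").write_text(self.to_json())


def read_table(
    path: str | Path, schema: Mapping[str, type] | None = None
) -> pd.DataFrame:
    """Read a delimited text table (separator auto-detected) strictly.

    ``schema`` maps required column names to types; a missing column or a
    non-coercible cell raises with the column (and row) named.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for col, typ in schema.items():
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad.index[0]) + 2 if len(bad) else "?"
                raise ValueError(
                    f"{path}: column {col!r} row {row}: cannot parse as "
                    f"{typ.__name__}"
                ) from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a DataFrame as headered delimited text (never mutates input)."""
    df.to_csv(path, sep=sep, index=False)


def _packaged(name: str):
    return resources.files("vwbr.data").joinpath(name)


def load_table1_areas() -> pd.DataFrame:
    """Working volume vs contact area and specific area of the 0.1 L vessel.

    Columns: volume_mL, area_cm2, specific_area_per_m.  The specific-area
    column carries the published values verbatim (they are quoted to three
    significant figures and the 60 mL row rounds area and ratio
    independently).
    """
    with resources.as_file(_packaged("table1_areas.csv")) as p:
        return read_table(
            p,
            {"volume_mL": float, "area_cm2": float, "specific_area_per_m": float},
        )


def load_table3_constants() -> dict[str, SherwoodConstants]:
    """The three published constant sets of the Sherwood correlation.

    Keys: ``experimental``, ``simulation``, ``adjusted``.  The Schmidt
    exponent is printed as 0.333 but is the exact rational 1/3; the loader
    restores the exact value.
    """
    with resources.as_file(_packaged("table3_constants.csv")) as p:
        df = read_table(p)
    out = {}
    for col, label in (
        ("experimental", "experimental"),
        ("simulation", "simulation"),
        ("adjusted_simulation", "adjusted"),
    ):
        row = df.set_index("constant")[col]
        beta = float(row["beta"])
        if abs(beta - 0.333) < 5e-4:
            beta = 1.0 / 3.0
        out[label] = SherwoodConstants(
            k=float(row["k"]),
            alpha=float(row["alpha"]),
            beta=beta,
            gamma=float(row["gamma"]),
            provenance=label,
        )
    return out


def load_packaged_trace() -> IntensityTrace:
    """The packaged synthetic luminescence trace (seeded generator output).

    Ground truth recorded in the file header comment: kLa = 2.0 1/h.
    """
    with resources.as_file(_packaged("synthetic_trace.csv")) as p:
        return read_trace(p)


def read_trace(path: str | Path) -> IntensityTrace:
    """Read a pre-extracted (time_s, intensity_counts) trace.

    Optional columns I_max / I_min (single values) set the plateau levels.
    """
    df = read_table(path, {"time_s": float, "intensity_counts": float})
    kwargs: dict[str, float] = {}
    for col, name in (("I_max", "I_max"), ("I_min", "I_min")):
        if col in df.columns:
            kwargs[name] = float(df[col].iloc[0])
    return IntensityTrace(
        times=df["time_s"].to_numpy(),
        I_recorded=df["intensity_counts"].to_numpy(),
        **kwargs,
    )


def write_trace(trace: IntensityTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": trace.times, "intensity_counts": trace.I_recorded}
    )
    if np.isfinite(trace.I_max):
        df["I_max"] = trace.I_max
        df["I_min"] = trace.I_min
    write_table(df, path)


def read_spectrum_series(path: str | Path) -> SpectrumSeries:
    """Read long-format (time_s, wavelength_nm, counts[, dark]) spectra."""
    df = read_table(
        path, {"time_s": float, "wavelength_nm": float, "counts": float}
    )
    times = np.unique(df["time_s"].to_numpy())
    wl = np.unique(df["wavelength_nm"].to_numpy())
    pivot = df.pivot_table(
        index="time_s", columns="wavelength_nm", values="counts"
    )
    if pivot.isna().any().any():
        raise ValueError(f"{path}: ragged spectra (missing time/wavelength cells)")
    dark = (
        df.pivot_table(index="time_s", columns="wavelength_nm", values="dark")
        .iloc[0]
        .to_numpy()
        if "dark" in df.columns
        else np.zeros(wl.size)
    )
    return SpectrumSeries(
        times=times, wavelengths=wl, counts=pivot.to_numpy(), dark=dark
    )


def read_correlation_dataset(path: str | Path) -> CorrelationDataset:
    """Read (Re, Sc, G, Sh) records, with optional weight column."""
    df = read_table(path, {"Re": float, "Sc": float, "G": float, "Sh": float})
    return CorrelationDataset(
        Re=df["Re"].to_numpy(),
        Sc=df["Sc"].to_numpy(),
        G=df["G"].to_numpy(),
        Sh=df["Sh"].to_numpy(),
        weights=df["weight"].to_numpy() if "weight" in df.columns else None,
    )


def write_correlation_dataset(data: CorrelationDataset, path: str | Path) -> None:
    df = pd.DataFrame({"Re": data.Re, "Sc": data.Sc, "G": data.G, "Sh": data.Sh})
    if data.weights is not None:
        df["weight"] = data.weights
    write_table(df, path)


def read_gradient_field(path: str | Path, nu: float) -> GradientField:
    """Read a per-cell field table: x y z cell_volume dudx...dwdz [k_sgs nu_t]."""
    schema = {c: float for c in ["x", "y", "z", "cell_volume"] + _GRADIENT_COLUMNS}
    df = read_table(path, schema)
    grad = df[_GRADIENT_COLUMNS].to_numpy().reshape(-1, 3, 3)
    return GradientField(
        position=df[["x", "y", "z"]].to_numpy(),
        cell_volume=df["cell_volume"].to_numpy(),
        gradU=grad,
        nu=nu,
        k_sgs=df["k_sgs"].to_numpy() if "k_sgs" in df.columns else None,
        nu_t=df["nu_t"].to_numpy() if "nu_t" in df.columns else None,
    )


def write_gradient_field(field: GradientField, path: str | Path) -> None:
    df = pd.DataFrame(field.position, columns=["x", "y", "z"])
    df["cell_volume"] = field.cell_volume
    flat = field.gradU.reshape(len(field), 9)
    for i, col in enumerate(_GRADIENT_COLUMNS):
        df[col] = flat[:, i]
    if field.k_sgs is not None:
        df["k_sgs"] = field.k_sgs
    if field.nu_t is not None:
        df["nu_t"] = field.nu_t
    write_table(df, path)


def read_surface_field(
    path: str | Path, C_sat: float, C_bulk_mean: float
) -> SurfaceFluxField:
    """Read a per-face surface table: area, dCdy, D_ABt."""
    df = read_table(path, {"area": float, "dCdy": float, "D_ABt": float})
    return SurfaceFluxField(
        area=df["area"].to_numpy(),
        dCdy=df["dCdy"].to_numpy(),
        D_ABt=df["D_ABt"].to_numpy(),
        C_sat=C_sat,
        C_bulk_mean=C_bulk_mean,
    )


def write_properties_report(
    temperatures, path: str | Path, config: RunConfig | None = None
) -> pd.DataFrame:
    """Tabulate T, nu, D_AB, C_sat, Sc over a temperature list."""
    from . import physchem

    config = config or RunConfig()
    fit = physchem.DiffusivityFit(config.diffusivity_c0, config.diffusivity_c1)
    rows = []
    for T in temperatures:
        props = physchem.medium_properties(T, config.pO2, fit)
        rows.append(
            {
                "T_C": T,
                "nu_m2_s": props.nu,
                "D_AB_m2_s": props.D_AB,
                "C_sat_mol_m3": props.C_sat,
                "Sc": physchem.schmidt(props),
            }
        )
    df = pd.DataFrame(rows)
    write_table(df, path)
    return df
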