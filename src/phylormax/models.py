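"""Candidate model formulas and design-matrix construction.

Metabolic scaling theory predicts that a mass-specific biological rate such
as the maximum population growth rate follows

    r_max ∝ i0 * M^beta * exp(-E / (kB * T)),

which in log space is the linear model

    log r_max = b0 + b1 * log M + b2 * (1 / (kB * T)),

with b1 the mass-scaling exponent (expected near -1/4) and b2 the negative
activation energy -E (expected in [-1.0, -0.6] eV). The analysis compares
ten candidate structures built from log body mass, inverse temperature
(``invtemp`` = 1/(kB*T), eV^-1), and median depth: main effects plus the
mass x temperature, mass x depth, and temperature x depth interactions.

Covariate conventions (recorded in each design matrix):

* natural log for mass and r_max;
* temperature enters only as invtemp, never raw degrees C;
* invtemp and depth are centered and scaled (z-scored, sd with n-1) by
  default; log mass is left on its natural scale so the mass slope is
  directly comparable to metabolic-theory exponents;
* interaction columns are products of the transformed main-effect columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_EV",
    "ModelSpec",
    "DesignMatrix",
    "inverse_temperature",
    "standardize",
    "enumerate_models",
    "build_design_matrix",
]

#: Boltzmann constant in eV per Kelvin
BOLTZMANN_EV = 8.617e-5

#: covariate column order used everywhere downstream
_MAIN_ORDER = ("log_mass", "invtemp", "depth")
_INTERACTION_ORDER = (
    ("log_mass", "invtemp"),
    ("log_mass", "depth"),
    ("invtemp", "depth"),
)


def inverse_temperature(temp_c):
    """Arrhenius inverse temperature 1/(kB*T) in eV^-1 from degrees Celsius."""
    temp_c = np.asarray(temp_c, dtype=float)
    if np.any(temp_c <= -273.15):
        raise ValueError("temperature at or below absolute zero")
    out = 1.0 / (BOLTZMANN_EV * (temp_c + 273.15))
    return float(out) if out.ndim == 0 else out


def standardize(x) -> tuple[np.ndarray, float, float]:
    """Z-score a vector; returns ``(z, mean, sd)`` with sd using n-1.

    The centering constants are retained so that predictions at new covariate
    values can be placed on the fitted scale.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize expects a 1-d vector of length >= 2")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot standardize a constant vector")
    return (x - mu) / sd, mu, sd


@dataclass(frozen=True)
class ModelSpec:
    """One candidate formula: main effects plus interactions.

    ``name`` is the formula label used in reports (R-style, with ``*``
    expanding to mains plus interaction as usual).
    """

    name: str
    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for m in self.main_effects:
            if m not in _MAIN_ORDER:
                raise ValueError(f"unknown main effect {m!r}")
        for pair in self.interactions:
            if any(p not in self.main_effects for p in pair):
                raise ValueError(
                    f"interaction {pair} involves a term absent from "
                    f"main effects {self.main_effects}"
                )

    @property
    def k(self) -> int:
        """Number of regression coefficients including the intercept."""
        return 1 + len(self.main_effects) + len(self.interactions)

    def column_names(self) -> list[str]:
        cols = ["intercept"]
        cols += [m for m in _MAIN_ORDER if m in self.main_effects]
        cols += [
            f"{a}:{b}" for a, b in _INTERACTION_ORDER
            if (a, b) in self.interactions
        ]
        return cols


@dataclass
class DesignMatrix:
    """Numeric design matrix with its response and transform constants."""

    spec: ModelSpec
    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    species: list[str]
    transform: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def enumerate_models() -> list[ModelSpec]:
    """The ten candidate model structures, mass-only baseline first.

    Ordered from the single-predictor baseline through the full
    two-interaction structure; coefficient counts are 2,3,3,4,5,4,4,5,5,6.
    """
    M, T, D = "log_mass", "invtemp", "depth"
    return [
        ModelSpec("logrmax~logM", (M,)),
        ModelSpec("logrmax~logM+depth", (M, D)),
        ModelSpec("logrmax~logM+1/kBT", (M, T)),
        ModelSpec("logrmax~logM+1/kBT+depth", (M, T, D)),
        ModelSpec("logrmax~logM+1/kBT*depth", (M, T, D), ((T, D),)),
        ModelSpec("logrmax~logM*depth", (M, D), ((M, D),)),
        ModelSpec("logrmax~logM*1/kBT", (M, T), ((M, T),)),
        ModelSpec("logrmax~logM*depth+1/kBT", (M, T, D), ((M, D),)),
        ModelSpec("logrmax~logM*1/kBT+depth", (M, T, D), ((M, T),)),
        ModelSpec("logrmax~logM*1/kBT+logM*depth", (M, T, D), ((M, T), (M, D))),
    ]


def spec_by_name(name: str) -> ModelSpec:
    """Look up one of the shipped specs by its formula label."""
    for spec in enumerate_models():
        if spec.name == name:
            return spec
    raise KeyError(f"no shipped model named {name!r}")


def build_design_matrix(
    spec: ModelSpec,
    table: pd.DataFrame,
    *,
    scale: bool = True,
    transform: dict | None = None,
) -> DesignMatrix:
    """Build the design matrix and log r_max response for one candidate model.

    Parameters
    ----------
    spec
        The candidate structure.
    table
        Species table with columns ``species, mass` (g) or ``log_mass``,
        ``median_temp`` (degrees C) or ``invtemp``, ``median_depth`` (m) or
        ``depth``, and ``rmax`` (yr^-1, > 0).
    scale
        If True (default), invtemp and depth are centered and scaled; if
        False they are centered only, leaving slopes on the natural eV^-1 /
        meter scale.
    transform
        Reuse previously stored centering constants (for prediction on the
        training scale) instead of recomputing them from ``table``.

    Raises
    ------
    ValueError
        If any required covariate is missing or non-finite, naming the
        offending species.
    """
    table = table.reset_index(drop=True)
    species = [str(s) for s in table["species"]]

    raw: dict[str, np.ndarray] = {}
    if "log_mass" in table.columns:
        raw["log_mass"] = table["log_mass"].to_numpy(float)
    else:
        raw["log_mass"] = np.log(table["mass"].to_numpy(float))
    if "invtemp" in table.columns:
        raw["invtemp"] = table["invtemp"].to_numpy(float)
    elif "median_temp" in table.columns or "temp_c" in table.columns:
        temp_col = "median_temp" if "median_temp" in table.columns else "temp_c"
        raw["invtemp"] = inverse_temperature(table[temp_col].to_numpy(float))
    else:
        raw["invtemp"] = np.full(len(table), np.nan)
    for cand in ("depth", "median_depth", "depth_m"):
        if cand in table.columns:
            raw["depth"] = table[cand].to_numpy(float)
            break
    else:
        raw["depth"] = np.full(len(table), np.nan)

    for name in spec.main_effects:
        bad = [sp for sp, v in zip(species, raw[name]) if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite {name} for species: {bad}")

    if transform is None:
        transform = {"scale": scale, "log": "natural"}
        for name in ("invtemp", "depth"):
            if name not in spec.main_effects:
                continue
            mu = float(raw[name].mean())
            sd = float(raw[name].std(ddof=1)) if scale else 1.0
            if sd == 0.0:
                raise ValueError(f"constant {name} column cannot be scaled")
            transform[name] = {"center": mu, "scale": sd}
    cols: dict[str, np.ndarray] = {"log_mass": raw["log_mass"]}
    for name in ("invtemp", "depth"):
        if name in transform:
            t = transform[name]
            cols[name] = (raw[name] - t["center"]) / t["scale"]

    names = spec.column_names()
    parts = [np.ones(len(table))]
    for name in names[1:]:
        if ":" in name:
            a, b = name.split(":")
            parts.append(cols[a] * cols[b])
        else:
            parts.append(cols[name])
    X = np.column_stack(parts)

    y = None
    if "rmax" in table.columns:
        rmax = table["rmax"].to_numpy(float)
        bad = [sp for sp, v in zip(species, rmax) if not (v > 0)]
        if bad:
            raise ValueError(f"rmax must be > 0; offending species: {bad}")
        y = np.log(rmax)
    return DesignMatrix(
        spec=spec, X=X, y=y, columns=names, species=species,
        transform=transform,
    )
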