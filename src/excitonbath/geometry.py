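"""Pigment geometry and point-dipole excitonic couplings.

A pigment is reduced to its Mg position and the unit direction of its Qy
transition dipole (ND -> NB in PDB atom nomenclature).  The coupling between
two pigments k and m is evaluated in the point-dipole approximation,

    V_km = f * 5.034 * mu_k mu_m * kappa / R_km^3   [cm^-1],

with the orientation factor kappa = e_k.e_m - 3 (e_k.r)(e_m.r), the screening
factor f accounting for the protein dielectric, dipole strengths in Debye,
and R_km the Mg-Mg distance in angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .units import CONSTANTS

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class PigmentGeometry:
    """Mg position and unit transition-dipole direction of one pigment."""

    label: str
    monomer: str
    mg_position: np.ndarray
    dipole_direction: np.ndarray

    def __post_init__(self) -> None:
        mg = np.asarray(self.mg_position, dtype=float)
        d = np.asarray(self.dipole_direction, dtype=float)
        if mg.shape != (3,) or d.shape != (3,):
            raise ValueError("mg_position and dipole_direction must be 3-vectors")
        if not np.all(np.isfinite(mg)):
            raise ValueError(f"pigment {self.label}: non-finite Mg position")
        if abs(np.linalg.norm(d) - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"pigment {self.label}: dipole_direction is not a unit vector"
            )
        object.__setattr__(self, "mg_position", mg)
        object.__setattr__(self, "dipole_direction", d)


@dataclass(frozen=True)
class CouplingConfig:
    """Constants of the point-dipole coupling.

    ``screening_factor`` (f) and ``dipole_strength_product`` (mu_k*mu_m, D^2)
    default to the values standard for BChl a in FMO: f = 0.8 and 37.5 D^2.
    """

    screening_factor: float = 0.8
    dipole_strength_product: float = 37.5

    def __post_init__(self) -> None:
        if self.screening_factor <= 0 or self.dipole_strength_product <= 0:
            raise ValueError("coupling constants must be positive")


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} is not a unit vector (|v| = {np.linalg.norm(v):g})")
    return v


def orientation_factor(e_k: np.ndarray, e_m: np.ndarray, r_hat: np.ndarray) -> float:
    """Dipole-dipole orientation factor kappa = e_k.e_m - 3(e_k.r)(e_m.r).

    All three arguments must be unit vectors; kappa lies in [-2, 2].
    """
    e_k = _check_unit(e_k, "e_k")
    e_m = _check_unit(e_m, "e_m")
    r_hat = _check_unit(r_hat, "r_hat")
    return float(e_k @ e_m - 3.0 * (e_k @ r_hat) * (e_m @ r_hat))


def point_dipole_coupling(
    pig_k: PigmentGeometry,
    pig_m: PigmentGeometry,
    config: CouplingConfig | None = None,
) -> float:
    """Excitonic coupling V_km between two pigments in cm^-1."""
    config = config or CouplingConfig()
    r = pig_m.mg_position - pig_k.mg_position
    dist = float(np.linalg.norm(r))
    if dist <= 0.1:
        raise ValueError(
            f"pigments {pig_k.label} and {pig_m.label} are coincident "
            f"(Mg-Mg distance {dist:g} A)"
        )
    kappa = orientation_factor(pig_k.dipole_direction, pig_m.dipole_direction, r / dist)
    return (
        config.screening_factor
        * CONSTANTS.dipole_coupling_prefactor
        * config.dipole_strength_product
        * kappa
        / dist**3
    )


def _display_labels(pigments: Sequence[PigmentGeometry]) -> list[str]:
    monomers = {p.monomer for p in pigments}
    if len(monomers) == 1:
        labels = [p.label for p in pigments]
    else:
        labels = [f"{p.label}:{p.monomer}" for p in pigments]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate pigment labels")
    return labels


def coupling_matrix(
    pigments: Sequence[PigmentGeometry],
    config: CouplingConfig | None = None,
) -> pd.DataFrame:
    """Pairwise point-dipole couplings as a labeled symmetric matrix (cm^-1).

    The diagonal is zero; site energies are supplied separately when the
    Frenkel Hamiltonian is assembled.  When pigments span several monomers
    labels are qualified as ``label:monomer``.
    """
    if len(pigments) < 2:
        raise ValueError("need at least 2 pigments")
    labels = _display_labels(pigments)
    n = len(pigments)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = point_dipole_coupling(pigments[i], pigments[j], config)
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=labels, columns=labels)
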