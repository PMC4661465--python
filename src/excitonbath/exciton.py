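"""Frenkel exciton Hamiltonian assembly, diagonalization and spectra.

The Hamiltonian of an aggregate of N pigments is the N x N symmetric matrix
with site energies (Qy transition energies of each pigment in its protein
environment) on the diagonal and excitonic couplings off the diagonal, both
in cm^-1.  Its eigenstates are the delocalized exciton levels; the squared
eigenvector components give each pigment's contribution to a level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .units import wavenumber_to_ev

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-6


@dataclass(frozen=True)
class ExcitonHamiltonian:
    """Labeled symmetric exciton Hamiltonian in cm^-1."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if mat.shape != (n, n):
            raise ValueError(f"matrix shape {mat.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.all(np.isfinite(mat)):
            raise ValueError("non-finite Hamiltonian entries")
        if np.max(np.abs(mat - mat.T), initial=0.0) > _SYM_TOL:
            raise ValueError("Hamiltonian is not symmetric within 1e-6 cm^-1")
        if np.any(np.diag(mat) <= 0):
            raise ValueError("site energies (diagonal) must be positive")
        object.__setattr__(self, "labels", [str(l) for l in self.labels])
        object.__setattr__(self, "matrix", 0.5 * (mat + mat.T))

    @property
    def n_pigments(self) -> int:
        return len(self.labels)

    @property
    def site_energies(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix), index=self.labels, name="site_energy_cm1")

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class ExcitonResult:
    """Eigen-decomposition of an exciton Hamiltonian.

    Energies are stored ascending; level 0 is the lowest exciton.  Reports
    conventionally list levels in descending energy (level 1 = highest),
    which ``to_table(descending=True)`` provides.
    """

    labels: list[str]
    exciton_energies: np.ndarray  # cm^-1, ascending
    eigenvectors: np.ndarray  # columns = exciton states, orthonormal
    contributions: np.ndarray  # rows = levels (ascending), cols = pigments

    @property
    def exciton_energies_ev(self) -> np.ndarray:
        return wavenumber_to_ev(self.exciton_energies)

    def to_table(self, descending: bool = True) -> pd.DataFrame:
        """Exciton energies (eV) and pigment contributions, one row per level."""
        order = np.arange(len(self.exciton_energies))
        if descending:
            order = order[::-1]
        df = pd.DataFrame(
            self.contributions[order], columns=self.labels,
            index=pd.RangeIndex(1, len(order) + 1, name="level"),
        )
        df.insert(0, "energy_eV", self.exciton_energies_ev[order])
        df.insert(1, "energy_cm1", self.exciton_energies[order])
        return df


def build_hamiltonian(
    site_energies: Mapping[str, float] | pd.Series,
    couplings: pd.DataFrame,
) -> ExcitonHamiltonian:
    """Assemble a Hamiltonian from site energies and a coupling matrix.

    The label sets must be identical; the pigment order follows
    ``site_energies``.
    """
    energies = pd.Series(site_energies, dtype=float)
    energies.index = energies.index.map(str)
    couplings = couplings.copy()
    couplings.index = couplings.index.map(str)
    couplings.columns = couplings.columns.map(str)
    if set(energies.index) != set(couplings.index) or set(couplings.index) != set(
        couplings.columns
    ):
        raise ValueError("site-energy and coupling labels do not match")
    labels = list(energies.index)
    mat = couplings.loc[labels, labels].to_numpy(dtype=float).copy()
    np.fill_diagonal(mat, energies.to_numpy())
    return ExcitonHamiltonian(labels=labels, matrix=mat)


def diagonalize(hamiltonian: ExcitonHamiltonian) -> ExcitonResult:
    """Diagonalize the Hamiltonian into exciton energies and contributions."""
    energies, vectors = np.linalg.eigh(hamiltonian.matrix)
    gaps = np.diff(energies)
    if np.any(gaps < 1e-9 * max(1.0, float(np.max(np.abs(energies))))):
        logger.warning(
            "degenerate exciton levels: contributions reported per returned "
            "eigenvector without subspace rotation"
        )
    return ExcitonResult(
        labels=list(hamiltonian.labels),
        exciton_energies=energies,
        eigenvectors=vectors,
        contributions=(vectors**2).T,
    )


def average_hamiltonian(
    snapshots: Sequence[ExcitonHamiltonian],
) -> ExcitonHamiltonian:
    """Element-wise mean of per-snapshot Hamiltonians (identical labels)."""
    if len(snapshots) == 0:
        raise ValueError("empty snapshot sequence")
    labels = snapshots[0].labels
    for snap in snapshots[1:]:
        if snap.labels != labels:
            raise ValueError("snapshot labels differ")
    mean = np.mean([snap.matrix for snap in snapshots], axis=0)
    return ExcitonHamiltonian(labels=list(labels), matrix=mean)


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Stick spectrum and its Gaussian-broadened envelope."""

    axis: np.ndarray  # cm^-1
    intensity: np.ndarray  # D^2 per cm^-1 (unit-area broadening)
    stick_positions: np.ndarray  # cm^-1
    stick_intensities: np.ndarray  # D^2


def absorption_spectrum(
    result: ExcitonResult,
    pigment_dipoles: np.ndarray,
    grid: np.ndarray,
    width: float = 80.0,
) -> AbsorptionSpectrum:
    """Absorption spectrum from exciton states and pigment transition dipoles.

    The transition dipole of exciton alpha is mu_alpha = sum_i c_{alpha,i}
    mu_i; stick intensities are |mu_alpha|^2, convolved with a unit-area
    Gaussian of FWHM ``width`` (cm^-1).  Unitarity guarantees the total
    stick intensity equals sum_i |mu_i|^2.
    """
    dipoles = np.asarray(pigment_dipoles, dtype=float)
    if dipoles.shape != (len(result.labels), 3):
        raise ValueError(
            f"expected {len(result.labels)} pigment dipoles, got shape {dipoles.shape}"
        )
    if width <= 0:
        raise ValueError("broadening width must be positive")
    grid = np.asarray(grid, dtype=float)
    # columns of eigenvectors are states: mu_alpha = V^T @ dipoles
    exciton_dipoles = result.eigenvectors.T @ dipoles
    sticks = np.einsum("ij,ij->i", exciton_dipoles, exciton_dipoles)
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    intensity = np.zeros_like(grid)
    for pos, amp in zip(result.exciton_energies, sticks):
        intensity += amp * norm * np.exp(-0.5 * ((grid - pos) / sigma) ** 2)
    return AbsorptionSpectrum(
        axis=grid,
        intensity=intensity,
        stick_positions=result.exciton_energies.copy(),
        stick_intensities=sticks,
    )


def average_excitonic_gap(result: ExcitonResult) -> float:
    """Mean adjacent-level gap of the sorted exciton energies (cm^-1)."""
    n = len(result.exciton_energies)
    if n < 2:
        raise ValueError("need at least 2 exciton levels")
    e = np.sort(result.exciton_energies)
    return float((e[-1] - e[0]) / (n - 1))
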