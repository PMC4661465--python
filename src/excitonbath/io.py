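"""Readers and writers for the file formats the pipeline touches.

Formats: PDB coordinate records (pigment geometries, multi-model
trajectories), comma-delimited labeled matrices (Hamiltonians), and tabular
site-energy time series.  All energies are cm^-1, times fs, distances
angstrom; CSV files are comma-delimited UTF-8 with '.' decimals and labels
in the first row/column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .errors import EmptyInputError, FileFormatError
from .geometry import PigmentGeometry

logger = logging.getLogger(__name__)

#: PDB residue names recognized as bacteriochlorophyll by default.
DEFAULT_PIGMENT_RESIDUES = frozenset({"BCL", "BCHL"})

_SITE_ENERGY_COLUMNS = ("time_fs", "pigment", "monomer", "energy_cm1")


@dataclass(frozen=True)
class SiteEnergyTrajectory:
    """Uniformly sampled site-energy time series of one pigment in one monomer."""

    pigment_label: str
    monomer_label: str
    time_step: float  # fs
    energies: np.ndarray  # cm^-1

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if e.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(e)):
            raise ValueError("energies must be finite")
        object.__setattr__(self, "energies", e)

    @property
    def times(self) -> np.ndarray:
        """Sample times in fs, starting at 0."""
        return np.arange(self.energies.size) * self.time_step


def _require_nonempty(path: str | Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    return path


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pigments_from_pdb(
    path: str | Path,
    residue_names: Iterable[str] = DEFAULT_PIGMENT_RESIDUES,
) -> list[PigmentGeometry]:
    """Extract pigment geometries from the first model of a PDB file.

    Each matching residue must contain MG, ND and NB atoms; the transition
    dipole direction is the unit vector from ND to NB and the Mg position is
    the MG coordinate.  Residue number and chain id become the pigment and
    monomer labels.
    """
    path = _require_nonempty(path)
    names = {n.upper() for n in residue_names}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pigments", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise FileFormatError(f"{path}: no models found") from None
    pigments: list[PigmentGeometry] = []
    for chain in model:
        for residue in chain:
            if residue.get_resname().strip().upper() not in names:
                continue
            label = str(residue.get_id()[1])
            atoms = {a.get_name().strip().upper(): a for a in residue}
            missing = [a for a in ("MG", "ND", "NB") if a not in atoms]
            if missing:
                raise FileFormatError(
                    f"residue {residue.get_resname()} {label} (chain {chain.id}) "
                    f"is missing atoms: {', '.join(missing)}"
                )
            nd = atoms["ND"].get_coord().astype(float)
            nb = atoms["NB"].get_coord().astype(float)
            vec = nb - nd
            norm = float(np.linalg.norm(vec))
            if norm < 1e-9:
                raise FileFormatError(
                    f"residue {label} (chain {chain.id}): ND->NB vector has zero length"
                )
            pigments.append(
                PigmentGeometry(
                    label=label,
                    monomer=str(chain.id),
                    mg_position=atoms["MG"].get_coord().astype(float),
                    dipole_direction=vec / norm,
                )
            )
    if not pigments:
        raise FileFormatError(f"{path}: no residues named {sorted(names)} found")
    return pigments


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resseq: int, xyz: np.ndarray,
    element: str,
) -> str:
    # fixed columns: name 13-16, altLoc 17, resName 18-20, chain 22, resSeq 23-26
    return (
        f"HETATM{serial:5d} {name:<4s} {resname:>3s} {chain:1s}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pigments_to_pdb(
    pigments: Sequence[PigmentGeometry],
    path: str | Path,
    resname: str = "BCL",
) -> None:
    """Write pigments as minimal PDB HETATM records (MG, ND, NB per residue).

    ND and NB are placed 1 A either side of Mg along the dipole direction so
    that ``read_pigments_from_pdb`` recovers position and direction.
    """
    lines = []
    serial = 1
    for i, p in enumerate(pigments, start=1):
        resseq = int(p.label) if p.label.isdigit() else i
        chain = (p.monomer or "A")[0]
        nd = p.mg_position - p.dipole_direction
        nb = p.mg_position + p.dipole_direction
        for name, xyz, element in (
            ("MG", p.mg_position, "MG"),
            ("ND", nd, "N"),
            ("NB", nb, "N"),
        ):
            lines.append(
                _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element)
            )
            serial += 1
    lines.append("END\n")
    Path(path).write_text("".join(lines), encoding="utf-8")


def read_coordinate_frames(path: str | Path) -> list[dict[str, np.ndarray]]:
    """Read a (possibly multi-model) PDB file as one coordinate set per model.

    Atom labels are ``chain/resseq/name`` and every model must contain the
    same atom set.
    """
    path = _require_nonempty(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames: list[dict[str, np.ndarray]] = []
    for model in structure:
        frame: dict[str, np.ndarray] = {}
        for chain in model:
            for residue in chain:
                resseq = residue.get_id()[1]
                for atom in residue:
                    key = f"{chain.id}/{resseq}/{atom.get_name().strip()}"
                    frame[key] = atom.get_coord().astype(float)
        frames.append(frame)
    if not frames:
        raise FileFormatError(f"{path}: no models found")
    keys = set(frames[0])
    for i, frame in enumerate(frames[1:], start=2):
        if set(frame) != keys:
            raise FileFormatError(f"{path}: model {i} has a different atom set")
    return frames


# ---------------------------------------------------------------------------
# Site-energy tables
# ---------------------------------------------------------------------------

def read_site_energy_table(path: str | Path) -> list[SiteEnergyTrajectory]:
    """Read a site-energy table into one trajectory per (pigment, monomer).

    Expected columns: ``time_fs``, ``pigment``, ``monomer``, ``energy_cm1``.
    The time grid must be uniform per trajectory (relative jitter < 1e-6).
    """
    path = _require_nonempty(path)
    df = pd.read_csv(path, dtype={"pigment": str, "monomer": str})
    missing = [c for c in _SITE_ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    trajectories = []
    for (pigment, monomer), group in df.groupby(["pigment", "monomer"], sort=True):
        group = group.sort_values("time_fs")
        times = group["time_fs"].to_numpy(dtype=float)
        if times.size < 2:
            raise FileFormatError(
                f"{path}: trajectory ({pigment}, {monomer}) has fewer than 2 samples"
            )
        steps = np.diff(times)
        dt = float(np.mean(steps))
        if dt <= 0 or np.max(np.abs(steps - dt)) > 1e-6 * max(dt, 1.0):
            raise FileFormatError(
                f"{path}: non-uniform time grid for trajectory ({pigment}, {monomer})"
            )
        trajectories.append(
            SiteEnergyTrajectory(
                pigment_label=str(pigment),
                monomer_label=str(monomer),
                time_step=dt,
                energies=group["energy_cm1"].to_numpy(dtype=float),
            )
        )
    return trajectories


def write_site_energy_table(
    trajectories: Sequence[SiteEnergyTrajectory], path: str | Path
) -> None:
    """Write trajectories in the tabular format ``read_site_energy_table`` reads."""
    parts = []
    for traj in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "time_fs": traj.times,
                    "pigment": traj.pigment_label,
                    "monomer": traj.monomer_label,
                    "energy_cm1": traj.energies,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Hamiltonian matrices
# ---------------------------------------------------------------------------

def read_hamiltonian_csv(path: str | Path) -> "ExcitonHamiltonian":
    """Read a labeled square matrix CSV as an exciton Hamiltonian (cm^-1).

    Row and column labels must match.  The matrix is symmetrized by
    averaging; an asymmetry above 1e-3 cm^-1 is logged as a warning.
    """
    from .exciton import ExcitonHamiltonian  # local import avoids a cycle

    path = _require_nonempty(path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.shape[0] != df.shape[1]:
        raise FileFormatError(f"{path}: matrix is not square {df.shape}")
    if list(df.index) != list(df.columns):
        raise FileFormatError(f"{path}: row and column labels differ")
    mat = df.to_numpy(dtype=float)
    asym = float(np.max(np.abs(mat - mat.T))) if mat.size else 0.0
    if asym > 1e-3:
        logger.warning("%s: symmetrizing matrix with max asymmetry %.3g cm^-1", path, asym)
        warnings.warn(f"{path}: max asymmetry {asym:.3g} cm^-1; symmetrized by averaging")
    mat = 0.5 * (mat + mat.T)
    return ExcitonHamiltonian(labels=list(df.index), matrix=mat)


def write_hamiltonian_csv(hamiltonian: "ExcitonHamiltonian", path: str | Path) -> None:
    """Write a Hamiltonian as a labeled CSV matrix readable by the paired reader."""
    hamiltonian.as_dataframe().to_csv(path, float_format="%.12g")


def write_matrix_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write any labeled square matrix (e.g. a coupling matrix) as CSV."""
    matrix.to_csv(path, float_format="%.12g")
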