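"""Trajectory structural statistics: RMSD, distance series, histogram FWHM.

Frames are coordinate sets mapping atom labels to 3-vectors in angstrom.
RMSD uses the closed-form optimal rigid-body superposition (Kabsch with the
proper-rotation determinant correction, via scipy's ``align_vectors``).
Mg-N distance distributions in stable pigment-binding sites are
Gaussian-like; their width is reported as the FWHM of a fitted Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.transform import Rotation

CoordinateSet = Mapping[str, np.ndarray]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548 sigma


@dataclass(frozen=True)
class CoordinateTrajectory:
    """Sequence of coordinate frames sharing one atom label set."""

    frame_times: np.ndarray
    frames: list[dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        times = np.asarray(self.frame_times, dtype=float)
        if times.size != len(self.frames):
            raise ValueError("frame_times and frames lengths differ")
        if self.frames:
            keys = set(self.frames[0])
            for i, frame in enumerate(self.frames):
                if set(frame) != keys:
                    raise ValueError(f"frame {i} has a different atom label set")
        object.__setattr__(self, "frame_times", times)

    @property
    def atom_labels(self) -> set[str]:
        return set(self.frames[0]) if self.frames else set()


def _stack(coords: CoordinateSet, labels: Sequence[str]) -> np.ndarray:
    missing = [l for l in labels if l not in coords]
    if missing:
        raise KeyError(f"missing atom labels: {missing[:5]}")
    return np.array([coords[l] for l in labels], dtype=float)


def superpose_rmsd(
    reference: CoordinateSet,
    frame: CoordinateSet,
    selection: Iterable[str] | None = None,
    fit: bool = True,
) -> float:
    """RMSD between a frame and a reference over a label selection (angstrom).

    With ``fit=True`` the frame is first superposed onto the reference by
    the optimal rigid rotation + translation over the selection; with
    ``fit=False`` the raw coordinate RMSD is returned.
    """
    labels = sorted(selection) if selection is not None else sorted(reference)
    if not labels:
        raise ValueError("empty selection")
    ref = _stack(reference, labels)
    frm = _stack(frame, labels)
    if fit:
        if len(labels) < 3:
            raise ValueError("superposition needs at least 3 selected atoms")
        ref_c = ref - ref.mean(axis=0)
        frm_c = frm - frm.mean(axis=0)
        rotation, _ = Rotation.align_vectors(ref_c, frm_c)
        frm = rotation.apply(frm_c)
        ref = ref_c
    return float(np.sqrt(np.mean(np.sum((frm - ref) ** 2, axis=1))))


def rmsd_series(
    traj: CoordinateTrajectory,
    reference: CoordinateSet,
    selection: Iterable[str] | None = None,
    fit: bool = True,
) -> pd.Series:
    """Per-frame RMSD against a reference structure."""
    values = [superpose_rmsd(reference, frame, selection, fit) for frame in traj.frames]
    return pd.Series(values, index=traj.frame_times, name="rmsd_A")


def distance_series(
    traj: CoordinateTrajectory,
    atom_pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-frame Euclidean distances for each atom-label pair (angstrom)."""
    labels = traj.atom_labels
    for a, b in atom_pairs:
        for name in (a, b):
            if name not in labels:
                raise KeyError(f"atom label {name!r} not present in trajectory")
    data = {}
    for a, b in atom_pairs:
        xa = np.array([f[a] for f in traj.frames])
        xb = np.array([f[b] for f in traj.frames])
        data[f"{a}-{b}"] = np.linalg.norm(xa - xb, axis=1)
    return pd.DataFrame(data, index=traj.frame_times)


def _gaussian(x: np.ndarray, amp: float, mean: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


@dataclass(frozen=True)
class FwhmResult:
    peak_position: float  # angstrom
    fwhm: float  # angstrom
    fitted: bool  # False when the empirical half-max fallback was used


def histogram_fwhm(
    values: Sequence[float], bin_width: float = 0.01
) -> FwhmResult:
    """Peak position and FWHM of a Gaussian-like distribution.

    A 3-parameter Gaussian is least-squares fitted to the histogram of
    ``values`` (FWHM = 2.3548 sigma).  On non-convergence the empirical
    half-maximum crossing width is returned with ``fitted=False``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width:
        raise ValueError("degenerate sample: no spread beyond one bin")
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(values.mean()), float(values.std()))
    try:
        popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=5000)
        amp, mean, sigma = popt
        if amp <= 0 or not np.isfinite(sigma):
            raise RuntimeError("unphysical Gaussian fit")
        return FwhmResult(
            peak_position=float(mean),
            fwhm=float(abs(sigma) * GAUSSIAN_FWHM_FACTOR),
            fitted=True,
        )
    except RuntimeError:
        warnings.warn("Gaussian fit failed; using empirical half-max width")
        half = counts.max() / 2.0
        above = np.nonzero(counts >= half)[0]
        width = centers[above[-1]] - centers[above[0]] + bin_width
        return FwhmResult(
            peak_position=float(centers[np.argmax(counts)]),
            fwhm=float(width),
            fitted=False,
        )


#: Named atom-selection predicates for PDB naming conventions.
BACKBONE_HEAVY_ATOMS = frozenset({"N", "CA", "C", "O"})
#: Phytyl-tail atom names (numbered chain carbons) excluded from pigment RMSD.
PHYTYL_ATOMS = frozenset({f"C{i}" for i in range(1, 21)} | {"O1", "O2"})


def select_backbone(labels: Iterable[str]) -> set[str]:
    """Backbone heavy atoms from 'chain/resseq/name' labels."""
    return {l for l in labels if l.rsplit("/", 1)[-1] in BACKBONE_HEAVY_ATOMS}


def select_without_phytyl(labels: Iterable[str]) -> set[str]:
    """Drop phytyl-tail atoms (flexible chain excluded from pigment RMSD)."""
    return {l for l in labels if l.rsplit("/", 1)[-1] not in PHYTYL_ATOMS}
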