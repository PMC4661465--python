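"""Synthetic generators with the statistical structure the analysis assumes.

The upstream stages of a site-energy pipeline (MD sampling and excited-state
calculations) are replaced here by:

* an Ornstein-Uhlenbeck (OU) process for site-energy fluctuations — the
  stationary Gaussian process whose exponential correlation
  C(t) = 2 lambda k_B T exp(-t/tau) is exactly the classical limit of a
  Drude bath;
* toy ring geometries for coupling and exciton tests;
* Gaussian-jittered coordinate trajectories for structural statistics.

All generators take an explicit integer seed and are bit-reproducible for a
fixed (seed, config) on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .geometry import PigmentGeometry
from .io import SiteEnergyTrajectory
from .structure import CoordinateTrajectory
from .units import thermal_energy


@dataclass(frozen=True)
class OUConfig:
    """Configuration of the OU site-energy generator.

    Defaults emulate a 20-ps, 0.5-fs-step sampling of one pigment in each
    of the three monomers of a trimeric complex at 300 K, with a
    reorganization energy of 100 cm^-1 and a 15-fs bath correlation time —
    the scale on which the slow bath component of FMO-type complexes lives.
    """

    lambda_reorg: float = 100.0  # cm^-1
    tau_corr: float = 15.0  # fs
    temperature: float = 300.0  # K
    mean_energy: float = 11450.0  # cm^-1, typical BChl a Qy site energy
    time_step: float = 0.5  # fs
    n_steps: int = 40_000
    n_monomers: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lambda_reorg, 0.0) < 0 or self.tau_corr <= 0:
            raise ValueError("lambda_reorg must be >= 0 and tau_corr > 0")
        if self.temperature <= 0 or self.time_step <= 0:
            raise ValueError("temperature and time_step must be positive")
        if self.n_steps < 2 or self.n_monomers < 1:
            raise ValueError("need n_steps >= 2 and n_monomers >= 1")

    @property
    def stationary_variance(self) -> float:
        """sigma^2 = 2 lambda k_B T in cm^-2."""
        return 2.0 * self.lambda_reorg * thermal_energy(self.temperature)


def generate_ou_site_energies(
    config: OUConfig, pigment_label: str = "1"
) -> list[SiteEnergyTrajectory]:
    """Stationary OU site-energy series, one independent series per monomer.

    Exact discretization: X_{n+1} = X_n e^{-dt/tau} + sqrt(sigma^2 (1 -
    e^{-2 dt/tau})) xi_n with X_0 drawn from the stationary distribution, so
    every marginal is exactly N(0, sigma^2) and the autocorrelation is
    exactly exponential regardless of the step size.
    """
    rng = np.random.default_rng(config.seed)
    sigma2 = config.stationary_variance
    decay = np.exp(-config.time_step / config.tau_corr)
    innovation = np.sqrt(sigma2 * (1.0 - decay**2))
    trajectories = []
    for m in range(config.n_monomers):
        x = np.empty(config.n_steps)
        x[0] = rng.normal(0.0, np.sqrt(sigma2)) if sigma2 > 0 else 0.0
        noise = rng.standard_normal(config.n_steps - 1)
        # recursion x[i] = decay x[i-1] + innovation xi[i-1] as an IIR filter
        x[1:], _ = lfilter(
            [innovation], [1.0, -decay], noise, zi=np.array([decay * x[0]])
        )
        trajectories.append(
            SiteEnergyTrajectory(
                pigment_label=pigment_label,
                monomer_label=chr(ord("A") + m),
                time_step=config.time_step,
                energies=config.mean_energy + x,
            )
        )
    return trajectories


DIPOLE_SCHEMES = ("tangential", "parallel", "random")


def generate_pigment_ring(
    n: int,
    radius: float,
    dipole_scheme: str = "tangential",
    seed: int = 0,
    monomer: str = "A",
) -> list[PigmentGeometry]:
    """Pigments equally spaced on a circle in the xy-plane.

    Dipole schemes: ``tangential`` (in-plane, along the ring), ``parallel``
    (all along z) or ``random`` (seeded uniform unit vectors).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if dipole_scheme not in DIPOLE_SCHEMES:
        raise ValueError(
            f"unknown dipole scheme {dipole_scheme!r}; choose from {DIPOLE_SCHEMES}"
        )
    rng = np.random.default_rng(seed)
    pigments = []
    for k in range(n):
        angle = 2.0 * np.pi * k / n
        position = radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        if dipole_scheme == "tangential":
            direction = np.array([-np.sin(angle), np.cos(angle), 0.0])
        elif dipole_scheme == "parallel":
            direction = np.array([0.0, 0.0, 1.0])
        else:
            v = rng.standard_normal(3)
            direction = v / np.linalg.norm(v)
        pigments.append(
            PigmentGeometry(
                label=str(k + 1),
                monomer=monomer,
                mg_position=position,
                dipole_direction=direction,
            )
        )
    return pigments


def generate_jittered_trajectory(
    base: Mapping[str, np.ndarray],
    sigma: float,
    n_frames: int,
    rigid_motion: bool = False,
    seed: int = 0,
) -> CoordinateTrajectory:
    """Coordinate frames = base + isotropic Gaussian jitter (+ rigid motion).

    Emulates a structurally stable trajectory: per-atom displacements are
    iid N(0, sigma^2) per axis; when ``rigid_motion`` is set each frame is
    additionally rotated by a uniform random rotation and translated by a
    random offset, which optimal superposition must remove.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    labels = sorted(base)
    coords = np.array([base[l] for l in labels], dtype=float)
    frames = []
    for _ in range(n_frames):
        pts = coords + sigma * rng.standard_normal(coords.shape)
        if rigid_motion:
            rot = Rotation.random(rng=rng)
            pts = rot.apply(pts) + rng.normal(0.0, 5.0, size=3)
        frames.append({l: pts[i].copy() for i, l in enumerate(labels)})
    return CoordinateTrajectory(frame_times=np.arange(n_frames, dtype=float), frames=frames)
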