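"""Site-energy fluctuation statistics and Drude bath characterization.

The fluctuations of a pigment's site energy along a classical trajectory
define the bath correlation function

    C(t_j) = (1/N_l) sum_l (1/N) sum_i dE_l(t_i + t_j) dE_l(t_i),

averaged over symmetry-equivalent monomers l (biased estimator: the inner
sum is divided by the full series length N).  C(t) is approximated by a
biexponential with a white-noise residue: a slow component exp(-t/tau_slow)
carrying the reorganization energy through the classical
fluctuation-dissipation amplitude a = 2 lambda k_B T, and a fast,
temperature-controlled component near 4 fs at 300 K.  The slow timescale
maps onto the Drude spectral density J(w) = 2 lambda gamma w / (w^2 +
gamma^2) with cutoff gamma = 1/(2 pi c tau_slow).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from statsmodels.tsa.stattools import acovf

from .errors import FitError
from .io import SiteEnergyTrajectory
from .units import (
    CONSTANTS,
    matsubara_timescale,
    thermal_energy,
    timescale_to_wavenumber,
)


@dataclass(frozen=True)
class CorrelationFunction:
    """Real bath correlation function on a uniform lag grid from 0 (cm^-2 vs fs)."""

    lags: np.ndarray  # fs
    values: np.ndarray  # cm^-2

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.ndim != 1 or lags.shape != values.shape:
            raise ValueError("lags and values must be matching 1-d arrays")
        if lags[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        steps = np.diff(lags)
        if lags.size > 1 and (
            np.any(steps <= 0) or np.max(np.abs(steps - steps[0])) > 1e-9 * steps[0]
        ):
            raise ValueError("lag grid must be strictly increasing and uniform")
        if values[0] < 0:
            raise ValueError("C(0) must be non-negative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)

    @property
    def time_step(self) -> float:
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0


@dataclass(frozen=True)
class BathParameters:
    """Biexponential bath-fit parameters for one pigment."""

    lambda_reorg: float  # cm^-1
    tau_slow: float  # fs (= 1/gamma)
    tau_fast: float  # fs (= 1/gamma')
    amplitude_slow: float  # cm^-2
    amplitude_fast: float  # cm^-2
    temperature: float  # K
    pigment_label: str = ""

    def __post_init__(self) -> None:
        if self.lambda_reorg < 0:
            raise ValueError("lambda_reorg must be non-negative")
        if not (self.tau_slow > self.tau_fast > 0):
            raise ValueError("need tau_slow > tau_fast > 0")

    @property
    def gamma_wavenumber(self) -> float:
        """Drude cutoff gamma = 1/(2 pi c tau_slow) in cm^-1."""
        return timescale_to_wavenumber(self.tau_slow)


@dataclass(frozen=True)
class SpectralDensity:
    """Spectral density J(omega) on a non-negative frequency grid (cm^-1)."""

    omega: np.ndarray  # cm^-1
    j_values: np.ndarray  # cm^-1

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        j = np.asarray(self.j_values, dtype=float)
        if omega.shape != j.shape:
            raise ValueError("omega and j_values shapes differ")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "j_values", j)


# ---------------------------------------------------------------------------
# Correlation function estimation
# ---------------------------------------------------------------------------

def fluctuations(traj: SiteEnergyTrajectory) -> np.ndarray:
    """Centered site-energy fluctuations dE(t_i) = E(t_i) - <E> in cm^-1."""
    e = traj.energies
    return e - e.mean()


def default_max_lag(n_samples: int, time_step: float) -> float:
    """Default correlation-window length: min(2000 fs, half the series)."""
    return min(2000.0, (n_samples - 1) * time_step / 2.0)


def autocorrelation(
    fluct_series: Sequence[np.ndarray],
    time_step: float,
    max_lag: float | None = None,
) -> CorrelationFunction:
    """Monomer-averaged biased autocorrelation of centered series.

    Each series contributes ``acovf`` with the biased normalization (divide
    by the full length N); the results are averaged over monomers.  C(0)
    therefore equals the pooled biased variance.
    """
    series = [np.asarray(s, dtype=float) for s in fluct_series]
    if not series:
        raise ValueError("need at least one series")
    n = series[0].size
    if any(s.size != n for s in series):
        raise ValueError("all series must have the same length")
    if time_step <= 0:
        raise ValueError("time_step must be positive")
    if max_lag is None:
        max_lag = default_max_lag(n, time_step)
    n_lags = int(round(max_lag / time_step))
    if n_lags > n - 1:
        raise ValueError("max_lag exceeds the series span")
    acfs = [
        acovf(s, adjusted=False, demean=False, fft=True, nlag=n_lags) for s in series
    ]
    values = np.mean(acfs, axis=0)
    lags = np.arange(n_lags + 1) * time_step
    return CorrelationFunction(lags=lags, values=values)


# ---------------------------------------------------------------------------
# Biexponential WNR fit
# ---------------------------------------------------------------------------

def _biexp(t: np.ndarray, a: float, tau_s: float, b: float, tau_f: float) -> np.ndarray:
    return a * np.exp(-t / tau_s) + b * np.exp(-t / tau_f)


def _tail_init(lags: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Log-linear fit of the positive tail -> (amplitude, timescale) guess."""
    mask = values > 0
    # use the second half of the window where the slow component dominates
    half = lags.size // 2
    mask[:half] = False
    if mask.sum() >= 3:
        coef = np.polyfit(lags[mask], np.log(values[mask]), 1)
        if coef[0] < 0:
            return float(np.exp(coef[1])), float(-1.0 / coef[0])
    # fallback: 1/e crossing of C
    c0 = values[0]
    below = np.nonzero(values < c0 / math.e)[0]
    tau = float(lags[below[0]]) if below.size else float(lags[-1] / 2)
    return float(c0), max(tau, lags[1] if lags.size > 1 else 1.0)


def fit_biexponential_wnr(
    corr: CorrelationFunction,
    temperature: float,
    mode: str = "pade",
    pigment_label: str = "",
    max_restarts: int = 8,
    seed: int | None = None,
) -> BathParameters:
    """Fit C(t) ~ a exp(-t/tau_slow) + b exp(-t/tau_fast).

    ``mode='pade'`` (default) pins tau_fast at the temperature-fixed
    Matsubara timescale hbar/(2 pi k_B T) (~4 fs at 300 K) and fits the
    remaining three parameters; this is the white-noise-residue prescription
    and is well-posed even when the data is close to a single exponential.
    ``mode='unconstrained'`` frees all four parameters (bounded nonlinear
    least squares, multi-start initialization from a log-linear tail fit
    plus, when ``seed`` is given, randomized restarts); use it when both
    timescales are genuinely resolvable, as the two components of a
    near-exponential C(t) are otherwise degenerate.

    The reorganization energy uses the classical fluctuation-dissipation
    amplitude mapping lambda = a_slow / (2 k_B T).
    """
    if mode not in ("unconstrained", "pade"):
        raise ValueError(f"unknown fit mode {mode!r}")
    lags = corr.lags
    values = corr.values
    if lags.size < 20:
        raise ValueError("correlation function needs at least 20 lags")
    c0 = float(values[0])
    if c0 <= 0:
        raise ValueError("C(0) must be positive")
    dt = corr.time_step

    # Adaptive fit window: beyond ~10 integral correlation times the
    # estimator carries only statistical noise, which would otherwise be
    # absorbed by a spurious ultra-slow component.  Weighting inside the
    # window is uniform and lag 0 is included.
    tau_int = max(float(np.trapezoid(values, lags)) / c0, 2.0 * dt)
    window = min(float(lags[-1]), 10.0 * tau_int)
    keep = lags <= window
    if keep.sum() < 20:
        keep = np.zeros_like(keep)
        keep[:20] = True
    lags = lags[keep]
    values = values[keep]
    kbt = thermal_energy(temperature)
    tau_fixed = matsubara_timescale(temperature)

    a0, tau_s0 = _tail_init(lags, values)
    a0 = min(max(a0, 1e-3 * c0), c0)
    tau_s0 = float(np.clip(tau_s0, 2 * dt, lags[-1]))
    starts: list[np.ndarray] = []
    for tau_f0 in (tau_fixed, dt, tau_s0 / 4):
        b0 = max(c0 - a0, 1e-3 * c0)
        starts.append(np.array([a0, tau_s0, b0, tau_f0]))
    starts.append(np.array([0.7 * c0, tau_s0, 0.3 * c0, tau_fixed]))
    if seed is not None:
        rng = np.random.default_rng(seed)
        for _ in range(max_restarts):
            starts.append(
                np.array(
                    [
                        c0 * rng.uniform(0.2, 1.0),
                        tau_s0 * rng.uniform(0.5, 2.0),
                        c0 * rng.uniform(0.0, 0.5),
                        rng.uniform(dt, 4 * tau_fixed),
                    ]
                )
            )

    tiny = 1e-12
    if mode == "pade":
        def resid(p: np.ndarray) -> np.ndarray:
            return _biexp(lags, p[0], p[1], p[2], tau_fixed) - values

        bounds = ([0.0, tiny, 0.0], [np.inf, np.inf, np.inf])
        squeeze = lambda p: (p[0], p[1], p[2], tau_fixed)  # noqa: E731
        start_slices = [s[:3] for s in starts]
    else:
        def resid(p: np.ndarray) -> np.ndarray:
            return _biexp(lags, *p) - values

        bounds = ([0.0, tiny, 0.0, tiny], [np.inf, np.inf, np.inf, np.inf])
        squeeze = lambda p: tuple(p)  # noqa: E731
        start_slices = list(starts)

    best = None
    best_cost = np.inf
    for p0 in start_slices:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            sol = least_squares(resid, p0, bounds=bounds, max_nfev=2000)
        except Exception:
            continue
        if sol.cost < best_cost and np.all(np.isfinite(sol.x)):
            best, best_cost = sol, sol.cost

    if best is None or not np.isfinite(best_cost):
        raise FitError(
            f"biexponential fit did not converge after {len(start_slices)} starts",
            best_residual=None if best is None else float(best_cost),
        )

    a, tau_s, b, tau_f = squeeze(best.x)
    # identify the slow component regardless of which slot converged to it
    if tau_f > tau_s:
        a, b = b, a
        tau_s, tau_f = tau_f, tau_s
    if tau_f < dt:
        warnings.warn(
            f"fast timescale collapsed below the time step; reporting the "
            f"bound {dt} fs"
        )
        tau_f = dt
    if tau_s <= tau_f:
        tau_s = tau_f * (1 + 1e-9)
    return BathParameters(
        lambda_reorg=a / (2.0 * kbt),
        tau_slow=float(tau_s),
        tau_fast=float(tau_f),
        amplitude_slow=float(a),
        amplitude_fast=float(b),
        temperature=temperature,
        pigment_label=pigment_label,
    )


def fit_trajectory(
    trajectories: Sequence[SiteEnergyTrajectory],
    temperature: float,
    max_lag: float | None = None,
    mode: str = "pade",
    seed: int | None = None,
) -> BathParameters:
    """Convenience: fluctuations -> monomer-averaged C(t) -> WNR fit.

    All trajectories must belong to the same pigment (one per monomer).
    """
    labels = {t.pigment_label for t in trajectories}
    if len(labels) != 1:
        raise ValueError("trajectories must share one pigment label")
    steps = {t.time_step for t in trajectories}
    if len(steps) != 1:
        raise ValueError("trajectories must share one time step")
    corr = autocorrelation(
        [fluctuations(t) for t in trajectories], trajectories[0].time_step, max_lag
    )
    return fit_biexponential_wnr(
        corr, temperature, mode=mode, pigment_label=labels.pop(), seed=seed
    )


# ---------------------------------------------------------------------------
# Spectral densities and aggregates
# ---------------------------------------------------------------------------

def drude_spectral_density(
    lambda_reorg: float, gamma: float, omega: np.ndarray
) -> SpectralDensity:
    """Drude(-Lorentz) spectral density J(w) = 2 lambda gamma w / (w^2 + gamma^2).

    J peaks at w = gamma with J(gamma) = lambda; all quantities in cm^-1.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if lambda_reorg < 0:
        raise ValueError("lambda_reorg must be non-negative")
    omega = np.asarray(omega, dtype=float)
    j = 2.0 * lambda_reorg * gamma * omega / (omega**2 + gamma**2)
    return SpectralDensity(omega=omega, j_values=j)


def numerical_spectral_density(
    corr: CorrelationFunction, temperature: float, omega: np.ndarray
) -> SpectralDensity:
    """Spectral density from C(t) via the classical fluctuation-dissipation map.

    J(w) = beta w int_0^inf C(t) cos(wt) dt, evaluated by trapezoidal
    quadrature with t converted to cm through ct (beta = 1/k_B T in cm).
    Warns when C has not decayed below 5% of C(0) at the last lag.
    """
    values = corr.values
    if values[0] > 0 and abs(values[-1]) > 0.05 * values[0]:
        warnings.warn(
            "correlation function has not decayed below 5% of C(0); "
            "the transform window may truncate the integral"
        )
    omega = np.asarray(omega, dtype=float)
    beta = 1.0 / thermal_energy(temperature)
    two_pi_c = 2.0 * np.pi * CONSTANTS.speed_of_light
    # phase(w, t) = 2 pi c w t with w in cm^-1, t in fs
    phase = two_pi_c * np.outer(omega, corr.lags)
    integral = np.trapezoid(values[None, :] * np.cos(phase), corr.lags, axis=1)
    j = beta * omega * two_pi_c * integral
    return SpectralDensity(omega=omega, j_values=j)


@dataclass(frozen=True)
class BathSummary:
    """Aggregates of per-pigment bath parameters."""

    mean_lambda: float  # cm^-1
    mean_tau_slow: float  # fs
    cutoff_wavenumber: float  # cm^-1, from the mean slow timescale
    mean_tau_fast: float  # fs
    n_pigments: int


def aggregate_bath(params: Sequence[BathParameters]) -> BathSummary:
    """Average per-pigment bath parameters.

    The cutoff frequency converts the mean slow timescale (not the mean
    rate): gamma_bar = 1/(2 pi c mean(tau_slow)).
    """
    if not params:
        raise ValueError("empty parameter sequence")
    mean_tau_slow = float(np.mean([p.tau_slow for p in params]))
    return BathSummary(
        mean_lambda=float(np.mean([p.lambda_reorg for p in params])),
        mean_tau_slow=mean_tau_slow,
        cutoff_wavenumber=timescale_to_wavenumber(mean_tau_slow),
        mean_tau_fast=float(np.mean([p.tau_fast for p in params])),
        n_pigments=len(params),
    )


def transport_parameter(
    lambda_reorg: float,
    gamma: float,
    gap_g: float,
    temperature: float,
    formula: Callable[[float, float, float, float], float] | None = None,
) -> float:
    """Dimensionless energy-scales-convergence parameter.

    The default combination is Lambda = lambda * gamma / (g * k_B T), where
    g is the average excitonic gap; a value near 1 marks the regime where
    reorganization, bath cutoff, excitonic splitting and thermal energy are
    commensurate and transport is near-optimal.  A custom ``formula``
    receives (lambda, gamma, g, k_B T), all in cm^-1.
    """
    if gamma <= 0 or gap_g <= 0 or temperature <= 0:
        raise ValueError("gamma, gap and temperature must be positive")
    if lambda_reorg < 0:
        raise ValueError("lambda_reorg must be non-negative")
    kbt = thermal_energy(temperature)
    if formula is not None:
        return float(formula(lambda_reorg, gamma, gap_g, kbt))
    return lambda_reorg * gamma / (gap_g * kbt)
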