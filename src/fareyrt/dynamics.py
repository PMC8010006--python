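"""Discrete HKB circle map: iteration, rotation numbers, bifurcation surfaces.

The map models the relative phase of two coupled effectors (e.g. the two
index fingers in a two-alternative forced-choice task) driven at frequency
ratio ``omega``:

    phi[n+1] = phi[n] + omega - (K / 2*pi) * (1 + A*cos(2*pi*phi[n])) * sin(2*pi*phi[n])

optionally reduced mod 1.  ``K`` is the coupling strength and ``A`` the
relative prominence of the antiphase attractor; the coupling term is the
gradient of the HKB potential -a*cos(theta) - b*cos(2*theta) rewritten as
sin(theta)*(a + 2b*cos(theta)) with theta = 2*pi*phi.

Asymptotic summaries:

* the rotation number rho (average phase advance per iteration of the
  unwrapped map), whose plateaus over an ``omega`` grid form the Devil's
  staircase / Arnold-tongue structure, and
* the retained tail of wrapped trajectories over an ``omega`` grid (the
  bifurcation surface), summarised per ``omega`` by a circular mean.

Note on parameter regime: for K*(1+A) > 1 the map is non-invertible, Arnold
tongues may overlap, and the measured rotation number can depend on the
random seed phase inside attractor-competition bands.  The default analysis
parameters (K=0.95, A=0.85) are in this regime; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircleMapParams",
    "PhaseTrajectory",
    "StaircasePoint",
    "BifurcationSample",
    "Staircase",
    "BifurcationSurface",
    "step",
    "iterate",
    "rotation_number",
    "devils_staircase",
    "bifurcation_surface",
    "circular_mean",
    "UndefinedMeanError",
]

#: Analysis defaults: strong coupling with a prominent antiphase attractor,
#: chosen so the staircase is connected with wide tongues.
DEFAULT_K = 0.95
DEFAULT_A = 0.85
DEFAULT_N_ITER = 10_000
DEFAULT_N_AVG = 2_500
DEFAULT_N_KEEP = 100
DEFAULT_OMEGA_STEP = 0.001

TWO_PI = 2.0 * np.pi


class UndefinedMeanError(ValueError):
    """Circular mean of a phase set with zero resultant vector."""


@dataclass(frozen=True)
class CircleMapParams:
    """The model triple (omega, K, A).

    omega : dimensionless driving ratio, >= 0 (unit interval for R-leading
        use; may exceed 1 for L-leading use).
    coupling : K >= 0.
    antiphase_weight : A in [0, 1].
    """

    omega: float
    coupling: float = DEFAULT_K
    antiphase_weight: float = DEFAULT_A

    def __post_init__(self) -> None:
        if not np.isfinite(self.omega) or self.omega < 0:
            raise ValueError(f"omega must be finite and >= 0, got {self.omega}")
        if not np.isfinite(self.coupling) or self.coupling < 0:
            raise ValueError(f"coupling must be finite and >= 0, got {self.coupling}")
        if not 0.0 <= self.antiphase_weight <= 1.0:
            raise ValueError(
                f"antiphase_weight must lie in [0, 1], got {self.antiphase_weight}"
            )


@dataclass(frozen=True)
class PhaseTrajectory:
    """An iterated phase sequence; wrapped values lie in [0, 1)."""

    seed_phase: float
    phases: np.ndarray
    wrapped: bool

    def __len__(self) -> int:
        return len(self.phases)


@dataclass(frozen=True)
class StaircasePoint:
    omega: float
    rho: float
    params: CircleMapParams


@dataclass(frozen=True)
class BifurcationSample:
    omega: float
    retained_phases: np.ndarray
    circular_mean: float


def _coupling_term(phi: np.ndarray | float, k: float, a: float) -> np.ndarray | float:
    theta = TWO_PI * np.asarray(phi, dtype=float)
    return (k / TWO_PI) * (1.0 + a * np.cos(theta)) * np.sin(theta)


def step(phi, params: CircleMapParams, wrap: bool = True):
    """One application of the map.  Accepts scalars or arrays of phases."""
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase must be finite")
    if wrap and (np.any(phi < 0.0) or np.any(phi >= 1.0)):
        raise ValueError("wrapped phase must lie in [0, 1)")
    out = phi + params.omega - _coupling_term(phi, params.coupling, params.antiphase_weight)
    if wrap:
        out = np.mod(out, 1.0)
        # np.mod can round a tiny negative argument up to exactly 1.0
        out = np.where(out == 1.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def iterate(
    phi0: float, params: CircleMapParams, n: int, wrap: bool = True
) -> PhaseTrajectory:
    """Iterate the map ``n`` times from ``phi0``; returns n+1 phases."""
    if n < 0:
        raise ValueError(f"iteration count must be >= 0, got {n}")
    phases = np.empty(n + 1, dtype=float)
    phases[0] = phi0
    phi = phi0
    for i in range(1, n + 1):
        phi = step(phi, params, wrap=wrap)
        phases[i] = phi
    return PhaseTrajectory(seed_phase=phi0, phases=phases, wrapped=wrap)


def _unwrapped_tail_mean_increment(
    phi0: np.ndarray, omega: np.ndarray, k: float, a: float, n_iter: int, n_avg: int
) -> np.ndarray:
    """Mean per-step advance over the final n_avg of n_iter unwrapped steps.

    Vectorised over a batch of (phi0, omega) pairs.  Equal to
    (phi[n_iter] - phi[n_iter - n_avg]) / n_avg; the leading n_iter - n_avg
    steps serve as transient burn-in.
    """
    phi = np.array(phi0, dtype=float, copy=True)
    snapshot = None
    for i in range(n_iter):
        if i == n_iter - n_avg:
            snapshot = phi.copy()
        phi = phi + omega - _coupling_term(phi, k, a)
    if snapshot is None:  # n_avg == n_iter
        snapshot = np.asarray(phi0, dtype=float)
    return (phi - snapshot) / n_avg


def rotation_number(
    params: CircleMapParams,
    n_iter: int = DEFAULT_N_ITER,
    n_avg: int = DEFAULT_N_AVG,
    rng: np.random.Generator | None = None,
    phi0: float | None = None,
) -> float:
    """Estimate rho = average rotations per iteration for one parameter triple.

    The seed phase is drawn uniformly from [0, 1) unless ``phi0`` is given;
    the map is iterated unwrapped and the mean per-iteration advance over the
    final ``n_avg`` steps is returned.  For K = 0 this equals omega exactly.
    """
    if n_avg > n_iter:
        raise ValueError(f"n_avg ({n_avg}) must not exceed n_iter ({n_iter})")
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    if phi0 is None:
        rng = np.random.default_rng() if rng is None else rng
        phi0 = float(rng.random())
    out = _unwrapped_tail_mean_increment(
        np.asarray(phi0), np.asarray(params.omega),
        params.coupling, params.antiphase_weight, n_iter, n_avg,
    )
    return float(out)


@dataclass(frozen=True)
class Staircase:
    """Rotation-number estimates over an omega grid (the Devil's staircase)."""

    omegas: np.ndarray
    rhos: np.ndarray
    coupling: float
    antiphase_weight: float

    @property
    def points(self) -> list[StaircasePoint]:
        return [
            StaircasePoint(
                float(o), float(r),
                CircleMapParams(float(o), self.coupling, self.antiphase_weight),
            )
            for o, r in zip(self.omegas, self.rhos)
        ]

    def lookup(self, omega) -> np.ndarray | float:
        """rho at the nearest grid omega (grid step 0.001 by default, so the
        omega discrepancy is at most half a step)."""
        omega = np.asarray(omega, dtype=float)
        idx = np.searchsorted(self.omegas, omega)
        idx = np.clip(idx, 1, len(self.omegas) - 1)
        left = self.omegas[idx - 1]
        right = self.omegas[idx]
        idx = np.where(omega - left <= right - omega, idx - 1, idx)
        out = self.rhos[idx]
        return float(out) if out.ndim == 0 else out


def devils_staircase(
    coupling: float = DEFAULT_K,
    antiphase_weight: float = DEFAULT_A,
    omega_grid: np.ndarray | None = None,
    n_iter: int = DEFAULT_N_ITER,
    n_avg: int = DEFAULT_N_AVG,
    rng: np.random.Generator | None = None,
) -> Staircase:
    """Estimate rho over an omega grid (default 0..1 in steps of 0.001).

    Each grid point gets its own uniform random seed phase, drawn
    sequentially from ``rng`` so a single integer seed reproduces the run.
    """
    if omega_grid is None:
        n = int(round(1.0 / DEFAULT_OMEGA_STEP))
        omega_grid = np.linspace(0.0, 1.0, n + 1)
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.size == 0:
        raise ValueError("omega grid must be non-empty")
    if np.any(np.diff(omega_grid) <= 0):
        raise ValueError("omega grid must be strictly ascending")
    if n_avg > n_iter:
        raise ValueError(f"n_avg ({n_avg}) must not exceed n_iter ({n_iter})")
    rng = np.random.default_rng() if rng is None else rng
    phi0 = rng.random(omega_grid.size)
    rhos = _unwrapped_tail_mean_increment(
        phi0, omega_grid, coupling, antiphase_weight, n_iter, n_avg
    )
    return Staircase(omega_grid, rhos, coupling, antiphase_weight)


@dataclass(frozen=True)
class BifurcationSurface:
    """Final retained wrapped phases for each omega on a grid."""

    omegas: np.ndarray
    phases: np.ndarray  # shape (n_omega, n_keep)
    circular_means: np.ndarray
    coupling: float
    antiphase_weight: float

    @property
    def samples(self) -> list[BifurcationSample]:
        return [
            BifurcationSample(float(o), p, float(m))
            for o, p, m in zip(self.omegas, self.phases, self.circular_means)
        ]


def bifurcation_surface(
    coupling: float = DEFAULT_K,
    antiphase_weight: float = DEFAULT_A,
    n_omega: int = 1000,
    n_iter: int = DEFAULT_N_ITER,
    n_keep: int = DEFAULT_N_KEEP,
    rng: np.random.Generator | None = None,
) -> BifurcationSurface:
    """Wrapped trajectories over ``n_omega`` evenly spaced drives on [0, 1].

    Each drive is seeded with a unit-interval random phase and iterated
    ``n_iter`` times; the final ``n_keep`` wrapped phases are retained and
    summarised by their circular mean.
    """
    if n_keep > n_iter:
        raise ValueError(f"n_keep ({n_keep}) must not exceed n_iter ({n_iter})")
    if n_omega < 1:
        raise ValueError("n_omega must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    omegas = np.linspace(0.0, 1.0, n_omega)
    phi = rng.random(n_omega)
    kept = np.empty((n_omega, n_keep), dtype=float)
    for i in range(n_iter):
        phi = np.mod(phi + omegas - _coupling_term(phi, coupling, antiphase_weight), 1.0)
        phi[phi == 1.0] = 0.0
        if i >= n_iter - n_keep:
            kept[:, i - (n_iter - n_keep)] = phi
    means = np.array([circular_mean(row) for row in kept])
    return BifurcationSurface(omegas, kept, means, coupling, antiphase_weight)


def circular_mean(phases) -> float:
    """Mean of unit-interval phases respecting the adjacency of 0 and 1.

    The phases are placed on the circle at angles 2*pi*phi, the mean
    resultant vector's angle is mapped back to the unit interval, and an
    exact 0 is reported as 1 (the wrap convention used for L-leading
    drives), so the result lies in (0, 1].
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular mean of empty input")
    theta = TWO_PI * phases
    x = np.cos(theta).mean()
    y = np.sin(theta).mean()
    if np.hypot(x, y) < 1e-12:
        raise UndefinedMeanError("zero resultant vector: circular mean undefined")
    mean = np.arctan2(y, x) / TWO_PI
    mean = np.mod(mean, 1.0)
    return 1.0 if mean == 0.0 else float(mean)
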