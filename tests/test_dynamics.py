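"""Circle-map engine: stepping, rotation numbers, staircase, surfaces.

The analysis parameters (K=0.95, A=0.85) put the map beyond the
invertibility line K*(1+A) = 1, where Arnold tongues can overlap and the
measured rotation number depends on the seed phase inside
attractor-competition bands.  Monotonicity/symmetry assertions here
therefore target the uncoupled and locked regimes where the monotone-map
premises hold; the band behaviour itself is covered by determinism and
wrap-contract checks.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fareyrt import (
    CircleMapParams,
    bifurcation_surface,
    circular_mean,
    devils_staircase,
    iterate,
    rotation_number,
    step,
)
from fareyrt.dynamics import UndefinedMeanError


class TestStep:
    def test_coupling_vanishes_at_zero_phase(self):
        assert step(0.0, CircleMapParams(0.3)) == pytest.approx(0.3)

    def test_coupling_vanishes_at_antiphase(self):
        assert step(0.5, CircleMapParams(0.25)) == pytest.approx(0.75)

    def test_quarter_phase_kills_antiphase_term(self):
        # cos(pi/2) = 0, sin(pi/2) = 1: phi - K/(2*pi), evaluated by hand
        expected = 0.25 - 0.95 / (2 * math.pi)
        assert step(0.25, CircleMapParams(0.0)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0988028, abs=5e-7)

    def test_rejects_nonfinite_phase(self):
        with pytest.raises(ValueError):
            step(float("nan"), CircleMapParams(0.3))

    def test_rejects_out_of_range_wrapped_phase(self):
        with pytest.raises(ValueError):
            step(1.2, CircleMapParams(0.3), wrap=True)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CircleMapParams(-0.1)
        with pytest.raises(ValueError):
            CircleMapParams(0.3, coupling=-1.0)
        with pytest.raises(ValueError):
            CircleMapParams(0.3, antiphase_weight=1.5)


class TestIterate:
    def test_zero_iterations_returns_seed_only(self):
        traj = iterate(0.42, CircleMapParams(0.3), 0)
        assert len(traj) == 1 and traj.phases[0] == 0.42

    def test_pure_rotation_accumulates_unwrapped(self):
        traj = iterate(0.0, CircleMapParams(0.1, coupling=0.0), 10, wrap=False)
        assert traj.phases[-1] == pytest.approx(1.0)
        assert len(traj) == 11

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            iterate(0.0, CircleMapParams(0.1), -1)

    @given(st.floats(0.0, 0.999), st.floats(0.0, 0.999))
    def test_wrap_contract(self, phi0, omega):
        traj = iterate(phi0, CircleMapParams(omega), 200, wrap=True)
        assert np.all(traj.phases >= 0.0) and np.all(traj.phases < 1.0)


class TestRotationNumber:
    @given(st.floats(0.0, 1.0), st.integers(0, 2**31 - 1))
    def test_uncoupled_limit_equals_omega(self, omega, seed):
        rho = rotation_number(
            CircleMapParams(omega, coupling=0.0),
            n_iter=2000, n_avg=500, rng=np.random.default_rng(seed),
        )
        assert rho == pytest.approx(omega, abs=1e-10)

    def test_locks_to_half_on_the_root_plateau(self):
        rho = rotation_number(CircleMapParams(0.5), rng=np.random.default_rng(0))
        # oracle: the same estimator at 10x iterations agrees
        rho_long = rotation_number(
            CircleMapParams(0.5), n_iter=100_000, n_avg=25_000,
            rng=np.random.default_rng(1),
        )
        assert rho == pytest.approx(0.5, abs=0.005)
        assert rho_long == pytest.approx(rho, abs=0.005)

    def test_navg_exceeding_niter_rejected(self):
        with pytest.raises(ValueError):
            rotation_number(CircleMapParams(0.3), n_iter=100, n_avg=200)


class TestStaircase:
    def test_endpoints_and_root_plateau(self):
        sc = devils_staircase(
            omega_grid=np.array([0.0, 0.5, 1.0]), rng=np.random.default_rng(5)
        )
        assert sc.rhos == pytest.approx([0.0, 0.5, 1.0], abs=0.005)

    def test_uncoupled_staircase_is_identity(self):
        grid = np.linspace(0.0, 1.0, 21)
        sc = devils_staircase(
            coupling=0.0, omega_grid=grid, n_iter=2000, n_avg=500,
            rng=np.random.default_rng(2),
        )
        assert sc.rhos == pytest.approx(grid, abs=1e-9)

    def test_monotone_and_symmetric_for_invertible_map(self):
        """For K*(1+A) <= 1 the map is an orientation-preserving circle
        homeomorphism: rho is unique, non-decreasing in omega, and the odd
        coupling term gives rho(omega) + rho(1-omega) = 1.  (The analysis
        parameters K=0.95, A=0.85 are supercritical, where overlapping
        tongues break both properties inside attractor-competition bands.)"""
        grid = np.linspace(0.0, 1.0, 201)
        sc = devils_staircase(
            coupling=0.5, antiphase_weight=0.85, omega_grid=grid,
            rng=np.random.default_rng(6),
        )
        assert np.all(np.diff(sc.rhos) >= -0.01)
        assert np.max(np.abs(sc.rhos + sc.rhos[::-1] - 1.0)) <= 0.02

    def test_supercritical_staircase_locks_root_plateau(self, staircase):
        """At the analysis parameters the 1/2 tongue spans a wide interval
        around omega = 0.5 and the estimate is exact on the plateau."""
        om = staircase.omegas
        plateau = (om >= 0.45) & (om <= 0.55)
        assert staircase.rhos[plateau] == pytest.approx(0.5, abs=1e-9)
        assert staircase.rhos[0] == pytest.approx(0.0, abs=0.005)
        assert staircase.rhos[-1] == pytest.approx(1.0, abs=0.005)

    def test_lookup_uses_nearest_grid_point(self, coarse_staircase):
        sc = coarse_staircase
        assert sc.lookup(0.504) == sc.rhos[50]
        assert sc.lookup(0.506) == sc.rhos[51]
        assert sc.lookup(0.0) == sc.rhos[0] and sc.lookup(1.0) == sc.rhos[-1]

    def test_determinism_bit_identical(self):
        grid = np.linspace(0.0, 1.0, 51)
        a = devils_staircase(omega_grid=grid, rng=np.random.default_rng(9))
        b = devils_staircase(omega_grid=grid, rng=np.random.default_rng(9))
        assert np.array_equal(a.rhos, b.rhos)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            devils_staircase(omega_grid=np.array([]))


class TestBifurcationSurface:
    def test_wrap_contract_and_shape(self):
        surf = bifurcation_surface(
            n_omega=50, n_iter=500, n_keep=20, rng=np.random.default_rng(3)
        )
        assert surf.phases.shape == (50, 20)
        assert np.all(surf.phases >= 0.0) and np.all(surf.phases < 1.0)

    def test_locked_drive_concentrates_phases(self):
        """At the root plateau the retained phases sit in a narrow attractive
        band; the uncoupled control at an irrational drive equidistributes."""
        rng = np.random.default_rng(4)
        golden = (math.sqrt(5) - 1) / 2

        def tail_phases(coupling, omega):
            from fareyrt import iterate

            traj = iterate(
                float(rng.random()),
                CircleMapParams(omega, coupling=coupling),
                2000, wrap=True,
            )
            return traj.phases[-100:]

        locked = tail_phases(0.95, 0.52)
        free = tail_phases(0.0, golden)

        def resultant(phases):
            theta = 2 * np.pi * phases
            return np.hypot(np.cos(theta).mean(), np.sin(theta).mean())

        # locked on the 1/2 plateau: a period-2 orbit, so each alternate
        # subsequence is a single tight cluster on the circle
        evens, odds = locked[::2], locked[1::2]
        assert min(resultant(evens), resultant(odds)) > 1 - 1e-9
        assert resultant(free) < 0.2

    def test_keep_exceeding_iterations_rejected(self):
        with pytest.raises(ValueError):
            bifurcation_surface(n_omega=5, n_iter=10, n_keep=20)


class TestCircularMean:
    def test_singleton(self):
        assert circular_mean([0.25]) == pytest.approx(0.25)

    def test_wraparound_pair_maps_zero_to_one(self):
        assert circular_mean([0.1, 0.9]) == 1.0

    def test_matches_vector_sum_oracle(self):
        phases = [0.2, 0.3, 0.4]
        # oracle: explicit complex resultant
        z = sum(complex(math.cos(2 * math.pi * p), math.sin(2 * math.pi * p))
                for p in phases)
        expected = (math.atan2(z.imag, z.real) / (2 * math.pi)) % 1.0
        assert circular_mean(phases) == pytest.approx(expected)
        assert circular_mean(phases) == pytest.approx(0.3)

    def test_empty_and_zero_resultant_errors(self):
        with pytest.raises(ValueError):
            circular_mean([])
        with pytest.raises(UndefinedMeanError):
            circular_mean([0.0, 0.25, 0.5, 0.75])
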