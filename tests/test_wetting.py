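"""Equilibrium solver: caps, Young angle, branches, regimes, energies."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from embryowet.wetting import (
    Branch,
    ConfinementGeometry,
    InterfacialTensions,
    InvalidGeometryError,
    OutOfPartialWettingError,
    Regime,
    classify_wetting_regime,
    cylinder_second_variation,
    equilibrium_in_cylinder,
    equilibrium_in_frustum,
    spherical_cap,
    total_energy,
    young_angle,
)
from embryowet.wetting import _cylinder_energy


def cap_volume_by_integration(a, y):
    """Solid-of-revolution oracle for the spherical-cap volume."""
    R = (a * a + y * y) / (2 * abs(y))
    z0 = abs(y) - R  # cap occupies z in [0, |y|], sphere center at z0

    def rho2(z):
        return R * R - (z - z0) ** 2

    val, _ = quad(lambda z: math.pi * rho2(z), 0.0, abs(y))
    return val


class TestSphericalCap:
    def test_flat_cap_identity(self):
        cap = spherical_cap(50.0, 0.0)
        assert cap.volume == 0.0
        assert math.isinf(cap.R)
        assert cap.flat

    def test_hemisphere_closed_form(self):
        cap = spherical_cap(1.0, 1.0)
        assert cap.R == pytest.approx(1.0)
        assert cap.phi == pytest.approx(math.pi / 2)
        assert cap.volume == pytest.approx(2 * math.pi / 3)
        assert cap.area == pytest.approx(2 * math.pi)

    def test_volume_against_integration_oracle(self):
        cap = spherical_cap(3.0, 1.0)
        assert cap.volume == pytest.approx(14 * math.pi / 3)
        assert cap.volume == pytest.approx(cap_volume_by_integration(3.0, 1.0), rel=1e-9)

    @pytest.mark.parametrize("a,y", [(2.0, -1.5), (5.0, 0.3), (4.0, -4.0)])
    def test_signed_volume_matches_oracle_magnitude(self, a, y):
        cap = spherical_cap(a, y)
        assert abs(cap.volume) == pytest.approx(cap_volume_by_integration(a, y), rel=1e-9)
        assert math.copysign(1.0, cap.volume) == math.copysign(1.0, y)

    def test_invalid_radius(self):
        with pytest.raises(InvalidGeometryError):
            spherical_cap(-1.0, 1.0)


class TestYoungAngle:
    @pytest.mark.parametrize("delta,theta", [(0.0, 90.0), (-1.0, 0.0), (0.5, 120.0), (1.0, 180.0)])
    def test_closed_form(self, delta, theta):
        assert young_angle(InterfacialTensions.from_delta(delta)) == pytest.approx(theta)

    def test_out_of_range_carries_regime(self):
        with pytest.raises(OutOfPartialWettingError) as e:
            young_angle(InterfacialTensions.from_delta(1.5))
        assert e.value.regime is Regime.DEWETTING
        with pytest.raises(OutOfPartialWettingError) as e:
            young_angle(InterfacialTensions.from_delta(-1.5))
        assert e.value.regime is Regime.TOTAL_WETTING_TRANSITION

    def test_adhesion_spreads(self):
        thetas = [young_angle(InterfacialTensions.from_delta(d)) for d in np.linspace(0.9, -0.9, 10)]
        assert np.all(np.diff(thetas) < 0)


def brute_force_stable_cap_height(V, r, delta, n_grid=2000):
    """Constrained energy-minimization oracle on the admissible cap range.

    Physically admissible cylinder shapes have |y| <= r (caps at most
    hemispherical) and a non-negative slab that the inward caps do not
    self-intersect.
    """
    t = InterfacialTensions.from_delta(delta)
    y = np.linspace(-r, r, n_grid)
    E, h = _cylinder_energy(y, V, r, t)
    ok = (h >= 0) & (h + 2 * np.minimum(y, 0.0) >= 0)
    if not ok.any():
        return None
    return float(y[ok][np.argmin(E[ok])])


class TestCylinderEquilibrium:
    def test_neutral_tension_flat_caps(self):
        V = math.pi * 50.0**2 * 100.0
        br = equilibrium_in_cylinder(V, 50.0, InterfacialTensions.from_delta(0.0))
        eq = br.stable
        assert eq.theta_a == pytest.approx(90.0)
        assert eq.y == pytest.approx(0.0)
        assert eq.h == pytest.approx(100.0)
        assert eq.deltaP == pytest.approx(0.0)
        assert br.unstable is None  # the unstable branch escapes to infinity

    def test_stable_branch_matches_energy_grid_oracle(self):
        eq = equilibrium_in_cylinder(7e5, 50.0, InterfacialTensions.from_delta(-0.3)).stable
        y_star = brute_force_stable_cap_height(7e5, 50.0, -0.3)
        assert eq.y == pytest.approx(y_star, rel=0.01)

    def test_oracle_equivalence_random_sweep(self, rng):
        checked = 0
        while checked < 20:
            r = rng.uniform(30, 90)
            delta = rng.uniform(-0.95, 0.95)
            V = rng.uniform(3e5, 3e6)
            br = equilibrium_in_cylinder(V, r, InterfacialTensions.from_delta(delta))
            if br.stable.regime is Regime.DEWETTING:
                continue
            y_star = brute_force_stable_cap_height(V, r, delta)
            assert y_star is not None
            tol = 0.01 * max(abs(br.stable.y), 2 * r / 2000)
            assert abs(br.stable.y - y_star) <= tol + 2 * r / 2000
            checked += 1

    def test_second_variation_signs(self):
        t = InterfacialTensions.from_delta(-0.5)
        br = equilibrium_in_cylinder(2e6, 60.0, t)
        assert cylinder_second_variation(br.stable.y, 60.0, t) > 0
        assert cylinder_second_variation(br.unstable.y, 60.0, t) < 0
        assert br.stable.branch is Branch.Y_MINUS_STABLE
        assert br.unstable.branch is Branch.Y_PLUS_UNSTABLE

    def test_branches_merge_towards_total_wetting(self):
        gaps = []
        for delta in [-0.6, -0.8, -0.95, -0.999]:
            br = equilibrium_in_cylinder(2e6, 50.0, InterfacialTensions.from_delta(delta))
            gaps.append(abs(br.unstable.y - br.stable.y))
        assert np.all(np.diff(gaps) < 0)
        assert gaps[-1] < 0.1 * gaps[0]

    def test_small_volume_dewets_without_exception(self):
        eq = equilibrium_in_cylinder(1e3, 50.0, InterfacialTensions.from_delta(0.6)).stable
        assert eq.regime is Regime.DEWETTING
        assert not eq.bridged
        # detached sphere of equal volume
        assert eq.reconstructed_volume() == pytest.approx(1e3, rel=1e-9)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(InvalidGeometryError):
            equilibrium_in_cylinder(float("nan"), 50.0, InterfacialTensions.from_delta(0.0))

    def test_volume_conservation_random(self, rng):
        for _ in range(30):
            delta = rng.uniform(-0.9, 0.9)
            V = rng.uniform(2e5, 5e6)
            eq = equilibrium_in_cylinder(V, rng.uniform(30, 90), InterfacialTensions.from_delta(delta)).stable
            assert abs(eq.reconstructed_volume() - V) / V < 1e-6


class TestFrustumEquilibrium:
    def test_cylinder_limit(self):
        alpha = 1e-4
        zc = 50.0 / math.tan(alpha)
        geom = ConfinementGeometry.frustum(alpha, (zc - 300.0, zc + 300.0))
        V = math.pi * 50.0**2 * 100.0
        eq = equilibrium_in_frustum(V, geom, InterfacialTensions.from_delta(0.0))
        ref = equilibrium_in_cylinder(V, 50.0, InterfacialTensions.from_delta(0.0)).stable
        assert eq.theta_a == pytest.approx(ref.theta_a, abs=0.09)
        assert eq.theta_b == pytest.approx(ref.theta_b, abs=0.09)
        assert (eq.z1 - eq.z2) == pytest.approx(ref.h, rel=1e-3)

    def test_free_solution_residuals(self):
        # free interior equilibrium: all stationarity conditions hold
        geom = ConfinementGeometry.frustum(0.1, (10.0, 5000.0))
        delta, V = 0.4, 1e6
        eq = equilibrium_in_frustum(V, geom, InterfacialTensions.from_delta(delta))
        assert not eq.pinned_bottom
        scale = V ** (1.0 / 3.0)
        # Laplace pressure equality between caps
        dP_a = 4 * eq.z3 / (eq.a**2 + eq.z3**2)
        dP_b = 4 * eq.z4 / (eq.b**2 + eq.z4**2)
        assert abs(dP_a - dP_b) * scale < 1e-8
        # Young's condition at both lines
        assert abs(math.sin(eq.phi_a - geom.alpha) - delta) < 1e-8
        assert abs(math.sin(eq.phi_b + geom.alpha) - delta) < 1e-8
        assert abs(eq.reconstructed_volume() - V) / V < 1e-8

    def test_pinned_solution_residuals(self):
        geom = ConfinementGeometry.frustum(0.1, (200.0, 5000.0))
        delta, V = -0.2, 1e6
        eq = equilibrium_in_frustum(V, geom, InterfacialTensions.from_delta(delta))
        assert eq.pinned_bottom and eq.z2 == geom.z_range[0]
        scale = V ** (1.0 / 3.0)
        dP_a = 4 * eq.z3 / (eq.a**2 + eq.z3**2)
        dP_b = 4 * eq.z4 / (eq.b**2 + eq.z4**2)
        assert abs(dP_a - dP_b) * scale < 1e-8
        assert abs(math.sin(eq.phi_a - geom.alpha) - delta) < 1e-8  # Young at the free line
        assert abs(eq.reconstructed_volume() - V) / V < 1e-8

    def test_weak_adhesion_near_spherical(self):
        # a crypt whose wall reaches the tip region, so a small droplet can
        # keep a (tiny) contact band instead of detaching
        crypt = ConfinementGeometry.frustum(0.2, (10.0, 700.0))
        eq = equilibrium_in_frustum(2e5, crypt, InterfacialTensions.from_delta(0.95))
        assert eq.theta_a == pytest.approx(math.degrees(math.acos(-0.95)), abs=1e-9)
        assert eq.theta_a > 150.0
        # contact band much shorter than the droplet extent: nearly a sphere
        extent = (eq.z1 + max(eq.z3, 0.0)) - (eq.z2 - max(eq.z4, 0.0))
        assert (eq.z1 - eq.z2) < 0.35 * extent

    def test_theta_b_monotone_in_delta(self, crypt):
        deltas = np.linspace(-0.9, 0.9, 25)
        thetas = [
            equilibrium_in_frustum(8e5, crypt, InterfacialTensions.from_delta(d)).theta_b
            for d in deltas
        ]
        assert np.all(np.diff(thetas) >= -1e-9)

    def test_volume_conservation_random(self, crypt, rng):
        for _ in range(30):
            d = rng.uniform(-0.99, 0.99)
            V = rng.uniform(2e5, 3e6)
            eq = equilibrium_in_frustum(V, crypt, InterfacialTensions.from_delta(d))
            assert abs(eq.reconstructed_volume() - V) / V < 1e-6


class TestEnergyAndRegimes:
    def test_energy_linearity(self):
        t1 = InterfacialTensions(delta_gamma=0.0, gamma0=1.0)
        assert total_energy(10.0, 7.0, t1) == pytest.approx(10.0)
        t2 = InterfacialTensions(delta_gamma=-0.4, gamma0=1.0)
        t2x = InterfacialTensions(delta_gamma=-0.8, gamma0=2.0)
        assert total_energy(10.0, 7.0, t2x) == pytest.approx(2 * total_energy(10.0, 7.0, t2))

    def test_stable_below_unstable_random_sweep(self, rng):
        seen = 0
        while seen < 50:
            delta = rng.uniform(-0.95, 0.95)
            if delta == 0:
                continue
            V = rng.uniform(5e5, 5e6)
            br = equilibrium_in_cylinder(V, rng.uniform(30, 80), InterfacialTensions.from_delta(delta))
            if br.unstable is None or br.stable.regime is Regime.DEWETTING:
                continue
            assert br.stable.energy < br.unstable.energy
            seen += 1

    def test_regime_partition_is_total(self, crypt, rng):
        labels = set()
        for _ in range(60):
            d = rng.uniform(-1.3, 1.3)
            V = rng.uniform(1e4, 3e6)
            eq = equilibrium_in_frustum(V, crypt, InterfacialTensions.from_delta(d))
            lab = classify_wetting_regime(eq)
            assert lab in {"I", "II", "III", "IV"}
            labels.add(lab)
        assert {"I", "III", "IV"} <= labels  # the sweep reaches several regimes

    def test_flat_cap_neutral_is_regime_II(self):
        V = math.pi * 50.0**2 * 100.0
        eq = equilibrium_in_cylinder(V, 50.0, InterfacialTensions.from_delta(0.0)).stable
        assert classify_wetting_regime(eq) == "II"

    def test_no_adhesion_is_regime_IV(self, crypt):
        eq = equilibrium_in_frustum(8e5, crypt, InterfacialTensions.from_delta(1.2))
        assert classify_wetting_regime(eq) == "IV"

    def test_transition_is_regime_I(self, crypt):
        eq = equilibrium_in_frustum(8e5, crypt, InterfacialTensions.from_delta(-1.0))
        assert classify_wetting_regime(eq) == "I"
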