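"""Equilibrium shapes of a confined droplet with adaptive substrate adhesion.

The implanting embryo is modelled as a fluid droplet of fixed volume ``V``
held inside an axisymmetric confinement — a cylinder of radius ``r`` or a
conical frustum of half-angle ``alpha`` (apex at ``z = 0``, wall radius
``z * tan(alpha)``).  The droplet carries a droplet–medium surface tension
``gamma0`` and a Young tension difference ``delta_gamma`` between the
droplet–substrate and substrate–medium interfaces.  Shapes are axisymmetric
with exact spherical caps, so the configuration space is finite-dimensional
and equilibria follow from making the interfacial energy

    E = gamma0 * (free cap areas) + delta_gamma * (wall contact area)

stationary under the volume constraint, with the Laplace pressure ``deltaP``
acting as the Lagrange multiplier.

Conventions
-----------
* Contact angles are measured through the droplet interior between the
  droplet surface and the wall and reported in degrees; Young's relation
  reads ``cos(theta) = -delta`` with ``delta = delta_gamma / gamma0``, so
  increasing adhesion (decreasing ``delta``) spreads the droplet.
* Cap heights are signed: positive caps bulge outward (away from the
  droplet), negative caps curve into it.
* Lengths in micrometres, volumes in cubic micrometres; ``gamma0 = 1``
  internally so that only ``delta`` matters for the shape.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "ConfinementGeometry",
    "InterfacialTensions",
    "SphericalCap",
    "DropletEquilibrium",
    "CylinderBranches",
    "Branch",
    "Regime",
    "InvalidGeometryError",
    "OutOfPartialWettingError",
    "spherical_cap",
    "young_angle",
    "equilibrium_in_cylinder",
    "equilibrium_in_frustum",
    "classify_wetting_regime",
    "total_energy",
]


class InvalidGeometryError(ValueError):
    """Raised for geometrically impossible inputs."""


class OutOfPartialWettingError(ValueError):
    """Raised when |delta| > 1, outside the partial-wetting range.

    Carries the regime the tension ratio maps to instead.
    """

    def __init__(self, delta: float):
        self.delta = delta
        self.regime = Regime.TOTAL_WETTING_TRANSITION if delta < -1 else Regime.DEWETTING
        super().__init__(
            f"delta = {delta:g} lies outside the partial-wetting range [-1, 1]; "
            f"regime: {self.regime.value}"
        )


class Branch(str, enum.Enum):
    Y_MINUS_STABLE = "y_minus_stable"
    Y_PLUS_UNSTABLE = "y_plus_unstable"


class Regime(str, enum.Enum):
    TOTAL_WETTING_TRANSITION = "total_wetting_transition"
    PARTIAL_WETTING = "partial_wetting"
    DEWETTING = "dewetting"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfinementGeometry:
    """The crypt idealised as a cylinder or a conical frustum.

    Parameters
    ----------
    kind : {"cylinder", "frustum"}
    r : float, optional
        Cylinder radius (μm).  Required for ``kind="cylinder"``.
    alpha : float, optional
        Frustum half-angle (radians); the wall radius at axial coordinate
        ``z`` is ``z * tan(alpha)`` with the apex at ``z = 0``.
    z_range : (float, float), optional
        Physical axial extent of the frustum wall (μm), ordered, with a
        non-negative lower bound.
    """

    kind: str
    r: Optional[float] = None
    alpha: Optional[float] = None
    z_range: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.kind not in ("cylinder", "frustum"):
            raise InvalidGeometryError(f"unknown geometry kind {self.kind!r}")
        if self.kind == "cylinder":
            if self.r is None or not np.isfinite(self.r) or self.r <= 0:
                raise InvalidGeometryError("cylinder requires radius r > 0")
        else:
            if self.alpha is None or not (0 < self.alpha < math.pi / 2):
                raise InvalidGeometryError("frustum requires 0 < alpha < pi/2")
            if self.z_range is None:
                raise InvalidGeometryError("frustum requires z_range")
            lo, hi = self.z_range
            if not (0 <= lo < hi) or not np.isfinite(hi):
                raise InvalidGeometryError("z_range must be ordered with lower bound >= 0")

    @classmethod
    def cylinder(cls, r: float) -> "ConfinementGeometry":
        return cls(kind="cylinder", r=float(r))

    @classmethod
    def frustum(cls, alpha: float, z_range: Tuple[float, float]) -> "ConfinementGeometry":
        return cls(kind="frustum", alpha=float(alpha), z_range=(float(z_range[0]), float(z_range[1])))

    def wall_radius(self, z):
        """Wall radius at axial coordinate ``z`` (μm)."""
        if self.kind == "cylinder":
            return np.broadcast_to(self.r, np.shape(z)).astype(float) if np.ndim(z) else self.r
        return np.tan(self.alpha) * np.asarray(z, dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "ConfinementGeometry":
        import yaml

        with open(path) as fh:
            spec = yaml.safe_load(fh)
        kind = spec["kind"]
        if kind == "cylinder":
            return cls.cylinder(spec["r"])
        return cls.frustum(spec["alpha"], tuple(spec["z_range"]))


@dataclass(frozen=True)
class InterfacialTensions:
    """Droplet–medium tension ``gamma0`` and Young tension ``delta_gamma``.

    ``delta = delta_gamma / gamma0`` is the only shape-relevant quantity; it
    is negative for net adhesion (spreading) and positive when contact with
    the wall is penalised.
    """

    delta_gamma: float
    gamma0: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.gamma0) or self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive and finite")
        if not np.isfinite(self.delta_gamma):
            raise ValueError("delta_gamma must be finite")

    @property
    def delta(self) -> float:
        return self.delta_gamma / self.gamma0

    @classmethod
    def from_delta(cls, delta: float, gamma0: float = 1.0) -> "InterfacialTensions":
        return cls(delta_gamma=delta * gamma0, gamma0=gamma0)


@dataclass(frozen=True)
class SphericalCap:
    """A spherical cap over a contact circle, with signed height."""

    contact_radius: float
    height: float
    R: float  # curvature radius, signed like height; inf for a flat cap
    phi: float  # opening angle (radians), signed like height
    area: float  # lateral (spherical) area
    volume: float  # signed cap volume

    @property
    def flat(self) -> bool:
        return not np.isfinite(self.R)


@dataclass
class DropletEquilibrium:
    """One solved droplet shape.

    Cylinder solutions report the contact-line separation ``h`` and the
    common signed cap height ``y``; frustum solutions report the axial
    contact-line positions ``z1`` (top) > ``z2`` (bottom) and the signed cap
    heights ``z3`` (top) and ``z4`` (bottom), all measured from the apex.
    """

    V: float
    theta_a: float  # top / polar contact angle (degrees)
    theta_b: float  # bottom / mural contact angle (degrees)
    R_a: float
    R_b: float
    phi_a: float  # radians, signed
    phi_b: float
    deltaP: float
    energy: float
    branch: Branch
    regime: Regime
    # contact radii at the top and bottom contact lines
    a: Optional[float] = None
    b: Optional[float] = None
    # cylinder fields
    h: Optional[float] = None
    y: Optional[float] = None
    # frustum fields
    z1: Optional[float] = None
    z2: Optional[float] = None
    z3: Optional[float] = None
    z4: Optional[float] = None
    bridged: bool = True  # False when the returned shape is a detached sphere
    pinned_bottom: bool = False
    pinned_top: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["branch"] = self.branch.value
        d["regime"] = self.regime.value
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def reconstructed_volume(self) -> float:
        """Recompute the volume from the stored shape fields."""
        if not self.bridged:
            return (4.0 / 3.0) * math.pi * self.R_a**3
        if self.h is not None:
            return math.pi * self.a**2 * self.h + 2.0 * _cap_volume(self.a, self.y)
        t = self.b / self.z2 if self.z2 else self.a / self.z1
        slab = (math.pi / 3.0) * t * t * (self.z1**3 - self.z2**3)
        return slab + _cap_volume(self.a, self.z3) + _cap_volume(self.b, self.z4)


@dataclass(frozen=True)
class CylinderBranches:
    """The pair of cylinder equilibria: stable ``y-`` and unstable ``y+``."""

    stable: DropletEquilibrium
    unstable: Optional[DropletEquilibrium]

    def __iter__(self):
        return iter((self.stable, self.unstable))


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------


def _cap_volume(a: float, y: float) -> float:
    return (math.pi / 6.0) * y * (3.0 * a * a + y * y)


def _cap_area(a: float, y: float) -> float:
    return math.pi * (a * a + y * y)


def spherical_cap(contact_radius: float, cap_height: float) -> SphericalCap:
    """Spherical cap over a circle of ``contact_radius`` with signed height.

    ``R = (a² + y²) / (2|y|)`` carries the sign of the height; a zero height
    gives a flat cap with ``R = inf``.  The volume is signed like the height
    so that inward-curving caps subtract from the droplet volume.
    """
    a, y = float(contact_radius), float(cap_height)
    if not np.isfinite(a) or a <= 0:
        raise InvalidGeometryError("contact_radius must be positive")
    if y == 0.0:
        return SphericalCap(a, 0.0, math.inf, 0.0, math.pi * a * a, 0.0)
    R = (a * a + y * y) / (2.0 * y)
    phi = math.asin(min(1.0, a / abs(R))) * math.copysign(1.0, y)
    if abs(y) > a:  # taller than a hemisphere: the rim sits below the equator
        phi = math.copysign(math.pi - abs(phi), y)
    return SphericalCap(a, y, R, phi, _cap_area(a, y), _cap_volume(a, y))


def young_angle(tensions: InterfacialTensions) -> float:
    """Equilibrium contact angle ``theta = arccos(-delta)`` in degrees."""
    delta = tensions.delta
    if abs(delta) > 1.0:
        raise OutOfPartialWettingError(delta)
    return math.degrees(math.acos(-delta))


def total_energy(
    free_cap_area: float, contact_area: float, tensions: InterfacialTensions
) -> float:
    """Interfacial energy ``E = gamma0 * A_free + delta_gamma * A_contact``."""
    return tensions.gamma0 * free_cap_area + tensions.delta_gamma * contact_area


# ---------------------------------------------------------------------------
# Cylinder equilibria
# ---------------------------------------------------------------------------


def _cylinder_energy(y, V, r, tensions: InterfacialTensions):
    """Energy of the one-parameter cylinder family at cap height ``y``.

    The slab height ``h`` is eliminated through the volume constraint, so
    this is the reduced energy whose stationary points are the equilibria.
    """
    y = np.asarray(y, dtype=float)
    h = (V - 2.0 * (np.pi / 6.0) * y * (3.0 * r * r + y * y)) / (np.pi * r * r)
    E = tensions.gamma0 * 2.0 * np.pi * (r * r + y * y) + tensions.delta_gamma * 2.0 * np.pi * r * h
    return E, h

def _dewetted_sphere(V: float, tensions: InterfacialTensions) -> DropletEquilibrium:
    R = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    return DropletEquilibrium(
        V=V,
        theta_a=180.0,
        theta_b=180.0,
        R_a=R,
        R_b=R,
        phi_a=math.pi,
        phi_b=math.pi,
        deltaP=2.0 * tensions.gamma0 / R,
        energy=tensions.gamma0 * 4.0 * math.pi * R * R,
        branch=Branch.Y_MINUS_STABLE,
        regime=Regime.DEWETTING,
        bridged=False,
    )


def equilibrium_in_cylinder(
    V: float, r: float, tensions: InterfacialTensions
) -> CylinderBranches:
    """Both equilibrium branches of a droplet bridging a cylinder.

    Stationarity of the reduced energy gives ``delta = 2 r y / (r² + y²)``
    with the two roots ``y∓ = r (1 ∓ sqrt(1 - delta²)) / delta``; the
    second variation ``d²E/dy² = 4π (gamma0 - delta_gamma * y / r)`` is
    positive on ``y-`` (stable) and negative on ``y+`` (unstable).  When the
    stable branch cannot bridge the cylinder at the requested volume
    (``h < 0``) a detached sphere of equal volume is returned with the
    dewetting regime label.
    """
    if not (np.isfinite(V) and V > 0 and np.isfinite(r) and r > 0):
        raise InvalidGeometryError("V and r must be positive and finite")
    delta = tensions.delta
    g0 = tensions.gamma0
    if delta >= 1.0:
        return CylinderBranches(_dewetted_sphere(V, tensions), None)
    delta_eff = max(delta, -1.0)
    transition = delta <= -1.0

    s = math.sqrt(max(0.0, 1.0 - delta_eff * delta_eff))
    if delta_eff == 0.0:
        ys = [0.0, None]
    else:
        ys = [r * (1.0 - s) / delta_eff, r * (1.0 + s) / delta_eff]

    sols = []
    for y, branch in zip(ys, (Branch.Y_MINUS_STABLE, Branch.Y_PLUS_UNSTABLE)):
        if y is None:
            sols.append(None)
            continue
        E, h = _cylinder_energy(y, V, r, tensions)
        cap = spherical_cap(r, y) if y != 0.0 else spherical_cap(r, 0.0)
        theta = math.degrees(math.acos(-delta_eff))
        bridged = h >= 0.0
        regime = Regime.TOTAL_WETTING_TRANSITION if transition else Regime.PARTIAL_WETTING
        if branch is Branch.Y_MINUS_STABLE and not bridged:
            sols.append(_dewetted_sphere(V, tensions))
            continue
        sols.append(
            DropletEquilibrium(
                V=V,
                theta_a=theta,
                theta_b=theta,
                R_a=cap.R,
                R_b=cap.R,
                phi_a=cap.phi,
                phi_b=cap.phi,
                deltaP=2.0 * tensions.delta_gamma / r,
                energy=float(E),
                branch=branch,
                regime=regime,
                a=r,
                b=r,
                h=float(h),
                y=float(y),
                bridged=bool(bridged),
            )
        )
    if sols[0].regime is Regime.DEWETTING:
        return CylinderBranches(sols[0], None)
    return CylinderBranches(sols[0], sols[1])


def cylinder_second_variation(y: float, r: float, tensions: InterfacialTensions) -> float:
    """``d²E/dy²`` of the reduced cylinder energy at cap height ``y``."""
    return 4.0 * math.pi * (tensions.gamma0 - tensions.delta_gamma * y / r)


# ---------------------------------------------------------------------------
# Frustum equilibria
# ---------------------------------------------------------------------------
#
# Stationarity of E - deltaP * V in (z1, z2, z3, z4) yields
#   deltaP = 4 g0 z3 / (a² + z3²) = 4 g0 z4 / (b² + z4²)   (Laplace, both caps)
#   sin(phi_a - alpha) = delta                              (Young, top line)
#   sin(phi_b + alpha) = delta                              (Young, bottom line)
# with a = z1 tan(alpha), b = z2 tan(alpha), and phi the signed cap opening
# angle (sin(phi) = a / R).  Pressure equality fixes z2 / z1 =
# sin(phi_b) / sin(phi_a) and the whole family is self-similar, so the
# volume constraint sets the scale in closed form.  A free interior solution
# with z2 < z1 exists only for delta > sin(alpha); for smaller delta the
# energy decreases towards the apex (a wetting droplet migrates down a cone)
# and the bottom contact line pins at the lower end of the wall, where the
# pinned system (Young at the top line + pressure equality + volume) is
# solved instead and the ``pinned_bottom`` flag is set.


def _frustum_shape_fields(z1, z2, alpha, phi_a, phi_b):
    t = math.tan(alpha)
    a, b = z1 * t, z2 * t
    z3 = a * math.tan(phi_a / 2.0)
    z4 = b * math.tan(phi_b / 2.0)
    return a, b, z3, z4


def _frustum_volume(z1, z2, z3, z4, alpha):
    t = math.tan(alpha)
    slab = (math.pi / 3.0) * t * t * (z1**3 - z2**3)
    return slab + _cap_volume(z1 * t, z3) + _cap_volume(z2 * t, z4)


def _frustum_energy(z1, z2, z3, z4, alpha, tensions: InterfacialTensions):
    t = math.tan(alpha)
    a, b = z1 * t, z2 * t
    wall = math.pi * t / math.cos(alpha) * (z1 * z1 - z2 * z2)
    return total_energy(_cap_area(a, z3) + _cap_area(b, z4), wall, tensions)


def _make_frustum_eq(V, z1, z2, alpha, phi_a, phi_b, tensions, *, pinned_bottom=False, pinned_top=False, regime=Regime.PARTIAL_WETTING):
    g0 = tensions.gamma0
    a, b, z3, z4 = _frustum_shape_fields(z1, z2, alpha, phi_a, phi_b)
    R_a = a / math.sin(phi_a) if phi_a != 0.0 else math.inf
    R_b = b / math.sin(phi_b) if phi_b != 0.0 else math.inf
    dP = 2.0 * g0 / R_a if np.isfinite(R_a) else (2.0 * g0 / R_b if np.isfinite(R_b) else 0.0)
    return DropletEquilibrium(
        V=V,
        theta_a=math.degrees(math.pi / 2.0 + phi_a - alpha),
        theta_b=math.degrees(math.pi / 2.0 + phi_b + alpha),
        R_a=R_a,
        R_b=R_b,
        phi_a=phi_a,
        phi_b=phi_b,
        deltaP=dP,
        energy=_frustum_energy(z1, z2, z3, z4, alpha, tensions),
        branch=Branch.Y_MINUS_STABLE,
        regime=regime,
        a=a,
        b=b,
        z1=z1,
        z2=z2,
        z3=z3,
        z4=z4,
        pinned_bottom=pinned_bottom,
        pinned_top=pinned_top,
    )


def _pinned_bottom_solve(V, geom, delta, tensions, regime):
    """Bottom contact line pinned at z_range[0]; solve the volume for z1."""
    alpha = geom.alpha
    z_lo, z_hi = geom.z_range
    beta = math.asin(max(-1.0, min(1.0, delta)))
    phi_a = alpha + beta
    sin_a = math.sin(phi_a)

    def phi_b_of(z1):
        # pressure equality sin(phi_b)/b = sin(phi_a)/a  ->  shallow branch
        s = (z_lo / z1) * sin_a
        return math.asin(max(-1.0, min(1.0, s)))

    def vol_err(z1):
        pb = phi_b_of(z1)
        _, _, z3, z4 = _frustum_shape_fields(z1, z_lo, alpha, phi_a, pb)
        return _frustum_volume(z1, z_lo, z3, z4, alpha) - V

    # bracket: volume grows monotonically with z1
    lo = z_lo * (1.0 + 1e-9)
    if vol_err(lo) > 0:
        return _dewetted_sphere(V, tensions)
    hi = z_lo * 2.0
    while vol_err(hi) < 0:
        hi *= 2.0
        if hi > 1e9 * z_lo:  # pragma: no cover - unreachable for finite V
            raise InvalidGeometryError("pinned-bottom volume bracket failed")
    z1 = optimize.brentq(vol_err, lo, hi, xtol=1e-12 * z_lo, rtol=1e-14)
    pinned_top = z1 > z_hi
    if pinned_top:
        z1 = z_hi  # droplet overfills the wall; pin both lines
        # with both lines pinned only pressure equality + volume remain:
        # solve for phi_a with phi_b tied through pressure equality
        def vol_err2(pa):
            pb = math.asin(max(-1.0, min(1.0, (z_lo / z_hi) * math.sin(pa))))
            _, _, z3, z4 = _frustum_shape_fields(z_hi, z_lo, alpha, pa, pb)
            return _frustum_volume(z_hi, z_lo, z3, z4, alpha) - V

        pa = optimize.brentq(vol_err2, -math.pi / 2 + 1e-12, math.pi / 2 - 1e-12, rtol=1e-14)
        return _make_frustum_eq(V, z_hi, z_lo, alpha, pa, math.asin(max(-1.0, min(1.0, (z_lo / z_hi) * math.sin(pa)))), tensions, pinned_bottom=True, pinned_top=True, regime=regime)
    return _make_frustum_eq(V, z1, z_lo, alpha, phi_a, phi_b_of(z1), tensions, pinned_bottom=True, regime=regime)


def equilibrium_in_frustum(
    V: float, geom: ConfinementGeometry, tensions: InterfacialTensions
) -> DropletEquilibrium:
    """Equilibrium droplet shape inside a conical frustum.

    Solves the stationarity system (Young's condition at the contact lines,
    equal Laplace pressure across both caps, and the volume constraint) in
    closed form where a free interior equilibrium exists, and the
    boundary-pinned system otherwise; ``delta >= 1`` or a droplet unable to
    bridge the wall yields a detached sphere in the dewetting regime.
    """
    if geom.kind != "frustum":
        raise InvalidGeometryError("equilibrium_in_frustum requires a frustum geometry")
    if not (np.isfinite(V) and V > 0):
        raise InvalidGeometryError("V must be positive and finite")
    delta = tensions.delta
    if delta >= 1.0:
        return _dewetted_sphere(V, tensions)
    regime = Regime.TOTAL_WETTING_TRANSITION if delta <= -1.0 else Regime.PARTIAL_WETTING
    alpha = geom.alpha
    z_lo, z_hi = geom.z_range

    if delta > math.sin(alpha):
        beta = math.asin(delta)
        phi_a = alpha + beta
        phi_b = beta - alpha
        k = math.sin(phi_b) / math.sin(phi_a)  # z2 / z1 from pressure equality
        _, _, z3u, z4u = _frustum_shape_fields(1.0, k, alpha, phi_a, phi_b)
        V_unit = _frustum_volume(1.0, k, z3u, z4u, alpha)
        z1 = (V / V_unit) ** (1.0 / 3.0)
        z2 = k * z1
        if z2 >= z_lo and z1 <= z_hi:
            return _make_frustum_eq(V, z1, z2, alpha, phi_a, phi_b, tensions, regime=regime)
        if z1 > z_hi and z2 >= z_lo:
            # overfilled at the top: pin the top line, keep Young at the bottom;
            # pressure equality ties sin(phi_a) = (z_hi / z2) sin(phi_b)
            def vol_err(z2v):
                s = (z_hi / z2v) * math.sin(phi_b)
                if abs(s) > 1.0:
                    return math.inf
                pa = math.asin(s)
                _, _, z3, z4 = _frustum_shape_fields(z_hi, z2v, alpha, pa, phi_b)
                return _frustum_volume(z_hi, z2v, z3, z4, alpha) - V

            try:
                z2v = optimize.brentq(vol_err, z_lo, z_hi * (1 - 1e-9), rtol=1e-14)
                pa = math.asin((z_hi / z2v) * math.sin(phi_b))
                return _make_frustum_eq(
                    V, z_hi, z2v, alpha, pa, phi_b, tensions, pinned_top=True, regime=regime
                )
            except ValueError:
                return _pinned_bottom_solve(V, geom, delta, tensions, regime)
    # no free interior equilibrium: the droplet slides towards the apex
    return _pinned_bottom_solve(V, geom, delta, tensions, regime)


# ---------------------------------------------------------------------------
# Regime classification
# ---------------------------------------------------------------------------


def classify_wetting_regime(eq: DropletEquilibrium, *, merge_tol_deg: float = 0.1) -> str:
    """Map a solved equilibrium onto the wetting regimes I–IV.

    I   branch coincidence at the transition to total wetting (theta -> 0°),
    II  partial wetting with flat or inward-curving caps (theta <= 90°),
    III partial wetting with outward-curving caps (theta > 90°),
    IV  dewetting (detached droplet).

    The regime partition is total: every solved equilibrium receives exactly
    one label.
    """
    if eq.regime is Regime.DEWETTING or not eq.bridged:
        return "IV"
    if eq.regime is Regime.TOTAL_WETTING_TRANSITION or eq.theta_b <= merge_tol_deg:
        return "I"
    return "II" if eq.theta_b <= 90.0 else "III"
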