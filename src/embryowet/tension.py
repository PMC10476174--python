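"""Time-dependent Young tension and quasi-static shape trajectories.

Adhesion between the mural trophectoderm and the uterine matrix matures over
time; the model captures this with a five-constant sigmoid time course of the
normalized Young tension ``delta(t) = delta_gamma(t) / gamma0``: plateaus
``c1`` before ``t1`` and ``c2`` after ``t2``, a smooth monotone ramp in
between, and a modulation parameter ``a >= 0`` controlling the steepness of
the ramp (``a = 0`` gives the symmetric smooth ramp).

Shape dynamics are quasi-static: the droplet is assumed to be at its
equilibrium shape for the instantaneous volume ``V(t)`` (an input, measured
or synthetic — inflation–collapse included) and tension ``delta(t)``; no
viscous relaxation timescale is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .wetting import (
    ConfinementGeometry,
    InterfacialTensions,
    equilibrium_in_frustum,
    equilibrium_in_cylinder,
    classify_wetting_regime,
)

__all__ = ["SigmoidTension", "ShapeTimeSeries", "tension_at", "simulate_shape_series"]


@dataclass(frozen=True)
class SigmoidTension:
    """Five-constant sigmoid law for the normalized Young tension.

    Parameters
    ----------
    c1, c2 : float
        Initial and final normalized tension (dimensionless).
    t1, t2 : float
        Start and end of the adaptation window (hours post-E3.5), t1 < t2.
    a : float
        Modulation parameter, >= 0; larger values steepen the ramp.

    The equivalent parametrization (t0, dt) with mid-time
    ``t0 = (t1 + t2) / 2`` and duration ``dt = t2 - t1`` is exposed as
    properties and through :meth:`from_midpoint`.
    """

    c1: float
    c2: float
    t1: float
    t2: float
    a: float = 0.0

    def __post_init__(self):
        if not self.t1 < self.t2:
            raise ValueError("require t1 < t2")
        if self.a < 0:
            raise ValueError("require a >= 0")

    @property
    def t0(self) -> float:
        return 0.5 * (self.t1 + self.t2)

    @property
    def dt(self) -> float:
        return self.t2 - self.t1

    @classmethod
    def from_midpoint(cls, c1, c2, t0, dt, a=0.0) -> "SigmoidTension":
        return cls(c1=c1, c2=c2, t1=t0 - dt / 2.0, t2=t0 + dt / 2.0, a=a)


def tension_at(t, params: SigmoidTension):
    """Normalized tension ``delta`` at time(s) ``t`` (hours).

    Exact plateaus outside [t1, t2]; inside, a monotone C¹ ramp built from
    the cubic smoothstep ``s(u) = u²(3 - 2u)`` sharpened by the modulation
    parameter through ``s^(1+a) / (s^(1+a) + (1-s)^(1+a))``; ``a = 0``
    recovers the symmetric smoothstep, whose midpoint value is
    ``(c1 + c2) / 2`` at ``t0``.
    """
    t = np.asarray(t, dtype=float)
    u = np.clip((t - params.t1) / (params.t2 - params.t1), 0.0, 1.0)
    s = u * u * (3.0 - 2.0 * u)
    p = 1.0 + params.a
    num = s**p
    ramp = num / (num + (1.0 - s) ** p)
    out = params.c1 + (params.c2 - params.c1) * ramp
    return out if out.ndim else float(out)


@dataclass
class ShapeTimeSeries:
    """Measured or simulated embryo shape dynamics.

    Times in hours post-E3.5, volumes in μm³, contact angles in degrees.
    """

    times: np.ndarray
    V: np.ndarray
    theta_a: Optional[np.ndarray] = None
    theta_b: Optional[np.ndarray] = None
    sem_theta_a: Optional[np.ndarray] = None
    sem_theta_b: Optional[np.ndarray] = None
    z1: Optional[np.ndarray] = None
    z2: Optional[np.ndarray] = None
    regime: Optional[Sequence[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing 1-D")
        for name in ("V", "theta_a", "theta_b", "sem_theta_a", "sem_theta_b", "z1", "z2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in length")
        if np.any(self.V <= 0):
            raise ValueError("V must be positive")

    def __len__(self):
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_h": self.times, "V_um3": self.V}
        for name, col in (
            ("theta_a", "theta_a_deg"),
            ("theta_b", "theta_b_deg"),
            ("sem_theta_a", "sem_theta_a_deg"),
            ("sem_theta_b", "sem_theta_b_deg"),
            ("z1", "z1_um"),
            ("z2", "z2_um"),
        ):
            v = getattr(self, name)
            if v is not None:
                cols[col] = v
        if self.regime is not None:
            cols["regime"] = list(self.regime)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ShapeTimeSeries":
        def get(col):
            return df[col].to_numpy(dtype=float) if col in df else None

        return cls(
            times=df["t_h"].to_numpy(dtype=float),
            V=df["V_um3"].to_numpy(dtype=float),
            theta_a=get("theta_a_deg"),
            theta_b=get("theta_b_deg"),
            sem_theta_a=get("sem_theta_a_deg"),
            sem_theta_b=get("sem_theta_b_deg"),
            z1=get("z1_um"),
            z2=get("z2_um"),
            regime=list(df["regime"]) if "regime" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "ShapeTimeSeries":
        return cls.from_frame(pd.read_csv(path))


def _interp_volume(times, v_times, v_values):
    times = np.asarray(times, dtype=float)
    v_times = np.asarray(v_times, dtype=float)
    if times.min() < v_times.min() - 1e-9 or times.max() > v_times.max() + 1e-9:
        raise ValueError(
            "requested times extend beyond the volume series; extrapolation is forbidden"
        )
    return np.interp(times, v_times, np.asarray(v_values, dtype=float))


def simulate_shape_series(
    v_series,
    geom: ConfinementGeometry,
    params: SigmoidTension,
    times=None,
    gamma0: float = 1.0,
) -> ShapeTimeSeries:
    """Quasi-static contact-angle trajectory driven by a volume series.

    Parameters
    ----------
    v_series : (times, volumes) pair or ShapeTimeSeries
        Driving volume dynamics; interpolated piecewise-linearly in time.
    geom : ConfinementGeometry
    params : SigmoidTension
        The tension time course; a constant-tension null model is obtained
        with ``c1 == c2``.
    times : array, optional
        Output time grid; defaults to the observation times of the driving
        volume series.

    Each output point is a full equilibrium solve at the instantaneous
    (V, delta); dewetting and boundary pinning are recorded per time point
    as regime labels, never raised.
    """
    if isinstance(v_series, ShapeTimeSeries):
        v_t, v_v = v_series.times, v_series.V
    else:
        v_t, v_v = np.asarray(v_series[0], dtype=float), np.asarray(v_series[1], dtype=float)
    if times is None:
        times = v_t
    times = np.asarray(times, dtype=float)
    V = _interp_volume(times, v_t, v_v)
    deltas = np.atleast_1d(tension_at(times, params))

    theta_a = np.empty_like(times)
    theta_b = np.empty_like(times)
    z1 = np.full_like(times, np.nan)
    z2 = np.full_like(times, np.nan)
    regimes = []
    for i, (t, v, d) in enumerate(zip(times, V, deltas)):
        tens = InterfacialTensions.from_delta(float(d), gamma0)
        if geom.kind == "frustum":
            eq = equilibrium_in_frustum(float(v), geom, tens)
            if eq.bridged:
                z1[i], z2[i] = eq.z1, eq.z2
        else:
            eq = equilibrium_in_cylinder(float(v), geom.r, tens).stable
        theta_a[i], theta_b[i] = eq.theta_a, eq.theta_b
        regimes.append(classify_wetting_regime(eq))
    return ShapeTimeSeries(
        times=times,
        V=V,
        theta_a=theta_a,
        theta_b=theta_b,
        z1=z1,
        z2=z2,
        regime=regimes,
        meta={"params": params, "gamma0": gamma0},
    )
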