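# embryowet

Biophysics of mouse embryo implantation as a droplet-wetting process.

When a mouse blastocyst implants, the mural trophectoderm (mTE) adheres to
the uterine matrix and the embryo's shape inside the uterine crypt changes
from a weakly attached ball towards a spread, invaginating egg cylinder.
`embryowet` models the embryo as a fluid droplet of volume `V` confined in
an idealized crypt — a cylinder of radius `r` or a conical frustum of
half-angle `α` — with droplet–medium tension `γ₀` and Young tension `Δγ`
(droplet–substrate minus substrate–medium). Equilibrium shapes follow from
making

    E = γ₀·A_free + Δγ·A_contact      subject to fixed V

stationary, with the Laplace pressure `ΔP` as the volume multiplier and the
contact angle obeying `cos θ = −Δγ/γ₀`. Adhesion maturation is a
five-constant sigmoid `δ(t) = Δγ/γ₀` (plateaus `c1 → c2` over a window
`[t1, t2]`, modulation `a ≥ 0`), and the normalized tension trajectory is
inferred from measured contact-angle/volume time series by simulation-based
(likelihood-free) inference.

The package is aimed at quantitative developmental biologists and
biophysicists working with light-sheet recordings of ex vivo implantation:
it also reimplements the accompanying measurement operators (contact angle
by radial reslicing, distance-transform middle-axis arc length,
cross-sectional diameter, embryo length, kymograph front tracking, polar-TE
aspect ratios, cell counts and tissue volumes), trajectory statistics
(sliding-window speed, per-axis directionality, nearest-4 neighborhood
persistence, displacement and log-linear staging regressions, developmental
efficiency), and seeded synthetic-data generators so the entire pipeline
runs with no external data.

## Worked example

Simulate an embryo with adhesion switching on around 45 h post-E3.5, add
measurement noise, and re-infer the tension course:

```python
import numpy as np
from embryowet import (ConfinementGeometry, SigmoidTension, PriorSpec,
                       simulate_shape_series, fit_tension)
from embryowet.tension import ShapeTimeSeries

crypt = ConfinementGeometry.frustum(alpha=0.2, z_range=(230.0, 700.0))
truth = SigmoidTension.from_midpoint(c1=0.4, c2=-0.6, t0=45.0, dt=10.0)
times = np.linspace(36.0, 56.0, 20)                  # hours post-E3.5
V = 8e5 * np.exp(0.03 * (times - 36.0))              # μm³, growing embryo

clean = simulate_shape_series((times, V), crypt, truth)
print(f"theta_b: {clean.theta_b[0]:.1f} -> {clean.theta_b[-1]:.1f} deg")

rng = np.random.default_rng(0)
obs = ShapeTimeSeries(times=times, V=V,
                      theta_b=clean.theta_b + rng.normal(0, 3, times.size),
                      sem_theta_b=np.full(times.size, 3.0))
post = fit_tension(obs, crypt, PriorSpec(t0=(36.0, 56.0)),
                   n_sims=10_000, seed=1)
print({k: round(v, 2) for k, v in post.point_estimate.items()})
```

Output:

```
theta_b: 127.5 -> 85.9 deg
{'c1': 0.41, 'c2': -0.62, 't0': 44.82, 'dt': 22.31, 'a': 2.45}
```

The mural contact angle falls from 128° towards 86° as the normalized
tension drops; the posterior median recovers the initial (+0.4) and final
(−0.6) tension and the 45 h mid-time of the switch from the noisy angles
alone (`dt` and `a` are only weakly identified, as expected for a smooth
ramp observed at this noise level).

A command-line interface mirrors the library
(`embryowet simulate-equilibrium | simulate | fit | synth | tracks |
cohort`); see `embryowet --help`.

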