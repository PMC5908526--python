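# spermflow

Elastohydrodynamic simulation of sperm-like swimmers in periodic thin
liquid films, with the analysis statistics of active suspensions.

## Who this is for

Researchers in biological fluid dynamics and active matter who want to
simulate undulatory swimmers whose flagellar dynamics are *resolved* —
rather than coarse-grained into steady dipoles — and to analyse the flows
they generate: force moments, polar/nematic order parameters and energy
spectra.  The package reproduces solitary-swimmer, swimmer-pair and small
suspension experiments on a single workstation.

## Model

Each swimmer is an inextensible elastic flagellum (29 linked segments,
bending modulus `K_B`) clamped to an oblate-spheroid head.  Internal
torques drive the flagellum toward a preferred curvature wave

    kappa_0(s, t) = K_0 A(s) sin(k s - omega t + phi),

with amplitude `K_0 l = 12.76`, wavenumber `k = 2 pi / l`, and a linear
amplitude ramp `A(s)` near the free end.  The frequency follows from the
sperm number `Sp = (4 pi omega eta / K_B)^{1/4} l = 12`.  Swimmers move
in the midplane of a triply periodic film of thickness `L_z = 0.277 d`
(`d` the swimmer length); inextensibility is enforced with Lagrange
multipliers and the motion is integrated with BDF2 + Broyden at 300 steps
per undulation period.

The mobility problem — forces and torques on all segments and heads to
their velocities — is solved either with the **force-coupling method**
(FCM: Gaussian force envelopes, spectral periodic Stokes solve; full
hydrodynamic interactions) or with **resistive force theory** (RFT: local
anisotropic drag, no interactions), whose coefficients can be calibrated
against an FCM reference run.  Because all bodies live on the film
midplane, the FCM mobility is evaluated through precomputed midplane
kernel tables, which makes 30-period runs a matter of minutes while
remaining numerically equivalent to the grid solver.

Per-swimmer undulation frequencies can be redrawn every period from a
lognormal law with standard deviation `sigma_omega` (e.g. `omega/5`).
This single source of variability decides the suspension's fate:
identical frequencies let neighbouring flagella synchronize and aggregate
into clusters, while realistic variability suppresses synchronization and
yields turbulence-like motion.

## Worked example

```python
from spermflow.experiments import solitary_reference

ref = solitary_reference()          # 30 periods, FCM, 6.2 d film
print(f"periods per flagellum length: {ref['periods_per_l']:.2f}")
print(f"mean G11 [F0 d]:  {ref['mean_G11']:.4f}")
print(f"mean K111 [F0 d^2]: {ref['mean_K111']:.4f}")
print(f"|G11| max/mean: {ref['ratio_G']:.1f}")
```

prints (a few minutes on one core):

```
periods per flagellum length: 23.75
mean G11 [F0 d]:  -0.1178
mean K111 [F0 d^2]: -0.2292
|G11| max/mean: 22.1
```

The swimmer needs 23.75 undulation periods to advance one flagellum
length.  The negative period-averaged dipole `G11` identifies it as a
pusher (fluid pushed out fore and aft); the normalization `F0` is the
drag on the head at the mean swimming speed, and the instantaneous dipole
oscillates far above its mean — the time-dependent flow is much stronger
than the average dipolar flow.

A command-line interface wraps the same machinery:

```
spermflow fixture pair --dphi pi/2          # emit a canned pair config
spermflow run --config pair.toml            # simulate, write HDF5
spermflow analyze moments trajectory.h5     # CSV force-moment series
spermflow calibrate-rft                     # fit RFT drag coefficients
```

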