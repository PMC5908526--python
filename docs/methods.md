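# Methods

## Model

A swimmer is a discrete elastic flagellum attached to a cell head, moving
in a triply periodic thin film of fluid at zero Reynolds number.

**Geometry.** The flagellum of length `l` is discretized into `N_flag = 29`
spherical segments of hydrodynamic radius `b` at spacing `ds = l/N_flag`,
each carrying a position and an orientation.  The head is an oblate
spheroid with in-plane half axis `a = 3b` and half height `b`; the overall
swimmer length is `d = 2.1 a + l`, the extra `0.1 a` accounting for the
neck linkage.  In simulation units `eta = 1`, `b = 1`, `d = 70.1`,
`l = 63.8`, `ds = 2.2`.

**Constraints.** Inextensibility and connectivity are imposed exactly
through joint constraints `Y_{j+1} - Y_j = (ds/2)(t_j + t_{j+1})`, an
attachment-point constraint tying the first segment to the head at offset
`1.1 a` along the head axis, and a clamped-end condition aligning the
first tangent with the head axis.  Each constraint carries a Lagrange
multiplier; constraint forces and torques are the exact negative gradients
of `Lambda . g`, so they do no work and exert no net force or torque.

**Actuation.** The flagellum is driven toward the preferred curvature

    kappa_0(s, t) = K0 A(s) sin(k s + Phi + phi),   dPhi/dt = -omega,

with `K0 l = 12.76`, `k = 2 pi / l`, and a ramp `A(s)` that decays
linearly from 1 to 0 over the final `gamma_tip` fraction of the flagellum,
mimicking the reduced waveform amplitude near the tip.  The drive enters
as equal-and-opposite joint torques `K_B (kappa_disc - kappa_0)` with
`kappa_disc = sin(dtheta)/ds`, the negative gradient of the discrete
driven elastic energy `E = (K_B/ds) sum (1 - t_j . t_{j+1}) -
K_B sum kappa_0 dtheta` — actuation is therefore strictly internal.  The
undulation frequency follows from the sperm number,
`omega = Sp^4 K_B / (4 pi eta l^4)` with `Sp = 12`, giving
`omega = 0.17927`, `T = 35.05`, and the time step is `dt = T/300`.

**Tip ramp calibration.** The ramp extent is the single free parameter of
the actuation model.  It was calibrated once against the published
solitary swimming speed (23.7 undulation periods per flagellum length):
speed varies weakly and non-monotonically with `gamma_tip` (24.5 at 0.05,
22.6 at 0.20, 21.8 at 0.30 on the reference film), and `gamma_tip = 0.13`
reproduces 23.7 to 0.2% under the full measurement protocol.  It is the
package default and was not revisited afterwards.

## Hydrodynamics

**Force-coupling method (FCM).** Bodies spread forces onto the fluid with
Gaussian envelopes `sigma = a_h / sqrt(pi)` and torques as the
antisymmetric dipole of a narrower Gaussian `sigma_d = a_h/(6 sqrt(pi))^{1/3}`,
where `a_h` is the hydrodynamic radius (`b` for segments).  The Stokes
equations are solved spectrally in the periodic box and velocities are
read back with the adjoint averaging operators, making the grand mobility
symmetric positive-semidefinite.  The head is carried by a single FCM
particle whose envelope radius reproduces the analytic edgewise
translational drag of the oblate spheroid (effective radii 2.159 for
translation, 2.544 for rotation about the film normal, from the
Oberbeck/Jeffery integrals).  Derivative-like spectral operators zero the
Nyquist wavenumber to preserve Hermitian symmetry; only the rotlet
(antisymmetric) dipole is included, the stresslet correction being out of
scope of the segment model used here.

**Thin film.** The domain is `L x L x L_z` with `L_z = 19.40 = 0.277 d`
and uniform spacing `dx = L_z/64 = 0.3031` (`sigma_b/dx = 1.86`).
Swimmer motion is restricted to the midplane `z = L_z/2`; by symmetry the
midplane of the periodic film behaves like the plane of a free-standing
liquid film, and in-plane interactions are longer-ranged than the 3D
Oseen decay (verified in the tests).

**Midplane kernel tables.** Because every body sits exactly on the
midplane, the FCM mobility reduces to a translation-invariant convolution
in the plane.  The production solver therefore precomputes midplane
kernel tables — 2D inverse transforms of the analytically-enveloped,
kz-summed periodic Stokes response — and evaluates pairwise mobilities by
periodic bicubic interpolation.  This is numerically equivalent to the
grid solver (envelope aliasing ~1e-7 at this resolution, interpolation
~1e-4 relative; equivalence is asserted against the direct
spread/solve/interpolate path in the tests) and makes desk-scale runs
possible: a 30-period solitary run takes minutes instead of days.  The
direct grid path remains the reference implementation and is used for
field snapshots and spectra.

**Resistive force theory (RFT).** The local-drag backend assigns each
segment parallel/perpendicular coefficients (`xi_perp = 2 xi_par`,
slender-body seeds) and the head its Stokes drags; there is no coupling
between bodies, so RFT suspensions interact only sterically.
`calibrate_rft` fits `(xi_par, xi_perp)` by Nelder-Mead in log space so a
solitary RFT swimmer matches the mean speed and lateral waveform envelope
of an FCM reference; self-consistency (recovery of known coefficients
from an RFT-generated reference to <1%) is tested.

## Time integration

The coupled system (positions, orientation angles, multipliers) is
advanced with BDF2 (backward Euler bootstrap on the first step); the
bending term makes the system stiff at `dt = T/300`, so each step solves
the fully implicit nonlinear system.  The unknowns are scaled to make the
residual Jacobian O(1) (lengths by `ds`, multipliers by the force moving
a segment one `ds` per step).  Broyden's inverse-Jacobian secant update
is used in limited-memory form (restart cap 50) with a short backtracking
guard; production stepping seeds it with a per-swimmer block-diagonal
finite-difference Jacobian, refreshed when convergence degrades, and
carries the secant memory across steps (typically 8–15 iterations per
step at residual tolerance `1e-8 sqrt(n_dof)`).  The planar restriction
is structural — the dynamical variables are in-plane positions and a
rotation angle about the film normal — so `U_z = 0` and
`W_x = W_y = 0` hold exactly and the restriction exerts no reaction on
the fluid.  Joint residuals stay below `1e-8 ds` over 30-period runs.

Steric repulsion between non-bonded bodies uses the quartic barrier
`F_S [(R^2-r^2)/(R^2-r_c^2)]^4` with `R = 1.1 (a_i + a_j)` and
`F_S = 15 pi d` at contact; candidate pairs come from a periodic KD-tree
with a re-use skin.  For planar motion the oblate head's in-plane steric
cross-section is the circle of radius `a`, which the spherical barrier
reproduces exactly in the plane.

## Analysis statistics

**Force moments.** The raw moments `D_ij = sum F_i r_j` and
`Q_ijk = sum F_i r_j r_k` are taken about the swimmer's centre of mass in
the frame whose x-axis is the mean swimming direction; `G` is the
symmetric-traceless dipole, `K^S`/`K^A` the symmetric(-traceless in the
first two indices)/antisymmetric quadrupoles.  For the swimmer analysis
the forces are the hydrodynamic drag forces `F^H` (minus the forces
exerted on the fluid): this is the sign convention in which a pusher has
`G11 < 0`.  Moments are reported in units of `F0 d` and `F0 d^2`, with
`F0` the in-plane drag of the isolated head translating at the mean
swimming speed, computed with the same mobility solver (periodic-film
correction included).  The dipole-plus-quadrupole reconstruction of the
swimmer's own midplane flow matches the directly computed field to a few
per cent at separations of 2–5 d (12.45 d box), validating the tensors as
the true flow multipoles.  The quadrupole/dipole crossover radius is
estimated from far-field scaling as `r* = max_t|K111| / max_t|G11|` (in
units of d).  Contributions of the spread torques to the quadrupole are
excluded: the moment operation is defined on the force monopoles, and
rotlets carry no symmetric dipole.

**Order parameters.** `S1 = <p_n . e0>_n` and the planar nematic order
`S2 = <2 (p_n . e0)^2 - 1>_n`, with `p_n` the unit head-minus-tail axis
low-pass filtered over one period (robust to the undulation wobble) and
`e0` the initial swimming direction.

**Spectra.** The fluid energy spectrum sums `(1/2)|u_hat|^2` over
in-plane wavevector shells of width `2 pi / L` (so `sum_k S(k)` is the
mean kinetic-energy density of the midplane flow — Parseval holds to
1e-8); with this shell-sum convention, white (spatially uncorrelated)
forcing of the film yields `S(k) ~ k^-3` at sub-flagellum scales: each
mode carries `|u_hat|^2 ~ k^-4` and shell populations grow like `k`.
The uncorrelated-forcing oracle deposits random point forces on the
midplane, divides out the deposition envelope (exact in Fourier space up
to 85% of Nyquist), evaluates the *film-averaged* (kz = 0) flow — equal
to the midplane flow at scales beyond the film thickness, and the field
whose white-forcing response is quasi-2D — and fits the log-log slope
over `k` in `[0.45, 2.0]`.  (The pointwise midplane slice would instead
pick up the `k^-1` background of all vertical slab modes.)  The swimmer centre-of-mass velocity field is deposited
with a weight-normalized Gaussian kernel of width `d/4` (empty cells
zero), giving the documented noise floor at sub-flagellum scales.  The
low-pass filter is a centred running mean of width `8 T`.

**Clusters.** Aggregation is quantified by connected components of the
graph linking swimmers with minimum body-body distance below `3 b` and
mean-orientation alignment above `cos 30°` — a transparent substitute
metric for cluster growth, checked against a brute-force component
search.

## Scales used in the shipped experiments

The published production suspensions (N = 1000, 200–400 periods, 3072^2
grids) are far beyond a single workstation; the package reproduces the
single-swimmer and pair experiments at full fidelity and the collective
contracts at reduced scale, a deliberate design choice:

- solitary reference: 6.2 d box (1440^2 x 64 effective grid), 30 periods,
  moments averaged over periods 10–30 (~7 minutes);
- pair interaction maps: 4.4 d box, 4 periods per offset;
- collective contracts: swimmer pairs with and without frequency noise,
  and 12-swimmer RFT suspensions over ~8 periods.

Box-size sensitivity of the solitary speed was checked (23.75 at 6.2 d vs
equivalent at 12.45 d within measurement resolution).

## Known limitations

- The exact tip-ramp extent, steric functional form and head treatment of
  the model family implemented here are not fully specified in the literature; the
  choices above are documented and configurable, with `gamma_tip` the one
  calibrated quantity.
- The instantaneous force-moment oscillation (dominated by the 2-omega
  tension dipole) is sensitive to these choices; its relative amplitude
  here (max/mean ~22 for G11) is larger than the published ~5.5, which
  shifts the max-based quadrupole/dipole crossover estimate accordingly.
- Planar waveforms only; no walls; no load-dependent actuation; no
  stresslet-level FCM correction.
- The synthetic placements (jittered lattice, rejection-sampled isotropic
  states) emulate the statistical geometry of the published initial
  conditions but not any particular experimental microstructure; passing
  collective contracts at N ~ 12 demonstrates mechanism, not
  production-scale phenomenology.
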