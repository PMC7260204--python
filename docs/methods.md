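# Methods

## Physical model

The bead is a superparamagnetic sphere (radius r_mb, density rho_mb) whose
magnetization follows the instantaneous external field with an effective
susceptibility chi and no remanence.  Its moment carries the sphere volume,

    m = chi * H_ext * (4 pi / 3) r_mb^3 ,

and its stray field is the standard point-dipole field evaluated from the
bead centre.  chi is a field-calibrated scaling constant (default 0.0256 for
8 um polystyrene micromer-M-type beads, reused for the 2.8 um beads); it
absorbs the nanoparticle loading of the bead shell, so no demagnetising
correction is applied on top of it.  The same moment convention is used in
the potential and everywhere else — mixing conventions rescales every force
by a constant factor.  We checked the convention against the disc system:
with the r^3 convention above, a 20 mT field rotating at 0.9 Hz is
overcritical and produces looping events, as observed; inflating the moment
8x (a diameter-cubed convention) makes the trap deep enough that looping
disappears, which contradicts the observed behaviour.

The bead–structure interaction energy is computed by the magnetostatic
reciprocal theorem: instead of the film's stray field everywhere, only the
bead's dipole field is needed,

    U(s) = -mu0 * sum_cells M_p(c) . [ 2 * H_mb(r_c - s) ] * dV ,

where the factor 2 is the reciprocity factor of the mutual-energy
formulation and position-independent terms (M_p . H_ext, integration
constant) are dropped because only grad U matters.  Each film cell
contributes as a point dipole at its centre; with the bead centre at least
r_mb/2 above a nanometre-thick film this cell-lumping is the controlling
approximation and is validated against brute-force summation and the
two-dipole closed form in the test suite.

Drag is Stokes drag with the linear near-wall correction, in-plane factor
1 + 9r/(16(r+z)) and out-of-plane factor 1 + 9r/(8(r+z))
(z = bead-centre height above its resting height; at contact these are
1.5625 and 2.125).  Water viscosity comes from the Vogel-type correlation
eta(T) = 2.414e-5 * 10^{247.8/(T_K - 140)} Pa s (within ~1 % of handbook
values over 0–100 C; default T = 22 C, eta = 0.955 mPa s), overridable.
Inertia uses the added-mass form m_eff = (4 pi/3) r^3 (rho_mb +
rho_water/2); with micrometre beads the dynamics is deeply overdamped
(m_eff / Gamma_hd ~ 10 us), so an implicit stiff solver is essential.

Dry friction acts only while the bead sits on the substrate:
F_f = -Fc * max(0, -F_mz) * v/|v| — only a downward magnetic load generates
friction (an upward force means imminent lift-off), and there is no static
friction (at rest the direction is undefined; F_f = 0 and drag keeps creep
negligible).  The direction factor is regularised as v/(|v| + v_eps) with
v_eps = 1e-8 m/s, three orders below any transport speed of interest, to
keep the right-hand side Lipschitz at the onset of rest intervals.

Gravity is buoyancy-corrected, F_G = -(rho_mb - rho_water) V g zhat
(simulating in water without buoyancy would be inconsistent with the
added-mass term).  Polystyrene default rho_mb = 1050 kg/m^3.

## Fitting the landscape

Time: each node's potential across the field states of one period is fitted
with a Fourier series of order N by least squares on the sample grid (for
uniform sampling this is the DFT).  Square-wave switching sequences are
built by concatenating each state slab `copies` times; a concatenated
two-state sequence of 200 samples fitted at N = 100 has exactly 2N samples —
the degenerate Nyquist sine column is handled by the minimum-norm solution,
and fewer than 2N samples raises an error.

Space: around every node a 3x3x3 window (5x5x5 optional) is fitted, per
Fourier coefficient, with the 11-term basis (1, x, y, z, xy, xz, yz, xyz,
x^2, y^2, z^2) in local coordinates centred on the node and scaled by the
grid spacing (z by the window's mean layer spacing, so unequal z spacing is
handled).  Because the spatial fit is a fixed linear operator per window
pattern, submatrix coefficient matrices are assembled lazily from the stored
Fourier maps and cached; the max reconstruction residual is recorded per
window.  At non-periodic edges the window shifts inward (the centre stays on
the node); on periodic axes it wraps, giving the overlapping border
submatrices needed for seam-consistent evaluation.  The magnetic force is
the analytic negative gradient of the active polynomial.

Nearest-node selection uses a half-spacing hysteresis: the active submatrix
changes only when the trajectory genuinely leaves the current node's cell,
so chattering at boundaries is avoided.

## Periodic structures

Periodic potentials are summed with a minimum-image wrap of the in-plane
displacement plus +/- n_images whole-period shifts.  The wrap uses the
floor form d - L*floor(d/L + 1/2), which maps d and d +/- L identically even
when a displacement lands exactly on the half-period boundary (commensurate
cell and node grids do this routinely); the resulting maps are periodic to
machine precision, as is evaluation across the seam.  Defaults: 1 image per
side for micrometre-pitch element arrays (neighbouring tiles sit many bead
heights away, and the dipole tile sum converges as distance^-2); 300 per
side along the stripe axis at the full profile, 150 at the coarse profile
(a +/-15 um window around a bead 1.4 um above the film is converged far
below any tolerance used here).

## Time stepping

The equation of motion advances in steps of at most 7e-4 s (also the output
resolution).  At the start of each step the out-of-plane force decides the
regime: at ground level with no net upward force (magnetic z-force plus
buoyant weight <= 0) the 2-D in-plane equation is solved with z frozen and
friction active; otherwise the 3-D equation including gravity is used.  A
3-D step ending below the surface is clamped to z = 0 with v_z = 0.  Within
a step LSODA integrates with rtol 1e-8, atol 1e-12 m on positions and
1e-13 m/s on velocities; if the multistep method reports convergence
trouble (it can at rest onsets, where friction makes the RHS nearly
discontinuous) the step is retried with the Radau IRK method.  After each
step the active submatrix re-centres on the nearest node; boundary wraps,
floor clamps, regime switches and submatrix hops are logged as events.

## Synthetic parent states

Upstream micromagnetic states are not distributed with the package, so the
scenario presets use uniformly saturated shape masks: M = Ms * uhat inside
the element footprint, zero outside, with uhat along the applied field for
soft elements (disc, triangles, ovals — emulating their near-saturated
in-field states) or fixed by the exchange bias for the stripes.  Saturation
values: J_s = 1 T for permalloy, 1.5 T for FeCoSiB.  For a uniformly
magnetised structure whose magnetization follows the field, all field
angles derive from one pass of the reduced stray-tensor field (a 3x3
symmetric tensor per node), exactly equal to per-state summation; for fixed
magnetization a reduced stray-vector field plays the same role.  Both paths
are verified against direct per-state summation.

What the uniform masks do not capture, and the consequences observed:

* A relaxed disc "onion" state concentrates its rim charge at the poles;
  the uniform mask spreads it as cos(phi) around the whole rim.  In-plane
  trajectory features survive (looping occurs at 0.9 Hz; apex distance to
  the disc edge ~11 um), but the out-of-plane repulsion the bead crosses
  during slip is several times weaker, and the simulated looping lift
  (~0.7 um) sits well below the ~3 um seen with relaxed states.
* Relaxed triangle states similarly reshape edge charges; the simulated
  stepwise transport across the lattice (half a unit cell per switch, with
  the characteristic bracket-shaped path) matches, but the landscape along
  the step path stays attractive and the post-switch lift is ~0.01 um
  rather than micrometres.
* Perfectly uniform exchange-biased stripes produce four landscapes whose
  minima all sit within ~1 um of the stripe-edge charge lines; no cyclic
  order of the four field states then walks the bead monotonically across
  the array, and the simulated bead relaxes into a rocking limit cycle at
  z ~ 0.  The real system's micromagnetic response (partial transverse
  demagnetisation at the compensated-bias phase, field-induced z-tilt,
  state inhomogeneities) is what breaks these near-ties; a prescribed
  single-domain response model is available through the per-state grid API
  but still falls short of a full ratchet at the honest force scale.
* The oval track (a convex hull of two arcs, tip radius 6 um, base radius
  10.5 um, 30 um pitch — the outline parameters are package choices) shows
  the intended unidirectional junction-to-junction transport with z = 0 and
  a rest at each junction while the neighbouring potentials overlap; the
  rest duration (~60 ms per half rotation at a 1 um/s speed floor) depends
  on the chosen gap and tip sharpness.

Because the uniform-state potential is quadratic in the field direction it
is exactly 180-degree periodic in field angle; reversal-symmetric relaxed
states share this property, so rotating-field scenarios advance the bead
twice per field rotation.

## Scenario presets and problem sizes

All physical parameters follow the published systems: chi = 0.0256,
Fc = 0.03, mu0 Hext = 20 mT, T = 22 C; disc r = 15 um / 30 nm film at
0.9 Hz (N = 30); triangles side 15 um / 50 nm film, 30/150 deg switching at
1 Hz (N = 100, 100 copies per state); stripes 10 um wide / 20 nm film,
12.5 um period, (Hy, Hz) four-state switching at 3 Hz (N = 50), 2.8 um
bead; ovals 26 x 21 um / 50 nm FeCoSiB, clockwise 1 Hz, 180 field angles
(N = 30).  Full-profile grids mirror the published meshes (200x200 nodes /
41 z-layers for the disc, and so on).

The "coarse" profile keeps every physical parameter and scales grids to
desk size: parent grids <= 256x256 cells, potential grids <= 64x64 nodes
and <= 10 z layers, and runs of 6.5 (disc), 4.5 (triangles), 2 (stripes)
and 2.5 (ovals) drive periods.  A convergence check on the disc (doubling
the z-layer count) left the looping metrics unchanged at this resolution.
A single sub-surface layer 0.2 um below ground level supports the z-fit at
the resting height.  Triangle orientation is vertex-up (mirror lines along
30/150 deg), which selects +y transport; the mirrored orientation gives the
mirror path.

## Known limitations

No Brownian motion, bead–bead interactions, lubrication corrections beyond
the linear wall factor, or surface adhesion; exchange-bias states are
prescribed rather than relaxed; binary OVF is not read.  Quantities driven
by the local force amplitude near structure edges (lift heights, stripe
step speeds) inherit the uniform-state bias described above and should be
read as lower bounds; in-plane, geometry-dominated quantities (orbit radii,
step lengths, rest locations) are robust to it.
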