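# Methods

## Physical model

The sample is an ex vivo slab, so the bioheat equation reduces to plain heat
conduction with a laser source:

    rho c dT/dt = k laplacian(T) + Q(r, z),

no perfusion and no metabolic term. The laser deposits energy by the
Beer–Lambert law only: inside the spot, Q(r, z) = mu_a I0 exp(-mu_a z) with
I0 = P / A_spot. Scattering is deliberately ignored — the samples are
characterised by a single absorption coefficient — which has one important
consequence discussed under *Limitations*.

Geometry is 2-D axisymmetric (r, z): default 64 radial × 32 axial cells over
a 2 cm radius and the material's slab thickness (6.5 mm for the liver-like
preset, 5 mm for agar-like). The top surface exchanges heat with ambient air
by convection (default h = 10 W/m²K, ambient 25 °C); the bottom and side are
clamped at ambient, standing in for the sample holder and surrounding
sample mass. The beam enters at normal incidence with a fixed 0.85 cm²
spot (flat-top by default; a Gaussian profile of equal effective area is
available) and a 3 W ceiling.

### Material parameters

| sample | mu_a (1/cm) | k (W/mK) | rho (kg/m³) | c (J/kgK) | thickness |
|---|---|---|---|---|---|
| agar-like | 0.15 | 0.60 | 1000 | 4186 | 5 mm |
| liver-like | 0.90 | 0.52 | 1060 | 3600 | 6.5 mm |

The absorption coefficients follow the reported 808 nm values (agar below
0.20 cm⁻¹; liver 0.80–0.99 cm⁻¹, midpoint taken). The thermal constants are
not measured by the bench study; agar is treated as water-like and liver
takes literature-typical soft-tissue values. Everything is configurable via
YAML and logged (with a config hash) in every run's metadata.

## Numerics

The discretisation is cell-centred finite volume. Fluxes are conductances
times temperature differences, so with insulated boundaries and no source
the scheme conserves ∫rho·c·T dV to round-off at every step — the energy
audit in the tests measures drift at the 1e-14 level per 10 s window even
with the laser on and losses active. On the axis the innermost face has zero
area, so no coordinate-singularity treatment is needed.

Time stepping is explicit Euler. The stable step is computed per grid as
min(rho c V / sum of adjoining conductances) — about 70 ms on the default
grid — and every advance is sub-stepped (safety factor 0.9) so sensor frames
and controller ticks are hit exactly. A raw step above the bound is
rejected. Validation: the surface temperature under constant flux matches
the semi-infinite analytic solution (2q/k)·sqrt(alpha t / pi) to 0.02 %, and
halving the grid spacing changes the 60 s axial surface temperature by
0.03 % — both far inside the 2 % / 1 % tolerances asserted in the tests.

Dirichlet and convective boundaries use half-cell conductances; the
convective top combines the film coefficient and the half-cell conduction in
series. Surface temperatures reported to the sensor are top-layer cell
values; an optional extrapolation to the z = 0 face exists for validation.

## Virtual sensor

Each pixel of the 32×32 array averages the surface temperature over its
footprint cell (3×3 sub-samples of the radially interpolated surface) and
adds independent Gaussian read noise. The footprint is a square of side
2·d·tan(FOV/2) ≈ 14.8 mm (25 mm distance, 33° FOV), centred on the beam
axis; the 49° mounting obliquity of the physical unit is ignored because the
operator re-centres the image on the spot anyway. The controller's process
variable is the mean of the four central pixels — 0-based indices
(15,15), (15,16), (16,15), (16,16), i.e. rows/columns 16–17 when counting
from 1 — which straddle the beam axis and therefore read the peak of the
heating zone. Frames are emitted strictly at multiples of 1/frame-rate
(3 Hz by default; the hardware range 2–27 Hz is enforced).

The bench study does not quantify sensor noise (its ±0.39 °C stability
mixes sensor and process noise), so the default noise sd of 0.1 °C is this
package's choice of a plausible thermopile read noise; it is configurable
and drawn from a dedicated, per-run-seeded stream.

## Controller

The loop refreshes every 350 ms and always consumes the most recent
completed frame (zero-order hold; loop and 3 Hz frame clock are
asynchronous). The first tick records the t = 0 anchor; the first tick at or
past 5 s records the t = 5 anchor, classifies the sample once — a rise
strictly greater than 5 °C keeps g = 0, otherwise g = 30 — and the gain
never changes again. During the window the loop already drives with g = 0
(the firmware initialises the gain to zero). With signed error
diff = measured − target:

- diff < −1.0 °C → 100 % (3 W at full scale);
- diff > +0.6 °C → a configurable floor, default 0 % (the published rule
  only says the drive is "set to a lower value"; off is the safest reading,
  and the formula already hands over continuously at 100 % on the other
  edge);
- otherwise → (50 + g) − diff·(50 − g), clamped to [0, 100].

Threshold ties go to the formula branch (the published inequalities are
strict); a 1e-9 °C tolerance absorbs binary-representation error at band
edges like 43.1 − 42.5. Percent maps linearly to power (100 % = 3 W) and
affinely to drive current between a 0.5 A lasing threshold and 3.5 A full
scale — a parametric stand-in for the diode's calibration curve, which is
configurable and invertible (so averaging current and inverting gives
exactly the average power).

Non-finite readings hold the previous command and flag a fault; a tick
whose frame has not refreshed repeats its command and is flagged stale.

## Protocols and statistics

A temperature-controlled run couples solver, sensor and controller through
two narrow interfaces (frame source, command sink), so the same loop runs
against a CSV frame replay bit-identically — the replay test asserts exact
command reproduction. Fixed-power runs bypass the controller but log
identically. The fixed drive of a contrast pair is the trapezoidal time
average of the controlled run's current trace, inverted through the
calibration — computed within the same simulation rather than taken from
the bench's hardware-specific 1.47/2.11/2.67 W values. Replicates use
base seed + index; a record's metadata carries material, seed, protocol and
config hash. Summary statistics default to the final two-thirds of the run
(post-ramp) and use linear-interpolation quartiles.

The Arrhenius integral Omega(t) = ∫ A exp(−Ea/RT) dtau is evaluated by the
trapezoidal rule on the measured trace. A and Ea are not part of the bench
study; the shipped presets are the classic Henriques–Moritz skin pair
(A = 3.1e98 s⁻¹, Ea = 6.28e5 J/mol) and a commonly used liver pair
(A = 7.39e39 s⁻¹, Ea = 2.577e5 J/mol). Omega is exactly linear at constant
temperature and convex under a linear rise — the package's quantitative
restatement of why feedback control limits damage.

## Problem sizes

The shipped defaults — 64×32 cells, 300 s runs, ~70 ms solver sub-steps,
858 controller ticks, 901 frames — run a full closed-loop experiment in
under a second on one core, so the test suite and the acceptance script
re-simulate everything from scratch on every invocation.

## Limitations

- **No scattering.** With pure Beer–Lambert deposition the liver-like
  surface rises 3.9 °C in the 5 s window at 3 W (agar-like: 0.6 °C), so the
  discrimination step classifies *both* presets as slow-heating (g = 30).
  On the bench, real liver rises faster than 1 °C/s — consistent with the
  fluence build-up that backscattering adds near the surface of a turbid
  medium, which this model omits. The discrimination logic itself is exact
  (the worked temperature pairs reproduce the published outcomes); only the
  coupled simulation lacks a sample fast enough to trigger the g = 0 branch.
  Band containment is unaffected: the closed loop holds the liver-like
  sample at 43.09 ± 0.09 °C (post-ramp, seed-stable) inside [41.5, 43.1] °C.
- **Heat-sunk boundaries.** With the bottom and side clamped at ambient,
  only ~9 % of beam power is absorbed in the thin agar-like slab and it
  plateaus near 31 °C at full power, short of a 42.5 °C target the bench
  did reach (42.10 ± 0.37 °C); an insulating dish model would close part of
  that gap. The controlled-liver and fixed-power experiments, which the
  quantitative checks rest on, are insensitive to this choice.
- The loop rides the upper band edge (mean ≈ 43.09 °C for a 42.5 °C
  target), echoing the bench's slight high bias (42.92 ± 0.39 °C) — a
  proportional controller with these gains has no integral action to remove
  the offset. Excursions beyond the band ± 3 noise-sd are possible at some
  seeds; the band-containment guarantee is about the post-ramp *mean*.
- Not modelled: temperature-dependent optical/thermal properties, phase
  change and charring, moisture loss, beam misalignment, emissivity error,
  sensor dead pixels, perfusion (in vivo use would need all of these
  revisited).
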