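# Methods

`mrtsim` models a compact microbeam radiation therapy (MRT) source built
from a conventional reflection-target x-ray tube and a divergence-matched
multislit collimator, and computes the dosimetric quantities used to
characterise the microbeam field it produces: peak dose, valley dose,
peak-to-valley dose ratio (PVDR), and 10–90% penumbra.

## Geometry

Coordinates: origin at the focal-spot centre, z up along the central beam
axis, x across the slits, y along them.  The tungsten plate (default 5 mm
thick) sits with its beam-facing (entrance) surface 70 mm above the source;
the slit pitch (400 μm) is defined at the exit (top) surface.  Slit k has
its exit centre at k·pitch, a tilt of arctan(k·pitch / 75 mm), and an
entrance centre scaled by 70/75 — every slit axis extended backwards passes
through the focal-spot centre.  Two closed forms follow: the adjacent-slit
tilt step arctan(400 μm / 75 mm) = 18.33 arc min, and an entrance pitch
smaller than the exit pitch by 400·5/75 = 26.67 μm.  A design is rejected as
degenerate when the tilt step exceeds the angular acceptance of a single
slit, arctan(width/thickness).

Manufacturing perturbations add seeded Gaussian tilt and spacing errors and
a deterministic alternating tilt offset (odd slits +ε, even −ε), the
signature of an alternating wire-cutting direction.  A noteworthy parity
property: at the exact design alignment, with a symmetric focal spot, the
transmission of a slit is an even function of its tilt error, so the
alternating offset produces *no* odd/even intensity pattern; the pattern
appears — linearly in ε — as soon as the collimator operates at a small
horizontal offset.  The alternation tests therefore evaluate the property
at a 100 μm offset, the edge of the alignment tolerance of the device.

The anode sits on the low-beam-number (−x) side.  The focal spot is
modelled as the physical line focus on the tilted target: a track of length
w/sin(θ_a) whose apparent width is w·sin(takeoff)/sin(θ_a), where the
takeoff angle is θ_a plus the emission angle toward +x.  The target angle
θ_a is not a published datum for this tube; it was fixed at 10° by
requiring the beam-1 (anode-side) penumbra at 10 mm depth to stay at the
measured ≈20 μm, which demands an apparent anode-side spot of ≈0.15 mm.
The wide-penumbra edge (beam 49) then follows as a prediction.  Setting
`line_focus: false` collapses the spot to a flat 0.4 mm distribution.

## Spectrum and beam quality

The continuum uses the Kramers thin-target form N(E) ∝ (E_max − E)/E in
1 keV bins, with tungsten K lines (58.0, 59.3, 67.2, 69.1 keV; default 8%
of unfiltered fluence) above the K edge, filtered by the inherent 0.8 mm Be
window, 1 mm added Al, and an inherent tungsten self-filtration layer that
stands in for anode self-absorption — the dominant correction to the bare
Kramers shape.  That thickness is the beam-quality calibration parameter:
22.5 μm reproduces the measured first half-value layer of 0.31 mm Cu for
the 160 kV beam (air-kerma-weighted transmission, bracketing root finder,
10⁻⁴ mm).  It is equivalent to a mean bremsstrahlung production depth of
≈4 μm seen through the 10° target, and the heel model below uses exactly
that depth, keeping the two self-filtration terms consistent.  Attenuation
and energy-absorption coefficients for W, Cu, Be, Al, PMMA, water and air
are embedded static tables (1–200 keV, log-log interpolation, duplicated
nodes at the Cu K and W L/K edges) compiled from the standard public
NIST/XCOM compilations.

The heel effect is applied per ray as *differential* self-filtration,
depth·(cot(takeoff) − cot(θ_a)) of extra tungsten, zero on axis by
construction: beams toward the anode are weaker and harder, which produces
the measured rise of peak dose across the field (simulated ≈40% at 1 mm).

## Monte Carlo transport

Photon-only transport with struct-of-arrays batches (everything
vectorised; ~10⁷ effective histories in ~15 s on one core).

*Source.* Directions are importance-sampled through points on the
collimator exit plane — 90% into the slit apertures (enlarged by 40 μm),
10% across the full face — with weights carrying the exact solid-angle
correction of the mixture; the estimator is unbiased for everything inside
the sampled cone, and the plate is modelled wide enough that nothing
outside it can reach the scoring region.

*Collimator.* In the projective coordinate ξ = x·z_exit/z with τ = 1/z,
both the ray and every slit wall are straight lines, so the in-slit
interval of a ray — and hence its exact tungsten path — comes from two
linear inequalities per photon.  No stepping, no voxelisation; grazing rays
get the correct partial attenuation, which is what forms the slit-edge
penumbra.  Photons attenuated below 10⁻³ undergo Russian roulette
(unbiased).  Each transmitted photon contributes a divergence record
(exit position, angular deviation from the local slit axis); for the
extended spot the deviation spread fills the slit acceptance
arctan(50 μm / 5 mm) ≈ 34′, while a point source collapses it to ≈2.3′.

*Phantom.* 100×100×50 mm³ PMMA resting on the collimator (water is a
config option; the measured reference data are also reported in a
water-equivalent phantom, and the choice moves PVDR by <10%).  Interactions:
photoelectric absorption, incoherent scattering from the free-electron
Klein–Nishina distribution (Kahn's rejection method), and coherent
scattering with angles from independent-atom form factors (inverse-CDF in
the squared momentum transfer with Thomson rejection).  Coherent scattering
is *on* by default: at these energies its few-degree deflections displace
photons by 0.5–2 mm over the scoring depths — several pitches — and
omitting it visibly underestimates the valley dose at 5–10 mm.  The
interaction mix is renormalised so the three partial coefficients sum
exactly to the tabulated total.  Energy cutoff 5 keV; photon splitting
(default ×4) at phantom entry for valley statistics.

*Scoring.* Collision kerma with a plane track-length estimator: each
crossing of a scoring plane adds weight·E·(μ_en/ρ)(E)/|cos θ_z| (obliquity
capped at 1/0.05) to the bin at the crossing x; 2 μm bins so the 10 μm and
140 μm metric windows are exact bin unions.  Slits are treated as infinite
along y and the grids integrate over y (1D convention): a bare point source
then scales as 1/z in grid units (x-compression only), and the tests check
true inverse-square on 2D plane crossings separately.  Per-bin variance
comes from the spread over independent seeded chunks.  Electron transport
is replaced by an optional Gaussian blur (default σ 6 μm, a CSDA-range
heuristic for the ≤60 keV secondaries).

## Metrics and detector response

Peak dose = mean over the central 10 μm of a beam; valley dose = mean over
the central 140 μm of a trough, the trough centre being the midpoint
between adjacent peak centres (the symmetric, pitch-consistent choice);
per-beam PVDR uses the mean of the two adjacent valleys and the field PVDR
is the mean over interior beams (edge beams are flagged, one-sided, and
excluded).  Penumbra is the 10%→90% fall-off distance of the *local peak
dose* (valley not subtracted; a subtracted variant is a flag away), with
crossings confirmed by two consecutive samples below the level to be robust
to per-bin Monte Carlo noise, then refined by linear interpolation.

The measured 20 μm penumbra at 1 mm depth includes film and microscope
response as well as electron transport.  The canonical analysis therefore
simulates raw (unblurred) profiles and calibrates a single Gaussian
detector-response σ by bisection so the central-beam penumbra at 1 mm
equals 20 μm (σ ≈ 4.5–5 μm results); that σ is then reused at 5 and
10 mm.  For a Gaussian-blurred step the 10–90% width is 2.5631σ, which the
tests use as a closed-form check.

Absolute dose rate is not modelled; a single multiplicative constant
anchors the mean interior-beam peak at 1 mm to the measured 300 mGy/s.
All ratios (PVDR, edge ratios, alternation) are invariant under it.

## Alignment

Relative output versus rigid collimator displacement — horizontal across
the slits, vertical along the beam axis — is the total transmitted
energy-weight per source history (a fluorescence-screen proxy; the screen's
energy response is not modelled).  Common random numbers across scan points
remove most scan noise.  The 95% windows extracted by linear interpolation
come out at ≈100 μm horizontally and ≈1.2–1.4 mm vertically (measured: ±100 μm
and ±1.5 mm).  The vertical plateau is quadratic, not linear: the focal
spot's angular spread dominates each slit's acceptance, so small
distance errors only degrade output at second order.

## Synthetic fixtures

The fixture generator builds trapezoidal microbeam trains (linear flanks
from zero, plateau ≥10 μm, flat trough ≥140 μm) over a pedestal with
optional linear valley taper, odd/even peak alternation and Gaussian noise,
all with closed-form ground truth recorded in the profile metadata: PVDR =
peak/pedestal, 10–90% penumbra = 0.8·flank width, edge ratio = 1 − taper.
They exercise every metric exactly, without any transport.  What they do
not emulate: scatter tails between beams, beam-to-beam pitch growth with
depth, heel-induced asymmetry, or correlated noise from film readout — so
exact fixture recovery validates the metric definitions, not the physics.

## Known limitations

- The simulated valley contains collimator leakage (negligible, <10⁻⁶ of
  the peak) and phantom scatter only.  The measured valley dose rate is
  nearly depth-independent (10.2/11.2/10.7 mGy/s at 1/5/10 mm), which
  points to an additional diffuse pedestal (cabinet scatter, off-focal tube
  radiation) of a few mGy/s that is out of scope here.  Consequently the
  simulated PVDR at 1 mm (≈40) overshoots the measured 30±3, while at
  10 mm — where phantom scatter dominates — simulation and measurement
  agree (15.2 vs 15.5).
- Kerma approximation: energy transferred to electrons is scored at the
  interaction site; the residual electron blur is folded into the
  calibrated detector response.
- Free-electron Compton (no binding/Doppler) and independent-atom form
  factors; fine below a few percent at 50–160 keV.
- No coupled electron–photon transport, no absolute output from tube
  current, no cabinet or detector-hardware scatter.
- The anode angle and the heel production depth are calibrated, not
  measured, quantities; both live in the configuration and are reported
  with every run.
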