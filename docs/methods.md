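# Model and methods

## Overview

`flashchem` models the radiation chemistry of liquid water irradiated
by a synchrotron proton beam, in three layers:

1. closed-form **beam arithmetic** turning machine parameters into the
   expected number of protons entering a microscopic region of interest
   (ROI) per 24 ns micropulse, under UHDR (whole spill in a 50 ms
   pulse) and CDR (flux scaled down by the measured dose-rate ratio,
   726.3) conditions;
2. a calibrated **spur surrogate** that converts each injected proton
   into a ~1 ps radical distribution plus its deposited energy; and
3. a **step-by-step (SBS) chemical-stage engine** that diffuses every
   radical as a Brownian particle in the periodic ROI box and executes
   bimolecular reactions by encounter radius, with proton injections
   merged at their sampled arrival times.

The observable throughout is the chemical yield
G(t) = N(t)/E × 100 in molecules per 100 eV, an intensity quantity:
the instantaneous species count normalised by the cumulative energy
deposited by all injected protons.

## Beam model

The spill charge Q = 4.96 nC extracted over Δ_UHDR = 50 ms gives a mean
proton rate Φ̄ = Q/(eΔ) with e = 1.6×10⁻¹⁹ C.  Within the micropulse
fine structure (width Δ_mp = 24 ns, period T_mp = 143 ns) the
instantaneous rate is Φ = Φ̄·T_mp/Δ_mp.  A Gaussian pencil-beam spot of
σ = 3 mm has central areal flux Ψ = Φ/(2πσ²); the ROI sits at the
centre of a 2×2 spot pattern with spacing a = 5 mm, a distance a/√2
from each (sequentially delivered) spot, so the flux there carries the
factor exp(−(a/√2)²/2σ²).  The expected protons per micropulse through
the R = 50 µm ROI face is n = Ψ R² Δ_mp ≈ 1.96, rounded to 2 when a
schedule is built (`round_protons`).  The CDR condition divides the
areal flux — not the total rate — by the dose-rate ratio; this keeps
rates [1/ms] and fluxes [1/(cm²·ms)] dimensionally distinct and
reproduces both derived CDR values (8.99×10⁶ and 4.49×10⁶ per cm²·ms).
Since n_CDR ≈ 0.0027 (one proton per ~53 µs, far beyond radical
lifetimes), CDR chemistry is modelled as independent single protons.

Proton arrival times are uniform inside each micropulse window; for a
fractional number n < 1 of protons per micropulse, each micropulse
independently receives one proton with probability n (a uniform deviate
per micropulse).  Entry points are uniform over the ROI face — the face
is three orders of magnitude smaller than the spot, so the Gaussian
weighting across it is negligible — and protons travel perpendicular to
the face.  The 2 s inter-pulse delay is represented in the timing
constants but never simulated chemically; all scenarios live within one
pulse.

## Track surrogate

Full track-structure transport is replaced by a Poisson spur model.  A
proton crossing depth L at linear energy transfer (LET) deposits energy
in N ~ Poisson(LET·L/W) discrete events at uniform depths along a
straight track; each event deposits W and spawns radicals whose count
is Poisson(W·G_tot/100) and whose species follow calibrated 1 ps
yields.  Default 1 ps yields (molecules/100 eV): e⁻_aq 4.9, ·OH 5.5,
H· 0.62, H₃O⁺ 4.9, OH⁻ 0.5, H₂ 0.15, H₂O₂ 0.0 — standard low-LET water
radiolysis values for the end of the physicochemical stage, not fitted
here.  Species are drawn independently per radical, so yields match
their targets exactly in expectation; per-spur ionic charge is balanced
only on average (the standard yield sets themselves are not exactly
charge-balanced), a deliberate simplification of physicochemical-stage
correlations.

Spatially each event's radicals are Gaussian around the event point
with SD σ(LET) = σ_base·(LET_ref/LET)^0.2, widening for sparse
(high-energy) tracks as a proxy for longer secondary-electron ranges;
hydrated electrons get an extra thermalization factor (×2.5) because
sub-excitation electrons travel nanometres beyond the heavy-species
spur core before hydrating.  LET values are tabulated at 142.4, 50, 10
and 1 MeV (0.49, 1.19, 4.70, 40.29 keV/µm — entrance to Bragg peak)
with log-log interpolation in between and no extrapolation.

**Calibration.**  σ_base and the electron factor are the surrogate's
free parameters.  They were fixed once by requiring the single-proton
(CDR) 1 µs endpoints at 142.4 MeV to match reference chemistry,
G(·OH) = 3.03 and G(e⁻_aq) = 2.75 molecules/100 eV, giving
σ_base = 0.30 nm and factor 2.5 (`scripts/calibrate_tracks.py` re-runs
the scan; shipped defaults land within ~3% of both targets).  The
calibrated core is narrower than literature spur radii because the
engine uses strict Smoluchowski encounter radii with no partially
diffusion-controlled corrections — smaller reaction cross-sections are
compensated by tighter initial correlations.  All knobs live in the
`[track]` config section.

## Chemical stage

**Diffusion.**  Per-axis Gaussian steps with SD √(2 D dt); defaults
(nm²/s): e⁻_aq 4.9×10⁹, ·OH 2.8×10⁹, H₃O⁺ 9.5×10⁹, H· 7.0×10⁹,
OH⁻ 5.3×10⁹, H₂O₂ 2.3×10⁹, H₂ 4.8×10⁹.

**Reactions.**  Nine standard aqueous channels at pH 7 without oxygen
or scavengers (rate constants in M⁻¹s⁻¹): e+e→H₂+2OH⁻ (5.5×10⁹),
e+·OH→OH⁻ (3.0×10¹⁰), e+H₃O⁺→H· (2.3×10¹⁰), e+H·→H₂+OH⁻ (2.5×10¹⁰),
e+H₂O₂→·OH+OH⁻ (1.1×10¹⁰), ·OH+·OH→H₂O₂ (5.5×10⁹), ·OH+H·→H₂O
(1.5×10¹⁰), H·+H·→H₂ (5.0×10⁹), H₃O⁺+OH⁻→2H₂O (1.1×10¹¹).  Each
channel's encounter radius is the Smoluchowski closure
r = k/(4π(D₁+D₂)N_A); pairs whose minimum-image separation falls below
r react, closest pair first, each particle at most once per step, with
products placed at the minimum-image pair midpoint (water-only products
remove the particles).  Background H₃O⁺/OH⁻ from water autoionisation
is not simulated — only radiolytic species are tracked.

**Periodic boundaries.**  All six faces are periodic: a radical leaving
one side re-enters through the opposite side, and pair distances use
the minimum-image convention.  This emulates the equilibrium influx
from the irradiated surroundings of the ROI.

**Adaptive stepping.**  Steps come from a fixed ladder (module default
{0.1, 1, 3, 10, 100, 1000} ps): the largest rung whose RMS 3-D
displacement of the fastest species present, √(6 D_max dt), stays below
half the smallest gap beyond any reactive pair's encounter radius;
steps are clamped so the clock lands exactly on every injection time.
Species counts change only at reactions and injections, so the engine
records an event history and samples it exactly onto any recording grid
(uniform 2 ps by default; experiment scenarios use a ~400-point
logarithmic grid to resolve both picosecond spur kinetics and the
microsecond tail without holding 5×10⁵ rows per repeat).  Experiment
scenarios use a denser ladder {1, 3, 10, 30, 100, 300, 1000} ps with a
1 ps floor — the same half-gap criterion, quantised more finely — which
was also the setting used during calibration.

**Injection semantics.**  When the clock reaches a proton's arrival
time, chemistry pauses, the track surrogate's 1 ps batch (considered
instantaneous on the chemical timescale) is merged, the deposited
energy accumulates, and the new radicals first react on the following
step.

**Engines.**  Two implementations share these semantics: a reference
numpy path using a periodic KD-tree (also provides a brute-force
all-pairs mode for equivalence testing), and a numba cell-list/Verlet
kernel used by default when numba is importable.  All randomness in the
fast kernel is consumed from buffers drawn by the caller's seeded
generator, so a fixed master seed yields bitwise-identical histories
per engine.  Per-repeat generators derive from the master seed by a
counter scheme.

## Experiments and their scales

CDR: one proton per repeat, 1 µs of chemistry, endpoint statistics over
repeats (default 100; 20 at 1 MeV where tracks carry ~80× more
radicals).  UHDR: n_mp micropulses with 2 protons each, ending 1 µs
after the last micropulse (t_end = n_mp·T_mp + 1 µs).  Reported
uncertainty is the standard error of the mean divided by the mean,
quoted for ·OH.

Default geometry is the reference ROI (50 µm face × 20 µm depth; the
face comfortably exceeds the 16.7 µm one-pulse diffusion span of ·OH).
The test suite and desk-scale studies shrink the problem along two
axes, documented here as the package's chosen study sizes:

- **Depth** is reduced (e.g. 2 µm at 142.4 MeV, 60 nm at 1 MeV).  G is
  intensive, so shorter tracks change only the variance per repeat.
- **Face** is reduced to 0.25 µm for UHDR-vs-CDR comparisons.  This
  raises the concurrent track areal density so that radical clouds from
  different protons actually overlap within a microsecond.  In this
  engine, inter-track recombination requires track separations within
  ~100 nm: pair-separation scans show the two-track yield deficit
  vanishing beyond ~200 nm, because cross-track chemistry at larger
  spacing would proceed through dilute, long-time kinetics that a
  strict encounter-radius SBS scheme at desk-scale step counts cannot
  resolve (sub-nm radii versus multi-nm steps).  The desk-scale FLASH
  comparison therefore demonstrates the mechanism — spatiotemporal
  overlap of radicals from different protons reducing ·OH yield, with a
  monotone, bounded dependence on micropulse count — at an overlap
  density reached by shrinking the box rather than by accumulating
  hundreds of micropulses.

## Numerical choices

- Ladder + half-gap stepping as above; bounds and ladder configurable
  per run.  The Verlet-list skin (12 nm) only trades speed, not
  accuracy: lists are rebuilt whenever accumulated displacement could
  let a pair cross undetected.
- Reaction conflicts resolve deterministically by ascending pair
  distance (stable order); no randomness inside the reaction step.
- Products at the minimum-image midpoint; newly created products react
  no earlier than the next step.
- Well-mixed validity: in a homogeneous single-channel test regime the
  engine's decay matches second-order mean-field kinetics to within a
  few percent once the diffusion transient r/√(πDt) is small; an
  isolated pair reacts at the mean-field rate k/V.  These regimes are
  exercised in the test suite with a synthetic high-rate channel whose
  radius (2.4–7 nm) the fixed test step resolves.
- Degenerate inputs: an empty state advances the clock in one jump; a
  zero-depth track yields an empty batch with zero energy; G(t) is NaN
  wherever no energy has been deposited.

## What the generator emulates — and what it does not

The surrogate reproduces: total deposited energy (LET·L in
expectation), calibrated 1 ps yields independent of LET, event density
scaling with LET (so low-energy tracks are spatially denser), and a
plausible spur-relaxation time course whose 1 µs single-track endpoints
match reference chemistry at 142.4 MeV.

It does **not** transport secondary electrons: there are no δ-ray
sub-tracks, no track-end blobs, and no energy leaving or entering the
ROI through energetic secondaries.  Consequently the spatial structure
beyond the ~nm spur scale is absent, and phenomena carried by the
extended δ-ray halo of high-energy protons — notably inter-track mixing
at micrometre track spacings, and its decrease toward the Bragg peak
where δ-ray ranges collapse — are outside the surrogate's reach.  At
desk scale this shows up as the relative UHDR reduction at 1 MeV coming
out *larger* than at 142.4 MeV when both are forced into the same
overlap-dense box: Bragg-peak tracks carry ~80× more radicals, so once
clouds overlap they recombine across tracks more strongly, whereas the
physical ordering (weaker inter-track effect at lower energy) arises at
realistic spacings through δ-ray structure this model omits.  Passing
desk-scale tests therefore validate the beam arithmetic, the engine's
kinetics and the overlap mechanism's direction and trend — not the
absolute magnitude of FLASH yield changes at clinical geometry, nor
their energy ordering.

Also not modelled: oxygen and scavengers, pH variation, first-order
radical decay channels, dose in Gy, multiple scattering or nuclear
reactions (tracks are straight, monoenergetic, constant-LET), and the
independent-reaction-time (IRT) method.

## Known limitations

- Strict encounter-radius (fully diffusion-controlled) reactions:
  partially diffusion-controlled channels are represented only through
  their Smoluchowski-equivalent radii, compensated by calibration.
- Dilute-phase (sub-µM, > 100 ns) bimolecular kinetics are
  under-resolved at the largest ladder steps; endpoint yields are
  dominated by the dense phase, where steps are small, but slow
  homogeneous tails are truncated.
- H₂O₂ endpoints (~0.29 at 142.4 MeV) sit below typical reference
  values (~0.49): with a zero initial H₂O₂ yield all peroxide must form
  through ·OH+·OH, whose strict Smoluchowski radius is small.  The
  initial-yield table is configurable if peroxide accuracy matters.
- CDR repeats assume strict proton independence; possible slow
  cross-proton H₂O₂ chemistry over ~53 µs gaps is ignored.
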