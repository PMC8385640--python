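# Methods

This note documents the models, numerical choices and known limitations of
`achmap`. It is written for a reader who wants to know precisely what is
being computed, which knobs matter, and what the test suite does and does
not demonstrate about real atrial tissue.

## Scope and pipeline

The package reconstructs, end to end, an in-silico method for locating
atrial parasympathetic (acetylcholine-release) innervation sites from a
grid of unipolar electrograms (EGMs):

1. **Tissue model** — a 2D sheet (5 × 5 cm, 251 × 251 nodes at dx = 0.02 cm
   at full scale) of Courtemanche human atrial myocytes, with diffuse
   fibrosis modeled by replacing nodes with MacCannell active fibroblasts,
   and circular ACh patches (dose 0.1 μM) activating IKACh.
2. **Monodomain solve** — explicit finite differences, flux-form 5-point
   Laplacian with edge-wise diffusion coefficients, Rush–Larsen gating;
   full-edge pacing at cycle length 1000 ms; the last paced beat is kept.
3. **EGM forward model** — the current-dipole integral
   φe(r′,t) = Σ −∇Vm·∇(1/d) dA over all nodes, for a 16 × 16 electrode
   mesh (2 mm pitch, 0.8 × 0.8 mm footprints averaged over 25 punctual
   EGMs, heights z ∈ {0.5, 1, 2} mm), normalized by the height-dependent
   factor (350/250/150) to the clinical 6–7 mV depolarization range, then
   zero-phase filtered (2 Hz high-pass; 2–30 Hz and 2–250 Hz band-passes
   for noisy repolarization/depolarization analysis).
4. **Detection** — automatic delineation of the repolarization window TW
   (grid reference t_ref = median steepest-negative-slope time; t_R = the
   grid-global absolute repolarization peak searched ≥ 100 ms after t_ref;
   TW = [t_R − 30, t_R + 150] ms); per-electrode signed repolarization
   amplitude R_A (largest-|·| local extremum in TW, sign kept) and
   depolarization peak-to-peak D_A (EGM onset → TW onset); ROC-scanned
   thresholds (D grid: 40 values around the global mean in 0.1 mV steps;
   R grid: 1 % steps of the grid maximum spanning −80…+80 %); one-stage
   classification (ACh iff R_A > R_th) for non-fibrotic and uniformly
   fibrotic sheets, two-stage (fibrotic iff D_A < D_th, then a per-region
   R_th) for patchy fibrosis; accuracy / sensitivity / false-positive-rate
   scoring against the generator's exact patch registry.

## Ionic models

**Myocyte.** Full Courtemanche–Ramirez–Nattel state (21 variables),
currents in pA/pF, concentrations in mM. Persistent-AF electrical
remodeling scales g_to × 0.5, g_CaL × 0.3, g_Kur × 0.5; paroxysmal AF is
electrically identical to control. A (g_K1, g_CaL) multiplier grid (±30 %
in 15 % steps, 25 combinations) supports cell-to-cell variability studies.

**IKACh.** Kneller-form current
`g(ACh) · [0.0517 + 0.4516/(1+exp((V+59.53)/17.18))] · (V−EK)` with
`g = GMAX/(1 + 9.13652/ACh^0.477811)`, ACh in μM. The saturating
conductance GMAX is set to 2 nS/pF — a rescaling of the canine value (10)
into the submicromolar dose range — so that 0.1 μM shortens the human
atrial APD90 by roughly half (297 → 152 ms at CL 1000 ms) rather than
nearly abolishing the plateau. This is the decisive free constant of the
reconstruction: with the unscaled canine conductance the ACh-zone
repolarization leaves the delineated window entirely and the detection
premise (positive repolarization peaks over ACh sites, in every substrate)
fails, contrary to the published phenomenology the method rests on.

**Fibroblast.** MacCannell active fibroblast (Vm plus the r/s gates of the
time-dependent K+ current; IK1, NaK pump and Na+ background; Cm = 6.3 pF)
with intracellular K+/Na+ fixed at their steady values. Its integrated
resting potential is about −49.6 mV, consistent with the published model.

**Integration.** Rush–Larsen exponential updates for all 15 gates, forward
Euler for Vm and concentrations; dt = 0.005–0.01 ms (fixed by default, an
optional controller relaxes to 0.01 ms when all |dVm/dt| < 5 mV/ms).
Single cells are pre-paced for 60 s at CL 1000 ms before tissue runs; a
warning is emitted if the last two beats still differ by > 1 % in APD90.

## Monodomain solver

Diffusion coefficients live on lattice edges: d_long = 0.003 cm²/ms
(control/PxAF) or 0.002 (PsAF) along the fiber axis (y), × 0.5 transverse,
× 0.25 on any edge touching a fibroblast. Flux-form differencing makes
no-flux boundaries exact (the spatial mean is conserved to rounding under
pure diffusion). Pacing stimulates the bottom two node rows (40 pA/pF,
2 ms, about twice diastolic threshold).

Measured at dx = 0.02 cm, dt = 0.005 ms: longitudinal CV ≈ 85 cm/s,
transverse/longitudinal ratio 0.688 (√0.5 = 0.707 expected from CV ∝ √D).
Refining dx 0.04 → 0.02 cm changes CV by ≈ 7 %: a standard second-order FD
scheme cannot reach the 0.2 % refinement figure reported for the original
higher-order meshfree/FEM solver, which is out of scope here; the solver
suite pins the magnitude, the monotone refinement direction and the
anisotropy ratio instead.

## Phantom Vm engine

Full-matrix reproduction (≈ 28 configurations) with the PDE solver costs
hours; the experiment pipeline therefore defaults to a kinematic phantom
that is *calibrated against the solver*:

* A planar wave travels along the fiber axis at 70 cm/s (× √(D/D₀) for
  PsAF); each node plays an action-potential waveform.
* Waveforms come from a **coupled-template bank**: a 1D monodomain cable
  (real ionic models, same dx/dt) through an ACh slab of width 1.4 × the
  circle radius — the slab whose boundary-to-area loading matches a disc,
  calibrated once against a 2D reference solve — sampled as a function of
  signed distance to the zone rim. This captures the electrotonic blending
  that dominates the amplitude structure: the zone core repolarizes much
  later than an isolated ACh cell, and tissue just outside the rim earlier
  than the far field.
* Fibrosis: fibroblast nodes play an attenuated (gain 0.30), low-pass
  smoothed (6 ms) copy of the local waveform around the fibroblast rest,
  and everything inside fibrotic patches activates late (4 ± 2 ms jitter).
  The depolarization-amplitude loss over fibrotic regions emerges from the
  fibroblast mixing alone; an optional uniform depression of patch
  myocytes exists but defaults to off, matching the monodomain reference
  (a uniform depression creates a spurious patch-boundary dipole that
  buries the in-patch ACh signature).
* Spatially correlated repolarization-time dispersion (APD coefficient of
  variation 4 %, correlation length 0.3 cm — literature-scale atrial
  values) and Gaussian smoothing over one electrotonic space constant
  (0.5 mm) finish the movie.

Validated against full monodomain runs of the same geometries, the phantom
reproduces electrode-level R_A means and spreads (e.g. non-ACh
0.053 ± 0.141 mV phantom vs 0.047 ± 0.153 mV solver on a matched case) and
the delineated windows to within a few ms. What the phantom does **not**
model: reentry or any non-planar activation, rate dependence, fibrosis-
induced CV slowing beyond a fixed delay, boundary curvature corrections to
the slab-derived templates, and ventricular far field.

## Synthetic noise

The patient noise segments used originally are unavailable. The substitute
is Gaussian noise band-limited to 1–100 Hz with exactly unit power (an
optional 1/f^α tilt is available). The flat default keeps the share of
noise power inside the 2–30 Hz repolarization band (~28 %) comparable to
broadband clinical EGM noise, which is dominated by muscle/mains/electronic
content above 30 Hz; a 1/f-tilted spectrum concentrates ~60 % of the power
in-band and makes any nominal SNR much harsher for repolarization analysis
than the clinical recordings it stands in for. Noise is scaled per
electrode so that 10·log10(P_signal/P_noise) equals the requested SNR, with
signal power measured on the clean EGM over the analyzed beat.

The analysis window is a property of the simulated case: it is delineated
once on the clean 2-Hz-high-passed EGMs and reused for every noise level of
that case. Delineating on 0 dB signals instead occasionally locks t_R onto
a noise excursion and collapses the map, a cliff incompatible with the
graded degradation the method is reported to show.

## Design choices on under-specified points

* **Grid-level t_ref** — median over electrodes of each electrode's
  steepest-negative-slope time.
* **EGM onset** (start of the depolarization segment) — first sample at
  which the grid-max |φ| exceeds 5 % of the grid depolarization maximum.
* **Eq.-3 ties** (|min| = |max| in TW) — resolved to the positive value
  (the ACh signature) and flagged.
* **ROC ties** — among thresholds at the same minimal Euclidean distance to
  (FPR 0, Se 1), the median threshold is returned, which lands mid-gap for
  separable classes.
* **Ground truth** — an electrode is ACh-/fibrosis-true iff its center lies
  inside a patch circle (boundary inclusive). Footprint-partial electrodes
  are the main source of scoring ambiguity.
* **ACh circle counts** per geometry (the published figures are drawings):
  6 × r 0.32, 3 × r 0.5, 1 × r 0.76, and 2 × r 0.5 + 3 × r 0.24 cm —
  chosen once to give comparable total ACh area (1.8–2.4 cm²) inside the
  centrally mapped region; patches are placed uniformly at random without
  overlap, fully inside the mapped region.
* **Fnu layouts** — two named presets (four mid-size patches / two large
  patches, scaled to the domain) stand in for the published drawings.
* **Beats before analysis** — tissue runs use pre-converged single-cell
  states and analyze the second paced beat by default (first beat for the
  calibration cables, whose nodes are likewise pre-converged).

## Problem sizes used by the tests and the acceptance script

The test suite and `scripts/acceptance.py` run the pipeline at the desk
profile: the full 5 × 5 cm domain and 16 × 16 mesh with dx coarsened to
0.04 cm and the phantom engine (two replicate tissue realizations per
configuration; five for the control-tissue summary). The monodomain solver
itself is exercised on strips and small sheets (quiescence, conservation,
planar propagation, CV refinement and anisotropy, substrate effects). A
`full` profile (dx 0.02, solver engine) runs the identical code paths for
overnight-scale reproduction.

## Known limitations

* The exact constants of the updated IKACh dose–response are not public;
  the GMAX = 2 nS/pF choice is calibrated to the published phenomenology
  (see above) and all downstream amplitudes inherit it.
* Under this reconstruction the electrotonic blending ring just outside
  ACh patches carries genuinely elevated repolarization amplitudes; the
  ROC optimum for control tissue therefore sits near 35–55 % of the grid
  maximum — partly above the published 23–41 % band — and rim electrodes
  produce most false positives (full-solver desk run: R_th 44 %, Ac 0.90).
  A sensitivity scan over the IKACh saturating conductance (2–6 nS/pF)
  leaves the threshold level essentially unchanged: it is a property of the
  blending ring, not of the dose.
* With grid-maximum repolarization amplitudes of ~0.4 mV (solver-verified)
  and 0 dB noise of ~0.28 mV RMS (28 % of it inside the 2–30 Hz band), the
  repolarization amplitude ranking is close to chance at the harshest noise
  level; detection accuracy there falls to ~0.5–0.6 rather than the ≥ 0.76
  reported originally, whose repolarization waves must have been several
  times larger relative to the depolarization.
* Fibrosis detection from D_A alone is weak for 20 % patchy fibrosis, and
  misclassified regions propagate into ACh classification; the original
  study reports the same failure mode, though with milder impact.
* 2D sheets, planar pacing only; no collagen obstacles, no regional
  electrophysiological heterogeneity, no arrhythmia induction.
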