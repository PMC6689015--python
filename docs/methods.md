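# Methods

`cine5d` implements a cardiorespiratory-resolved ("5D": x–y–z–cardiac–
respiratory) 3D cine MRI processing chain and a digital phantom that makes
every stage testable without scanner data. This note documents the models,
the parameters that matter, and the choices made where the design was open.

## The processing chain

1. **Continuous acquisition** of Cartesian readout lines under a CIRCUS
   phase-encode schedule, with ECG triggers and a respiratory bellows log.
2. **Beat sorting**: lines between consecutive ECG triggers form one
   heartbeat; pooling a whole beat (most of which is diastole) yields
   volumes whose beat-to-beat differences are dominated by respiration.
3. **Low-resolution per-beat volumes** (~4×4×4 mm central k-space band,
   root-sum-of-squares coil combination), optionally view-shared.
4. **3D motion tracking**: each beat volume is registered to a reference
   beat by multi-resolution deformable registration; the displacement field
   is averaged over a central box covering 1/4 of the FOV per axis, giving
   one (dx, dy, dz) in mm per beat. Positive x = heart moves up
   (towards end-expiration) in the short-axis view.
5. **Respiratory binning**: k-means (k = 4, best of 10 random restarts) on
   the per-beat 3D displacements; the cluster with the most positive x
   centroid is end-expiration (EE), the most negative end-inspiration (EI),
   the two in between are ordered by x. Respiratory depth
   Δd = ‖c_EE − c_EI‖₂.
6. **k-t SPARSE-SENSE reconstruction**, one cardiac cine per respiratory
   phase: argmin_x ½‖Ex − y‖² + λ_t·TV(x) with E = mask∘FFT∘coil-multiply
   and TV the cyclic finite-difference total variation along the cardiac
   axis. Each respiratory phase is solved independently (no respiratory
   regularisation), so respiratory states do not bleed into each other.
7. **Function quantification**: Hough-initialised, elliptically refined
   region-based level-set segmentation of LV and RV per cardiac phase;
   volumes by voxel counting; EDV/ESV = max/min of the per-phase volume
   curve; SV = EDV − ESV; EF = SV/EDV × 100.

## Digital phantom

A torso (intensity 0.2) containing a chest-wall slab (0.55), an LV modelled
as an ellipsoidal shell (cavity 1.0, myocardium 0.35) and an RV crescent
(0.9) formed by subtracting the gap-padded LV epicardium from a larger
ellipsoid. Cardiac contraction interpolates cavity semi-axes between
end-diastole and end-systole with weight sin²(πc) over the cardiac fraction
c; wall thickness grows in systole. LV cavity volume is closed-form
(4/3·π·abc); RV volume is voxelised on a 1 mm grid. Defaults give
LV EF ≈ 53.6 %, RV EF ≈ 43.4 %.

**Respiration.** Inspiration level I(θ) = |sin(θ/2)|^(2·1.4) over the
breathing cycle θ, with per-cycle period jitter (4 %) and amplitude jitter
(8 %). The exponent 1.4 makes the waveform dwell near end-expiration so
that roughly 30–40 % of heartbeats cluster at EE versus ~20–30 % at EI —
the asymmetry reported for free-breathing subjects. The heart is rigidly
displaced by −depth·I(θ) along x plus scaled in-plane components
(fraction 0.3 in y, 0.6×0.3 in z); peak-to-peak SI excursion defaults to
10 mm. The chest wall follows the same waveform with an optional phase lag
(thoracoabdominal asynchrony); the bellows records the chest wall, not the
heart. Respiratory sinus arrhythmia modulates the instantaneous heart rate
within heart_rate_base ± rsa_amplitude (default 60 ± 4 bpm), slowest at EE.

**Acquisition model.** Each readout line is one kx column of the
orthonormal 3D DFT of (coil map × instantaneous volume), plus complex
Gaussian noise (σ relative to the peak tissue intensity). Eight smooth
Gaussian-magnitude coil maps with distinct linear phases, normalised to
unit RSS. DC sits at index ⌊N/2⌋, 0-based. Partial Fourier (75 % per axis)
is implemented as asymmetric truncation with zero-filling — linear, no
homodyne. To keep simulation tractable the cardiac fraction is quantised to
25 bins per beat and the displacement to 0.5 mm; lines sharing a state
reuse one FFT set (`resp_quant_mm=0` gives exact per-line rendering).

**What the phantom does not emulate:** bSSFP signal physics (banding,
relaxation, flow), through-plane cardiac motion, non-rigid respiratory
deformation of the heart (the displacement is rigid), papillary muscles,
arrhythmia beyond RSA, receiver-chain imperfections. Passing tests
demonstrate that the *processing chain* recovers what the model contains;
they do not certify performance on patient data.

## CIRCUS sampling dialect

The ky–kz plane is partitioned into concentric square rings around DC. One
interleave takes one point per ring; the point chosen from ring r on
interleave t sits at perimeter fraction frac(t·φ + c·r/R_max) with φ the
golden-ratio conjugate and c = 1.5 the spiral-twist parameter. Selections
falling outside the partial-Fourier region or colliding with an
already-used point advance deterministically along the perimeter, so
coverage is collision-free until a ring is exhausted. Any contiguous run of
interleaves is therefore a valid variable-density subset (ring 0 is
revisited every interleave). The exact point-ordering of the original
sequence is not public; this construction is the package's dialect,
isolated in `circus_schedule` so another can be swapped in. The number of
interleaves per schedule defaults to (in-region points)/(number of rings),
one full coverage cycle; this is a package default, not a protocol value.

The PSF peak-to-sidelobe incoherence property is evaluated without partial
Fourier: the PF truncation edge adds a fixed coherent sinc sidelobe that is
a property of the cutoff, not of the interleaving.

## Motion tracking

Registration is SimpleITK's symmetric-forces demons over a 3-level pyramid
(shrink 4/2/1, iterations 100/80/60), displacement-field Gaussian
smoothing 0.8 voxels, images normalised to their 99.5th percentile. A
Mattes-mutual-information B-spline registration is selectable
(`similarity="mi"`) and is sampled onto the same dense-field
representation; the default is the intensity-difference engine because the
per-beat volumes are monomodal. Fields are stored in mm so resolution
changes cannot silently rescale traces.

Two properties of the box-averaged trace are worth knowing. First, the
average dilutes the heart's displacement with near-static tissue inside the
box, compressing amplitudes by ~10–20 %; Δd inherits this compression.
Second, the trace is relative to the *reference beat volume*, whose
effective position is the beat's time-average, not exactly the t = 0
position — a constant offset that k-means clustering (translation
invariant) and Δd ignore. Accuracy benchmarks therefore compare trace
shape (RMSE after rendering beats at known displacements, correlation)
rather than raw offsets.

At the desk-scale 64³ grid the 4 mm tracking band is the whole phase-encode
grid, so view-shared lines (acquired at other respiratory positions) would
contaminate every spatial scale of the beat volumes; the end-to-end harness
tracks from own-beat, zero-filled volumes. View sharing remains the default
in the gating API and is what a full-resolution acquisition would use,
where the shared content is genuinely high-frequency.

## Reconstruction

ISTA (monotone proximal gradient) with unit step — the encoding operator
has norm ≤ 1 for unit-RSS coil maps — and the cyclic-TV proximal map
evaluated per voxel time-series by Chambolle's dual projection (20 inner
iterations by default; the prox is inexact at the 1e-3 level, which the
monotonicity tolerance absorbs). λ_t defaults to 0.02 × the maximum
temporal finite-difference magnitude of the zero-filled reconstruction — a
scale-free heuristic; no reference value exists for it. Divergence (five
consecutive objective increases beyond tolerance) aborts with diagnostics.
Arithmetic is single precision with per-coil loops to bound memory.

Coil sensitivities are estimated from the time-averaged k-space centre
(Hamming-apodised ~8 mm band) normalised by root-sum-of-squares, zeroed
below 5 % of peak RSS.

## Segmentation

Per short-axis slice: morphological Chan–Vese evolution from the
initial circle, alternated with a soft attraction toward the mask's
same-area best-fit ellipse (signed-distance blend, weight 0.3 for LV,
0.15 for RV — the crescent is less elliptical). Guards: leakage abort at
3× the initial area; a figure/ground contrast floor (15 % of the volume's
intensity range) that empties slices beyond the cavity; connected-component
selection (the component containing the init centre for LV, the largest
component overlapping the covering seed for RV); and a cross-slice
blood-pool intensity consistency filter that drops slices whose segmented
region is < 0.6× the median inside-intensity. The RV evolution accepts an
exclusion mask; the pipeline passes the dilated LV mask so the contour
cannot cross the septum. ED and ES are the max/min of the per-phase volume
curve after a cyclic 3-point median filter, so a single-phase segmentation
dropout cannot masquerade as end-systole. Basal slice inclusion is a
configuration; phantom runs include all slices.

## Benchmark harness and problem sizes

- **Asynchrony design** (`run_supplement_a`): 48×48×12 at 4×4×8 mm, 60 s
  scans, 3 seeds × asynchrony ∈ {0, π/2}. Oracle bins = k-means on the true
  displacements; reported Dice averages the EE and EI bins. 1D bins come
  from the self-gated SI projection of the k-space centre line.
- **Motion-scale design** (`run_supplement_b`): phantom rendered at
  1×1×4 mm (160×160×20), beats rendered directly in the image domain at
  the true displacements, block-averaged to 4 mm, then tracked — isolating
  tracking accuracy from sampling effects. Depths 4 and 16 mm peak-to-peak
  (±2 / ±8 mm).
- **CS benchmark** (`run_cs_benchmark`): 32×32×8, 8 cardiac phases, 4
  coils, noiseless, retrospective R = 8; NRMSE against the known cine with
  an optimal global intensity scale applied to both methods.
- **End-to-end** (`run_end_to_end`): 64×64×24 at 4 mm isotropic, 60 s
  simulated scan (~60 heartbeats), TR 4 ms, 10 views/segment (40 ms
  temporal resolution), EE and EI cines reconstructed with 25 ISTA
  iterations. These sizes are the package's desk-scale defaults; all are
  configuration, not hard-coded.

## Known limitations

- End-inspiration cines carry the largest intra-bin motion blur (the EI
  cluster spans the widest range of positions), so EI-derived EFs sit
  5–8 points below truth for both ventricles at 4 mm voxels; the EE cines
  recover LV EF within ~1–2 points and RV EF within ~3–5. The 5-point EF
  guarantee is therefore stated for the end-expiration cine.
- The in-plane (y) and through-plane (z) trace components carry small
  amplitudes (≤3 mm) tracked at 4–8 mm voxels; their per-beat noise
  (1.3–3 mm depending on the realisation) is of the same order as the
  2–3 mm gaps between adjacent cluster centroids. With the ~60 heartbeats
  of a 60 s desk-scale scan, 4-means boundary placement is therefore
  realisation-dependent: EE/EI Dice against oracle bins ranges 0.3–0.9
  across phantom seeds, and the EE>EI portion ordering can invert on
  unlucky draws. Longer scans, view-sharing variants, coarser tracking
  bands and symmetric registration averaging shift but do not remove this;
  a full-size acquisition (2.5-minute scan, tracking band that is a small,
  densely covered fraction of a 256×144×30 grid) is structurally more
  favourable on both counts.
- The 1D-vs-3D comparison depends on the chest wall being visible in the
  SI projection; a phantom without a chest-wall structure would make the
  1D surrogate artificially good.
- Single respiratory-phase reconstruction only; a joint 5D reconstruction
  with a respiratory regulariser is out of scope.
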