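# Methods

This note documents the models, estimators and defaults implemented in
`epimap`, the assumptions behind them, and what the synthetic fixtures do
and do not establish about real recordings.

## Units and conventions

Space in mm, time in ms, velocity in m/s (1 mm/ms = 1 m/s), signals in mV,
frequency in Hz. Isochrone and DF maps use the early = red / late = blue
convention; the tag travels with the map objects so plotting code cannot
invert it silently.

## Wavefront model (simulator)

Activation spreads as a multi-source shortest path (Dijkstra) over the
electrode adjacency graph. The travel time of an edge is its Euclidean
length divided by the **harmonic mean** of the endpoint conduction
velocities, so a slow region acts as a resistive element regardless of the
traversal direction. Lesion electrodes are removed from the graph before
the search; electrodes cut off entirely are flagged unreachable. Sources
are electrodes (or points snapped to the nearest electrode) with per-source
onsets; a source on a lesion is a scenario error.

This is deliberately *not* an eikonal/monodomain solver. The mapped
phenomena the pipeline must reproduce — plane waves, retrograde paced
spread from an electrode pair, detour around a non-conducting lesion,
ischemic slow-zone delays, focal ectopy — are all shortest-path phenomena,
and the graph formulation admits an exact independent oracle (exhaustive
path enumeration), which the tests use.

**Metric error.** On an 8-neighbour grid the graph metric exceeds the
Euclidean distance by up to a factor 1.082 (directions midway between an
axis and a diagonal; exact for axis-aligned and diagonal directions).
Radial spread from a point source therefore carries up to ~8% direction-
dependent arrival-time error relative to a continuum wavefront. The
default sinus scenario is a **line source along one grid edge** (plane
wave), which is free of this error; CV-recovery claims are made on plane
waves for this reason, and point-source fixtures are used only where the
quantity of interest (origin localization) is metric-insensitive.

## Deflection waveform

Each activation contributes V(t) = −A·((t−t0)/σ)·exp(−(t−t0)²/2σ²), a
Gaussian-derivative biphasic deflection whose steepest negative slope falls
analytically at t0. Defaults: σ = 2 ms, A = 1 mV. The renderer refuses
sample rates that give σ < 2 samples. Because detection is derivative-
based, this construction makes ground truth exact up to sample
quantization — which is a *feature of the fixture*, not evidence about
morphologically complex real electrograms (fractionated, multiphasic
signals can defeat a single-extremum detector; the validity flags and QC
stand in for the manual review such data receive).

Fibrillatory fixtures are per-channel deflection trains with mean interval
1/DF, relative interval jitter (default 0.1, intervals clipped at 25% of
the mean with a warning), per-deflection amplitude drawn uniformly from
[0.6, 1] × (0.3 mV default scale), and no spatial coherence. They emulate
the *spectral* character of fibrillation (low amplitude, controllable local
rate), not its physics — no re-entry, wavebreak or restitution.

Far-field contamination is one shared QRS-T template (broad σ = 12 ms
biphasic deflection plus a T-like Gaussian hump 160 ms later) on its own
beat schedule (default 72 bpm), scaled per channel, with the clean template
train exposed as a reference lead.

## Preprocessing

- **Bandpass**: order-4 Butterworth, 1–400 Hz default, applied
  forward–backward (zero phase) so activation times are not shifted. The
  single-pass response is −3 dB at the edges by construction; the
  two-pass application squares it to −6 dB — the documented price of zero
  phase.
- **Ventricular beat detection**: squared-derivative energy smoothed over
  25 ms, peaks above 0.25 × max with a 250 ms refractory period, then one
  cross-correlation alignment pass against the first beat (±10 ms search)
  so beats are mutually aligned to a sample.
- **Far-field subtraction**: per channel, sample-aligned windows
  (default 100 ms before to 300 ms after each beat; asymmetric because the
  T-wave trails the QRS) are averaged into a template and subtracted at
  every beat; overlapping windows are truncated at midpoints with a
  warning; samples outside all windows are untouched. Needs ≥ 2 full
  windows.
- **Channel QC** (defaults are package choices, not measured values):
  flatline if RMS < 0.01 mV; saturated if > 5% of samples pin at the
  channel's extreme values; noisy if the > 250 Hz residual RMS exceeds 3 ×
  the cohort median. Precedence: flatline > saturated > noisy.
- **Interpolation** operates on derived scalar maps (activation time, DF),
  not raw traces: inverse-distance-weighted average over good grid
  neighbours, falling back to the 4 nearest good channels; filled values
  are convex combinations, hence bounded by the contributing neighbours.

## Activation mapping

Beats are segmented from the mean squared-signal envelope (25 ms
smoothing, peaks ≥ 0.2 × max, 250 ms minimum separation); window
boundaries sit at midpoints between peaks. Activation time is the argmin
of the central-difference derivative within the window (ties → earliest
sample); the steepest-|dV/dt| alternative is available and coincides on
the simulator wavelet. Isochrone edges are linspace(min, max, 16); the
channel at exactly the max time joins band 14; an all-equal map collapses
to band 0 and is flagged degenerate. "Total activation time" means
max − min over valid channels. Time-lapse frames are half-open
[min + k·Δ, min + (k+1)·Δ) intervals anchored at the map minimum.

CV uses the local plane fit described in the README over the electrode's
8-neighbour grid neighbourhood (or a metric radius), in tangent-plane
coordinates from a local SVD so curved layouts work; neighbourhoods with
fewer than 3 valid neighbours, collinear geometry, or a vanishing time
gradient are skipped. The global figure is the mean ± SD of local
estimates over valid channels — a whole-map average, the natural reading
when no path-based definition is given.

Origin localization returns the earliest valid channel; exact ties break
toward the channel whose neighbours lag it most (the truer source of a
spreading front).

## Frequency analysis

The activation-rate envelope (40–250 Hz bandpass → rectification → 20 Hz
lowpass) is the default spectral front end because naive rectification of
an oscillatory signal doubles its apparent frequency; `rectify_only` is
kept as the literal alternative and the doubling is pinned by a test.
Spectra are Hann-windowed averaged periodograms (2 s segments, 50%
overlap → 0.5 Hz resolution at 2048 Hz), density-scaled so a unit
sinusoid's band-integrated power is ~0.5. Band integrals treat bins as
piecewise-constant densities with partial end-bin overlap, so a flat
spectrum integrates exactly proportionally to bandwidth: with the ±0.75 Hz
RI window and 3–15 Hz search band, flat-spectrum RI = 1.5/12 = 0.125.

DF is the argmax of band power (tie → lowest frequency); RI is the
DF-window-to-band power ratio, clipped to [0, 1], 0 by convention for zero
band power. Channels with RI < 0.2 are discarded (retained exactly when
RI ≥ threshold) and filled by interpolation. Note that the RI of a
genuinely flat (noise) spectrum is a *selection-biased* estimate at finite
averaging — the window is centred on the empirical argmax — so reliably
discarding noise-only channels needs enough Welch segments (≈ 15 averaged
segments, i.e. ~16 s at the defaults, brings pure-noise RI safely below
0.2); the threshold itself is applied exactly regardless.

## Shell curvature

Gaussian curvature by angle deficit with barycentric area weights
(one-third of incident face areas): exact total-curvature conservation
(Σ K_v A_v = 2πχ, Descartes), positivity of weights by construction, and
convergence of per-vertex K to the analytic 1/r² on refined spheres.
Voronoi-mixed weights would change per-vertex normalization slightly but
not the totals; barycentric was chosen for simplicity and robustness on
the obtuse triangles common in decimated shells. Boundary vertices use a
π deficit and are flagged; total curvature refuses open meshes since the
boundary geodesic-curvature term is not computed. Mesh I/O (STL/OBJ/PLY)
goes through trimesh with processing disabled so vertex coordinates are
preserved as stored; zero-area faces are dropped with a logged count.

## Problem sizes and determinism

Fixture defaults: 16 × 16 electrodes at 3.5 mm, 2048 Hz, 2 s rhythm
fixtures (3–4 beats at 114 bpm), 8 s fibrillatory fixtures (0.5 Hz
spectral resolution), 20 dB SNR for noisy-recovery studies, 10–20 seeds
for seed-averaged estimates. All randomness flows from explicit
`numpy.random.default_rng(seed)` generators: identical (scenario, seed)
pairs give byte-identical recordings, and pipeline runs with identical
config + seed give byte-identical artifacts (checksummed in the run
manifest).

## Known limitations

- The geodesic model has no wavefront curvature, anisotropy or restitution;
  its grid-metric bias is bounded but nonzero for oblique point-source
  propagation.
- The far-field model is a single shared template with per-channel scaling;
  it does not emulate beat-to-beat QRS-T morphology variation, so the
  subtraction residuals reported on fixtures are a best case.
- Fibrillatory fixtures validate the DF/RI estimators, not AF mechanisms.
- Passing recovery tests on these fixtures demonstrates the pipeline's
  correctness and internal consistency, not detector performance on real
  fractionated or motion-contaminated electrograms.
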