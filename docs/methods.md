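# Methods

This note documents the models, parameter choices and numerical
conventions behind axocalc, and what validation on synthetic data does
and does not establish.

## Ratiometric calibration

Concentrations are obtained from background- and autofluorescence-
corrected channel ratios R = F₃₄₀/F₃₈₀ via

    [Ca²⁺] = K_eff (R − R_min)/(R_max − R),
    K_eff  = K_D (R_max + α)/(R_min + α),

with K_D = 228 nM (Fura-2 in cells). Defaults R_min = 0.5, R_max = 6.0
are typical in-cell values; in practice both are estimated from
ionomycin saturation/depletion recordings as the mean ratio over the
final 20 % of the trace (`plateau_fraction = 0.2`), requiring
R_min < R_max. α defaults to 1.0 for every compartment; its physical
measurement is instrument-specific, so the generator and the analyzer
share the configured value, which keeps round-trips exact. Out-of-range
ratios are made total rather than fatal: R ≤ R_min maps to 0 nM,
R ≥ R_max (or any value that would exceed the reporting ceiling,
default 10 µM) clips to the ceiling, and affected elements are flagged.
The ratio↔concentration pair is an exact algebraic inverse; tests hold it
to 10⁻⁹ relative error. Whether R_min/R_max are global or per-compartment
is a user choice; the global default is used throughout.

## Preprocessing and segmentation

The 380 nm channel is registered onto the 340 nm channel by per-frame
integer-pixel cross-correlation (subpixel registration is out of scope);
constant frames get shift (0, 0) by convention, and shifts beyond
`max_shift` raise an error naming the frame. Background correction
subtracts the time-averaged blank recording (medium, no cells) per
channel per pixel, clipping at a configurable floor (default 0).
Compartment-specific autofluorescence, measured in unloaded neurons, is
subtracted from ROI-mean (or per-pixel) signals before the ratio is
formed; frames with corrected F₃₈₀ ≤ 0 are flagged invalid.

Segmentation thresholds the pixel-wise Pearson correlation of the two
channel traces, computed over the entire recording (a single map per
recording, no sliding window). Pixels with zero variance in either
channel are invalid and excluded. The mask is r ≤ −0.3 followed by
removal of 8-connected components smaller than 10 px; no morphological
cleanup beyond that. The intensity-based baseline combines per-channel
median-projection thresholds by intersection — the stricter reading of
"combined", hence the more favourable baseline to beat. Where a nucleus
annotation overlaps the soma, the nucleus takes precedence; "cytosol"
means the somatic cytosol ring.

## Pixel maps

The per-pixel pipeline applies the identical calculations per pixel:
baseline map = mean of the first 30 frames (7.5 s at the 4 Hz
acquisition this emulates; the window is expressed in frames, with
seconds depending on the configured frame interval), peak-amplitude
map = mean of the 8 frames covering the 2 s stimulation window, located
from the protocol onset and frame interval, never from signal detection.
The distance map is the quasi-Euclidean (8-connected chamfer, weights 1
and √2) shortest path constrained to the mask, computed with a sparse
Dijkstra from the soma centre (annotation-supplied, defaulting to the
soma-ROI centroid snapped to the nearest mask pixel); unreachable pixels
are flagged infinite. Tests verify exact agreement with an independent
explicit-graph Dijkstra on random masks.

## Transport

Kymographs take, at each 1 px arc-length step along the traced path, the
maximum over a perpendicular 3 px band (maximum preserves dim moving
spots better than the mean; width configurable). The automated tracker —
a deliberate replacement for interactive tracing — detects per-frame
ridges above a robust noise floor (median + 5 MAD-σ) with parabolic
sub-pixel refinement and links them greedily under a per-frame
displacement gate (5 px) with a 2-frame gap tolerance, discarding tracks
shorter than 10 frames. It does not disambiguate crossing trajectories;
the round-trip accuracy claim (≥95 % recovered at ≤1 px RMS) holds for
non-crossing, well-separated ensembles at high SNR.

Event segmentation calls an interval a pause when speed stays below
0.05 µm/s for at least 2 s (two frames at 1 Hz); everything else is a run
signed by its displacement, with anterograde = increasing distance from
the soma end (the first path vertex). Adjacent same-type events merge.
"Mobile" is not defined in the transport literature this emulates; the
default is total travelled distance ≥ 2 µm per recording, exposed as a
parameter and recorded in output metadata. "Motor velocity" is the
distance-weighted mean run speed. Distances come from event
displacements, so anterograde + retrograde = total exactly, and binned
distances (30 s bins, boundary-split events allocated proportionally to
overlap) sum exactly to the total. Pooling across axon segments uses the
trajectory `segment` id.

## Statistics

Two-group comparisons apply a Shapiro–Wilk gate per group at α = 0.05
(the gate test is a design choice; constant samples are treated as
non-normal): both normal → two-sided unpaired Student t; otherwise
two-sided Mann–Whitney U, exact when n_a·n_b ≤ 400 without ties, normal
approximation with continuity and tie corrections otherwise —
reproducibility preferred over speed. Stars use strict thresholds
(0.05/0.01/0.001). SD uses the n−1 denominator; binned traces report
mean ± SEM with single-value and empty bins flagged, not fatal. The
whole gate holds its nominal size empirically (rejection rate ≈ 0.049
over 10⁴ null replicates). No multiple-testing correction is applied.
Comparisons can treat mitochondria (default) or recordings as the unit
of analysis.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
fitted.

**Phantom.** A disk soma (radius 8 px) with concentric nucleus
(0.55 R) and somatic-cytosol ring (to 0.8 R), one axon and five
dendrites as jittered random walks rasterised 2–3 px wide, at
0.32 µm/px in a 160 px field. Branch identities are kept for per-branch
amplitude assignment.

**Calcium dynamics.** Each action potential contributes an
instantaneous-rise, exponentially decaying increment (τ = 1.5 s);
increments sum linearly and the summed waveform is rescaled to the
frequency-dependent plateau. The per-AP increment and decay constant are
free parameters of this package, not measured quantities. The
frequency → absolute axonal peak map linearly interpolates the three
characterised paradigms — 2 Hz → 182 ± 17 nM, 20 Hz → 419 ± 76 nM,
100 Hz → 713 ± 211 nM — over a ~50 nM resting baseline (somatic cytosol
100 nM); between-cell amplitude scatter uses the anchored SDs
(truncated normal), switched off in the noiseless preset. The nucleus
filters the waveform through an extra 3 s low-pass (slower rise, 0.8×
amplitude); the cytosol overshoots (1.3×). Dendritic branches carry
static uniform multipliers 1 ± 0.4, optionally augmented by static
per-pixel variation (`pixel_amp_cv`), both reproduced exactly across
repeated stimulations. An axial amplitude gradient parameter exists and
defaults to 0 (spatially uniform axonal response). Recordings emulate
4 Hz × 30 s acquisition for short bursts and 1 Hz × 210 s for the 2 min
paradigm.

**Optics.** Total dye brightness S ≈ 2000 counts splits between the
channels as F₃₄₀ = S·R/(1+R), F₃₈₀ = S/(1+R), so the noiseless ratio
after background (100 counts) and autofluorescence subtraction inverts
the calibration exactly, and responding pixels are anti-correlated by
construction. Bleaching is a common multiplicative decay (0.002 s⁻¹).
Debris objects are drifting Gaussian ellipses, bleaching fast
(0.03 s⁻¹) with a fixed 45/55 channel split — common-mode, hence
positively correlated. Optional bright fibers with a fixed ratio model
non-responsive processes. Noise is Gaussian read noise (6 counts RMS)
plus a Gaussian approximation to shot noise (σ² = expected counts),
emulating a 12-bit widefield camera. No PSF beyond 2-D Gaussian spots,
no immunolabeling or voltage-sensor channels.

**Transport process.** A continuous-time alternating run/pause chain:
run → pause at 0.05 s⁻¹ (mean run 20 s), pause → run at 1/30 s⁻¹ (mean
pause 30 s), stationary moving fraction 0.4; run speeds
truncated-normal 0.5 ± 0.15 µm/s in [0.05, 2]; direction reverses with
probability 0.3 at each run start. Runs reflect at the segment
boundaries — an organelle leaving the traced stretch is modelled as one
entering — which keeps the ensemble stationary; time is continuous and
sampling onto the frame grid (default 1 Hz × 300 s on a 100 µm segment)
happens only at render time. Activity-triggered halting (connecting
segments only) halts each mitochondrion with probability 0.9 at 2 s
after stimulus offset for an Exp(240 s) recovery interval; these values
were set once so that the ensemble binned-distance trace ends near half
its baseline under the default recording, the regime the analysis is
meant to resolve, and are not adjusted thereafter.

**Seeding.** One seed expands into per-stage sub-seeds via
`numpy.random.SeedSequence(seed).generate_state`, indexed by fixed stage
order, so every stage is independently reproducible; all sub-seeds stay
below 2³¹.

## What synthetic validation does and does not show

Passing tests establish internal consistency: the analysis inverts the
forward model exactly in the noiseless limit, segmentation and tracking
degrade gracefully under realistic noise, distances and statistics match
independent oracles, and the end-to-end system resolves a halting effect
of the configured size at the configured n. The generator does not
emulate focus drift, z-motion, dye compartmentalisation or
extrusion, spatially correlated noise, overlapping neurons, or crossing
mitochondrial trajectories; performance on real recordings with those
features is not demonstrated by these tests. The noiseless round-trip
equality of compartment traces additionally assumes within-compartment
spatial uniformity: with heterogeneous dendritic amplitudes the
ROI-level ratio-of-means differs from the mean concentration (an
intrinsic property of ratio imaging, shared by any ROI-based analysis),
which is why the noiseless preset sets the dendritic spreads to zero and
heterogeneity is exercised through the pixel-map analyses instead.

## Problem sizes

Default test and acceptance scenes use 160–192 px fields, 121–361
frames, 200–2000 mitochondria and 10⁴ statistical replicates; these
sizes were chosen to give the ensemble checks (2–3 SEM bands, ≥9/10
seeded concordance) adequate power while keeping a full validation run
in the minutes range on one CPU.
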