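# axocalc

Absolute calcium quantification from dual-wavelength (Fura-2) ratiometric
image stacks, and kymograph-based quantification of axonal mitochondrial
transport — with a synthetic-data generator that renders fully
ground-truthed experiments for validating every stage.

The package is aimed at neuroscientists analysing widefield Fura-2
recordings of cultured neurons (compartment-resolved absolute [Ca²⁺],
pixel-resolution response maps) and mitochondrial transport movies
(run/pause metrics, activity-dependent halting), and at method developers
who need a reproducible benchmark with known ground truth.

## The model

Fura-2 is excited alternately at 340 nm (Ca-bound form dominant) and
380 nm (Ca-free form dominant). After background and compartment-specific
autofluorescence correction, the intensity ratio R = F₃₄₀/F₃₈₀ reports
calcium concentration independently of dye amount:

```
K_eff = K_D · (R_max + α) / (R_min + α)
[Ca²⁺] = K_eff · (R − R_min) / (R_max − R)
```

where K_D = 228 nM for Fura-2, R_min and R_max are the in-cell ratios at
zero and saturating Ca²⁺ (measured with ionomycin + EGTA and
ionomycin + 2 mM Ca²⁺), and α is a correction factor for the unequal
excitation/collection efficiency of the two dye forms.

Segmentation exploits the same physics: at a pixel carrying genuine
ratiometric signal the two channel traces move in opposite directions
(Pearson r < 0 over the recording), while bleaching, cell movement and
fluorescent debris move them together (r ≥ 0). Thresholding the
pixel-wise correlation map at −0.3 isolates the responding silhouette and
rejects contamination that intensity thresholding cannot.

Transport analysis projects single-channel movies onto a traced axon
path (a kymograph: time × position), tracks mitochondria as ridges,
segments each trajectory into anterograde/retrograde runs and pauses, and
summarises per-mitochondrion distance travelled binned every 30 s, mobile
fraction, run velocity and pause counts, with a normality-gated two-group
comparison (Shapiro–Wilk, then unpaired t or two-sided Mann–Whitney U).

The synthetic generator inverts the calibration equation to render
anti-correlated 340/380 stacks from a simulated concentration field on a
compartmentalised neuron phantom (soma, nucleus, somatic cytosol,
dendrites, axon), including shot/read noise, bleaching, moving debris and
non-responsive fibers; mitochondrial movies come from a continuous-time
run/pause process with optional post-stimulus halting. Every output is a
pure function of (parameters, seed).

## Worked example

`examples/02_segmentation_and_traces.py` simulates a 100 Hz 2 s
stimulation recording, segments it by inverse correlation and recovers
absolute compartment traces:

```
correlation mask: 1225 px, Jaccard vs ground truth 1.000
axon       baseline   50.1 nM   peak  789.6 nM
dendrites  baseline   49.9 nM   peak  785.6 nM
soma       baseline   49.7 nM   peak  794.0 nM
nucleus    baseline   50.3 nM   peak  647.9 nM
cytosol    baseline  100.4 nM   peak 1106.8 nM
```

Baselines sit near 50 nM (somatic cytosol ~100 nM); the axonal peak
scatters around the 713 nM mean amplitude configured for 100 Hz bursts
(this seed drew ~790 nM from the between-cell distribution); the nucleus
responds more slowly and the cytosol overshoots, as configured. The other
examples cover calibration algebra (`01`), pixel-resolution maps with
geodesic distance-to-soma analysis (`03`), transport simulation, tracking
and recovery quantification (`04`), and the statistical layer (`05`).

A thin CLI wraps the same library for shell use:

```
axocalc simulate fura --seed 1 --out run/
axocalc run --seed 1 --out run/ --set mito.n_mito=50
axocalc calibrate --saturation sat.csv --depletion dep.csv --out calib.yaml
```

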