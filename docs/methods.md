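# Methods

`junctionkit` implements the computational side of a tight-junction barrier
experiment on endothelial monolayers: functional readouts (transendothelial
electrical resistance, tracer flux), widefield immunofluorescence
quantification, single-molecule localization microscopy (SMLM), and spatial
point statistics. Because such experiments rarely deposit raw data, every
analysis stage is paired with a synthetic generator that emulates the data's
statistical structure with known ground truth; the package's guarantees are
therefore phrased as parameter-recovery and property checks on synthetic
data, not as reproductions of any particular wet-lab measurement.

## Functional assays

TER of a monolayer grown on a porous filter insert is computed as
`TER = (R_raw − R_blank) · A` with the effective insert area `A = 0.33 cm²`
(12-well format). Treatment effects are summarized as fold changes
`TER_t / TER_0`, divided by the mean control ratio of the same experiment;
division (rather than subtraction) is used because treatment effects on
barrier resistance are multiplicative. Tracer (FITC-dextran) flux is read
off an unweighted ordinary-least-squares calibration line `AU = m·c + b`
and reported as `100 · mean(treated c) / mean(control c)`. Conditions are
compared with the classical equal-variance two-sample t-test; degenerate
zero-variance inputs are special-cased (equal means → p = 1, unequal →
p = 0 with a flag) instead of propagating NaNs.

The functional generator produces flat control TER trajectories around a
baseline of 12.9 Ω·cm² with substrate blanks of 121 Ω (polyester) and 88 Ω
(polycarbonate) added back into the raw resistances, so blank subtraction
is exercised downstream. Default treatment effects are a TER fold change of
1.30 at 1 h and 1.41 at 5 h and a flux reduction to 31.7% of control —
the magnitude of a barrier-tightening dipeptide treatment. Replicate noise
is multiplicative lognormal with mean exactly 1 and a configurable CV
(default 0.1, a typical inter-insert variability), so at CV = 0 the
generator's parameters are recovered exactly and at CV > 0 the recovery is
consistent as replicates grow.

## Widefield immunofluorescence

Z-stacks are reduced by maximum-intensity projection. Junction intensity is
the mean grey value per analyzed pixel inside a junction ROI; whole-image
intensity uses a full-true mask. ROI "annotation" is a mask input — in
tests and the demo the mask is rasterized from the known belt geometry, as
the package does not attempt to automate what is a manual step on real
images. Random junction sampling draws non-overlapping square patches
centred on mask pixels.

Whole-filter mosaics are stitched from a rectangular grid of tiles acquired
with ~10% nominal overlap. Pairwise offsets are refined by integer-pixel
normalized cross-correlation of the overlap strips within a ±search window
(default 5 px), falling back to nominal offsets with a warning when the
overlap is featureless; overlapping pixels are blended by linear feathering.
Sub-pixel registration is deliberately out of scope — stage jitter in this
acquisition regime is integer-pixel scale.

The widefield generator renders the belt network with one in-focus slice
and Gaussian-defocused neighbours (blur σ grows 2 px per slice), constant
substrate background ordered glass (100 ADU) < polycarbonate (300) <
polyester (600) — the autofluorescence ordering of these materials — and
optional Poisson noise.

## SMLM localization

The movie's first 30 frames are discarded (photoswitching settling). Per
frame, a robust background level and noise SD are estimated as the median
and 1.4826 × MAD. Candidate spots are strict 8-neighbourhood maxima of the
background-subtracted frame after a matched filter (Gaussian of the nominal
PSF width), required to exceed 3× the noise SD both on the filtered frame
(scaled by the kernel's L2 norm) and on the raw frame. The factor 3 is the
detection threshold in noise-SD units; the matched filter is what makes a
per-pixel threshold operationally meaningful at SMLM signal levels.
Candidates closer than half the fit window are merged keeping the brighter.

Each candidate is fit by least squares (Levenberg–Marquardt, analytic
Jacobian) with a symmetric 2D Gaussian integrated over the camera pixels:
offset, amplitude, x₀, y₀ and a single σ. Fits are rejected with reason
codes on non-convergence, σ outside [0.5, 3]× the nominal PSF σ, a centre
leaving the window, non-positive amplitude, or a singular covariance.
Position uncertainties come from the fit's parameter covariance; the
closed-form Thompson precision `√(s²/N + a²/12N + 8πs⁴b²/a²N²)` is used
only as an independent test oracle. Coordinates follow a half-open pixel
convention — pixel (i, j) spans `[j·p, (j+1)·p) × [i·p, (i+1)·p)` nm with
the origin at the field's top-left — which the localization-accuracy tests
depend on.

Counts are localization-event counts: repeated blinks of one fluorophore
are not merged, so densities in molecules/nm² are event densities and are
not calibrated to absolute molecule numbers. Multi-emitter fitting is not
attempted; overlapping candidates are merged and yield one (possibly
biased) fit, so simulations keep activation sparse (ON probability 0.003
per frame by default).

The SMLM generator uses independent per-frame Bernoulli ON states (no
dark-state memory), an integrated Gaussian PSF with σ = 130 nm (typical for
a 1.46-NA oil objective at 561–642 nm), Poisson shot noise multiplied by
the EM gain (default 100), Gaussian read noise and a constant baseline,
written as 16-bit stacks of 2000 frames at 80 nm/px. The EMCCD
excess-noise factor is omitted (a known limitation: real EMCCD noise is
~√2 higher than Poisson at high gain); saturation clips with a warning.

## Spatial statistics

Clustering is read out from the relative pairwise-distance frequency
spectrum of all same-channel pairs below 200 nm (10 nm bins, half-open);
cross-channel spectra extend to 400 nm. No edge correction is applied:
instead, the complete-spatial-randomness (CSR) reference is simulated
inside an ROI mask with the same number of points, which absorbs edge and
shape effects. The clustering call compares the observed frequency in the
bin containing 40 nm against the pointwise 2.5–97.5% envelope of (by
default 50) CSR simulations; the excess ratio is observed/CSR-mean in that
bin.

The conditioning mask matters. For junction-belt proteins the relevant null
is "spread uniformly along the belt", not "uniform in the 2D membrane
area": a 1D-concentrated pattern has a large short-distance excess over 2D
CSR even without clusters. The pipeline therefore rasterizes the belt at
20 nm/px into a thin support mask for the CSR reference, while the wider
(±400 nm) membrane mask is used only to select localizations and normalize
densities. With this null, dispersed placements stay inside the envelope
and Thomas-clustered placements (parents on the belt, offspring Gaussian
σ = 20 nm) are flagged.

Coordinate-based colocalization counts the percentage of channel-A
molecules with at least one channel-B molecule within 90 nm (the span of
two antibody–fluorophore complexes), each molecule counted once; swapping
the channels swaps the two percentages. All neighbour searches use a k-d
tree and are tested to be identical to O(n²) brute force.

The two-channel generator gives a chosen fraction of channel-A molecules a
partner offset by an isotropic Gaussian with σ = 20 nm (true partners fall
within 90 nm with probability > 0.99); remaining channel-B molecules are
non-junctional background placed uniformly in the field. The colocalized
fraction is only identifiable when incidental neighbours are rare, so the
recovery experiment uses a sparse channel (0.5 molecules/µm of belt over a
40 µm field); at junction-like densities (≳5/µm) belt adjacency alone
produces large colocalization percentages regardless of the generated
pairing — a caveat that applies equally to real junction data.

## Workflow and reproducibility

The four stages (functional → widefield → localization → spatial) run from
one configuration object (YAML-loadable) holding every shared constant:
0.33 cm², 30 discarded frames, threshold 3, 80 nm/px, 200/400 nm ranges,
90 nm radius, 40 nm evaluation bin. All randomness derives from the master
seed through named per-stage `SeedSequence` children, so re-running a
configuration reproduces every numeric output exactly. Each stage writes
its artifacts and a JSON summary fragment; completed stages are skipped on
re-run (deleting a late stage's outputs re-executes only that stage). The
`demo` subcommand runs the reference experiment — a clustered CLDN5-like
channel against a dispersed ZO-1-like channel on a 12.8 µm field of 6
cells, 2000-frame movies — in well under ten minutes on one CPU.

## Default parameter choices

| parameter | default | rationale |
| --- | --- | --- |
| PSF σ | 130 nm | 1.46-NA oil objective at 561–642 nm |
| pixel pitch | 80 nm | EMCCD sampling of the acquisition modelled |
| frames / discard | 2000 / 30 | acquisition protocol; settling period |
| ON probability | 0.003 /frame | sparse-activation regime for single-emitter fits |
| photons per ON frame | 1000 | mid-range single-fluorophore budget |
| belt labeling density | 15 /µm | matches junction event densities of ~10⁻⁴/nm² with ~0.5 µm belt width |
| cluster σ / size | 20 nm / 8 | nanodomain scale probed by the 40 nm bin |
| replicate CV | 0.1 | typical insert-to-insert variability |

## Problem sizes used in tests

Monte-Carlo checks use sizes chosen for tight oracles at desk scale: 500
generator runs for functional recovery, 500 rendered spots for the
precision bound, 100 random instances (n ≤ 2000) for brute-force
equivalence, 50 seeds for the clustering contrast and 20 for colocalization
recovery. `scripts/acceptance.py` re-runs the same computations (200
generator runs for the functional block) and the full demo workflow.

## Known limitations

- No EMCCD excess-noise factor, photobleaching decay, drift, aberrations,
  3D PSF or spectral crosstalk in the simulator.
- No blink-merging: absolute densities are event densities.
- No multi-emitter fitting; high activation densities bias localizations.
- Stitching refines integer-pixel offsets only.
- The synthetic belt geometry is a Voronoi tessellation of uniform seeds;
  real junctions are smoother and curvier, so tests validate the analysis
  operations, not biological realism of the geometry.
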