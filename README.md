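# junctionkit

Quantitative analysis of tight-junction barriers in endothelial monolayers,
covering the four measurement layers of a Transwell-filter experiment —

1. **functional assays** — transendothelial electrical resistance (TER) and
   FITC-dextran flux,
2. **widefield immunofluorescence** — junction-associated intensity per
   analyzed area from z-stacks, with tile stitching,
3. **single-molecule localization microscopy (SMLM)** — blinking movies to
   localization tables by per-frame detection and 2D Gaussian fitting,
4. **spatial statistics** — pairwise-distance clustering spectra against a
   complete-spatial-randomness (CSR) envelope, and coordinate-based
   colocalization of two channels

— together with a synthetic-data generator that emulates each data type
with known ground truth, so every stage is validated by parameter recovery.
It is aimed at groups doing barrier physiology and super-resolution imaging
of junction proteins (e.g. ZO-1 and claudin-5) who want a scripted,
reproducible version of this workflow.

## The core quantities

* **TER**: `TER = (R_raw − R_blank) · A` in Ω·cm², with blank-filter
  subtraction and the effective insert area `A = 0.33 cm²`; treatment
  effects as fold changes `(TER_t / TER_0) / control ratio`.
* **Flux**: tracer concentration from a linear fluorescence calibration,
  reported as percent of control.
* **Localization**: spots above `bg + 3·σ_noise` (robust median/MAD
  estimates, matched-filtered detection) fit with a pixel-integrated
  symmetric 2D Gaussian; the first 30 frames of each movie are discarded.
* **Clustering**: relative pairwise-distance frequency spectrum (0–200 nm,
  10 nm bins); a channel is *clustered* when the observed frequency in the
  40 nm bin exceeds the 97.5% envelope of CSR simulations conditioned on
  the junction-belt support.
* **Colocalization**: percent of molecules in each channel with a partner
  of the other channel within 90 nm (cross-channel spectra to 400 nm).

## Worked example

The `demo` subcommand generates a reference experiment — a clustered
CLDN5-like channel and a dispersed ZO-1-like channel on the same junction
network — and runs all four stages:

```sh
junctionkit demo --outdir demo_out --seed 1
```

This finishes in under a minute on one CPU and prints a summary such as
(abridged):

```json
{
  "ter_fold_1h": 1.204,
  "ter_fold_5h": 1.433,
  "flux_percent_of_control": 29.74,
  "junction_intensity_treated": 1108.7,
  "junction_intensity_control": 855.2,
  "density_per_nm2_CLDN5": 1.086e-04,
  "density_per_nm2_ZO1": 1.090e-04,
  "excess_ratio_CLDN5": 2.087,
  "clustered_CLDN5": true,
  "excess_ratio_ZO1": 0.885,
  "clustered_ZO1": false,
  "pct_ZO1_coloc": 39.96
}
```

Reading it: the simulated treatment raised TER ~1.2–1.4-fold and cut
tracer flux to ~30% of control (one draw at 10% replicate noise from
generator effects 1.30/1.41/31.7%); junction intensity is higher in the
treated rendering; both channels localize at ~1.1×10⁻⁴ events/nm², but
only the CLDN5-like channel shows a 40 nm pairwise-distance excess above
its CSR envelope (ratio 2.1) — the clustered-vs-dispersed contrast the
spatial stage is built to detect. Artifacts (TIFF stacks, localization
CSVs, histograms, masks, `summary.json`, a parameter log) are written
under `demo_out/`; re-running the same configuration reproduces every
number exactly, and stages with existing outputs are skipped.

The same stages are available individually (`functional`, `ifquant`,
`localize`, `spatial`, `run`) driven by a YAML configuration; the library
API mirrors them (`junctionkit.simulate`, `.functional`, `.ifquant`,
`.localize`, `.spatial`, `.pipeline`).

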