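# Methods

This note documents the models and procedures implemented in `lipotrace`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Co-localization classification

Per cell, the classifier selects the *k* pixels brightest in the reference
(neutral-lipid, Bodipy) channel and fits ordinary least squares of the PLIN2
intensity on the Bodipy intensity at those same pixels. The per-cell p-value
is the slope t-test with n − 2 degrees of freedom; a cell is called positive
when the slope is positive and p < α.

Choices and rationale:

- *k* = 50 and α = 0.05 are the conventional defaults of this assay readout.
- "Significant positive correlation" does not pin a sidedness. The default
  is two-sided p < α AND slope > 0 — this is what standard regression
  software reports, and its rejection set equals a one-sided test at α/2.
  A `one_sided_positive` option is provided; type-I calibration is asserted
  under that convention, where the null positive-call rate should be ≈ α.
- Ties at the top-*k* intensity cutoff are broken by raster order
  (row, then col), making the selection deterministic on quantized images.
- Cells smaller than *k* pixels are classified on all their pixels and
  flagged `undersized`; population summaries exclude them by default.
- Per-cell tests are deliberately not corrected for multiple testing: the
  procedure classifies each cell at raw p < α, and the population percentage
  is the quantity of interest.
- No background subtraction is applied by default. The slope t statistic is
  invariant under positive affine transforms of either channel, so constant
  offsets and gains do not affect the classification (asserted numerically
  to < 1e-9 in p).

The t-based p-value is validated against a 10⁵-resample permutation test of
|r| at n = 50 (agreement within 0.01), which holds for the roughly Gaussian
pixel noise the camera model produces.

## Cell detection

The study-style workflow selects at most one region per T cell. Manual
outlining is replaced by a reproducible chain on a configurable channel
(membrane by default): Gaussian smooth (σ = 2 px) → Otsu (or fixed)
threshold → hole fill → 8-connected components → area and circularity
filters (4πA/P², minimum 0.5) → deterministic ordering by centroid.
Externally drawn label masks can be imported instead, so real data with
manual ROIs bypasses detection. Watershed splitting of touching cells is out
of scope; the simulators place non-overlapping cells, matching the
one-ROI-per-cell assumption.

## Raft metrics

Per-cell mean CT-B fluorescence (abundance) and maximal CT-B fluorescence
(clustering) over the whole-cell ROI, averaged per field. "Maximal" is read
as the maximum pixel value, the cell-measurement convention of common
image-analysis software; a `top_fraction` variant (mean of the brightest
fraction of pixels) is provided for robustness to hot pixels, and metrics
can be restricted to a membrane annulus for sensitivity analysis. At fixed
total signal the mean is insensitive to how puncta are arranged while the
max grows with angular clustering — the property the two readouts are
designed to separate, asserted by paired simulation (100 seeds, sign test).

## Dye-dilution generation model

Log10 event intensities are modelled as a mixture of G + 1 Gaussians with
centers fixed at μ₀ − i·Δ (Δ = log₁₀2 for 2-fold dilution), one shared
width σ, and free weights fitted by EM. Weights are initialized from
histogram mass within Δ/2 of each center; σ is fitted (floored at 1e-4 log10
units, which makes the separable σ → 0 limit exact) or fixed. Counts are
soft (expected) assignments by default, hard assignment optional. EM runs to
a 1e-10 parameter tolerance within 1000 iterations and raises with
diagnostics otherwise.

μ₀ defaults to the rightmost histogram peak of the fitted sample; when a
matched unstimulated control is available its smoothed-histogram mode is
used instead (`unstimulated_control_mode`), mirroring how such controls are
carried in practice. A fixed μ₀ can be supplied. The metrics are invariant
to global intensity rescaling when μ₀ is re-estimated.

Percent divided and division index follow the standard precursor-cohort
arithmetic given in the README. Commercial flow-analysis packages use
proprietary peak-fitting constraints, so equivalence is asserted against the
simulator's ground truth (fraction recovery within ±0.02 at n = 20,000,
σ = 0.05 log10), not against any external program.

## Internal-standard lipidomics

Quantification is single-point: amount = intensity ratio to the class
standard × spiked nmol. The packaged standards map transcribes the full set
of 24 spiked amounts; where a class was spiked twice (Cer, S1P) one standard
per class is kept, as the contract requires, and the map is overridable.
Ether/hydroxy/glyco subclasses (PC[O], SM[t], …) fall back to their parent
class's standard through an editable alias table. Any per-sample global gain
cancels in the ratio, which is the point of the design.

Per-sample normalization offers nmol per µg protein (protein amounts must be
user-supplied for real data; the simulator invents them) and total-pool
fractions (rows sum to 1). Differential abundance uses Welch's unequal-
variance t-test on log2 amounts — a robust default for small-n lipidomics —
with the volcano annotated at raw p tiers 0.05/0.01/0.001 and |log2FC| ≥ 2;
a Benjamini–Hochberg FDR column is provided as an extra but is not part of
the tiering rule. Fold-changes are log2 ratios of group means.

VIP scores come from a PLS-DA fit: predictors autoscaled, group encoded 0/1
and centered, 2 latent components by default (common metabolomics practice),
NIPALS decomposition. With unit-norm weight vectors w_a, scores t_a, and
response loadings q_a, SSY_a = q_a²·t_aᵀt_a and

    VIP_j = sqrt( p · Σ_a SSY_a · w_ja² / Σ_a SSY_a )

so Σ VIP² = p by construction (asserted to 1e-9). Degenerate components
(zero weights once the response is fully explained) are discarded;
zero-variance species are dropped with a warning before autoscaling. The
implementation is cross-checked against an independently coded PLS1 NIPALS
to 1e-6.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

- **Co-localization fields** — non-overlapping disk cells (rejection
  sampling, 1000 retries per cell, 6 px separation buffer so smoothed masks
  stay separable), 2–5 disk aggregates per cell with uniform amplitudes; in
  coupled cells pre-noise PLIN2 = gain × Bodipy + background at aggregate
  pixels, background elsewhere. Defaults: 512×512 field, cell radius 12 px,
  background 100, membrane 400. The population-recovery check uses aggregate
  amplitudes of 150–250 counts over background, i.e. peak SNR ≈ 10 under the
  camera model.
- **Raft fields** — per-cell puncta at radial fraction 0.85 of the cell
  radius; angular half-spread (1 − c)·π + c·0.15 rad interpolates from
  uniform (c = 0) to one contiguous arc (c = 1); amplitude is fixed so total
  signal is independent of c.
- **CTV events** — generation drawn per event from the seeded cell-level
  fractions, intensity log-normal with log10 mean μ₀ − i·log₁₀(dilution),
  optional linear autofluorescence floor. Defaults μ₀ = 4.5, σ = 0.05 log10
  units, 20,000 events — a typical well-stained acquisition.
- **Lipid tables** — per-species baselines (0.025–4 nmol scale), seeded
  group log2 fold-changes, log-normal measurement noise at a given CV, a
  log-normal per-sample gain (loading/drift) that the internal-standard
  ratio must cancel, and one standard column per class at the packaged
  amount.

Optics and camera: isotropic Gaussian PSF, then Poisson shot noise on
(signal + background) plus additive Gaussian read noise (sd 2), rounded and
clipped to 16-bit. When all noise is disabled the float-valued image is
returned unchanged so noise-free identities hold exactly. Each generator
uses a single explicit seed (`numpy.random.default_rng`), no global state;
identical seed and parameters give bit-identical output.

What the simulators do **not** emulate: real cell morphology (cells are
disks), 3-D structure, spectral bleed-through, cytometer compensation and
gating, chromatographic artefacts, or class-dependent ionization response
beyond a single response factor per class. Passing tests therefore
demonstrate correctness of the quantification procedures under a clean but
fair camera/mixture model, not robustness to every artefact of real data —
which is why manual ROI import, fixed thresholds, and user-supplied
standards maps are all supported for real inputs.

## Problem sizes and numerics

Validation runs use 10 seeds × 200 cells (1280×1280 fields) for the
population co-localization check, ≥1000 cells for type-I calibration,
10 × 20,000 events for generation recovery, and 100 paired fields for the
raft clustering contrast — sizes at which binomial/Monte-Carlo error is
comfortably inside the asserted tolerances. Degenerate inputs are defined
throughout: constant-x regressions return p = 1 and are flagged rather than
raising; blank images yield zero ROIs with a warning; empty summaries and
unmatched donor pairs raise. FCS binary I/O is not implemented; event tables
are consumed as CSV or DataFrames.
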