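# lipotrace

Quantification toolkit for studies of T-cell lipid biology — the kind of
multi-assay characterization used to compare T cells from chronic lymphocytic
leukemia (CLL) patients with healthy donors. It turns four bespoke,
manually-driven quantification procedures into a tested, reproducible
pipeline, and ships synthetic-data generators with known ground truth so every
stage can be validated end to end without access to the original microscopes,
cytometers, or mass spectrometers.

## What it computes

**Lipid-droplet co-localization (`lipotrace.coloc`).** In each detected
T cell, the *k* = 50 pixels brightest in the neutral-lipid channel
(Bodipy 493/503) are selected and the droplet-coat protein channel (PLIN2) is
regressed on them by ordinary least squares. A cell is "co-localizing" when
the slope is positive and the slope t-test (n − 2 df) is significant at
α = 0.05; the population readout is the percentage of such cells per
condition.

**Lipid-raft metrics (`lipotrace.rafts`).** Cholera-toxin-B (CT-B) binds the
raft ganglioside GM1. Per cell, mean CT-B fluorescence measures raft
abundance and maximal CT-B fluorescence measures raft clustering; fields are
summarized by the average over their cells.

**Dye-dilution proliferation (`lipotrace.flow`).** A proliferation dye
(CellTrace Violet) halves at each division, so events form log2-spaced peaks
in log10 intensity. `DyeDilutionModel` fits a Gaussian mixture with fixed
centers μ₀ − i·log₁₀2, shared width σ, and free weights by EM. From the
generation counts nᵢ:

- percent divided = 100 · Σ_{i≥1} nᵢ / Σ nᵢ
- division index = Σ i·Pᵢ / Σ Pᵢ with precursor counts Pᵢ = nᵢ / 2ⁱ

**Internal-standard lipidomics (`lipotrace.lipidomics`).** Each lipid class
is spiked with one internal standard at a known amount, so

    amount(s, j) = intensity(s, j) / intensity(IS_class(s), j) × nmol(IS_class(s))

with the full table of spiked amounts packaged (e.g. PC(14:0)₂ 2 nmol,
TAG(14:0)₂ 0.5 nmol, SM(d18:1/12:0) 2.129 nmol). Downstream: per-sample
normalization (per µg protein or total-pool fractions), class profiles, Welch
t-tests on log2 amounts with volcano tiers (p < 0.05/0.01/0.001,
|log2FC| ≥ 2), and PLS-DA variable importance in projection (VIP), where
Σ VIP² equals the species count so VIP > 1 marks above-average
discriminators.

## Worked example

```python
import numpy as np
import lipotrace as lt

# a synthetic field: 25 T cells, 70% with PLIN2 coupled to Bodipy at gain 0.8
params = lt.ColocSimParams(n_cells=25, coloc_fraction=0.7, seed=1)
image, truth = lt.gen_coloc_field(params)

rois = lt.detect_cells(image, "membrane")
results = lt.classify_field(image, rois)
print(lt.summarize(results, "simulated"))
# simulated: 16/25 cells positive (64.0%)
print(int(truth.coupled.sum()), "cells truly coupled")
# 16 cells truly coupled

# dye-dilution metrics from 20,000 simulated events
events, _ = lt.gen_ctv_events(lt.CtvSimParams(
    n_events=20_000, generation_fractions=(0.125, 0.125, 0.25, 0.5), seed=7))
res = lt.DyeDilutionModel(
    events, config=lt.GenerationModelConfig(max_generations=5)).fit()
print(f"{res.percent_divided:.1f}% divided, division index {res.division_index:.2f}")
# 87.7% divided, division index 1.21
```

The classifier recovers the seeded coupling (16/25 = 64%, matching the 16
cells the 70%-coupling simulation actually drew), and the mixture fit recovers
the seeded generation structure (truth: 87.5% divided, division index 1.2).

A thin CLI mirrors the library: `lipotrace simulate ctv --seed 3 --out sim/`,
`lipotrace ctv --events sim/events.csv --out metrics.json`,
`lipotrace coloc --images fields/ --out cells.csv`, and
`lipotrace lipidomics vip --intensities t.csv --classes c.csv --groups g.csv
--out vip.csv`.

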