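# habquant

Quantitative analysis of the mouse habenula at single-cell resolution:
a tested reimplementation of the analysis workflow used to classify
medial (MHb) and lateral (LHb) habenula neuron subtypes from droplet
scRNA-seq, and to quantify subtype markers and rabies-tracing signal in
multiplexed FISH images.

The package is aimed at analysts who want to rerun, audit, or extend this
style of habenula (or generally small-brain-region) pipeline without the
original MATLAB/ImageJ/R tooling, and at methods developers who need a
ground-truth-driven test bed for each stage.

## What it computes

**Single-cell track** (`habquant.qc`, `habquant.cluster`, `habquant.de`):

- per-cell QC (nUMI, nGene, percent.mito) with inclusive filters
  (defaults 500 ≤ nUMI ≤ 18000, 200 ≤ nGene ≤ 6000, percent.mito ≤ 0.1)
  and gene filters (total UMI > 5; subset detection ≥ 0.5% of cells);
- log-normalization `x = ln(1 + 10⁴·c/total)` and per-gene OLS regression
  of technical covariates followed by z-scoring;
- PCA (20 components), a shared-nearest-neighbor graph
  (k = 20, Jaccard weights, prune 1/15), and resolution-scaled modularity
  clustering (resolution 1.2, 10 seeded restarts of Louvain-style local
  moving + aggregation);
- an activity-dependent-gene (ADG) module score (set mean minus
  bin-matched control mean over the immediate-early genes *Fos, Fosb,
  Egr1, Junb, Nr4a1, Dusp18, Jun, Jund*), hypergeometric detection of the
  ADG-dominated principal component, and reclustering with that component
  removed — the correction that merges spurious "activated" clusters;
- doublet-cluster flagging from co-expressed class panels, dendrograms
  over cluster-averaged PCs, and rule-based merging of poorly separated
  clusters;
- MAST-style hurdle differential expression: logistic detection part +
  Gaussian expression part with the cellular detection rate as covariate,
  summed-deviance likelihood-ratio test, prefilter
  (|avg_logFC| ≥ 0.25, min detection 0.1), Bonferroni correction.

**Imaging track** (`habquant.imaging`, `habquant.coexpr`):

- automatic cell ROI detection (channel sum → Gaussian smooth →
  Renyi-entropy threshold → hole fill → 4-connected components → area
  filter), with external masks accepted verbatim and an RbV-N-only mode
  for rabies-tracing images;
- background subtraction (mean signal outside all ROIs) and per-channel
  automatic thresholds combining Rényi entropies of orders α = 0.5, 1, 2;
- **fluorescence coverage (%)** — the fraction of pixels in a cell's ROI
  above the channel threshold — the core per-cell measurement;
- positive calls at an explicit coverage cutoff, channel co-expression
  contingency tables, normalized medial/lateral position profiles with an
  anterior/posterior window filter, starter-cell composition, and
  rabies-input proportions reported as mean ± SEM across animals with
  Welch/Holm comparisons between conditions.

**Synthetic data** (`habquant.sim`) generates UMI matrices (planted cell
types, lognormal library sizes, beta mitochondrial load, additive ADG
program, doublets), FISH images (non-overlapping elliptical cells with
controlled per-channel coverage, optional medial/lateral subtype
gradients), and multi-animal tracing datasets (multinomial marker
identities; presets for VTA-GABAergic and VTA-dopaminergic tracing at
48/41/10/2% and 61/20/10/0.7%), each with full ground truth.

## Worked example

Simulate a four-animal rabies-tracing experiment with the VTA-GABAergic
preset, call positives at a 5% coverage cutoff, and report the marker
composition of retrogradely labeled cells:

```python
import pandas as pd
from habquant.sim import generate_tracing_dataset, VGAT_PRESET
from habquant.coexpr import classify_positive, tracing_proportions

animals = generate_tracing_dataset(4, 200, VGAT_PRESET, seed=0)
frames = []
for a in animals:
    df = a.coverage.copy()
    df["animal_id"] = a.animal_id
    frames.append(df)
calls = classify_positive(pd.concat(frames), cutoff=5.0)
report = tracing_proportions(calls, ["Gpr151", "Chrm3", "Vgf", "Sst"])
summary = pd.DataFrame({"mean_pct": 100 * report.mean,
                        "sem_pct": 100 * report.sem})
print(summary.round(1))
print(f"n = {report.n_cells} cells / {report.n_animals} animals, "
      f"cutoff = 5% coverage")
```

prints

```
        mean_pct  sem_pct
Gpr151      46.6      0.9
Chrm3       41.0      1.1
Vgf         10.5      1.0
Sst          1.9      0.4
n = 800 cells / 4 animals, cutoff = 5% coverage
```

Each row is the fraction of RbV-N+ (retrogradely labeled) LHb neurons
positive for one subtype marker, averaged over animals; the error is the
SEM across the four animals, i.e. the biological-replicate error bar.
The configured ground truth here was 48/41/10/2%, so the pipeline
recovers the planted input proportions within sampling error.

The same workflow is available from the shell:

```bash
habquant simulate tracing --n-animals 4 --cells-per-animal 200 --out sim/
habquant fish stats --coverage sim/coverage.tsv --out stats/
```

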