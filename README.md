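# hyperplex

Marker-agnostic phenotyping of hyperplexed spatial-proteomics cell tables —
and the image-quantization utilities such pipelines replace.

## The problem

Multiplexed imaging (CODEX and similar) measures ~30 protein markers per
cell in situ.  After segmentation the data are a table: one row per cell,
spatial coordinates, one mean intensity per marker.  Crossbleed from
neighboring cells makes marker distributions continuous rather than on/off,
so threshold ("gating") analysis discards exactly the low-end signal where
rare populations hide — and the human eye, which distinguishes only a few
dozen gray tones, cannot rescue it visually.  `hyperplex` implements a
threshold-free pipeline for such tables:

1. **Lognormal shrinkage** — per marker, a Gaussian mixture is fitted to
   log-intensities (K by BIC, overlapping components merged) and each cell
   is contracted toward its component center, `x' = c + λ(x − c)`,
   sharpening weakly separated expression modes;
2. **UMAP** embedding of the standardized markers into 2-D;
3. **HDBSCAN** density clustering with minimum cluster size
   `max(20, ⌈5·10⁻⁵ n⌉)`, plus an upfront robust-z discard of aberrant
   cells;
4. **Effect-size marker ranking** — per cluster, every marker is tested
   cluster-vs-rest (Mann–Whitney, BH-adjusted) and significant markers are
   ranked by the standardized mean difference d, binned into tiers
   (|d| ≥ 0.8 / 0.5 / 0.2 → tier 1/2/3), including markers notable by
   *absence* (d < 0).

A synthetic CODEX-style generator (lognormal per-type programs, k-nearest-
neighbor crossbleed, a rare low-SNR population, ground truth) supports
benchmarking, and an `imageops` module provides the classical image
operations — bit-depth posterization, Otsu thresholding, stained-area
quantification, line profiles, log rendering, color deconvolution — used to
demonstrate what eye-guided, threshold-based analysis misses.

For the model details and design rationale see `docs/methods.md`.

## Worked example

```python
import hyperplex as hp
from hyperplex.io import RunConfig

# a rare population (5%) expressing one marker at very low signal-to-noise
table, truth = hp.generate_lowsnr_scenario(n_cells=20000, rare_fraction=0.05,
                                           shift=0.5, seed=1)
out = hp.run_pipeline(table, RunConfig(seed=1, counterstain="DAPI"))
print(out.manifest["counts"])

rare = truth.type_labels == truth.label_of("rare")
for r in out.rankings:
    members = out.result.labels == r.cluster_id
    if (members & rare).sum() > 0.5 * members.sum():
        print(r.top(3)[["marker", "effect_size", "p_adjusted", "tier"]])
```

Output (seed 1):

```
{'n_cells': 20000, 'n_discarded': 0, 'n_noise': 4, 'n_clustered': 19996}
marker  effect_size    p_adjusted  tier
 CKlow     0.850851 2.226566e-102     1
   M01    -0.798213  3.617930e-94     2
   M00    -0.794613  4.128274e-99     2
```

The weak marker `CKlow` — invisible to single-channel Otsu gating, which
recovers only ~37% of the rare cells — is ranked first, tier 1, in the
rare-majority cluster (~89% of rare cells recovered); the next-ranked
markers are the *depleted* structural channels that define this population
by absence.  The
same run writes `cells.csv`, `markers.csv`, a manifest and an embedding/
tissue-map plot when given `out_dir=...`.

The same pipeline is available from the shell:

```
hyperplex simulate --seed 1 --panel lowsnr --n-cells 20000 --out cells.csv
hyperplex run --input cells.csv --seed 1 --out-dir results/
hyperplex image posterize slide.png --bits 4 --out slide4bit.png
```

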