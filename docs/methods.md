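# Methods

## Problem setting

Hyperplexed in-situ staining (CODEX and kin) yields, after nuclear
segmentation, a table of mean marker intensities per cell — typically ~28
antibodies plus a DAPI counterstain, hundreds of thousands of cells.  Unlike
flow cytometry, the spatial signal is contaminated by *crossbleed* from
neighboring cells, so per-marker distributions are continuous and weakly
separated rather than cleanly on/off.  Threshold-based ("gating") analysis of
such channels is limited by exactly this continuity, and the human eye adds
its own ceiling: an observer who distinguishes only ~64 of 256 gray tones
cannot see a signal less than 4 gray levels (256/64) above background.  The
package implements a marker-agnostic pipeline that avoids thresholds
entirely, alongside the classical image-quantization operations (posterize,
Otsu, area quantification, log rendering, color deconvolution) it is
contrasted with.

## Pipeline

For a cell table X (n cells × m markers, non-negative):

1. **Lognormal shrinkage.**  Per marker, intensities are transformed to
   `log(v + ε)` (ε = 1 by default; intensities include zeros) and a Gaussian
   mixture is fitted with K = 1..`max_components` (default 5) selected by
   BIC, ties to the smaller K.  Each cell is hard-assigned to the component
   with the largest posterior responsibility and contracted toward the
   component center:

       x' = c_k + λ (x − c_k),   λ ∈ (0, 1].

   Hard assignment makes the map affine within a component, so pairwise
   distances scale by exactly λ and ordering is preserved.  The contraction
   sharpens weakly separated modes before embedding.  The contraction target
   is the fitted component mean by default; the component-wise empirical
   median is available (`target="median"`), with no practical difference on
   symmetric components.
2. **Standardization.**  Each shrunk column is z-scored.  Constant markers
   are flagged and carried as all-zero columns.
3. **Upfront statistical discard.**  Cells whose total standardized
   intensity has a robust z-score (median/MAD, consistency factor 1.4826)
   above `z_max` = 5, or whose raw counterstain is non-positive, are labeled
   DISCARDED and excluded from embedding and from all in/out comparisons.
4. **Embedding and clustering.**  UMAP (2 components, `n_neighbors` = 30,
   `min_dist` = 0.05, fixed seed) followed by HDBSCAN with minimum cluster
   size `max(20, ⌈5·10⁻⁵ · n⌉)` — the 20-cell floor dominates until runs
   approach half a million cells.  Density outliers are labeled NOISE.
   Cluster ids are contiguous from 0, largest cluster first.
5. **Marker ranking.**  Per cluster, every marker is tested cluster-vs-rest
   (two-sided Mann–Whitney on preprocessed values; DISCARDED cells excluded
   from the comparison), p-values BH-adjusted within the cluster, and
   significant markers ranked by |d|, where d is the pooled-SD standardized
   mean difference.  Tiers bin |d| at 0.8 / 0.5 / 0.2 (tiers 1/2/3;
   significant markers below 0.2 get tier 4) — conventional large/medium/
   small effect bands.  Markers significantly *depleted* (d < 0)
   characterize a cluster by absence.  Each cluster's report has three
   parts: (A) the ranked marker table, (B) the tissue map (member
   coordinates), (C) median/IQR of each diagnostic marker, on raw
   intensities, in-cluster vs whole population.

The test statistic and effect size are deliberately rank-based and
pooled-SD-based respectively: shrunk distributions are multimodal and far
from Gaussian, so a t-test would be miscalibrated, while d remains a useful
*ordering* even when its Gaussian interpretation does not hold.

### Component merging (a necessary guard)

BIC happily spends extra Gaussians approximating a smooth, skewed density —
crossbleed shoulders routinely push K to 4–5 on what is biologically one
population.  Contracting such overlapping pseudo-components apart cuts a
continuous population at arbitrary boundaries and fragments it downstream
into seed-dependent micro-clusters.  After selection, adjacent components
whose center gap is below `merge_threshold` = 4 pooled within-component SDs
are therefore merged (moment-matched).  The calibration: an equal mixture of
two Gaussians becomes bimodal only beyond a 2-SD gap, and at a 4-SD gap the
hard-assignment misclassification rate at the boundary falls to ~2%, so only
modes that can be assigned reliably are kept as shrinkage targets.  Markers
with genuine on/off structure sit well above this gap (ratio ≳ 4.3 in the
synthetic panels) and keep their splits.  `merge_threshold=0` disables the
guard and reproduces plain BIC shrinkage.

### Choice of λ

The contraction strength trades mode sharpening against fragmentation: at
λ = 1 shrinkage is inert; as λ → 0 every component collapses to a point and
any assignment error becomes a separate discrete profile, which the density
clusterer happily splits (47 clusters instead of 5, ARI 0.50, on a 5-type
benchmark at λ = 0.1).  The default λ = 0.7 contracts within-component
spread by 30% — enough to deepen density valleys measurably (see the
bimodality-enhancement test) while keeping populations connected across
benchmarks.  λ is exposed in the config and logged per run.

## Synthetic data

The generator produces the statistical structure the pipeline assumes, with
ground truth:

* Cell positions uniform in a field (default 1000×1000 px); type labels
  multinomial in the prevalences (or exact largest-remainder counts).
* Own signal per marker: `exp(N(μ_t,m, σ_t,m))` — lognormal within type.
* Observed signal: `(1−β)·own + β·mean(own of k=6 nearest neighbors) +
  |N(0, background_sd)|`.  Crossbleed mixes the neighbors' pre-noise own
  signal — a one-pass model that avoids iterative coupling; k = 6
  approximates the contact number of a planar cell packing.  β defaults to
  0.1 (0.05 in the benchmark panels); no quantitative crossbleed magnitude
  is available from real instruments, so β is a documented free parameter.
* Additive background is half-normal to preserve non-negativity
  (`background_sd` = 0.05 on the raw scale, i.e. ~5% of a typical
  unexpressed marker's median signal).

Preset panels: `codex_like_panel` (28 antibodies + DAPI, 8 populations,
fixed seeded programs), `well_separated_panel` (5 populations, prevalences
0.4/0.3/0.15/0.1/0.05, 20 markers, on/off log-means 2.0/0.0 at σ = 0.4 — a
5σ separation, comfortably above the 2σ needed for recovery benchmarks), and
`generate_lowsnr_scenario` (below).

**Low-SNR scenario.**  Five types, ten markers.  Four common types each
express an exclusive pair of structural markers (log-mean 2.0, σ 0.5); the
rare type (5%, exact count) expresses none of them — its profile is
distinctive only jointly, through absence.  One designated weak channel is
shifted by 0.5 log-units in the rare type against a log-SD of 0.7:
single-marker AUC ≈ 0.69, and no marker separates rare from rest at
AUC ≥ 0.75.  This emulates a marker expressed at very low signal-to-noise in
a rare stromal population: invisible to single-channel thresholding (Otsu
gating of the raw channel recovers ~37% of rare cells), but ranked
significant at tier ≤ 2 by the pipeline once the rare cluster is isolated by
its joint profile.

**Test images.**  `ramp` is a horizontal 8-bit gradient containing all 256
values; `posterize_panel` renders it at 8/7/6/5/4 bits.  `dendrite` places a
faint curvilinear structure (Gaussian cross-profile, peak amplitude `amp` =
10) over Gaussian background noise (`bg` = 20, `sd` = 5), with a bright soma
(peak 160) at the dendrite's origin and a pixel-level ground-truth mask of
the dendrite only.  The soma is essential to the scene's realism and to what
it demonstrates: a global Otsu threshold on a {background + faint structure}
image alone sits at the background mean and *recovers* most of the faint
structure; it is the presence of strong signal in the same frame that pulls
the threshold up (to ~65) and erases the faint pixels, which is precisely
the failure mode seen in real micrographs that contain both bright cell
bodies and dim dendrites.  A two-component mixture on pixel log-intensities
adapts to the full distribution and retains most dendrite pixels.

**What the generator does not emulate.**  Segmentation errors (doublets,
partial nuclei), spatially structured tissue architecture (niches,
follicles), marker-marker correlations within a type, autofluorescence
spectra, and batch effects.  Passing the recovery benchmarks therefore shows
the pipeline's statistical machinery works under its own model assumptions —
not that it is robust to all failure modes of real CODEX data.

## Numerical choices

* GMM fits: full covariance on 1-D data, `n_init=2`, `reg_covar=1e-6`,
  seeded; BIC compared with strict improvement so ties keep the smaller K.
* Otsu: exhaustive evaluation over all 256 thresholds via cumulative
  histogram; ties broken toward the smallest threshold for determinism.
  Constant images are a degenerate-input error.
* Posterize: level index `⌊v·L/256⌋` clamped to L−1, rendered back as
  `round(i·255/(L−1))`, so 0 and 255 map to themselves at every depth and
  the map is idempotent.
* Log rendering: `v' = round(255·log(1+v)/log(256))` — endpoints fixed,
  monotone.
* Color deconvolution: OD = −log₁₀((v+1)/256) per channel (+1 avoids
  log 0), solved against the unit stain matrix; with two stains the third
  vector is the normalized cross product; negative densities clamp to 0.
* Embedding: UMAP with a fixed `random_state` runs single-threaded and
  deterministically; determinism is favored over parallel speed.
* A single global seed fans out to per-stage seeds by fixed offsets
  (simulate +0, shrinkage +101, embedding +202, mod 2³¹) so stages can be
  re-run in isolation.
* The upfront discard criterion (robust z of total intensity > 5 +
  non-positive counterstain) is this package's own concrete rule; published
  pipelines report discarding a few percent "on a statistical basis"
  without specifying the statistic.

## Benchmark problem sizes

The recovery benchmarks in `hyperplex.benchmarks` are sized for a single
CPU: cluster recovery on 5,000 cells × 20 markers (~40 s), low-SNR
detection on ten independent 20,000-cell × 10-marker runs (~4 min), Otsu
oracle agreement on one hundred 64×64 images, mixture recovery at n=10,000.
These sizes are large enough that the measured quantities (ARI, detection
rate, recall) are stable to well within the margins asserted, while a full
run of the acceptance script stays around five minutes.

## Known limitations

* HDBSCAN's excess-of-mass selection never returns the hierarchy root by
  default, so a single homogeneous population comes back as noise unless
  `allow_single_cluster=True` is passed; conversely that flag would turn
  diffuse uniform data into one spurious cluster.  The default favors the
  realistic many-population case.
* With ~5% crossbleed the pipeline still over-partitions mildly (6–16
  clusters for 5 true types); the intended workflow keeps an expert in the
  loop to merge sub-clusters, aided by the ranked marker reports.
* Effect sizes are computed on preprocessed values; λ rescales
  within-component spread, so d values are comparable within a run but not
  across runs with different λ.
* The discard rule targets global-intensity aberrations only; it will not
  catch cells that are aberrant in a single marker.
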