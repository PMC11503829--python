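"""Self-contained recovery benchmarks run on the synthetic generator.

Each function generates its own data, runs the relevant part of the pipeline
and returns measured quantities.  They back the package's acceptance checks
and give users a quick way to gauge behavior on data with known ground truth:

* quantization arithmetic on the gray ramp;
* Otsu against an explicit exhaustive between-class-variance search;
* mixture parameter recovery on a two-mode lognormal;
* shrinkage contraction identities;
* cluster recovery (ARI) on a well-separated five-population panel;
* detection of a low-SNR marker in a rare population versus single-marker
  Otsu gating;
* faint-dendrite pixel recovery: global Otsu versus a two-component mixture
  classification of log-intensities.
"""

from __future__ import annotations

import numpy as np

from .cluster import min_cluster_size
from .imageops import (
    count_levels,
    mixture_foreground,
    otsu_split,
    otsu_threshold,
    posterize,
)
from .io import RunConfig
from .pipeline import run_pipeline
from .shrinkage import MarkerMixture, fit_mixture, shrink
from .synthetic import (
    generate_lowsnr_scenario,
    generate_test_images,
    well_separated_panel,
)

__all__ = [
    "quantization_summary",
    "otsu_oracle_agreement",
    "mixture_recovery",
    "shrinkage_contract_errors",
    "cluster_recovery",
    "lowsnr_detection",
    "dendrite_recovery",
]


def quantization_summary() -> dict:
    """Distinct gray levels after posterizing the full ramp to 4 and 6 bits,
    and the minimal step (in 8-bit gray levels) a 64-level repertoire implies."""
    ramp = generate_test_images("ramp")
    levels_6 = count_levels(posterize(ramp, 6))
    return {
        "levels_4bit": count_levels(posterize(ramp, 4)),
        "levels_6bit": levels_6,
        "min_gray_step_64_levels": 256 // levels_6,
        "n": int(ramp.size),
    }


def _exhaustive_otsu(img: np.ndarray) -> int:
    """Reference: evaluate between-class variance at every threshold directly."""
    v = img.ravel().astype(float)
    best_t, best_s = 0, -1.0
    for t in range(256):
        lo, hi = v[v <= t], v[v > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        s = (len(lo) / len(v)) * (len(hi) / len(v)) * (lo.mean() - hi.mean()) ** 2
        if s > best_s + 1e-12:
            best_s, best_t = s, t
    return best_t


def otsu_oracle_agreement(n_images: int = 100, size: int = 64, seed: int = 0) -> dict:
    """Fraction of seeded random images on which the fast implementation equals
    the exhaustive search."""
    agree = 0
    for i in range(n_images):
        r = np.random.default_rng(seed + i)
        img = r.integers(0, 256, size=(size, size), dtype=np.uint8)
        agree += otsu_threshold(img) == _exhaustive_otsu(img)
    return {"agreement_fraction": agree / n_images, "n": n_images}


def mixture_recovery(seed: int = 0, n: int = 10000) -> dict:
    """Recover a two-component lognormal mixture (meanlog 0 and 3, sdlog 0.2,
    equal weights).  Fitting is done on log(v), the scale on which the target
    centers are defined."""
    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [np.exp(rng.normal(0.0, 0.2, n // 2)), np.exp(rng.normal(3.0, 0.2, n // 2))]
    )
    mix = fit_mixture(values, max_components=5, seed=seed, pseudocount=0.0)
    return {
        "n_components": mix.n_components,
        "center_low": float(mix.centers[0]),
        "center_high": float(mix.centers[-1]),
        "weight_low": float(mix.weights[0]),
        "n": n,
    }


def shrinkage_contract_errors(seed: int = 0, n: int = 400) -> dict:
    """Exactness of the contraction map on a hand-built two-mode fit:
    identity at lambda=1, within-component distance scaling, collapse as
    lambda -> 0."""
    rng = np.random.default_rng(seed)
    c = np.array([0.0, 3.0])
    mix = MarkerMixture(np.array([0.5, 0.5]), c, np.array([0.2, 0.2]), c.copy())
    x = np.concatenate([rng.normal(0, 0.2, n // 2), rng.normal(3, 0.2, n // 2)])

    identity_err = float(np.max(np.abs(shrink(x, mix, 1.0) - x)))

    lam = 0.37
    upper = rng.normal(3.0, 0.15, 50)
    d_in = np.abs(upper[:, None] - upper[None, :])
    out = shrink(upper, mix, lam)
    d_out = np.abs(out[:, None] - out[None, :])
    scaling_err = float(np.max(np.abs(d_out - lam * d_in)))

    collapsed = shrink(x, mix, 1e-12)
    collapse_err = float(np.max(np.abs(collapsed - mix.centers[mix.assign(x)])))
    return {
        "identity_max_abs_error": identity_err,
        "distance_scaling_max_abs_error": scaling_err,
        "collapse_max_abs_error": collapse_err,
        "n": n,
    }


def cluster_recovery(seed: int = 1, n_cells: int = 5000) -> dict:
    """ARI between pipeline clusters and truth on the well-separated
    five-population panel (20 markers, crossbleed 0.05), excluding NOISE and
    DISCARDED cells."""
    from sklearn.metrics import adjusted_rand_score

    spec = well_separated_panel(n_cells=n_cells)
    out = run_pipeline(spec, RunConfig(seed=seed))
    lab = out.result.labels
    keep = lab >= 0
    ari = adjusted_rand_score(out.truth.type_labels[keep], lab[keep])
    return {
        "ari": float(ari),
        "n_clusters": out.result.n_clusters,
        "assigned_fraction": float(keep.mean()),
        "n": n_cells,
    }


def _best_match_cluster(labels: np.ndarray, target: np.ndarray) -> int:
    """Cluster with the highest F1 overlap against a ground-truth cell set."""
    best, best_f1 = -1, -1.0
    for cid in np.unique(labels[labels >= 0]):
        m = labels == cid
        f1 = 2 * (m & target).sum() / (m.sum() + target.sum())
        if f1 > best_f1:
            best, best_f1 = int(cid), f1
    return best


def lowsnr_detection(
    seeds: range | list = range(10),
    n_cells: int = 20000,
    rare_fraction: float = 0.05,
    shift: float = 0.5,
) -> dict:
    """Detection of the weak marker in the rare population, per seed.

    For each seed: run the full pipeline, find the cluster best matching the
    rare population, and record whether the weak marker is significant
    (BH-adjusted p < 0.05) with tier <= 2 there.  Also records what a
    single-marker Otsu dichotomization of the weak channel recovers, and the
    fraction of rare cells recovered by rare-majority clusters.
    """
    from collections import Counter

    hits, otsu_recalls, pipe_recalls = [], [], []
    for seed in seeds:
        table, truth = generate_lowsnr_scenario(
            n_cells=n_cells, rare_fraction=rare_fraction, shift=shift, seed=seed
        )
        rare = truth.type_labels == truth.label_of("rare")
        weak = table.marker_names[truth.spec.lowsnr_marker]

        otsu_recalls.append(float(otsu_split(table.marker(weak))[rare].mean()))

        out = run_pipeline(table, RunConfig(seed=seed, counterstain="DAPI"))
        lab = out.result.labels
        best = _best_match_cluster(lab, rare)
        ranking = next(r for r in out.rankings if r.cluster_id == best)
        row = ranking.table.set_index("marker").loc[weak]
        hits.append(bool(row["p_adjusted"] < 0.05 and row["tier"] <= 2))

        rare_majority = [
            int(c)
            for c in np.unique(lab[lab >= 0])
            if Counter(truth.type_labels[lab == c]).most_common(1)[0][0]
            == truth.label_of("rare")
        ]
        pipe_recalls.append(float(np.isin(lab, rare_majority)[rare].mean()))
    return {
        "n_detected": int(sum(hits)),
        "n_runs": len(hits),
        "detection_rate": sum(hits) / len(hits),
        "otsu_recall_mean": float(np.mean(otsu_recalls)),
        "pipeline_recall_mean": float(np.mean(pipe_recalls)),
        "n": n_cells,
    }


def dendrite_recovery(seed: int = 0) -> dict:
    """Faint-dendrite pixel recovery: global Otsu mask versus two-component
    mixture classification of pixel log-intensities (amp 10, bg 20, sd 5)."""
    img, mask = generate_test_images("dendrite", {"amp": 10, "bg": 20, "sd": 5}, seed)
    t = otsu_threshold(img)
    return {
        "otsu_recall": float((img[mask] > t).mean()),
        "mixture_recall": float(mixture_foreground(img, seed=seed)[mask].mean()),
        "n": int(mask.sum()),
    }
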