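"""End-to-end orchestration: simulate/load -> preprocess -> embed/cluster -> rank -> report.

A single global seed fans out to per-stage seeds by fixed offsets so any
stage can be re-run in isolation reproducibly.  Every run produces a
manifest recording the config snapshot, the derived seeds, an input hash and
exact per-stage cell accounting (input = discarded + noise + clustered).
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import ClusterResult, cluster, discard_outliers, embed, min_cluster_size
from .io import DISCARDED, CellTable, RunConfig, ValidationError, write_results
from .ranking import ClusterReport, MarkerRanking, build_report, rank_markers
from .shrinkage import PreprocessedMatrix, preprocess
from .synthetic import PanelSpec, SyntheticTruth, generate_cells

__all__ = ["PipelineOutput", "run_pipeline", "stage_seeds"]

log = logging.getLogger("hyperplex")

_STAGE_OFFSETS = {"simulate": 0, "shrinkage": 101, "embedding": 202}


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive per-stage seeds from the global seed by fixed offsets."""
    return {k: (seed + off) % (2**31) for k, off in _STAGE_OFFSETS.items()}


@dataclass
class PipelineOutput:
    table: CellTable
    matrix: PreprocessedMatrix
    result: ClusterResult
    rankings: list[MarkerRanking]
    reports: list[ClusterReport]
    manifest: dict
    truth: SyntheticTruth | None = None


def _input_hash(table: CellTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(table.markers).tobytes())
    h.update(np.ascontiguousarray(table.x).tobytes())
    h.update(np.ascontiguousarray(table.y).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    source: CellTable | PanelSpec,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineOutput:
    """Execute the full analysis on a cell table (or a panel spec to simulate).

    Stages: optional simulation, lognormal-shrinkage preprocessing, robust
    statistical discard, UMAP embedding of kept cells, HDBSCAN clustering
    with the minimum-cluster-size rule, per-cluster marker ranking, and the
    A/B/C cluster reports.  Deterministic per config seed.  When ``out_dir``
    is given, all outputs plus the manifest are written there; on failure the
    partial output directory is removed.
    """
    config = config or RunConfig()
    seeds = stage_seeds(config.seed)
    log.info(
        "run: contraction=%s max_components=%s umap=(%s, %s) tiers=%s seed=%s",
        config.contraction, config.max_components, config.umap_neighbors,
        config.umap_min_dist, config.tier_thresholds, config.seed,
    )

    truth = None
    if isinstance(source, PanelSpec):
        table, truth = generate_cells(source, seeds["simulate"])
    elif isinstance(source, CellTable):
        table = source
    else:
        raise ValidationError("source must be a CellTable or a PanelSpec")

    shrink_cfg = RunConfig(**{**asdict(config), "seed": seeds["shrinkage"]})
    matrix = preprocess(table, shrink_cfg)

    counterstain = (
        table.marker(config.counterstain) if config.counterstain in table.marker_names else None
    )
    keep = discard_outliers(matrix, z_max=config.z_max, counterstain=counterstain)
    n_discarded = int((~keep).sum())
    log.info("discarded %d/%d cells (%.2f%%) upfront", n_discarded, table.n_cells,
             100 * n_discarded / table.n_cells)

    mcs = min_cluster_size(
        int(keep.sum()), config.min_cluster_fraction, config.min_cluster_floor
    )
    emb_kept = embed(
        matrix.values[keep],
        n_neighbors=config.umap_neighbors,
        min_dist=config.umap_min_dist,
        seed=seeds["embedding"],
    )
    labels_kept = cluster(emb_kept, mcs)

    labels = np.full(table.n_cells, DISCARDED, dtype=int)
    labels[keep] = labels_kept
    embedding = np.full((table.n_cells, 2), np.nan)
    embedding[keep] = emb_kept
    result = ClusterResult(labels=labels, embedding=embedding)

    rankings = [
        rank_markers(
            matrix, labels, cid, alpha=config.alpha,
            tier_thresholds=config.tier_thresholds, marker_names=matrix.marker_names,
        )
        for cid in result.cluster_ids
    ]
    reports = build_report(table, matrix, result, rankings, config.diagnostic_markers)

    counts = result.counts()
    manifest = {
        "version": __version__,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "seeds": seeds,
        "input_hash": _input_hash(table),
        "min_cluster_size": mcs,
        "counts": counts,
        "n_clusters": result.n_clusters,
    }
    assert counts["n_discarded"] + counts["n_noise"] + counts["n_clustered"] == counts["n_cells"]

    if out_dir is not None:
        out = Path(out_dir)
        created = not out.exists()
        try:
            out.mkdir(parents=True, exist_ok=True)
            write_results(result, rankings, out, table=table)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
            _write_plots(table, result, out)
        except Exception:
            if created and out.exists():
                shutil.rmtree(out)
            raise
    return PipelineOutput(table, matrix, result, rankings, reports, manifest, truth)


def _write_plots(table: CellTable, result: ClusterResult, out: Path) -> None:
    """Embedding scatter (clusters colored, noise gray) + tissue map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(12, 5.5))
    for ax, (xs, ys), title in zip(
        axes,
        [(result.embedding[:, 0], result.embedding[:, 1]), (table.x, table.y)],
        ["UMAP embedding", "tissue map"],
    ):
        lab = result.labels
        gray = lab < 0
        ax.scatter(xs[gray], ys[gray], s=2, c="lightgray", linewidths=0)
        sc = ax.scatter(xs[~gray], ys[~gray], s=2, c=lab[~gray], cmap="tab20", linewidths=0)
        ax.set_title(title)
        if title == "tissue map":
            ax.invert_yaxis()  # image convention: origin top-left
    fig.colorbar(sc, ax=axes[-1], label="cluster")
    fig.tight_layout()
    fig.savefig(out / "clusters.png", dpi=150)
    plt.close(fig)
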