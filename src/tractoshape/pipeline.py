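"""End-to-end orchestration: centroids -> align -> distances -> isomap ->
k-means -> average shapes -> reports, driven by a single config.

A run is fully determined by its config and seed: every stochastic stage
draws its own seed derived from the global one by hashing the stage name,
and every artifact is written with fixed float formatting, so repeated runs
produce byte-identical outputs. A JSON manifest records the config and a
SHA-256 hash of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from tractoshape import io_streamlines as tio
from tractoshape.alignment import pca_align
from tractoshape.clustering import (
    average_shapes,
    composition_table,
    kmeans,
)
from tractoshape.geometry import PointCloud, extract_centroid
from tractoshape.manifold import isomap_embed
from tractoshape.morphometry import (
    compare_groups,
    length_stats,
    normalize_lengths,
    surface_normalization_factor,
)
from tractoshape.shape_distance import distance_matrix
from tractoshape.synthetic import generate_cohort

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed by hashing the stage name into the global seed."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Parameters of one full pipeline run.

    Defaults follow the analysis conventions of the pipeline: 21-point
    centroids, a 7-133 mm superficial-length window, isomap with 4
    neighbors and 2 output dimensions, and a k-sweep over {2, 5}.
    """

    n_points: int = 21
    min_length_mm: float = 7.0
    max_length_mm: float = 133.0
    n_neighbors: int = 4
    n_dims: int = 2
    disconnected: str = "bridge"
    k: Sequence[int] = (2, 5)
    seed: int = 0
    n_init: int = 10
    inputs: Sequence[str] = ()
    annotations: str | None = None
    synthetic: Mapping[str, Any] | None = None
    noise_sigma: float = 1.2
    scale: float = 40.0
    surfaces: Mapping[str, float] | None = None  # group -> pial area mm^2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_points": self.n_points,
            "min_length_mm": self.min_length_mm,
            "max_length_mm": self.max_length_mm,
            "n_neighbors": self.n_neighbors,
            "n_dims": self.n_dims,
            "disconnected": self.disconnected,
            "k": list(self.k),
            "seed": self.seed,
            "n_init": self.n_init,
            "inputs": list(self.inputs),
            "annotations": self.annotations,
            "synthetic": dict(self.synthetic) if self.synthetic else None,
            "noise_sigma": self.noise_sigma,
            "scale": self.scale,
            "surfaces": dict(self.surfaces) if self.surfaces else None,
        }


@dataclass
class RunResult:
    """Objects and file paths produced by :func:`run`."""

    centroids: list[PointCloud]
    aligned: list[PointCloud]
    distance_matrix: Any
    embedding: Any
    clusterings: dict[int, Any]
    compositions: dict[int, Any]
    length_report: Any
    group_comparison: Any | None
    manifest: dict[str, Any]
    outdir: Path
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig) -> tuple[list[PointCloud], dict[str, dict[str, str]]]:
    """Produce centroid clouds and annotations from synthetic or file inputs."""
    annotations: dict[str, dict[str, str]] = {}
    if config.synthetic is not None:
        cohort = generate_cohort(
            config.synthetic,
            n_points=config.n_points,
            noise_sigma=config.noise_sigma,
            scale=config.scale,
            seed=stage_seed(config.seed, "synthetic"),
        )
        for uid in cohort.ids:
            annotations[uid] = {
                "empirical_shape": cohort.family_of[uid],
                "group": cohort.group_of[uid],
            }
        return list(cohort.clouds), annotations
    if not config.inputs:
        raise ValueError("config needs either synthetic spec or input paths")
    bundles = []
    for p in config.inputs:
        bundles.extend(tio.read_bundles(p))
    bundles = tio.filter_by_length(bundles, config.min_length_mm, config.max_length_mm)
    if config.annotations:
        annotations = tio.read_annotations_csv(config.annotations)
    centroids = [extract_centroid(b, config.n_points) for b in bundles]
    return centroids, annotations


def run(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute the full shape-analysis pipeline and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _write(name: str, obj) -> Path:
        path = tio.write_results(obj, outdir / name)
        files[name] = _sha256(path)
        return path

    centroids, annotations = _load_inputs(config)
    tio.write_centroids_csv(centroids, outdir / "centroids.csv")
    files["centroids.csv"] = _sha256(outdir / "centroids.csv")

    aligned = [pca_align(c)[0] for c in centroids]
    D = distance_matrix(aligned)
    _write("distance_matrix.csv", D)

    emb = isomap_embed(
        D,
        n_neighbors=config.n_neighbors,
        n_dims=config.n_dims,
        disconnected=config.disconnected,
    )
    _write("embedding.csv", emb)

    shape_of = {
        uid: ann["empirical_shape"]
        for uid, ann in annotations.items()
        if "empirical_shape" in ann
    }
    group_of = {
        uid: ann["group"] for uid, ann in annotations.items() if "group" in ann
    }

    clusterings: dict[int, Any] = {}
    compositions: dict[int, Any] = {}
    for k in config.k:
        clustering = kmeans(
            emb, k, seed=stage_seed(config.seed, f"kmeans_k{k}"), n_init=config.n_init
        )
        clustering = average_shapes(aligned, clustering)
        clusterings[k] = clustering
        _write(f"clustering_k{k}.json", clustering)
        if shape_of:
            labels = {uid: int(clustering.labels[i]) for i, uid in enumerate(clustering.ids)}
            pct, counts = composition_table(labels, shape_of)
            compositions[k] = pct
            _write(f"composition_k{k}.csv", pct)
            _write(f"composition_counts_k{k}.csv", counts)

    class_of = shape_of or {c.source_id: "all" for c in centroids}
    report = length_stats(centroids, class_of)
    _write("length_report.csv", report.table)

    group_comparison = None
    if config.surfaces and group_of:
        groups = sorted(set(group_of.values()))
        if len(groups) == 2 and all(g in config.surfaces for g in groups):
            src, tgt = groups[0], groups[1]
            factor = surface_normalization_factor(
                config.surfaces[src], config.surfaces[tgt]
            )
            rep_src = length_stats(
                [c for c in centroids if group_of.get(c.source_id) == src],
                class_of, group=src,
            )
            rep_tgt = length_stats(
                [c for c in centroids if group_of.get(c.source_id) == tgt],
                class_of, group=tgt,
            )
            shared = sorted(set(rep_src.table.index) & set(rep_tgt.table.index))
            rep_src_n = normalize_lengths(rep_src, factor)
            rep_src_n = type(rep_src_n)(
                table=rep_src_n.table.loc[shared], group=src,
                normalization_factor=rep_src_n.normalization_factor,
            )
            rep_tgt_s = type(rep_tgt)(table=rep_tgt.table.loc[shared], group=tgt)
            group_comparison = compare_groups(rep_src_n, rep_tgt_s)
            _write("group_length_comparison.csv", group_comparison)

    manifest = {"config": config.to_dict(), "files": dict(sorted(files.items()))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))

    return RunResult(
        centroids=centroids,
        aligned=aligned,
        distance_matrix=D,
        embedding=emb,
        clusterings=clusterings,
        compositions=compositions,
        length_report=report,
        group_comparison=group_comparison,
        manifest=manifest,
        outdir=outdir,
        annotations=annotations,
    )
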