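"""Reading/writing streamline bundles and tabular pipeline artifacts.

Streamline containers follow the two community standards, TRK (TrackVis)
and TCK (MRtrix), via :mod:`nibabel.streamlines`; both are returned in
world-space millimetres (RAS), with TRK voxel-space coordinates transformed
by the header affine at read time. A plain CSV dialect (comma-separated,
header row, UTF-8, '.' decimal) is supported for centroids and for small
fixtures, and is also the format of every tabular artifact (distance
matrices, embeddings, composition tables).

The length filter retains streamlines whose arc length lies inside an
inclusive ``[min_mm, max_mm]`` window — the 7-133 mm window targets
superficial (short-association) connectivity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from tractoshape.geometry import PointCloud, arc_length

logger = logging.getLogger(__name__)

#: Annotation keys understood by reporting code.
ANNOTATION_SCHEMA = ("group", "hemisphere", "lobe", "empirical_shape")


@dataclass
class BundleSet:
    """A named set of streamlines with optional annotations.

    ``streamlines`` are ``(n_i, 3)`` float arrays in world mm; annotation
    keys are drawn from :data:`ANNOTATION_SCHEMA`.
    """

    name: str
    streamlines: list[np.ndarray]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        checked = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i} of {self.name!r} must be (n>=2, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} of {self.name!r} has non-finite points")
            if np.any(np.all(np.diff(arr, axis=0) == 0, axis=1)):
                raise ValueError(
                    f"streamline {i} of {self.name!r} has identical consecutive points"
                )
            checked.append(arr)
        self.streamlines = checked
        unknown = set(self.annotations) - set(ANNOTATION_SCHEMA)
        if unknown:
            raise ValueError(f"unknown annotation keys {sorted(unknown)}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("trk", "tck", "csv", "json"):
        return suffix
    raise ValueError(f"cannot infer streamline format from {path.name!r}")


def read_bundles(path: str | Path, format: str | None = None) -> list[BundleSet]:
    """Read bundles from a TRK/TCK/CSV file, in world millimetres.

    A TRK/TCK file yields one bundle named after the file stem. The CSV
    dialect has a header ``bundle,streamline,point,x,y,z`` (the
    ``streamline`` column may be omitted, in which case a new streamline
    starts whenever the point index resets to 0). An empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt in ("trk", "tck"):
        if path.stat().st_size == 0:
            logger.warning("empty streamline file %s", path)
            return []
        try:
            tractogram_file = nib.streamlines.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error text varies
            raise ValueError(f"malformed {fmt.upper()} file {path.name}: {exc}") from exc
        streamlines = [np.asarray(s, dtype=float) for s in tractogram_file.streamlines]
        if not streamlines:
            logger.warning("no streamlines in %s", path)
            return []
        return [BundleSet(name=path.stem, streamlines=streamlines)]
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.empty:
            logger.warning("empty CSV %s", path)
            return []
        required = {"bundle", "point", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"CSV {path.name} missing columns {sorted(missing)}")
        bundles = []
        for name, grp in df.groupby("bundle", sort=False):
            if "streamline" in df.columns:
                keys = grp["streamline"]
            else:
                keys = (grp["point"] == 0).cumsum()
            streamlines = [
                sub.sort_values("point")[["x", "y", "z"]].to_numpy(float)
                for _, sub in grp.groupby(keys, sort=False)
            ]
            bundles.append(BundleSet(name=str(name), streamlines=streamlines))
        return bundles
    raise ValueError(f"unsupported streamline format {fmt!r}")


def write_bundles(
    bundles: Sequence[BundleSet], path: str | Path, format: str | None = None
) -> Path:
    """Write bundles to TRK/TCK (world mm, identity affine) or CSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("trk", "tck"):
        streamlines = [s for b in bundles for s in b.streamlines]
        tractogram = Tractogram(streamlines, affine_to_rasmm=np.eye(4))
        cls = TrkFile if fmt == "trk" else TckFile
        cls(tractogram).save(str(path))
        return path
    if fmt == "csv":
        rows = []
        for b in bundles:
            for si, s in enumerate(b.streamlines):
                for pi, (x, y, z) in enumerate(s):
                    rows.append((b.name, si, pi, x, y, z))
        df = pd.DataFrame(rows, columns=["bundle", "streamline", "point", "x", "y", "z"])
        df.to_csv(path, index=False, float_format="%.17g")
        return path
    raise ValueError(f"unsupported streamline format {fmt!r}")


def filter_by_length(
    bundles: Sequence[BundleSet], min_mm: float, max_mm: float
) -> list[BundleSet]:
    """Keep streamlines with arc length in the inclusive ``[min_mm, max_mm]``.

    Bundles left with no streamline are dropped (and logged). Idempotent
    and order-preserving.
    """
    if not 0 <= min_mm < max_mm:
        raise ValueError(f"need 0 <= min_mm < max_mm, got [{min_mm}, {max_mm}]")
    out = []
    for b in bundles:
        kept = [s for s in b.streamlines if min_mm <= arc_length(s) <= max_mm]
        if kept:
            out.append(BundleSet(name=b.name, streamlines=kept, annotations=dict(b.annotations)))
        else:
            logger.info("bundle %s dropped: no streamline in [%g, %g] mm", b.name, min_mm, max_mm)
    return out


# ---------------------------------------------------------------------------
# tabular artifacts


def write_centroids_csv(clouds: Sequence[PointCloud], path: str | Path) -> Path:
    """Centroid clouds as a point-per-row CSV (``bundle,point,x,y,z``)."""
    path = Path(path)
    rows = []
    for i, c in enumerate(clouds):
        cid = c.source_id or f"cloud{i}"
        for pi, (x, y, z) in enumerate(c.points):
            rows.append((cid, pi, x, y, z))
    pd.DataFrame(rows, columns=["bundle", "point", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_centroids_csv(path: str | Path) -> list[PointCloud]:
    df = pd.read_csv(path)
    clouds = []
    for name, grp in df.groupby("bundle", sort=False):
        pts = grp.sort_values("point")[["x", "y", "z"]].to_numpy(float)
        clouds.append(PointCloud(pts, source_id=str(name)))
    return clouds


def write_annotations_csv(annotations: Mapping[str, Mapping[str, str]], path: str | Path) -> Path:
    """Per-bundle annotation table: ``bundle`` column plus schema columns."""
    df = pd.DataFrame.from_dict(annotations, orient="index")
    df.index.name = "bundle"
    df.to_csv(path)
    return Path(path)


def read_annotations_csv(path: str | Path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, index_col="bundle", dtype=str)
    return {str(i): {k: v for k, v in row.items() if pd.notna(v)} for i, row in df.iterrows()}


def write_results(obj, path: str | Path, format: str | None = None) -> Path:
    """Write a pipeline artifact (distance matrix, embedding, clustering,
    report table or point clouds) to CSV/JSON/TRK/TCK.

    Output is deterministic for a fixed input: floats use a fixed ``%.17g``
    representation and JSON keys are sorted.
    """
    from tractoshape.clustering import ShapeClustering
    from tractoshape.manifold import Embedding
    from tractoshape.shape_distance import DistanceMatrix

    path = Path(path)
    fmt = _infer_format(path, format)

    if isinstance(obj, DistanceMatrix):
        if fmt != "csv":
            raise ValueError("distance matrices are written as CSV")
        df = pd.DataFrame(obj.values, index=list(obj.ids), columns=list(obj.ids))
        df.index.name = "id"
        df.to_csv(path, float_format="%.17g")
        return path

    if isinstance(obj, Embedding):
        if fmt != "csv":
            raise ValueError("embeddings are written as CSV")
        df = pd.DataFrame(
            obj.coordinates, columns=[f"dim{i + 1}" for i in range(obj.n_dims)]
        )
        df.insert(0, "id", list(obj.ids))
        df["component"] = [obj.component_map[i] for i in obj.ids]
        df.to_csv(path, index=False, float_format="%.17g")
        return path

    if isinstance(obj, ShapeClustering):
        if fmt == "json":
            payload = {
                "k": obj.k,
                "seed": obj.seed,
                "inertia": obj.inertia,
                "ids": list(obj.ids),
                "labels": obj.labels.tolist(),
                "centers": obj.centers.tolist(),
                "average_shapes": [s.points.tolist() for s in obj.average_shapes],
            }
            path.write_text(json.dumps(payload, sort_keys=True, indent=1))
            return path
        if fmt in ("trk", "tck"):
            if not obj.average_shapes:
                raise ValueError("clustering has no average shapes to export")
            bundles = [
                BundleSet(name=s.source_id, streamlines=[s.points])
                for s in obj.average_shapes
            ]
            return write_bundles(bundles, path, fmt)
        raise ValueError("clusterings are written as JSON (or TRK/TCK averages)")

    if isinstance(obj, pd.DataFrame):
        if fmt == "csv":
            obj.to_csv(path, float_format="%.17g")
            return path
        if fmt == "json":
            path.write_text(obj.to_json(orient="split", indent=1))
            return path
        raise ValueError("tables are written as CSV or JSON")

    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], PointCloud):
        if fmt == "csv":
            return write_centroids_csv(obj, path)
        if fmt in ("trk", "tck"):
            bundles = [BundleSet(name=c.source_id or f"cloud{i}", streamlines=[c.points])
                       for i, c in enumerate(obj)]
            return write_bundles(bundles, path, fmt)
        raise ValueError("point clouds are written as CSV or TRK/TCK")

    raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_embedding_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_distance_matrix_csv(path: str | Path):
    from tractoshape.shape_distance import DistanceMatrix

    df = pd.read_csv(path, index_col="id")
    return DistanceMatrix(df.to_numpy(float), tuple(str(c) for c in df.columns))
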