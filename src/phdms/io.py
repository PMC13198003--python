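"""Core data containers and I/O for multiscale clustering input.

The pipeline consumes three tabular inputs: a spot table (spot identifiers
with 2-D tissue coordinates, typically in microns), a label matrix (one
integer cluster label per spot per scale, columns ordered fine to coarse),
and optionally a hard ground-truth annotation used for benchmarking.
Delimited text is the canonical interchange format; ``.h5ad`` containers are
supported as a convenience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotSet",
    "ScaleClustering",
    "ClusteringSequence",
    "GroundTruthAnnotation",
    "read_spot_table",
    "write_spot_table",
    "read_label_matrix",
    "write_label_matrix",
    "read_truth_table",
    "from_anndata",
    "cluster_sweep",
    "default_resolution_schedule",
]

#: sentinel ground-truth label for spots outside every annotated domain
UNASSIGNED = "__unassigned__"


class InputError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class SpotSet:
    """An ordered set of tissue spots with spatial coordinates.

    Parameters
    ----------
    ids
        Unique spot identifiers, one per spot, in input row order.
    coords
        Array of shape ``(n, 2)`` holding the spatial position of each spot
        in the tissue's coordinate units (microns for Visium-style data).
    """

    ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        coords = np.asarray(self.coords, dtype=float)
        if ids.ndim != 1 or len(ids) < 1:
            raise InputError("a spot set needs at least one spot")
        if coords.shape != (len(ids), 2):
            raise InputError(
                f"coordinates must be (n, 2); got {coords.shape} for {len(ids)} spots"
            )
        if not np.isfinite(coords).all():
            bad = np.where(~np.isfinite(coords).all(axis=1))[0][0]
            raise InputError(f"non-finite coordinate at spot {ids[bad]!r}")
        seen: dict = {}
        for row, sid in enumerate(ids):
            if sid in seen:
                raise InputError(f"duplicate spot id {sid!r} at row {row}")
            seen[sid] = row
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "_index", seen)

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def positions_of(self, ids: Sequence) -> np.ndarray:
        """Map spot ids to integer row positions, erroring on unknown ids."""
        index = self._index  # type: ignore[attr-defined]
        try:
            return np.fromiter((index[i] for i in ids), dtype=np.intp, count=len(ids))
        except KeyError as exc:
            raise InputError(f"unknown spot id {exc.args[0]!r}") from None


@dataclass(frozen=True)
class ScaleClustering:
    """A single-scale partition of the spot set.

    ``labels[s]`` is the dense integer cluster code of spot ``s``; the
    cluster ``C_{i,j}`` is the set of spots with code ``j`` at scale ``i``.
    """

    scale_index: int
    resolution: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise InputError(
                f"scale {self.scale_index}: labels must be integers, got {labels.dtype}"
            )
        object.__setattr__(self, "labels", labels.astype(np.int64))

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_members(self) -> dict[int, np.ndarray]:
        """Spot positions of each cluster, keyed by dense label."""
        order = np.argsort(self.labels, kind="stable")
        sorted_labels = self.labels[order]
        uniq, starts = np.unique(sorted_labels, return_index=True)
        bounds = np.append(starts, len(sorted_labels))
        return {
            int(lab): order[bounds[k] : bounds[k + 1]] for k, lab in enumerate(uniq)
        }


@dataclass(frozen=True)
class ClusteringSequence:
    """An ordered (fine to coarse) sequence of partitions of one spot set."""

    spots: SpotSet
    scales: tuple[ScaleClustering, ...]

    def __post_init__(self) -> None:
        scales = tuple(self.scales)
        if len(scales) < 2:
            raise InputError("a clustering sequence needs at least two scales")
        for sc in scales:
            if len(sc.labels) != self.spots.n:
                raise InputError(
                    f"scale {sc.scale_index} has {len(sc.labels)} labels "
                    f"for {self.spots.n} spots"
                )
        res = [sc.resolution for sc in scales]
        if any(b >= a for a, b in zip(res, res[1:])):
            raise InputError(f"resolutions must be strictly decreasing, got {res}")
        counts = [sc.n_clusters for sc in scales]
        if any(b > a for a, b in zip(counts, counts[1:])):
            warnings.warn(
                "cluster counts are not monotone non-increasing across scales "
                f"({counts}); column order is treated as authoritative",
                stacklevel=2,
            )
        object.__setattr__(self, "scales", scales)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def cluster_counts(self) -> list[int]:
        return [sc.n_clusters for sc in self.scales]


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """A hard (binary) ground-truth domain partition; spots may be unassigned."""

    spots: SpotSet
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        if len(labels) != self.spots.n:
            raise InputError(
                f"{len(labels)} truth labels for {self.spots.n} spots"
            )
        object.__setattr__(self, "labels", labels)

    def domains(self) -> dict[str, np.ndarray]:
        """Spot positions of each annotated domain, excluding unassigned."""
        out: dict[str, np.ndarray] = {}
        for name in pd.unique(self.labels):
            if name == UNASSIGNED or pd.isna(name):
                continue
            out[str(name)] = np.where(self.labels == name)[0]
        return out

    @property
    def n_domains(self) -> int:
        return len(self.domains())


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------


def _read_table(source) -> pd.DataFrame:
    return pd.read_csv(source, sep=None, engine="python")


def read_spot_table(source) -> SpotSet:
    """Read a delimited table with columns ``spot_id, x, y`` into a SpotSet."""
    df = _read_table(source)
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise InputError(f"spot table is missing required column {col!r}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise InputError(
                f"non-numeric {col!r} value {df[col].iloc[row]!r} at row {row}"
            )
        df[col] = vals
    return SpotSet(df["spot_id"].to_numpy(dtype=object), df[["x", "y"]].to_numpy())


def write_spot_table(spots: SpotSet, path) -> None:
    pd.DataFrame(
        {"spot_id": spots.ids, "x": spots.coords[:, 0], "y": spots.coords[:, 1]}
    ).to_csv(path, index=False)


def _dense_codes(values: pd.Series, scale_name: str) -> np.ndarray:
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.isna().any():
        row = int(np.argmax(numeric.isna().to_numpy()))
        raise InputError(
            f"non-integer label {values.iloc[row]!r} at row {row} "
            f"of scale column {scale_name!r}"
        )
    if not np.allclose(numeric, numeric.round()):
        raise InputError(f"fractional label in scale column {scale_name!r}")
    codes, _ = pd.factorize(numeric.astype(np.int64))
    return codes.astype(np.int64)


def read_label_matrix(source, spots: SpotSet) -> ClusteringSequence:
    """Read per-scale labels (columns fine to coarse, named by resolution).

    The table must contain exactly the spots of ``spots``; labels are
    re-encoded to dense integers per scale, which preserves every partition.
    """
    df = _read_table(source)
    if "spot_id" not in df.columns:
        raise InputError("label matrix is missing required column 'spot_id'")
    table_ids = set(df["spot_id"])
    missing = [i for i in spots.ids if i not in table_ids]
    if missing:
        raise InputError(f"label matrix is missing spot {missing[0]!r}")
    if len(df) != spots.n:
        extra = sorted(table_ids - set(spots.ids))[:1]
        raise InputError(
            f"label matrix has spots absent from the spot table: {extra[0]!r}"
            if extra
            else "label matrix has duplicated spot rows"
        )
    df = df.set_index("spot_id").loc[spots.ids]
    scale_cols = [c for c in df.columns]
    if not scale_cols:
        raise InputError("label matrix has no scale columns")
    scales = []
    for i, col in enumerate(scale_cols):
        try:
            res = float(col)
        except ValueError:
            res = float(len(scale_cols) - i)  # fall back to a decreasing rank
        scales.append(
            ScaleClustering(
                scale_index=i, resolution=res, labels=_dense_codes(df[col], col)
            )
        )
    return ClusteringSequence(spots=spots, scales=tuple(scales))


def write_label_matrix(seq: ClusteringSequence, path) -> None:
    data = {"spot_id": seq.spots.ids}
    for sc in seq.scales:
        data[f"{sc.resolution:g}"] = sc.labels
    pd.DataFrame(data).to_csv(path, index=False)


def read_truth_table(source, spots: SpotSet) -> GroundTruthAnnotation:
    """Read ``spot_id, domain`` annotations; absent spots become unassigned."""
    df = _read_table(source)
    for col in ("spot_id", "domain"):
        if col not in df.columns:
            raise InputError(f"truth table is missing required column {col!r}")
    if df["spot_id"].duplicated().any():
        dup = df["spot_id"][df["spot_id"].duplicated()].iloc[0]
        raise InputError(f"spot {dup!r} is annotated more than once")
    mapping = dict(zip(df["spot_id"], df["domain"]))
    labels = np.array(
        [mapping.get(i, UNASSIGNED) for i in spots.ids], dtype=object
    )
    labels[pd.isna(labels)] = UNASSIGNED
    return GroundTruthAnnotation(spots=spots, labels=labels)


def from_anndata(
    adata,
    label_keys: Sequence[str],
    spatial_key: str = "spatial",
    truth_key: str | None = None,
):
    """Extract spots, a clustering sequence, and optional truth from AnnData.

    Coordinates are read from ``adata.obsm[spatial_key]``; each entry of
    ``label_keys`` names an ``obs`` column holding one scale's labels,
    ordered fine to coarse.
    """
    if spatial_key not in adata.obsm:
        raise InputError(f"AnnData has no obsm[{spatial_key!r}] coordinates")
    spots = SpotSet(
        np.asarray(adata.obs_names, dtype=object),
        np.asarray(adata.obsm[spatial_key])[:, :2].astype(float),
    )
    scales = []
    for i, key in enumerate(label_keys):
        if key not in adata.obs:
            raise InputError(f"AnnData has no obs column {key!r}")
        codes, _ = pd.factorize(adata.obs[key])
        if (codes < 0).any():
            raise InputError(f"obs column {key!r} has missing labels")
        try:
            res = float(key)
        except ValueError:
            res = float(len(label_keys) - i)
        scales.append(ScaleClustering(i, res, codes.astype(np.int64)))
    seq = ClusteringSequence(spots=spots, scales=tuple(scales))
    truth = None
    if truth_key is not None:
        labels = np.asarray(adata.obs[truth_key], dtype=object)
        labels[pd.isna(labels)] = UNASSIGNED
        truth = GroundTruthAnnotation(spots=spots, labels=labels)
    return spots, seq, truth


# ---------------------------------------------------------------------------
# Resolution-sweep adapter
# ---------------------------------------------------------------------------


def default_resolution_schedule(n_scales: int = 8) -> list[float]:
    """Uniform grid of decreasing Leiden resolutions from 0.95 down to 0.15."""
    return [float(r) for r in np.linspace(0.95, 0.15, n_scales)]


def cluster_sweep(
    embedding: np.ndarray,
    spots: SpotSet,
    resolutions: Sequence[float] | None = None,
    *,
    n_neighbors: int = 15,
    seed: int = 0,
) -> ClusteringSequence:
    """Leiden community detection on a kNN graph of an embedding, one
    partition per resolution.

    This is the adapter contract for upstream spatially-aware embeddings
    (GraphST, SCAN-IT, Banksy, ...): any method that yields a per-spot
    feature matrix can feed the pipeline through this sweep. The default
    schedule is 8 uniformly spaced resolutions from 0.95 down to 0.15.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    if resolutions is None:
        resolutions = default_resolution_schedule()
    resolutions = [float(r) for r in resolutions]
    if not resolutions:
        raise InputError("resolution schedule is empty")
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] != spots.n:
        raise InputError(
            f"embedding has {embedding.shape[0]} rows for {spots.n} spots"
        )
    k = min(n_neighbors, spots.n - 1)
    adj = kneighbors_graph(embedding, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    mask = adj.row < adj.col
    graph = igraph.Graph(
        n=spots.n, edges=list(zip(adj.row[mask], adj.col[mask])), directed=False
    )
    scales = []
    for i, res in enumerate(resolutions):
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
            n_iterations=-1,
        )
        codes, _ = pd.factorize(np.asarray(part.membership))
        scales.append(ScaleClustering(i, res, codes.astype(np.int64)))
    return ClusteringSequence(spots=spots, scales=tuple(scales))
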