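"""Polygon layers and queen-contiguity spatial weights.

The weight matrix W is the backbone of every statistic in this package: two
areal units (districts) are first-order *queen* neighbours when their
boundaries share at least one point — a common edge or a common vertex.
Weights start binary and symmetric and are usually row-standardized, which
turns the spatial lag ``(Wx)_i`` into the average of ``x`` over the
neighbours of unit ``i``.

Units with no neighbours ("islands") are kept as all-zero rows rather than
dropped, and are reported so downstream statistics can handle them
explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from shapely import STRtree
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "PolygonLayer",
    "SpatialWeights",
    "read_polygon_layer",
    "write_polygon_layer",
    "build_queen_weights",
    "row_standardize",
    "spatial_lag",
    "write_weights_gal",
    "read_weights_gal",
]


class LayerError(ValueError):
    """Raised for unreadable, empty or inconsistent polygon layers."""


class WeightsError(ValueError):
    """Raised for invalid spatial-weights structures or files."""


@dataclass
class PolygonLayer:
    """An ordered collection of areal units with polygon geometry.

    The unit order is stable and defines the row order of every matrix and
    vector derived from the layer.
    """

    ids: list[str]
    names: list[str]
    geometries: list[BaseGeometry]
    crs_label: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            seen: set[str] = set()
            dups = sorted({i for i in self.ids if i in seen or seen.add(i)})
            raise LayerError(f"duplicate unit ids: {dups}")
        if any(not i for i in self.ids):
            raise LayerError("empty unit id")
        if not (len(self.ids) == len(self.names) == len(self.geometries)):
            raise LayerError("ids, names and geometries must align")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.names, self.geometries))


def read_polygon_layer(path, id_field: str, name_field: str | None = None) -> PolygonLayer:
    """Read a GeoJSON FeatureCollection of (multi)polygons.

    Parameters
    ----------
    path : path-like
        GeoJSON file with one feature per areal unit.
    id_field : str
        Property holding the unit identifier; must be present and unique
        for every feature.
    name_field : str, optional
        Property holding a human-readable name; defaults to the id.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features")
    if feats is None:
        raise LayerError(f"{path}: not a GeoJSON FeatureCollection")
    ids, names, geoms = [], [], []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_field not in props or props[id_field] in (None, ""):
            raise LayerError(f"feature {k}: missing id field {id_field!r}")
        uid = str(props[id_field])
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # unreadable geometry names the feature
            raise LayerError(f"feature {uid!r}: unreadable geometry ({exc})") from exc
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise LayerError(f"feature {uid!r}: geometry is {geom.geom_type}, not polygonal")
        ids.append(uid)
        names.append(str(props.get(name_field, uid)) if name_field else uid)
        geoms.append(geom)
    crs = ""
    if isinstance(gj.get("crs"), dict):
        crs = str(gj["crs"].get("properties", {}).get("name", ""))
    return PolygonLayer(ids, names, geoms, crs_label=crs)


def write_polygon_layer(layer: PolygonLayer, path, properties: dict[str, dict] | None = None) -> None:
    """Write a layer as GeoJSON; ``properties`` maps unit id -> extra props."""
    feats = []
    for uid, name, geom in layer:
        props = {"id": uid, "name": name}
        if properties and uid in properties:
            props.update(properties[uid])
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class SpatialWeights:
    """Neighbour structure w_ij with standardization state.

    ``neighbors[i]`` and ``weights[i]`` are aligned lists for the unit at
    position ``i`` of ``ids``. ``standardized`` is ``"binary"`` or ``"row"``.
    Diagonal entries are always zero (no self-neighbours).
    """

    ids: list[str]
    neighbors: list[list[str]]
    weights: list[list[float]]
    standardized: str = "binary"
    islands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {u: k for k, u in enumerate(self.ids)}
        for uid, nbrs in zip(self.ids, self.neighbors):
            if uid in nbrs:
                raise WeightsError(f"self-neighbour at unit {uid!r}")
        self._eig_cache: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def S0(self) -> float:
        """Aggregate of all spatial weights, S0 = sum_i sum_j w_ij."""
        return float(sum(sum(row) for row in self.weights))

    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def island_mask(self) -> np.ndarray:
        return self.cardinalities() == 0

    def to_sparse(self) -> sp.csr_matrix:
        """W as a CSR matrix in the layer's row order."""
        rows, cols, vals = [], [], []
        for i, (nbrs, ws) in enumerate(zip(self.neighbors, self.weights)):
            for j_id, w in zip(nbrs, ws):
                rows.append(i)
                cols.append(self._index[j_id])
                vals.append(w)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    def neighbor_sets(self) -> dict[str, set[str]]:
        return {u: set(nb) for u, nb in zip(self.ids, self.neighbors)}

    def subset(self, keep_ids: list[str]) -> "SpatialWeights":
        """Restrict to ``keep_ids`` (order preserved); binary form, dropped
        units simply vanish from neighbour lists."""
        keep = set(keep_ids)
        missing = keep - set(self.ids)
        if missing:
            raise WeightsError(f"unknown ids in subset: {sorted(missing)}")
        nbrs = []
        for uid in keep_ids:
            row = [j for j in self.neighbors[self._index[uid]] if j in keep]
            nbrs.append(row)
        w = SpatialWeights(
            list(keep_ids),
            nbrs,
            [[1.0] * len(r) for r in nbrs],
            standardized="binary",
            islands=[u for u, r in zip(keep_ids, nbrs) if not r],
        )
        return row_standardize(w) if self.standardized == "row" else w

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardized W (islands excluded).

        Row standardization of a symmetric binary matrix gives W = D^-1 A,
        similar to the symmetric D^-1/2 A D^-1/2, so the spectrum is real.
        Cached: the spectrum is reused across likelihood evaluations.
        """
        if self._eig_cache is None:
            mask = ~self.island_mask()
            if self.standardized != "row":
                raise WeightsError("eigenvalues are defined for row-standardized weights")
            A = binary_adjacency(self)[np.ix_(mask, mask)]
            d = A.sum(axis=1)
            if np.any(d == 0):
                raise WeightsError("zero-degree unit after island removal")
            ds = 1.0 / np.sqrt(d)
            self._eig_cache = np.linalg.eigvalsh(A * np.outer(ds, ds))
        return self._eig_cache


def binary_adjacency(w: SpatialWeights) -> np.ndarray:
    """Dense 0/1 adjacency irrespective of standardization."""
    A = np.zeros((w.n, w.n))
    for i, nbrs in enumerate(w.neighbors):
        for j_id in nbrs:
            A[i, w._index[j_id]] = 1.0
    return A


def build_queen_weights(layer: PolygonLayer, tol: float = 1e-9) -> SpatialWeights:
    """First-order queen contiguity: neighbours share >= 1 boundary point.

    Contiguity is detected by exact boundary proximity with coordinate
    tolerance ``tol`` (census shapefiles contain snapped but imperfect
    vertices). Units with no neighbour are retained as islands with a
    warning.
    """
    if len(layer) == 0:
        raise LayerError("cannot build weights from an empty layer")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    geoms = layer.geometries
    tree = STRtree(geoms)
    nbr_idx: list[set[int]] = [set() for _ in geoms]
    for i, g in enumerate(geoms):
        # bbox query padded by tol, then exact distance check
        cand = tree.query(g.buffer(tol) if tol > 0 else g)
        for j in cand:
            j = int(j)
            if j <= i:
                continue
            if g.distance(geoms[j]) <= tol:
                nbr_idx[i].add(j)
                nbr_idx[j].add(i)
    neighbors = [[layer.ids[j] for j in sorted(s)] for s in nbr_idx]
    islands = [layer.ids[i] for i, s in enumerate(nbr_idx) if not s]
    if islands:
        warnings.warn(f"{len(islands)} island unit(s) with no neighbours: {islands[:10]}")
    return SpatialWeights(
        list(layer.ids),
        neighbors,
        [[1.0] * len(nb) for nb in neighbors],
        standardized="binary",
        islands=islands,
    )


def build_rook_weights(layer: PolygonLayer, tol: float = 1e-9) -> SpatialWeights:
    """Rook contiguity (shared edge of non-zero length); used for analytic
    test fixtures such as the checkerboard, and as a queen subset check."""
    if len(layer) == 0:
        raise LayerError("cannot build weights from an empty layer")
    geoms = layer.geometries
    tree = STRtree(geoms)
    nbr_idx: list[set[int]] = [set() for _ in geoms]
    for i, g in enumerate(geoms):
        for j in tree.query(g.buffer(max(tol, 1e-12))):
            j = int(j)
            if j <= i:
                continue
            inter = g.buffer(tol).intersection(geoms[j].buffer(tol)) if tol > 0 else g.intersection(geoms[j])
            if inter.is_empty:
                continue
            # shared edge: boundary intersection with positive length
            edge = g.boundary.intersection(geoms[j].boundary)
            if edge.length > tol:
                nbr_idx[i].add(j)
                nbr_idx[j].add(i)
    neighbors = [[layer.ids[j] for j in sorted(s)] for s in nbr_idx]
    return SpatialWeights(
        list(layer.ids),
        neighbors,
        [[1.0] * len(nb) for nb in neighbors],
        standardized="binary",
        islands=[layer.ids[i] for i, s in enumerate(nbr_idx) if not s],
    )


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Divide each non-island row by its row sum; idempotent.

    Island rows stay all-zero, so after standardization S0 = n - #islands.
    """
    new_weights = []
    for ws in w.weights:
        s = sum(ws)
        new_weights.append([v / s for v in ws] if s > 0 else list(ws))
    return SpatialWeights(
        list(w.ids),
        [list(nb) for nb in w.neighbors],
        new_weights,
        standardized="row",
        islands=list(w.islands),
    )


def spatial_lag(w: SpatialWeights, x) -> np.ndarray:
    """(Wx)_i = sum_j w_ij x_j; islands get 0."""
    x = np.asarray(x, dtype=float)
    if x.shape != (w.n,):
        raise ValueError(f"x has length {x.shape}, weights have n={w.n}")
    if np.any(~np.isfinite(x)):
        raise ValueError("x contains missing/non-finite values")
    return w.to_sparse() @ x


def write_weights_gal(w: SpatialWeights, path) -> None:
    """Serialize the neighbour structure in GAL format (binary form)."""
    if w.n == 0:
        raise WeightsError("cannot write empty weights")
    with open(path, "w") as fh:
        fh.write(f"0 {w.n} spatvax id\n")
        for uid, nbrs in zip(w.ids, w.neighbors):
            fh.write(f"{uid} {len(nbrs)}\n")
            fh.write(" ".join(nbrs) + "\n" if nbrs else "\n")


def read_weights_gal(path) -> SpatialWeights:
    """Read a GAL neighbour-list file into binary spatial weights."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise WeightsError(f"{path}: empty GAL file")
    header = lines[0].split()
    try:
        n = int(header[1]) if len(header) >= 2 else int(header[0])
    except ValueError as exc:
        raise WeightsError(f"{path}: line 1: malformed GAL header") from exc
    ids, neighbors = [], []
    ln = 1
    for _ in range(n):
        if ln >= len(lines):
            raise WeightsError(f"{path}: line {ln + 1}: truncated GAL file")
        rec = lines[ln].split()
        if len(rec) != 2:
            raise WeightsError(f"{path}: line {ln + 1}: expected 'id count'")
        uid, k_s = rec
        try:
            k = int(k_s)
        except ValueError as exc:
            raise WeightsError(f"{path}: line {ln + 1}: bad neighbour count") from exc
        nbrs = lines[ln + 1].split() if ln + 1 < len(lines) else []
        if len(nbrs) != k:
            raise WeightsError(
                f"{path}: line {ln + 2}: {len(nbrs)} neighbours listed, {k} declared"
            )
        ids.append(uid)
        neighbors.append(nbrs)
        ln += 2
    return SpatialWeights(
        ids,
        neighbors,
        [[1.0] * len(nb) for nb in neighbors],
        standardized="binary",
        islands=[u for u, nb in zip(ids, neighbors) if not nb],
    )
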