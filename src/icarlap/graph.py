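"""Contiguity graphs for areal data and the ICAR structure matrix.

A :class:`SpatialGraph` holds the binary first-order neighbourhood of a set
of polygons (or an abstract region set) together with the derived matrices

* ``W``   — symmetric binary weight matrix, ``W[i, j] = 1`` iff *j* is a
  first-order neighbour of *i*;
* ``D_w`` — diagonal degree matrix, ``D_w[i, i]`` = number of neighbours;
* ``Q``   — structure matrix ``D_w - W``; every row sums to zero, so ``Q``
  is singular with rank ``n_regions - n_components``.

Graphs are built either from explicit edge lists (:func:`edges_to_graph`,
:func:`read_edge_list`, :func:`read_gal`) or from polygon boundaries
(:func:`polygons_to_graph`).  Polygon contiguity uses exact shared-vertex
matching (no coordinate snapping): queen contiguity requires at least one
shared boundary vertex, rook contiguity a shared boundary segment of
positive length.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "SpatialGraph",
    "edges_to_graph",
    "polygons_to_graph",
    "connected_components",
    "read_edge_list",
    "read_gal",
    "write_graph_audit",
]


class GraphInputError(ValueError):
    """Raised for malformed edge lists, unknown labels, or bad polygons."""


@dataclass(frozen=True)
class SpatialGraph:
    """First-order contiguity structure of ``n_regions`` areal units."""

    n_regions: int
    edges: frozenset[tuple[int, int]]  # unordered pairs stored as (i < j)
    region_labels: tuple[str, ...]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise GraphInputError("graph needs at least one region")
        if len(self.region_labels) != self.n_regions:
            raise GraphInputError("region_labels length != n_regions")
        for i, j in self.edges:
            if i == j:
                raise GraphInputError(f"self-edge on index {i}")
            if not (0 <= i < j < self.n_regions):
                raise GraphInputError(f"edge ({i}, {j}) out of range")

    # -- derived matrices ------------------------------------------------

    @property
    def W(self) -> sp.csr_matrix:
        """Symmetric binary spatial weight matrix (sparse CSR)."""
        if "W" not in self._cache:
            if self.edges:
                ii, jj = np.array(sorted(self.edges)).T
                rows = np.concatenate([ii, jj])
                cols = np.concatenate([jj, ii])
                data = np.ones(rows.size)
            else:
                rows = cols = data = np.empty(0)
            self._cache["W"] = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_regions, self.n_regions)
            )
        return self._cache["W"]

    @property
    def degrees(self) -> np.ndarray:
        """Number of first-order neighbours of each region (row sums of W)."""
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def D_w(self) -> sp.csr_matrix:
        return sp.diags(self.degrees).tocsr()

    @property
    def Q(self) -> sp.csr_matrix:
        """ICAR structure matrix ``D_w - W`` (singular, PSD)."""
        if "Q" not in self._cache:
            self._cache["Q"] = (self.D_w - self.W).tocsr()
        return self._cache["Q"]

    @property
    def components(self) -> tuple[tuple[int, ...], ...]:
        """Connected components as ordered tuples of region indices."""
        if "components" not in self._cache:
            n, labels = _cc(self.W, directed=False)
            comps: list[list[int]] = [[] for _ in range(n)]
            for idx, lab in enumerate(labels):
                comps[lab].append(idx)
            # deterministic order: by smallest member index
            comps.sort(key=lambda c: c[0])
            self._cache["components"] = tuple(tuple(c) for c in comps)
        return self._cache["components"]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def rank_Q(self) -> int:
        """Rank of Q: ``n_regions - n_components``."""
        return self.n_regions - self.n_components

    def index_of(self, label: str) -> int:
        if "label_index" not in self._cache:
            self._cache["label_index"] = {l: i for i, l in enumerate(self.region_labels)}
        try:
            return self._cache["label_index"][label]
        except KeyError:
            raise GraphInputError(f"unknown region label {label!r}") from None

    def quadratic(self, s: np.ndarray) -> float:
        """Pairwise-difference quadratic form ``s' Q s``."""
        s = np.asarray(s, dtype=float)
        if s.shape != (self.n_regions,):
            raise GraphInputError("vector length does not match n_regions")
        return float(s @ (self.Q @ s))


def edges_to_graph(
    edge_list: Iterable[tuple[str, str]], labels: Sequence[str]
) -> SpatialGraph:
    """Build a graph from labelled edge pairs.

    Duplicate and reversed pairs collapse to a single undirected edge;
    self-pairs and labels absent from ``labels`` are hard errors.
    """
    labels = tuple(str(l) for l in labels)
    if len(set(labels)) != len(labels):
        raise GraphInputError("duplicate region labels")
    index = {l: i for i, l in enumerate(labels)}
    edges = set()
    for a, b in edge_list:
        a, b = str(a), str(b)
        if a == b:
            raise GraphInputError(f"self-pair ({a!r}, {b!r}) in edge list")
        try:
            i, j = index[a], index[b]
        except KeyError as exc:
            raise GraphInputError(f"edge label {exc.args[0]!r} not in labels") from None
        edges.add((min(i, j), max(i, j)))
    graph = SpatialGraph(len(labels), frozenset(edges), labels)
    _warn_isolated(graph)
    return graph


def connected_components(graph: SpatialGraph) -> tuple[tuple[int, ...], ...]:
    """Partition of region indices into connected components."""
    return graph.components


def _warn_isolated(graph: SpatialGraph) -> None:
    isolated = np.nonzero(graph.degrees == 0)[0]
    if isolated.size:
        names = ", ".join(graph.region_labels[i] for i in isolated)
        warnings.warn(
            f"{isolated.size} region(s) with zero neighbours form their own "
            f"component(s); their spatial effect is pinned to 0: {names}",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Edge-list / GAL readers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a plain two-column (whitespace or comma separated) edge list."""
    path = Path(path)
    if not path.exists():
        raise GraphInputError(f"edge list file not found: {path}")
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise GraphInputError(f"{path}:{lineno}: expected two columns, got {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def read_gal(path: str | Path) -> tuple[list[tuple[str, str]], list[str]]:
    """Read a GAL neighbour-list file; returns (edge pairs, ordered labels)."""
    path = Path(path)
    if not path.exists():
        raise GraphInputError(f"GAL file not found: {path}")
    tokens_by_line = [l.split() for l in path.read_text().splitlines() if l.strip()]
    if not tokens_by_line:
        raise GraphInputError(f"empty GAL file: {path}")
    header = tokens_by_line[0]
    # header is either "n" or "0 n shapefile field"
    n = int(header[1]) if len(header) >= 2 else int(header[0])
    flat = [t for line in tokens_by_line[1:] for t in line]
    labels: list[str] = []
    pairs: list[tuple[str, str]] = []
    pos = 0
    for _ in range(n):
        if pos + 1 > len(flat):
            raise GraphInputError(f"truncated GAL file: {path}")
        lab, k = flat[pos], int(flat[pos + 1])
        pos += 2
        neigh = flat[pos : pos + k]
        if len(neigh) != k:
            raise GraphInputError(f"truncated neighbour list for {lab!r}: {path}")
        pos += k
        labels.append(lab)
        pairs.extend((lab, nb) for nb in neigh)
    return pairs, labels


# ---------------------------------------------------------------------------
# Polygon contiguity
# ---------------------------------------------------------------------------

def polygons_to_graph(
    path: str | Path,
    contiguity_rule: str = "queen",
    label_field: str | None = None,
) -> SpatialGraph:
    """Derive a first-order contiguity graph from polygon boundaries.

    Parameters
    ----------
    path:
        Polygon source. Supported formats, chosen by extension: ESRI
        shapefile (``.shp``), GeoJSON (``.geojson``/``.json``) or a CSV with
        a label column and a ``wkt`` geometry column.
    contiguity_rule:
        ``"queen"`` — neighbours share at least one boundary vertex;
        ``"rook"`` — neighbours share a boundary segment of positive length.
    label_field:
        Attribute/property/column carrying region identifiers.  Defaults to
        the first text attribute (shapefile), ``"name"``-like property
        (GeoJSON) or the first column (CSV).

    Vertex ordering follows record order in the source file.
    """
    if contiguity_rule not in ("queen", "rook"):
        raise GraphInputError(f"unknown contiguity rule {contiguity_rule!r}")
    path = Path(path)
    if not path.exists():
        raise GraphInputError(f"polygon file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".shp":
        from . import _shp

        labels, rings_per_poly = _shp.read_polygon_shapefile(path, label_field)
    elif suffix in (".geojson", ".json"):
        labels, rings_per_poly = _read_geojson(path, label_field)
    elif suffix == ".csv":
        labels, rings_per_poly = _read_wkt_csv(path, label_field)
    else:
        raise GraphInputError(f"unsupported polygon format: {path.suffix}")
    if len(labels) < 2:
        raise GraphInputError("need at least two polygons")
    edges = _contiguity_edges(rings_per_poly, contiguity_rule)
    graph = SpatialGraph(
        len(labels), frozenset(edges), tuple(str(l) for l in labels)
    )
    _warn_isolated(graph)
    return graph


Ring = Sequence[tuple[float, float]]


def _contiguity_edges(
    rings_per_poly: Sequence[Sequence[Ring]], rule: str
) -> set[tuple[int, int]]:
    """Shared-vertex (queen) or shared-segment (rook) adjacency.

    Exact coordinate equality after per-ring deduplication; no snapping.
    """
    edges: set[tuple[int, int]] = set()
    # a shared key (vertex or segment) may be touched by >2 polygons at
    # corner points, so collect the full owner set per key
    key_owners: dict[object, set[int]] = {}
    for poly, rings in enumerate(rings_per_poly):
        for ring in rings:
            pts = _dedup_ring(ring)
            if rule == "queen":
                for p in pts:
                    key_owners.setdefault(p, set()).add(poly)
            else:  # rook: consecutive vertex pairs (closed ring)
                m = len(pts)
                for a in range(m):
                    p, q = pts[a], pts[(a + 1) % m]
                    if p == q:
                        continue
                    key = (p, q) if p <= q else (q, p)
                    key_owners.setdefault(key, set()).add(poly)
    for owners in key_owners.values():
        if len(owners) > 1:
            ordered = sorted(owners)
            for a in range(len(ordered)):
                for b in range(a + 1, len(ordered)):
                    edges.add((ordered[a], ordered[b]))
    return edges


def _dedup_ring(ring: Ring) -> list[tuple[float, float]]:
    """Drop the closing vertex and consecutive duplicates."""
    pts = [(float(x), float(y)) for x, y in ring]
    if len(pts) > 1 and pts[0] == pts[-1]:
        pts = pts[:-1]
    out: list[tuple[float, float]] = []
    for p in pts:
        if not out or out[-1] != p:
            out.append(p)
    return out


def _rings_from_shapely(geom) -> list[Ring]:
    from shapely.geometry import MultiPolygon, Polygon

    if isinstance(geom, Polygon):
        polys = [geom]
    elif isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    else:
        raise GraphInputError(f"expected polygonal geometry, got {geom.geom_type}")
    rings: list[Ring] = []
    for poly in polys:
        rings.append(list(poly.exterior.coords))
        rings.extend(list(r.coords) for r in poly.interiors)
    return rings


def _read_wkt_csv(path: Path, label_field: str | None):
    df = pd.read_csv(path)
    if "wkt" not in df.columns:
        raise GraphInputError(f"{path}: no 'wkt' column")
    label_col = label_field or next(c for c in df.columns if c != "wkt")
    if label_col not in df.columns:
        raise GraphInputError(f"{path}: no column {label_col!r}")
    import shapely.wkt

    labels = df[label_col].astype(str).tolist()
    rings = [_rings_from_shapely(shapely.wkt.loads(w)) for w in df["wkt"]]
    return labels, rings


def _read_geojson(path: Path, label_field: str | None):
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features")
    if feats is None:
        raise GraphInputError(f"{path}: not a GeoJSON FeatureCollection")
    labels, rings_per_poly = [], []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if label_field is not None:
            if label_field not in props:
                raise GraphInputError(f"{path}: feature {k} lacks property {label_field!r}")
            labels.append(str(props[label_field]))
        else:
            name_keys = [p for p in props if p.lower() in ("name", "label", "id")]
            labels.append(str(props[name_keys[0]]) if name_keys else str(k))
        geom = feat.get("geometry") or {}
        gtype, coords = geom.get("type"), geom.get("coordinates")
        if gtype == "Polygon":
            rings = [[(x, y) for x, y in ring] for ring in coords]
        elif gtype == "MultiPolygon":
            rings = [[(x, y) for x, y in ring] for poly in coords for ring in poly]
        else:
            raise GraphInputError(f"{path}: feature {k} has non-polygon geometry {gtype!r}")
        rings_per_poly.append(rings)
    return labels, rings_per_poly


# ---------------------------------------------------------------------------
# Audit output
# ---------------------------------------------------------------------------

def write_graph_audit(graph: SpatialGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write the derived edge list and degree table as CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_path = out_dir / "edges.csv"
    degree_path = out_dir / "degrees.csv"
    lab = graph.region_labels
    pd.DataFrame(
        [(lab[i], lab[j]) for i, j in sorted(graph.edges)],
        columns=["region_i", "region_j"],
    ).to_csv(edge_path, index=False)
    comp_of = {}
    for c, members in enumerate(graph.components):
        for m in members:
            comp_of[m] = c
    pd.DataFrame(
        {
            "region": lab,
            "degree": graph.degrees.astype(int),
            "component": [comp_of[i] for i in range(graph.n_regions)],
        }
    ).to_csv(degree_path, index=False)
    return {"edges": edge_path, "degrees": degree_path}
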