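"""Spatial weight matrices from rook contiguity.

A :class:`SpatialWeights` object carries the binary contiguity matrix ``W0``
(symmetric, zero diagonal) together with its row-standardized form ``W``
(each row rescaled to sum to one, so the spatial lag ``W x`` is a neighbor
average).  Regions are identified by strings whose order is fixed at
construction and shared by every downstream vector and matrix.

Adjacency can be built from an explicit edge list, derived from polygon
geometries by the rook rule (shared boundary *segment*, not a shared corner
point), or read from a GAL file (GeoDa interchange dialect).  Island regions
with no neighbors — e.g. an island province — are patched by hand with
:func:`patch_islands`, mirroring the common practice of linking an island to
its nearest mainland neighbor.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RegionSet",
    "SpatialWeights",
    "build_rook_from_edges",
    "build_rook_from_polygons",
    "patch_islands",
    "row_standardize",
    "read_gal",
    "write_gal",
    "read_edge_csv",
    "write_edge_csv",
    "read_geojson_polygons",
    "nearest_neighbor_candidates",
    "china_provinces",
]


class WeightsError(ValueError):
    """Invalid weights construction or use."""


class IsolateError(WeightsError):
    """A region has no neighbors where one is required."""


@dataclass(frozen=True)
class RegionSet:
    """Ordered set of unique region identifiers."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise WeightsError(f"duplicate region ids: {dupes}")
        if len(self.ids) < 2:
            raise WeightsError("need at least 2 regions")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, region_id: str) -> int:
        try:
            return self.ids.index(region_id)
        except ValueError:
            raise WeightsError(f"unknown region id: {region_id!r}") from None


@dataclass
class SpatialWeights:
    """Binary contiguity matrix plus (optionally) its row-standardized form."""

    regions: RegionSet
    W0: np.ndarray
    standardized: bool = False
    _W: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        n = self.regions.n
        if self.W0.shape != (n, n):
            raise WeightsError(f"W0 shape {self.W0.shape} != ({n}, {n})")
        if np.any(np.diag(self.W0) != 0):
            raise WeightsError("W0 has nonzero diagonal entries")
        if not np.array_equal(self.W0, self.W0.T):
            raise WeightsError("W0 is not symmetric")
        if not np.all(np.isin(self.W0, (0.0, 1.0))):
            raise WeightsError("W0 entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.regions.n

    @property
    def W(self) -> np.ndarray:
        """Row-standardized matrix; raises if the weights contain isolates."""
        if self._W is None:
            rowsums = self.W0.sum(axis=1)
            isolates = self.isolates()
            if isolates:
                raise IsolateError(
                    f"cannot row-standardize: isolated regions {isolates}"
                )
            self._W = self.W0 / rowsums[:, None]
        return self._W

    def isolates(self) -> list[str]:
        """Region ids with zero neighbors."""
        zero = np.flatnonzero(self.W0.sum(axis=1) == 0)
        return [self.regions.ids[i] for i in zero]

    def neighbors(self, region_id: str) -> list[str]:
        i = self.regions.index(region_id)
        return [self.regions.ids[j] for j in np.flatnonzero(self.W0[i])]

    def n_edges(self) -> int:
        return int(self.W0.sum() // 2)

    def matrix(self, binary: bool = False) -> np.ndarray:
        """The matrix downstream analyses should use (standardized by default)."""
        return self.W0.copy() if binary else self.W.copy()


def build_rook_from_edges(
    edges: Iterable[tuple[str, str]], regions: RegionSet
) -> SpatialWeights:
    """Build a binary contiguity matrix from an undirected edge list.

    Every id in ``edges`` must belong to ``regions``; self-pairs are rejected.
    Regions not mentioned in any edge end up as isolates (standardization
    will refuse until they are patched).
    """
    n = regions.n
    W0 = np.zeros((n, n))
    for a, b in edges:
        if a == b:
            raise WeightsError(f"self-pair not allowed: ({a!r}, {b!r})")
        i, j = regions.index(a), regions.index(b)
        W0[i, j] = W0[j, i] = 1.0
    return SpatialWeights(regions, W0)


def build_rook_from_polygons(
    geometries: dict[str, object], tol: float = 1e-9
) -> SpatialWeights:
    """Rook contiguity from shapely polygons keyed by region id.

    Two regions are adjacent iff their boundaries share a segment of positive
    length (> ``tol``); touching at a single point (queen-only contact) does
    not count.
    """
    from shapely.validation import explain_validity

    ids = tuple(geometries.keys())
    regions = RegionSet(ids)
    geoms = list(geometries.values())
    for rid, g in zip(ids, geoms):
        if not g.is_valid:
            raise WeightsError(
                f"invalid geometry for {rid!r}: {explain_validity(g)}"
            )
    n = regions.n
    W0 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            if getattr(inter, "length", 0.0) > tol:
                W0[i, j] = W0[j, i] = 1.0
    return SpatialWeights(regions, W0)


def patch_islands(
    w: SpatialWeights, patch_pairs: Sequence[tuple[str, str]]
) -> SpatialWeights:
    """Add symmetric adjacency entries linking isolates to chosen neighbors.

    The canonical use is tying an island region to its geographically closest
    mainland region.  Pairs naming a non-isolated region are still applied
    (idempotent union) with a warning.  Raises if isolates remain afterwards.
    """
    isolates_before = set(w.isolates())
    W0 = w.W0.copy()
    for a, b in patch_pairs:
        if a == b:
            raise WeightsError(f"self-pair not allowed: ({a!r}, {b!r})")
        i, j = w.regions.index(a), w.regions.index(b)
        if a not in isolates_before and b not in isolates_before:
            warnings.warn(
                f"patch pair ({a!r}, {b!r}) names no isolated region; applied anyway",
                stacklevel=2,
            )
        W0[i, j] = W0[j, i] = 1.0
    patched = SpatialWeights(w.regions, W0)
    remaining = patched.isolates()
    if remaining:
        raise IsolateError(f"isolated regions remain after patching: {remaining}")
    return patched


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Return a copy flagged as standardized; rows of ``W`` sum to one."""
    out = SpatialWeights(w.regions, w.W0.copy(), standardized=True)
    out.W  # force computation; raises IsolateError on zero rows
    return out


# ---------------------------------------------------------------------------
# GAL interchange (GeoDa dialect): header "n", then per region a record line
# "id k" followed by one line listing the k neighbor ids.
# ---------------------------------------------------------------------------

def write_gal(w: SpatialWeights, path: str | Path) -> None:
    lines = [str(w.n)]
    for rid in w.regions.ids:
        nbrs = w.neighbors(rid)
        lines.append(f"{rid} {len(nbrs)}")
        lines.append(" ".join(nbrs))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gal(path: str | Path, symmetrize: bool = False) -> SpatialWeights:
    """Parse a GAL file; by default an asymmetric listing is rejected.

    With ``symmetrize=True`` the union of the listed directed links is taken.
    """
    raw = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [(k + 1, ln.strip()) for k, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise WeightsError(f"{path}: empty GAL file")
    lineno, header = lines[0]
    # GeoDa headers may carry extra tokens; n is the first integer-looking one
    try:
        n_declared = int(header.split()[0])
    except ValueError:
        raise WeightsError(f"{path}:{lineno}: bad header {header!r}") from None
    records: list[tuple[str, list[str]]] = []
    pos = 1
    while pos < len(lines):
        lineno, rec = lines[pos]
        parts = rec.split()
        if len(parts) != 2:
            raise WeightsError(f"{path}:{lineno}: expected 'id count', got {rec!r}")
        rid, cnt_s = parts
        try:
            cnt = int(cnt_s)
        except ValueError:
            raise WeightsError(f"{path}:{lineno}: bad neighbor count {cnt_s!r}") from None
        if cnt > 0:
            if pos + 1 >= len(lines):
                raise WeightsError(f"{path}:{lineno}: missing neighbor line for {rid!r}")
            nbr_lineno, nbr_line = lines[pos + 1]
            nbrs = nbr_line.split()
            if len(nbrs) != cnt:
                raise WeightsError(
                    f"{path}:{nbr_lineno}: {rid!r} declares {cnt} neighbors, "
                    f"line lists {len(nbrs)}"
                )
            pos += 2
        else:
            nbrs = []
            pos += 1
        records.append((rid, nbrs))
    if len(records) != n_declared:
        raise WeightsError(
            f"{path}: header declares n={n_declared} but file has {len(records)} records"
        )
    regions = RegionSet(tuple(rid for rid, _ in records))
    n = regions.n
    A = np.zeros((n, n))
    for rid, nbrs in records:
        i = regions.index(rid)
        for nb in nbrs:
            A[i, regions.index(nb)] = 1.0
    if not np.array_equal(A, A.T):
        if not symmetrize:
            bad = np.argwhere(A != A.T)
            i, j = bad[0]
            raise WeightsError(
                f"{path}: asymmetric adjacency ({regions.ids[i]!r} vs "
                f"{regions.ids[j]!r}); pass symmetrize=True to take the union"
            )
        A = np.maximum(A, A.T)
    return SpatialWeights(regions, A)


# ---------------------------------------------------------------------------
# Edge-list CSV (columns src,dst) and GeoJSON polygon input
# ---------------------------------------------------------------------------

def read_edge_csv(path: str | Path) -> list[tuple[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"src", "dst"} <= set(reader.fieldnames):
            raise WeightsError(f"{path}: edge CSV must have 'src,dst' header")
        return [(row["src"], row["dst"]) for row in reader]


def write_edge_csv(w: SpatialWeights, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        out = csv.writer(fh)
        out.writerow(["src", "dst"])
        ids = w.regions.ids
        for i, j in zip(*np.nonzero(np.triu(w.W0))):
            out.writerow([ids[i], ids[j]])


def read_geojson_polygons(path: str | Path, id_property: str = "id") -> dict[str, object]:
    """Load a GeoJSON FeatureCollection into {region_id: shapely geometry}."""
    from shapely.geometry import shape

    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    geoms: dict[str, object] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise WeightsError(f"feature missing id property {id_property!r}")
        geoms[str(props[id_property])] = shape(feat["geometry"])
    return geoms


def nearest_neighbor_candidates(
    geometries: dict[str, object], isolate_ids: Sequence[str], k: int = 3
) -> dict[str, list[tuple[str, float]]]:
    """Centroid-distance nearest candidates for each isolate, for the user to
    confirm as :func:`patch_islands` pairs (patching is deliberately manual)."""
    cents = {rid: g.centroid for rid, g in geometries.items()}
    out: dict[str, list[tuple[str, float]]] = {}
    for iso in isolate_ids:
        c = cents[iso]
        dists = sorted(
            ((rid, c.distance(p)) for rid, p in cents.items() if rid != iso),
            key=lambda t: t[1],
        )
        out[iso] = dists[:k]
    return out


def china_provinces(patch_hainan: bool = True) -> SpatialWeights:
    """The packaged 31-region mainland-China provincial rook adjacency.

    Reconstructed from public provincial geography (land borders); Hainan,
    an island, is patched to Guangdong — its geographically closest
    neighbor — unless ``patch_hainan`` is False.
    """
    with resources.files("sppanel.data").joinpath("china_rook_edges.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        reader = csv.DictReader(fh)
        edges = [(row["src"], row["dst"]) for row in reader]
    ids: list[str] = []
    for a, b in edges:
        for x in (a, b):
            if x not in ids:
                ids.append(x)
    if "Hainan" not in ids:
        ids.append("Hainan")
    w = build_rook_from_edges(edges, RegionSet(tuple(sorted(ids))))
    if patch_hainan:
        w = patch_islands(w, [("Hainan", "Guangdong")])
    return w
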