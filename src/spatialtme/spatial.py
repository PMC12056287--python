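"""Spatial statistics on cell maps.

Core quantities:

* **Contact graph** — two cells are "in contact" when their centre points are
  at most 8 μm apart (boundary inclusive).  Edges are unordered; the graph is
  built with a k-d tree but defined by the all-pairs rule.
* **Interaction statistics** — for every unordered subpopulation pair (A, B):
  the raw contact count; the *(p)-normalized interaction* = contacts(A, B) /
  total immune contacts; and the *normalized interaction* = contacts(A, B) /
  (n_A + n_B) (n_A for A = A).  Significance against the random background is
  assessed by permuting subpopulation labels across the immune-cell positions
  with the geometry fixed — this preserves exactly the geometry-driven random
  contact rate — and recomputing the statistic each round.  p values are the
  standard one-sided permutation form (1 + #{null ≥ obs}) / (1 + n_perm).
* **T-cell nests** — DBSCAN over T-cell coordinates with Eps = 40 μm and
  MinPts = 27 (neighbour counts include the point itself, matching the R
  ``dbscan`` convention).  Eps can be re-calibrated on annotated data as the
  crossing point of the sensitivity and specificity curves over an Eps grid.
* **Zoning** — signed distance to the tumor-stroma borderline assigns each
  cell to the tumor centre (CT), the 360 μm invasive-margin bands (IM_TUMOR /
  IM_STROMA, boundary inclusive) or the stromal outside.
* **Random region split** — spatially contiguous partition of a large section
  into k tiles of near-equal cell count (k-means on coordinates, fixed seed)
  for heterogeneity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN, KMeans

from .datamodel import CellTable, RegionGeometry
from .errors import ConfigurationError, GeometryError
from .phenotyping import IMMUNE_LINEAGES, T_LINEAGES

__all__ = [
    "ContactGraph",
    "build_contact_graph",
    "nearest_distances",
    "interaction_statistics",
    "NestLabeling",
    "detect_nests",
    "calibrate_eps",
    "eps_sensitivity_specificity",
    "signed_distance_to_polyline",
    "zone_cells",
    "random_region_split",
]

CONTACT_THRESHOLD_UM = 8.0
NEST_EPS_UM = 40.0
NEST_MIN_PTS = 27


@dataclass
class ContactGraph:
    """Symmetric cell-contact adjacency.

    ``edges`` holds row indices into ``cell_ids`` (each unordered pair once,
    i < j); ``distances`` the matching centre distances in μm.
    """

    cell_ids: np.ndarray
    edges: np.ndarray          # (m, 2) int
    distances: np.ndarray      # (m,) float
    threshold_um: float

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(threshold_um=self.threshold_um)
        g.add_nodes_from(self.cell_ids)
        g.add_weighted_edges_from(
            (self.cell_ids[i], self.cell_ids[j], d)
            for (i, j), d in zip(self.edges, self.distances)
        )
        return g


def build_contact_graph(table: CellTable, threshold_um: float = CONTACT_THRESHOLD_UM) -> ContactGraph:
    """All unordered cell pairs with centre distance ≤ ``threshold_um``."""
    if threshold_um < 0:
        raise ConfigurationError(f"contact threshold must be >= 0, got {threshold_um}")
    coords = table.coordinates
    if len(coords) == 0:
        return ContactGraph(table.cell_ids, np.empty((0, 2), dtype=np.int64),
                            np.empty(0), float(threshold_um))
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold_um, output_type="ndarray")  # inclusive boundary
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    dists = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return ContactGraph(table.cell_ids, pairs, dists, float(threshold_um))


def nearest_distances(
    table: CellTable,
    assignment: pd.DataFrame,
    from_subpop: str,
    to_subpop: str,
) -> pd.Series | None:
    """Per-cell distance from each ``from_subpop`` cell to the nearest
    ``to_subpop`` cell (excluding itself when the subpopulations coincide).

    Returns None ("no value") when the target subpopulation is empty — or,
    for from == to, has a single cell — per the zero-denominator convention.
    """
    sub = assignment["subpopulation"].to_numpy()
    coords = table.coordinates
    from_mask = sub == from_subpop
    to_mask = sub == to_subpop
    same = from_subpop == to_subpop
    if to_mask.sum() == 0 or (same and to_mask.sum() < 2):
        return None
    if from_mask.sum() == 0:
        return pd.Series(dtype=float, name=f"nearest_{to_subpop}_um")
    tree = cKDTree(coords[to_mask])
    if same:
        d, _ = tree.query(coords[from_mask], k=2)
        dist = d[:, 1]
    else:
        dist, _ = tree.query(coords[from_mask], k=1)
    return pd.Series(
        dist, index=pd.Index(table.cell_ids[from_mask], name="cell_id"),
        name=f"nearest_{to_subpop}_um",
    )


def _pair_index(lo: np.ndarray, hi: np.ndarray, k: int) -> np.ndarray:
    # condensed index of unordered pair (lo <= hi) among k labels
    return lo * k - (lo * (lo - 1)) // 2 + (hi - lo)


def interaction_statistics(
    graph: ContactGraph,
    assignment: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    area_mm2: float | None = None,
) -> pd.DataFrame:
    """Pairwise interaction statistics with a label-permutation null.

    Only immune cells (T lineages, DC, NK) enter the totals; tumor and
    endothelial cells are excluded.  For each unordered pair of observed
    immune subpopulations (including A = A) the frame reports the contact
    count, both normalizations, the permutation-null mean/sd of the
    normalized interaction, the z score and the one-sided enrichment p value.
    Pairs are ``excluded`` when a denominator is zero.

    The frame's ``attrs`` carry ``total_contacts``, ``n_immune_cells`` and —
    when ``area_mm2`` is given — ``contacts_per_mm2``, the descriptive
    random-background contact rate.
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    if len(assignment) != graph.n_nodes:
        raise ConfigurationError("assignment and graph cover different cells")

    immune = assignment["lineage"].isin(IMMUNE_LINEAGES).to_numpy()
    labels_all = assignment["subpopulation"].to_numpy()
    imm_idx = np.flatnonzero(immune)
    cats = np.array(sorted(set(labels_all[imm_idx])))
    k = len(cats)
    if k == 0:
        raise ConfigurationError("no immune cells in assignment")
    if k == 1:
        warnings.warn("only one immune subpopulation present: null is degenerate",
                      stacklevel=2)
    code_of = {c: i for i, c in enumerate(cats)}
    codes = np.array([code_of[l] for l in labels_all[imm_idx]], dtype=np.int64)
    n_by_cat = np.bincount(codes, minlength=k)

    # immune-immune edges, re-indexed into the immune subset
    remap = np.full(graph.n_nodes, -1, dtype=np.int64)
    remap[imm_idx] = np.arange(len(imm_idx))
    if graph.n_edges:
        e = graph.edges
        keep = immune[e[:, 0]] & immune[e[:, 1]]
        u, v = remap[e[keep, 0]], remap[e[keep, 1]]
    else:
        u = v = np.empty(0, dtype=np.int64)
    total_contacts = len(u)
    n_pairs = k * (k + 1) // 2

    cu, cv = codes[u], codes[v]
    obs = np.bincount(
        _pair_index(np.minimum(cu, cv), np.maximum(cu, cv), k), minlength=n_pairs,
    ).astype(float)

    rng = np.random.default_rng(seed)
    if total_contacts:
        perm = np.tile(codes, (n_perm, 1))
        perm = rng.permuted(perm, axis=1)
        pa, pb = perm[:, u], perm[:, v]
        pid = _pair_index(np.minimum(pa, pb), np.maximum(pa, pb), k)
        flat = (np.arange(n_perm, dtype=np.int64)[:, None] * n_pairs + pid).ravel()
        null = np.bincount(flat, minlength=n_perm * n_pairs).reshape(n_perm, n_pairs).astype(float)
    else:
        null = np.zeros((n_perm, n_pairs))

    ia, ib = np.triu_indices(k)
    denom = np.where(ia == ib, n_by_cat[ia], n_by_cat[ia] + n_by_cat[ib]).astype(float)
    normalized = obs / denom
    null_norm = null / denom
    null_mean = null_norm.mean(axis=0)
    null_sd = null_norm.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n_pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (normalized - null_mean) / null_sd, np.nan)
        p_normalized = obs / total_contacts if total_contacts else np.full(n_pairs, np.nan)
    p_perm = (1.0 + (null >= obs).sum(axis=0)) / (1.0 + n_perm)

    out = pd.DataFrame({
        "subpop_a": cats[ia],
        "subpop_b": cats[ib],
        "n_a": n_by_cat[ia],
        "n_b": n_by_cat[ib],
        "contact_count": obs.astype(int),
        "p_normalized": p_normalized,
        "normalized": normalized,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "z": z,
        "p_perm": p_perm,
        "excluded": (total_contacts == 0) | (denom == 0),
    })
    out.attrs["total_contacts"] = total_contacts
    out.attrs["n_immune_cells"] = int(len(imm_idx))
    out.attrs["n_perm"] = n_perm
    if area_mm2 is not None:
        out.attrs["contacts_per_mm2"] = total_contacts / float(area_mm2)
    return out


@dataclass
class NestLabeling:
    """DBSCAN nest labels over the selected population.

    ``labels[i]`` is the nest id of ``cell_ids[i]`` or -1 for noise.
    ``nests`` summarises each nest (size and per-subpopulation composition
    when an assignment was supplied).
    """

    cell_ids: np.ndarray
    labels: np.ndarray
    eps_um: float
    min_pts: int
    nests: pd.DataFrame

    @property
    def n_nests(self) -> int:
        return int(self.nests.shape[0])

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.cell_ids, name="cell_id"),
                         name="nest_id")


def _select_population(
    table: CellTable,
    assignment: pd.DataFrame | None,
    population: str | Sequence[str] | None,
) -> np.ndarray:
    if assignment is None:
        if population is not None:
            raise ConfigurationError("population filter requires an assignment")
        return np.ones(table.n_cells, dtype=bool)
    if population is None:
        return assignment["lineage"].isin(T_LINEAGES).to_numpy()
    pops = [population] if isinstance(population, str) else list(population)
    return assignment["subpopulation"].isin(pops).to_numpy()


def detect_nests(
    table: CellTable,
    assignment: pd.DataFrame | None = None,
    eps_um: float = NEST_EPS_UM,
    min_pts: int = NEST_MIN_PTS,
    population: str | Sequence[str] | None = None,
) -> NestLabeling:
    """DBSCAN T-cell-nest detection (Eps in μm, self-inclusive MinPts).

    By default runs on all T cells of the table; ``population`` restricts to
    specific subpopulations.  Every nest has at least ``min_pts`` members.
    """
    if not eps_um > 0:
        raise ConfigurationError(f"eps_um must be > 0, got {eps_um}")
    if min_pts < 1:
        raise ConfigurationError(f"min_pts must be >= 1, got {min_pts}")
    mask = _select_population(table, assignment, population)
    coords = table.coordinates[mask]
    ids = table.cell_ids[mask]
    if len(coords) == 0:
        labels = np.empty(0, dtype=int)
    else:
        # sklearn's min_samples counts the point itself, like the R dbscan package
        labels = DBSCAN(eps=eps_um, min_samples=min_pts).fit_predict(coords)
    rows = []
    if len(labels):
        sub = assignment["subpopulation"].to_numpy()[mask] if assignment is not None else None
        for nest_id in np.unique(labels[labels >= 0]):
            members = labels == nest_id
            row: dict[str, object] = {"nest_id": int(nest_id), "size": int(members.sum())}
            if sub is not None:
                vals, counts = np.unique(sub[members], return_counts=True)
                for s, c in zip(vals, counts):
                    row[f"frac_{s}"] = 100.0 * c / members.sum()
            rows.append(row)
    nests = pd.DataFrame(rows)
    return NestLabeling(ids, labels, float(eps_um), int(min_pts), nests)


def eps_sensitivity_specificity(
    table: CellTable,
    in_nest: np.ndarray,
    eps_grid: Sequence[float],
    min_pts: int = NEST_MIN_PTS,
    assignment: pd.DataFrame | None = None,
    population: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity of nest detection vs annotation per Eps value.

    ``in_nest`` is a boolean per selected cell (truth: the cell belongs to a
    nest).  Sensitivity = fraction of true nest cells labelled in-nest;
    specificity = fraction of true non-nest cells labelled noise.
    """
    mask = _select_population(table, assignment, population)
    truth = np.asarray(in_nest, dtype=bool)
    if len(truth) != int(mask.sum()):
        raise ConfigurationError(
            f"annotation length {len(truth)} does not match the {int(mask.sum())} selected cells"
        )
    if truth.all() or not truth.any():
        raise ConfigurationError(
            "annotation must contain both nest and non-nest cells for calibration"
        )
    rows = []
    for eps in eps_grid:
        labeling = detect_nests(table, assignment, eps_um=float(eps),
                                min_pts=min_pts, population=population)
        pred = labeling.labels >= 0
        rows.append({
            "eps_um": float(eps),
            "sensitivity": pred[truth].mean(),
            "specificity": (~pred[~truth]).mean(),
        })
    return pd.DataFrame(rows)


def calibrate_eps(
    table: CellTable,
    in_nest: np.ndarray,
    eps_grid: Sequence[float],
    min_pts: int = NEST_MIN_PTS,
    assignment: pd.DataFrame | None = None,
    population: str | Sequence[str] | None = None,
) -> float:
    """Pick Eps as the sensitivity/specificity crossing over an ascending grid.

    Returns the grid value minimising |sensitivity − specificity|; ties
    resolve to the smaller Eps.
    """
    grid = [float(e) for e in eps_grid]
    if len(grid) < 2:
        raise ConfigurationError("eps_grid needs at least 2 values")
    if sorted(grid) != grid:
        raise ConfigurationError("eps_grid must be ascending")
    curve = eps_sensitivity_specificity(table, in_nest, grid, min_pts, assignment, population)
    gap = (curve["sensitivity"] - curve["specificity"]).abs().to_numpy()
    return float(curve["eps_um"].iloc[int(np.argmin(gap))])  # argmin keeps the smaller eps on ties


def signed_distance_to_polyline(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance of points to an open polyline.

    Magnitude is the nearest-segment distance; the sign is positive on the
    LEFT of the polyline's direction of travel (positive cross product).
    Points exactly on the line get +0.  Ties between segments (shared
    vertices) are broken toward the segment whose side call is least
    ambiguous (largest |cross product|).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    verts = np.asarray(vertices, dtype=float)
    seg_keep = ~np.all(verts[1:] == verts[:-1], axis=1)
    a = verts[:-1][seg_keep]
    b = verts[1:][seg_keep]
    if len(a) == 0:
        raise GeometryError("degenerate borderline: all vertices identical")
    d = b - a                                   # (s, 2)
    len2 = (d ** 2).sum(axis=1)                 # (s,)
    out = np.empty(len(pts))
    chunk = max(1, int(5e6) // max(1, len(a)))
    for start in range(0, len(pts), chunk):
        p = pts[start:start + chunk]            # (c, 2)
        rel = p[:, None, :] - a[None, :, :]     # (c, s, 2)
        t = np.clip((rel * d).sum(axis=2) / len2, 0.0, 1.0)
        proj = a + t[:, :, None] * d
        diff = p[:, None, :] - proj
        dist2 = (diff ** 2).sum(axis=2)
        cross = d[None, :, 0] * rel[:, :, 1] - d[None, :, 1] * rel[:, :, 0]
        # nearest segment; among (near-)ties prefer the larger |cross|
        min_d2 = dist2.min(axis=1, keepdims=True)
        tied = dist2 <= min_d2 + 1e-9 * (1.0 + min_d2)
        score = np.where(tied, np.abs(cross), -np.inf)
        best = score.argmax(axis=1)
        rows = np.arange(len(p))
        sign = np.where(cross[rows, best] < 0, -1.0, 1.0)
        out[start:start + chunk] = sign * np.sqrt(dist2[rows, best])
    return out


def zone_cells(table: CellTable, geometry: RegionGeometry | None = None) -> np.ndarray:
    """Assign each cell a region label relative to the tumor-stroma borderline.

    Cells within ``margin_width_um`` of the borderline (boundary inclusive)
    are IM_TUMOR or IM_STROMA depending on their side; tumor-side cells
    beyond the band are CT; stroma-side cells beyond the band are OUTSIDE.
    Cells exactly on the borderline count as tumor side.
    """
    geometry = geometry if geometry is not None else table.geometry
    if geometry is None:
        raise ConfigurationError("no geometry on table and none supplied")
    if table.n_cells == 0:
        return np.empty(0, dtype=object)
    signed = signed_distance_to_polyline(table.coordinates, geometry.borderline)
    # cells exactly on the borderline count as tumor side
    tumor_side = (signed > 0 if geometry.tumor_side == "left" else signed < 0) | (signed == 0)
    in_band = np.abs(signed) <= geometry.margin_width_um
    labels = np.where(
        in_band,
        np.where(tumor_side, "IM_TUMOR", "IM_STROMA"),
        np.where(tumor_side, "CT", "OUTSIDE"),
    )
    return labels.astype(object)


def random_region_split(table: CellTable, k: int = 48, seed: int | None = None) -> np.ndarray:
    """Partition a section into k spatially contiguous tiles of near-equal
    cell count (k-means on coordinates with a fixed seed).  Returns a region
    index per cell; deterministic for a fixed seed."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if k > table.n_cells:
        raise ConfigurationError(f"k={k} exceeds the {table.n_cells} cells available")
    if k == 1:
        return np.zeros(table.n_cells, dtype=int)
    km = KMeans(n_clusters=k, random_state=0 if seed is None else int(seed), n_init=10)
    return km.fit_predict(table.coordinates)
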