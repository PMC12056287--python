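"""Shared builders and independent reference implementations (oracles).

The oracles are deliberately naive O(n²) re-implementations used only to
check the package's spatially-indexed code paths; they never share code with
the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from spatialtme import CellTable, MarkerPanel
from spatialtme.simulate import SUBPOP_POSITIVE


def table_from_markers(entries, sample_id="s1", area_mm2=None, geometry=None,
                       panel=None) -> CellTable:
    """Build a CellTable from (marker_set, x, y) triples."""
    panel = panel or MarkerPanel.default()
    rows = []
    for i, (markers, x, y) in enumerate(entries):
        row = {"cell_id": f"c{i}", "sample_id": sample_id, "x_um": float(x), "y_um": float(y)}
        for m in panel:
            row[m] = 1 if m in markers else 0
        rows.append(row)
    cells = pd.DataFrame(rows, columns=["cell_id", "sample_id", "x_um", "y_um", *panel.names])
    return CellTable(panel=panel, cells=cells, area_mm2=area_mm2, geometry=geometry)


def table_from_subpops(entries, **kwargs) -> CellTable:
    """Build a CellTable from (subpopulation, x, y) triples with the
    defining-marker positivity of each subpopulation."""
    return table_from_markers(
        [(SUBPOP_POSITIVE[s], x, y) for s, x, y in entries], **kwargs
    )


def random_table(rng, n, box=200.0, subpops=("Tc1", "Th1", "Treg", "DC"),
                 **kwargs) -> CellTable:
    """n cells with random labels uniformly placed in a box×box square."""
    labels = rng.choice(subpops, size=n)
    xy = rng.uniform(0, box, size=(n, 2))
    return table_from_subpops(
        [(s, x, y) for s, (x, y) in zip(labels, xy)], **kwargs
    )


# -- oracles --------------------------------------------------------------------


def brute_force_contact_pairs(coords: np.ndarray, threshold: float) -> set[tuple[int, int]]:
    """All-pairs inclusive thresholding, the defining rule of the contact graph."""
    n = len(coords)
    pairs = set()
    for i in range(n):
        d = np.sqrt(((coords[i + 1:] - coords[i]) ** 2).sum(axis=1))
        for j in np.flatnonzero(d <= threshold):
            pairs.add((i, int(i + 1 + j)))
    return pairs


def brute_force_nearest(coords_from: np.ndarray, coords_to: np.ndarray,
                        exclude_self: bool) -> np.ndarray:
    out = np.empty(len(coords_from))
    for i, p in enumerate(coords_from):
        d = np.sqrt(((coords_to - p) ** 2).sum(axis=1))
        if exclude_self:
            d = np.sort(d)[1:]
        out[i] = d.min()
    return out


def reference_dbscan(coords: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Plain-Python DBSCAN with self-inclusive neighbour counts.

    Clusters are seeded in ascending index order of unlabelled core points and
    fully expanded one at a time, so border points join the earliest-created
    adjacent cluster — the same deterministic convention as the library path.
    """
    n = len(coords)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    adj = d2 <= eps ** 2  # includes self
    core = adj.sum(axis=1) >= min_pts
    cid = 0
    for seed in range(n):
        if labels[seed] != -1 or not core[seed]:
            continue
        labels[seed] = cid
        stack = [seed]
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(adj[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(int(k))
        cid += 1
    return labels


def point_segment_distance(p, a, b) -> float:
    """Closed-form distance from point p to segment ab."""
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    t = float(np.dot(p - a, ab) / np.dot(ab, ab))
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (a + t * ab)))


def exhaustive_density_ascent_modes(X: np.ndarray, k: int) -> int:
    """Mode count of the KNN-density landscape by brute-force ascent."""
    X = np.asarray(X, float)
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    order = np.argsort(d, axis=1, kind="stable")
    dens = np.empty(n)
    for i in range(n):
        nb = [j for j in order[i] if j != i][:k]
        md = d[i, nb].mean()
        dens[i] = np.inf if md == 0 else 1.0 / md
    modes = 0
    for i in range(n):
        nb = [j for j in order[i] if j != i][:k]
        denser = [j for j in nb if dens[j] > dens[i] or (dens[j] == dens[i] and j < i)]
        if not denser:
            modes += 1
    return modes


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if (a | b) else 1.0
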