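"""Contact graph, interaction statistics, nest detection, zoning, splits."""

import numpy as np
import pandas as pd
import pytest

from spatialtme import (
    ConfigurationError,
    GeometryError,
    RegionGeometry,
    assign_phenotypes,
    build_contact_graph,
    calibrate_eps,
    detect_nests,
    interaction_statistics,
    nearest_distances,
    random_region_split,
    zone_cells,
)
from spatialtme.spatial import eps_sensitivity_specificity, signed_distance_to_polyline

from helpers import (
    brute_force_contact_pairs,
    brute_force_nearest,
    point_segment_distance,
    random_table,
    reference_dbscan,
    table_from_subpops,
)


# -- contact graph ---------------------------------------------------------------


def test_contact_threshold_is_inclusive():
    table = table_from_subpops([("Tc1", 0, 0), ("Th1", 8.0, 0)])
    assert build_contact_graph(table).n_edges == 1
    table2 = table_from_subpops([("Tc1", 0, 0), ("Th1", 8.01, 0)])
    assert build_contact_graph(table2).n_edges == 0


def test_contact_graph_matches_brute_force(rng):
    for _ in range(30):
        n = int(rng.integers(0, 300))
        thr = float(rng.uniform(2, 15))
        table = random_table(rng, n, box=float(rng.uniform(50, 400)))
        graph = build_contact_graph(table, threshold_um=thr)
        got = {tuple(e) for e in graph.edges}
        assert got == brute_force_contact_pairs(table.coordinates, thr)
        assert (graph.distances <= thr).all()


def test_contact_graph_rejects_negative_threshold():
    table = table_from_subpops([("Tc1", 0, 0)])
    with pytest.raises(ConfigurationError):
        build_contact_graph(table, threshold_um=-1.0)


def test_contact_graph_networkx_export():
    table = table_from_subpops([("Tc1", 0, 0), ("Th1", 5, 0), ("Treg", 100, 0)])
    g = build_contact_graph(table).to_networkx()
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 1


# -- nearest distances -----------------------------------------------------------


def test_nearest_distance_345():
    table = table_from_subpops([("Tc1", 0, 0), ("Th1", 3, 4), ("Th1", 10, 0)])
    d = nearest_distances(table, assign_phenotypes(table), "Tc1", "Th1")
    assert d.iloc[0] == pytest.approx(5.0)


def test_nearest_distance_excludes_self_and_empty_targets():
    table = table_from_subpops([("Tc1", 0, 0)])
    a = assign_phenotypes(table)
    assert nearest_distances(table, a, "Tc1", "Tc1") is None  # single cell
    assert nearest_distances(table, a, "Tc1", "Th1") is None  # empty target


def test_nearest_distances_match_brute_force(rng):
    for _ in range(20):
        table = random_table(rng, int(rng.integers(5, 120)), box=150.0)
        a = assign_phenotypes(table)
        sub = a["subpopulation"].to_numpy()
        for frm, to in (("Tc1", "Th1"), ("Tc1", "Tc1")):
            got = nearest_distances(table, a, frm, to)
            coords = table.coordinates
            f, t = sub == frm, sub == to
            if got is None:
                assert t.sum() == 0 or (frm == to and t.sum() < 2)
                continue
            want = brute_force_nearest(coords[f], coords[t], exclude_self=(frm == to))
            np.testing.assert_allclose(got.to_numpy(), want)


# -- interaction statistics ------------------------------------------------------


def _square_table():
    # A-A 1 contact, B-B 1, A-B 2: 6 μm square; diagonals 8.49 μm > 8
    return table_from_subpops(
        [("Tc1", 0, 0), ("Tc1", 0, 6), ("Th1", 6, 0), ("Th1", 6, 6)]
    )


def test_p_normalized_from_contact_counts():
    table = _square_table()
    res = interaction_statistics(build_contact_graph(table), assign_phenotypes(table),
                                 n_perm=50, seed=0)
    r = res.set_index(["subpop_a", "subpop_b"])
    assert res.attrs["total_contacts"] == 4
    assert r.loc[("Tc1", "Th1"), "contact_count"] == 2
    assert r.loc[("Tc1", "Th1"), "p_normalized"] == pytest.approx(0.5)
    assert r.loc[("Tc1", "Tc1"), "p_normalized"] == pytest.approx(0.25)
    assert res["p_normalized"].sum() == pytest.approx(1.0, abs=1e-12)


def test_normalized_uses_combined_cell_count(rng):
    # 5 close A-B pairs plus 5 isolated A and 5 isolated B: 5/(10+10)
    entries = []
    for i in range(5):
        entries += [("Tc1", 100 * i, 0), ("Th1", 100 * i + 4, 0)]
    entries += [("Tc1", 100 * i, 500) for i in range(5)]
    entries += [("Th1", 100 * i, 900) for i in range(5)]
    table = table_from_subpops(entries)
    res = interaction_statistics(build_contact_graph(table), assign_phenotypes(table),
                                 n_perm=50, seed=0)
    r = res.set_index(["subpop_a", "subpop_b"])
    assert r.loc[("Tc1", "Th1"), "n_a"] == 10
    assert r.loc[("Tc1", "Th1"), "normalized"] == pytest.approx(0.25)


def test_p_normalized_sums_to_one_on_simulated_cores():
    from spatialtme import generate_sample, preset
    for seed in range(5):
        table, _ = generate_sample(preset("MSI"), seed=seed)
        a = assign_phenotypes(table)
        res = interaction_statistics(build_contact_graph(table), a, n_perm=2, seed=0)
        if res.attrs["total_contacts"] > 0:
            assert res["p_normalized"].sum() == pytest.approx(1.0, abs=1e-9)


def test_no_contacts_marks_all_pairs_excluded():
    table = table_from_subpops([("Tc1", 0, 0), ("Th1", 500, 0)])
    res = interaction_statistics(build_contact_graph(table), assign_phenotypes(table),
                                 n_perm=10, seed=0)
    assert res["excluded"].all()
    assert res["p_normalized"].isna().all()


def test_interaction_requires_valid_n_perm_and_warns_on_degenerate():
    table = _square_table()
    a = assign_phenotypes(table)
    graph = build_contact_graph(table)
    with pytest.raises(ConfigurationError):
        interaction_statistics(graph, a, n_perm=0)
    solo = table_from_subpops([("Tc1", 0, 0), ("Tc1", 5, 0)])
    with pytest.warns(UserWarning, match="one immune subpopulation"):
        interaction_statistics(build_contact_graph(solo), assign_phenotypes(solo),
                               n_perm=10, seed=0)


def test_interactions_exclude_tumor_and_endothelium():
    entries = [("Tc1", 0, 0), ("Th1", 5, 0), ("Tumor", 2, 2), ("Endothelial", 3, 3)]
    table = table_from_subpops(entries)
    res = interaction_statistics(build_contact_graph(table), assign_phenotypes(table),
                                 n_perm=10, seed=0)
    assert set(res["subpop_a"]) | set(res["subpop_b"]) == {"Tc1", "Th1"}
    assert res.attrs["total_contacts"] == 1
    assert res.attrs["n_immune_cells"] == 2


def test_interaction_statistics_deterministic_for_seed():
    from spatialtme import generate_sample, preset
    table, _ = generate_sample(preset("MSS"), seed=7)
    a = assign_phenotypes(table)
    g = build_contact_graph(table)
    r1 = interaction_statistics(g, a, n_perm=100, seed=5)
    r2 = interaction_statistics(g, a, n_perm=100, seed=5)
    pd.testing.assert_frame_equal(r1, r2)


# -- nest detection --------------------------------------------------------------


def test_dbscan_matches_reference_on_random_instances(rng):
    for _ in range(30):
        n = int(rng.integers(0, 250))
        table = random_table(rng, n, box=float(rng.uniform(60, 300)))
        a = assign_phenotypes(table)
        eps = float(rng.uniform(10, 60))
        min_pts = int(rng.integers(3, 30))
        got = detect_nests(table, a, eps_um=eps, min_pts=min_pts)
        t_cells = a["lineage"].isin(("CYTOTOXIC_T", "HELPER_T", "OTHER_T")).to_numpy()
        want = reference_dbscan(table.coordinates[t_cells], eps, min_pts)
        np.testing.assert_array_equal(got.labels, want)


def test_min_pts_boundary_26_vs_27(rng):
    """26 mutually-reachable cells are no nest at MinPts=27; 27 are one."""
    def tight_cluster(k):
        xy = rng.uniform(0, 10, (k, 2))  # all pairwise << 40 μm
        return table_from_subpops([("Tc1", x, y) for x, y in xy])

    t26 = tight_cluster(26)
    lab26 = detect_nests(t26, assign_phenotypes(t26), eps_um=40, min_pts=27)
    assert lab26.n_nests == 0 and (lab26.labels == -1).all()
    t27 = tight_cluster(27)
    lab27 = detect_nests(t27, assign_phenotypes(t27), eps_um=40, min_pts=27)
    assert lab27.n_nests == 1
    assert lab27.nests["size"].iloc[0] == 27


def test_detect_nests_empty_input_and_parameter_validation():
    empty = table_from_subpops([])
    lab = detect_nests(empty, assign_phenotypes(empty))
    assert lab.n_nests == 0 and len(lab.labels) == 0
    t = table_from_subpops([("Tc1", 0, 0)])
    with pytest.raises(ConfigurationError):
        detect_nests(t, assign_phenotypes(t), eps_um=0.0)
    with pytest.raises(ConfigurationError):
        detect_nests(t, assign_phenotypes(t), min_pts=0)


def test_nests_run_on_t_cells_only_by_default(rng):
    xy = rng.uniform(0, 15, (30, 2))
    entries = [("Tc1", x, y) for x, y in xy[:15]] + [("Tumor", x, y) for x, y in xy[15:]]
    table = table_from_subpops(entries)
    lab = detect_nests(table, assign_phenotypes(table), eps_um=40, min_pts=10)
    assert len(lab.labels) == 15  # only the T cells were clustered
    assert lab.n_nests == 1
    assert lab.nests.loc[0, "frac_Tc1"] == pytest.approx(100.0)


def test_nest_composition_fractions(rng):
    xy = rng.uniform(0, 12, (30, 2))
    entries = [("Tc1", x, y) for x, y in xy[:20]] + [("Th1", x, y) for x, y in xy[20:]]
    table = table_from_subpops(entries)
    lab = detect_nests(table, assign_phenotypes(table), eps_um=40, min_pts=27)
    assert lab.n_nests == 1
    assert lab.nests.loc[0, "frac_Tc1"] == pytest.approx(100 * 20 / 30)
    assert lab.nests.loc[0, "frac_Th1"] == pytest.approx(100 * 10 / 30)


# -- eps calibration -------------------------------------------------------------


def _nested_scene(rng):
    """A tight 40-cell cluster plus sparse background, with truth labels."""
    core = rng.uniform(0, 30, (40, 2))
    bg = rng.uniform(100, 600, (60, 2))
    entries = [("Tc1", x, y) for x, y in core] + [("Tc1", x, y) for x, y in bg]
    truth = np.array([True] * 40 + [False] * 60)
    return table_from_subpops(entries), truth


def test_calibrate_eps_returns_smallest_perfect_separator(rng):
    table, truth = _nested_scene(rng)
    a = assign_phenotypes(table)
    grid = [5, 10, 15, 20, 25, 30, 40, 60]
    curve = eps_sensitivity_specificity(table, truth, grid, min_pts=20, assignment=a)
    eps = calibrate_eps(table, truth, grid, min_pts=20, assignment=a)
    perfect = curve[(curve.sensitivity == 1.0) & (curve.specificity == 1.0)]
    assert not perfect.empty
    assert eps == perfect["eps_um"].min()  # tie rule: smaller eps wins


def test_calibrate_eps_validates_inputs(rng):
    table, truth = _nested_scene(rng)
    a = assign_phenotypes(table)
    with pytest.raises(ConfigurationError, match="at least 2"):
        calibrate_eps(table, truth, [40], assignment=a)
    with pytest.raises(ConfigurationError, match="ascending"):
        calibrate_eps(table, truth, [40, 20], assignment=a)
    with pytest.raises(ConfigurationError, match="both nest and non-nest"):
        calibrate_eps(table, np.ones(len(truth), bool), [20, 40], assignment=a)


# -- zoning ----------------------------------------------------------------------


def _vertical_geom(tumor_side="right"):
    return RegionGeometry(borderline=np.array([[0.0, 0.0], [0.0, 1000.0]]),
                          tumor_side=tumor_side, margin_width_um=360.0)


def test_zone_labels_from_the_borderline():
    geom = _vertical_geom()  # walking +y, tumor to the right = +x...
    # with tumor_side="right": positive x is the right of the upward polyline
    table = table_from_subpops([
        ("Tc1", 100, 500),    # 100 μm into tumor
        ("Tc1", -100, 500),   # 100 μm into stroma
        ("Tc1", 500, 500),    # deep tumor -> CT
        ("Tc1", -500, 500),   # deep stroma -> OUTSIDE
        ("Tc1", 360, 500),    # exactly on the band edge -> inclusive
        ("Tc1", -360, 500),
        ("Tc1", 0, 500),      # on the line counts as tumor side
    ])
    labels = zone_cells(table, geom)
    assert list(labels) == [
        "IM_TUMOR", "IM_STROMA", "CT", "OUTSIDE", "IM_TUMOR", "IM_STROMA", "IM_TUMOR",
    ]


def test_zone_respects_declared_tumor_side():
    table = table_from_subpops([("Tc1", 100, 500), ("Tc1", 500, 500)])
    left = zone_cells(table, _vertical_geom(tumor_side="left"))
    assert list(left) == ["IM_STROMA", "OUTSIDE"]


def test_signed_distance_matches_point_segment_oracle(rng):
    verts = np.array([[0.0, 0.0], [100.0, 50.0], [250.0, 40.0], [300.0, 200.0]])
    pts = rng.uniform(-50, 350, (200, 2))
    got = signed_distance_to_polyline(pts, verts)
    for p, d in zip(pts, got):
        want = min(point_segment_distance(p, verts[i], verts[i + 1])
                   for i in range(len(verts) - 1))
        assert abs(abs(d) - want) < 1e-9


def test_zone_requires_geometry_and_rejects_degenerate():
    table = table_from_subpops([("Tc1", 0, 0)])
    with pytest.raises(ConfigurationError, match="geometry"):
        zone_cells(table)
    with pytest.raises(GeometryError, match="degenerate"):
        signed_distance_to_polyline(np.array([[1.0, 1.0]]),
                                    np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]]))


def test_zone_uses_table_geometry_when_attached():
    geom = _vertical_geom()
    table = table_from_subpops([("Tc1", 100, 500)], geometry=geom)
    assert list(zone_cells(table)) == ["IM_TUMOR"]


# -- random region split ---------------------------------------------------------


def test_region_split_contract(rng):
    table = random_table(rng, 400, box=1000.0)
    assert (random_region_split(table, k=1) == 0).all()
    r1 = random_region_split(table, k=8, seed=3)
    r2 = random_region_split(table, k=8, seed=3)
    np.testing.assert_array_equal(r1, r2)
    assert len(np.unique(r1)) == 8
    with pytest.raises(ConfigurationError):
        random_region_split(table, k=0)
    with pytest.raises(ConfigurationError):
        random_region_split(table, k=401)


def test_region_split_is_roughly_balanced_on_uniform_data(rng):
    table = random_table(rng, 4000, box=2000.0)
    regions = random_region_split(table, k=8, seed=0)
    counts = np.bincount(regions, minlength=8)
    assert counts.max() <= 2 * counts.min()
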