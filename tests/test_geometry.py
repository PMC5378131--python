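"""Geometry: icosphere construction, carving, fibrosis, neighbour map."""

import numpy as np
import pytest

from afca import ModelParams, physical_radius_from_volume
from afca.geometry import (ACTIVE, FIBROTIC, MV_HOLE, PV_HOLE,
                           build_icosphere, build_neighbour_map,
                           carve_anatomy, fibrosis_weights,
                           mark_functional_regions, mean_neighbourhood_size,
                           sample_fibrosis, great_circle, sph_to_xyz)


# ---------------------------------------------------------------------------
# independent oracle: explicit midpoint subdivision of the icosahedron
# ---------------------------------------------------------------------------

def _icosahedron():
    t = (1 + 5 ** 0.5) / 2
    verts = [(-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
             (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
             (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1)]
    faces = [(0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
             (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
             (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
             (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)]
    return verts, faces


def _subdivision_vertex_counts(max_level):
    verts, faces = _icosahedron()
    counts = [len(verts)]
    for _ in range(max_level):
        cache = {}
        n = len(verts)
        new_faces = []
        for (a, b, c) in faces:
            mids = []
            for (i, j) in ((a, b), (b, c), (c, a)):
                key = (min(i, j), max(i, j))
                if key not in cache:
                    cache[key] = n
                    n += 1
                mids.append(cache[key])
            ab, bc, ca = mids
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
        verts = verts + [None] * len(cache)  # positions irrelevant to the count
        counts.append(n)
    return counts


def test_icosphere_node_counts_match_explicit_subdivision():
    oracle = _subdivision_vertex_counts(5)
    for level, expected in enumerate(oracle):
        assert expected == 10 * 4 ** level + 2
        mesh = build_icosphere(level)
        assert mesh.n_nodes == expected
        assert np.allclose(np.linalg.norm(mesh.xyz, axis=1), 1.0)


def test_icosphere_rejects_negative_level():
    with pytest.raises(ValueError):
        build_icosphere(-1)


@pytest.mark.parametrize("volume_ml, radius_mm, sig", [
    (40.0, 21.2, 3),                       # left-atrium volume
    (4 / 3 * np.pi, 10.0, 6),              # unit radius in cm
    (1.0, 6.20, 3),
])
def test_sphere_radius_from_volume(volume_ml, radius_mm, sig):
    r = physical_radius_from_volume(volume_ml)
    assert r == pytest.approx(radius_mm, rel=10 ** (1 - sig) / 2)


def test_radius_from_volume_rejects_nonpositive():
    for v in (0.0, -1.0):
        with pytest.raises(ValueError):
            physical_radius_from_volume(v)


# ---------------------------------------------------------------------------
# carving
# ---------------------------------------------------------------------------

def test_pv_disc_radius_in_scaled_units(baseline_params):
    assert baseline_params.pv_radius_rad == pytest.approx(0.236, abs=5e-4)


def test_mv_rim_colatitude_and_membership(mesh5, baseline_params):
    # rim colatitude from the south pole solves 2 pi R sin(psi) = 85 mm
    psi = baseline_params.mv_radius_rad
    assert psi == pytest.approx(np.arcsin(85 / (2 * np.pi * 21.2)), abs=1e-12)
    assert psi == pytest.approx(0.694, abs=2e-3)
    d_south = mesh5.distance_rad(np.pi, 0.0)
    inside = d_south <= psi
    assert np.array_equal(inside & ~(mesh5.region == PV_HOLE),
                          mesh5.region == MV_HOLE)


def test_zero_pv_radius_removes_nothing():
    p = ModelParams(pv_radius_mm=1e-9)
    mesh = build_icosphere(2)
    carve_anatomy(mesh, p)
    assert not np.any(mesh.region == PV_HOLE)


def test_carving_is_idempotent(baseline_params):
    mesh = build_icosphere(3)
    carve_anatomy(mesh, baseline_params)
    before = mesh.region.copy()
    carve_anatomy(mesh, baseline_params)
    assert np.array_equal(before, mesh.region)


def test_excessive_holes_raise():
    p = ModelParams(pv_radius_mm=25.0)
    mesh = build_icosphere(2)
    with pytest.raises(ValueError, match="active"):
        carve_anatomy(mesh, p)


# ---------------------------------------------------------------------------
# fibrosis
# ---------------------------------------------------------------------------

def test_fibrosis_count_and_exclusions(mesh5, baseline_params):
    sample_fibrosis(mesh5, 300, 42, baseline_params)
    fib = np.flatnonzero(mesh5.region == FIBROTIC)
    assert fib.size == 300
    assert not np.any(mesh5.is_hole[fib])
    sample_fibrosis(mesh5, 0, 0, baseline_params)
    assert not np.any(mesh5.region == FIBROTIC)


def test_fibrosis_seed_reproducibility(mesh5, baseline_params):
    sample_fibrosis(mesh5, 100, 7, baseline_params)
    a = set(np.flatnonzero(mesh5.region == FIBROTIC))
    sample_fibrosis(mesh5, 100, 7, baseline_params)
    b = set(np.flatnonzero(mesh5.region == FIBROTIC))
    sample_fibrosis(mesh5, 100, 8, baseline_params)
    c = set(np.flatnonzero(mesh5.region == FIBROTIC))
    sample_fibrosis(mesh5, 0, 0, baseline_params)
    assert a == b
    assert a != c


def test_fibrosis_overdraw_raises(small_mesh, small_params):
    n_active = int((small_mesh.region == ACTIVE).sum())
    with pytest.raises(ValueError):
        sample_fibrosis(small_mesh, n_active + 1, 0, small_params)
    sample_fibrosis(small_mesh, 0, 0, small_params)


def test_fibrosis_hit_frequency_matches_weights(baseline_params):
    """10^4 draws of FC = 1: per-node hit counts agree with the analytic
    normal-density weights within 3 binomial standard errors."""
    mesh = build_icosphere(3)
    carve_anatomy(mesh, baseline_params)
    w = fibrosis_weights(mesh, baseline_params)
    n = 10_000
    rng = np.random.default_rng(123)
    cdf = np.cumsum(w)
    draws = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
    counts = np.bincount(draws, minlength=mesh.n_nodes)
    exp = n * w
    se = np.sqrt(np.maximum(n * w * (1 - w), 1e-12))
    z = np.abs(counts - exp) / np.maximum(se, 1.0)
    # a handful of >3 SE nodes is expected by chance among ~600; not many
    assert np.mean(z <= 3.0) > 0.99
    top = int(np.argmax(w))
    assert abs(counts[top] - exp[top]) <= 3 * se[top]


# ---------------------------------------------------------------------------
# neighbour map
# ---------------------------------------------------------------------------

def test_neighbour_map_symmetry_and_irreflexivity_brute_force(baseline_params):
    mesh = build_icosphere(2)
    carve_anatomy(mesh, baseline_params)
    build_neighbour_map(mesh, 2.544 * 8)   # level-2 spacing is 8x level-5
    nbrs = {i: set(mesh.neighbours(i)) for i in range(mesh.n_nodes)}
    ang = 2.544 * 8 / mesh.scale_mm
    for i in range(mesh.n_nodes):
        assert i not in nbrs[i]
        for j in nbrs[i]:
            assert i in nbrs[j]
        if mesh.is_hole[i]:
            assert not nbrs[i]
            continue
        # brute-force distance recheck
        d = great_circle(mesh.xyz, mesh.xyz[i][None, :])
        expected = {j for j in np.flatnonzero((d <= ang) & ~mesh.is_hole)
                    if j != i}
        assert nbrs[i] == expected


def test_mean_neighbourhood_is_about_36(sphere5):
    assert mean_neighbourhood_size(sphere5) == pytest.approx(36, abs=2)


def test_mean_spacing_below_interaction_radius(sphere5):
    from scipy.spatial import cKDTree
    tree = cKDTree(sphere5.xyz)
    d, _ = tree.query(sphere5.xyz, k=2)
    arc_mm = 2 * np.arcsin(d[:, 1] / 2) * sphere5.scale_mm
    assert arc_mm.mean() < 2.544


def test_tiny_radius_warns_and_gives_empty_neighbourhoods(baseline_params):
    mesh = build_icosphere(2)
    with pytest.warns(UserWarning):
        build_neighbour_map(mesh, 1e-3)
    assert mesh.indices.size == 0


# ---------------------------------------------------------------------------
# functional regions
# ---------------------------------------------------------------------------

def test_sn_disc_nonempty_and_disjoint_from_holes(mesh5):
    assert mesh5.sn_nodes.size > 0
    assert not np.any(mesh5.is_hole[mesh5.sn_nodes])


def test_zero_width_annulus_is_empty(baseline_params):
    p = baseline_params.replace(annulus_width_mm=0.0)
    mesh = build_icosphere(3)
    carve_anatomy(mesh, p)
    build_neighbour_map(mesh, p.interaction_radius_mm * 4)
    mark_functional_regions(mesh, p)
    assert mesh.annulus_nodes.size == 0


def test_annulus_and_burst_group_distances(mesh5, baseline_params):
    p = baseline_params
    r_in, r_out = p.pv_radius_rad, p.pv_radius_rad + p.mm_to_rad(2.0)
    pv_centres = np.array([sph_to_xyz(np.float64(t), np.float64(ph))
                           for t, ph in p.pv_centres])
    for a, pv in zip(mesh5.annulus_nodes, mesh5.annulus_pv):
        d = float(great_circle(mesh5.xyz[a], pv_centres[pv]))
        assert r_in < d <= r_out + 1e-12
    # every burst-group member lies within 2.12 mm of its annulus seed
    r_grp = p.mm_to_rad(p.burst_group_radius_mm)
    for ai in range(mesh5.annulus_nodes.size):
        seed = mesh5.annulus_nodes[ai]
        grp = mesh5.group_indices[
            mesh5.group_indptr[ai]:mesh5.group_indptr[ai + 1]]
        d = great_circle(mesh5.xyz[grp], mesh5.xyz[seed][None, :])
        assert np.all(d <= r_grp + 1e-12)
        assert seed in grp


def test_empty_sn_disc_raises(baseline_params):
    p = baseline_params.replace(sn_radius_mm=1e-6)
    mesh = build_icosphere(2)
    carve_anatomy(mesh, p)
    with pytest.raises(ValueError, match="sinus"):
        mark_functional_regions(mesh, p)
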