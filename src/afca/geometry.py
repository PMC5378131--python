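"""Spherical left-atrium substrate.

Builds the icosphere node set, carves the electrically inactive anatomical
holes (four pulmonary veins and the mitral valve), samples fibrotic nodes
from a normal density on the posterior wall, and assembles the fixed
neighbour map and functional regions (sinus-node disc, PV annuli and their
burst groups) consumed by the automaton.

All geometric membership tests use great-circle (geodesic) distance; at the
radii involved, chord and arc differ by well under 0.1%, but one convention
is fixed throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .params import ModelParams

# region codes
ACTIVE = 0
PV_HOLE = 1
MV_HOLE = 2
FIBROTIC = 3

REGION_NAMES = {ACTIVE: "active", PV_HOLE: "PV_hole",
                MV_HOLE: "MV_hole", FIBROTIC: "fibrotic"}


def sph_to_xyz(theta, phi):
    """Unit vector for colatitude ``theta`` (from +z) and azimuth ``phi``."""
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def great_circle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Great-circle distance (radians on the unit sphere) between unit vectors.

    Uses atan2(|u x v|, u.v), which is numerically stable near 0 and pi.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    cross = np.cross(u, v)
    cn = np.linalg.norm(np.atleast_2d(cross), axis=-1)
    if cross.ndim == 1:
        cn = cn[0]
    return np.arctan2(cn, (u * v).sum(axis=-1))


@dataclass
class AtrialMesh:
    """Node positions, region labels and connectivity of the substrate.

    ``xyz`` are unit-sphere positions; 1 scaled unit corresponds to
    ``scale_mm`` = 21.2 mm of physical length.  Hole nodes are retained in
    the arrays (with empty neighbour lists and permanently inert dynamics)
    so node indices always refer to the raw icosphere.
    """

    xyz: np.ndarray                      # (n, 3) float64 on the unit sphere
    region: np.ndarray                   # (n,) int8 region codes
    scale_mm: float = 21.2
    subdivision_level: Optional[int] = None
    # neighbour map (CSR over all nodes; holes have empty rows)
    indptr: Optional[np.ndarray] = None
    indices: Optional[np.ndarray] = None
    interaction_radius_mm: Optional[float] = None
    # functional regions
    sn_nodes: Optional[np.ndarray] = None
    annulus_nodes: Optional[np.ndarray] = None
    annulus_pv: Optional[np.ndarray] = None      # PV id per annulus node
    group_indptr: Optional[np.ndarray] = None    # burst group per annulus node
    group_indices: Optional[np.ndarray] = None

    # -- coordinates -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.xyz.shape[0]

    @property
    def theta(self) -> np.ndarray:
        return np.arccos(np.clip(self.xyz[:, 2], -1.0, 1.0))

    @property
    def phi(self) -> np.ndarray:
        return np.arctan2(self.xyz[:, 1], self.xyz[:, 0])

    # -- masks ---------------------------------------------------------------
    @property
    def is_hole(self) -> np.ndarray:
        return (self.region == PV_HOLE) | (self.region == MV_HOLE)

    @property
    def is_fibrotic(self) -> np.ndarray:
        return self.region == FIBROTIC

    @property
    def excitable(self) -> np.ndarray:
        """Nodes that take part in the dynamics (not holes, not fibrotic)."""
        return self.region == ACTIVE

    def copy(self) -> "AtrialMesh":
        """Copy with an independent region array; geometry and maps shared."""
        new = AtrialMesh(self.xyz, self.region.copy(), self.scale_mm,
                         self.subdivision_level, self.indptr, self.indices,
                         self.interaction_radius_mm, self.sn_nodes,
                         self.annulus_nodes, self.annulus_pv,
                         self.group_indptr, self.group_indices)
        return new

    def neighbours(self, i: int) -> np.ndarray:
        if self.indptr is None:
            raise ValueError("neighbour map not built")
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def distance_rad(self, centre_theta: float, centre_phi: float) -> np.ndarray:
        """Great-circle distance of every node from a (theta, phi) centre."""
        c = sph_to_xyz(np.float64(centre_theta), np.float64(centre_phi))
        return great_circle(self.xyz, c[None, :])


def build_icosphere(subdivision_level: int, scale_mm: float = 21.2) -> AtrialMesh:
    """Evenly distributed nodes from icosahedral dissection.

    Level L yields 10*4^L + 2 vertices; level 5 gives the 10 242-node
    substrate.  Deterministic for a given level.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision level must be >= 0")
    mesh = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    xyz = np.asarray(mesh.vertices, dtype=np.float64)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    expected = 10 * 4 ** subdivision_level + 2
    assert xyz.shape[0] == expected, "icosphere vertex count mismatch"
    return AtrialMesh(xyz=xyz, region=np.zeros(xyz.shape[0], np.int8),
                      scale_mm=scale_mm, subdivision_level=subdivision_level)


def carve_anatomy(mesh: AtrialMesh, params: ModelParams) -> AtrialMesh:
    """Label the PV and MV discs as permanent holes.

    Disc membership uses great-circle distance.  The MV is the disc centred
    on the south pole whose rim circumference equals the configured 85 mm on
    the physical sphere; each PV is a 5 mm (0.236 scaled units) disc.
    Idempotent; raises if fewer than half the nodes would remain active.
    """
    region = mesh.region
    # reset previous hole labels so carving is idempotent under re-parameterization
    region[(region == PV_HOLE) | (region == MV_HOLE)] = ACTIVE

    for (th, ph) in params.pv_centres:
        d = mesh.distance_rad(th, ph)
        inside = d <= params.pv_radius_rad
        region[inside & (region != FIBROTIC)] = PV_HOLE
    d_mv = mesh.distance_rad(*params.mv_centre)
    region[(d_mv <= params.mv_radius_rad) & (region != FIBROTIC)] = MV_HOLE

    active_frac = (region == ACTIVE).sum() / mesh.n_nodes
    if active_frac < 0.5:
        raise ValueError(
            f"carving leaves only {active_frac:.0%} of nodes active; "
            "check hole parameters")
    return mesh


def fibrosis_weights(mesh: AtrialMesh, params: ModelParams) -> np.ndarray:
    """Per-node sampling weight for fibrosis: isotropic normal density in
    great-circle distance from the posterior-wall centre, sigma = 0.4 sphere
    radii, normalized over currently active nodes (zero elsewhere)."""
    d = mesh.distance_rad(*params.fibrosis_centre)
    w = np.exp(-0.5 * (d / params.fibrosis_sigma_rad) ** 2)
    w[mesh.region != ACTIVE] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("no active nodes available for fibrosis sampling")
    return w / total


def sample_fibrosis(mesh: AtrialMesh, fc: int, rng,
                    params: ModelParams | None = None) -> AtrialMesh:
    """Relabel exactly ``fc`` distinct active nodes as fibrotic.

    Nodes are drawn without replacement by inverse-transform sampling on the
    discrete normalized weight distribution, re-normalized after each draw
    (one uniform per removed node).  Any previous fibrosis labels are
    cleared first, so repeated calls resample rather than accumulate.
    ``rng`` may be a seed or a numpy Generator.
    """
    rng = np.random.default_rng(rng)
    mesh.region[mesh.region == FIBROTIC] = ACTIVE
    if fc == 0:
        return mesh
    w = fibrosis_weights(mesh, params or _DEFAULT_PARAMS)
    n_avail = int((w > 0).sum())
    if fc > n_avail:
        raise ValueError(f"FC = {fc} exceeds the {n_avail} available active nodes")
    weights = w.copy()
    chosen = np.empty(fc, dtype=np.int64)
    for j in range(fc):
        cdf = np.cumsum(weights)
        u = rng.random() * cdf[-1]
        i = int(np.searchsorted(cdf, u, side="right"))
        i = min(i, len(weights) - 1)
        chosen[j] = i
        weights[i] = 0.0
    mesh.region[chosen] = FIBROTIC
    return mesh


_DEFAULT_PARAMS = ModelParams()


def build_neighbour_map(mesh: AtrialMesh, interaction_radius_mm: float) -> AtrialMesh:
    """Attach the symmetric, irreflexive neighbour map.

    For every non-hole node, all other non-hole nodes within the interaction
    radius (great-circle).  Fibrotic nodes are retained as entries — they
    occupy space but never activate — while hole nodes get empty rows.
    """
    if interaction_radius_mm <= 0:
        raise ValueError("interaction radius must be positive")
    ang = interaction_radius_mm / mesh.scale_mm
    chord = 2.0 * np.sin(ang / 2.0)
    keep = ~mesh.is_hole
    idx = np.flatnonzero(keep)
    pts = mesh.xyz[idx]
    tree = cKDTree(pts)
    dmin, _ = tree.query(pts, k=2)
    min_spacing_mm = 2 * np.arcsin(np.clip(dmin[:, 1] / 2, 0, 1)).min() * mesh.scale_mm
    if interaction_radius_mm < min_spacing_mm:
        warnings.warn(
            "interaction radius is below the minimum inter-node spacing; "
            "dynamics will be discretization-sensitive", stacklevel=2)
    pairs = tree.query_pairs(chord, output_type="ndarray")
    gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
    src = np.concatenate([gi, gj])
    dst = np.concatenate([gj, gi])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=mesh.n_nodes)
    indptr = np.zeros(mesh.n_nodes + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    mesh.indptr = indptr
    mesh.indices = dst.astype(np.int32)
    mesh.interaction_radius_mm = float(interaction_radius_mm)
    return mesh


def mark_functional_regions(mesh: AtrialMesh, params: ModelParams) -> AtrialMesh:
    """Locate the sinus-node disc, the PV annuli and their burst groups.

    SN disc: non-hole nodes within 1.696 mm of (5 pi/12, pi/2).  PV annulus:
    non-hole nodes in the 2 mm band outside each PV hole rim.  Each annulus
    node's burst group is the set of non-hole nodes within 2.12 mm of it
    (including itself).  Fibrotic nodes may appear in these sets; they are
    skipped at stimulation time because they are inert.
    """
    not_hole = ~mesh.is_hole
    d_sn = mesh.distance_rad(*params.sn_centre)
    sn = np.flatnonzero(not_hole & (d_sn <= params.mm_to_rad(params.sn_radius_mm)))
    if sn.size == 0:
        raise ValueError("sinus-node disc is empty; pacing impossible")

    ann_list, pv_list = [], []
    r_in = params.pv_radius_rad
    r_out = r_in + params.mm_to_rad(params.annulus_width_mm)
    for pv_id, (th, ph) in enumerate(params.pv_centres):
        d = mesh.distance_rad(th, ph)
        sel = np.flatnonzero(not_hole & (d > r_in) & (d <= r_out))
        ann_list.append(sel)
        pv_list.append(np.full(sel.size, pv_id, dtype=np.int32))
    annulus = np.concatenate(ann_list) if ann_list else np.empty(0, np.int64)
    annulus_pv = np.concatenate(pv_list) if pv_list else np.empty(0, np.int32)

    # burst groups via KD-tree around each annulus node
    keep_idx = np.flatnonzero(not_hole)
    tree = cKDTree(mesh.xyz[keep_idx])
    chord = 2.0 * np.sin(params.mm_to_rad(params.burst_group_radius_mm) / 2.0)
    groups = tree.query_ball_point(mesh.xyz[annulus], chord)
    gp_indptr = np.zeros(annulus.size + 1, dtype=np.int64)
    flat = []
    for a, g in enumerate(groups):
        members = keep_idx[np.asarray(g, dtype=np.int64)]
        flat.append(members)
        gp_indptr[a + 1] = gp_indptr[a] + members.size
    mesh.sn_nodes = sn.astype(np.int32)
    mesh.annulus_nodes = annulus.astype(np.int32)
    mesh.annulus_pv = annulus_pv
    mesh.group_indptr = gp_indptr
    mesh.group_indices = (np.concatenate(flat).astype(np.int32)
                          if flat else np.empty(0, np.int32))
    return mesh


def build_substrate(params: ModelParams | None = None, level: int = 5) -> AtrialMesh:
    """Carved, mapped and marked mesh ready for the automaton (no fibrosis).

    Convenience pipeline: icosphere -> carve holes -> neighbour map ->
    functional regions.  Fibrosis is sampled per trial with
    :func:`sample_fibrosis`.
    """
    params = params or ModelParams()
    mesh = build_icosphere(level, scale_mm=params.scale_mm)
    carve_anatomy(mesh, params)
    build_neighbour_map(mesh, params.interaction_radius_mm)
    mark_functional_regions(mesh, params)
    return mesh


def mean_neighbourhood_size(mesh: AtrialMesh) -> float:
    """Mean neighbour count over non-hole nodes (the ~36-node calibration)."""
    keep = ~mesh.is_hole
    deg = np.diff(mesh.indptr)[keep]
    return float(deg.mean())
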