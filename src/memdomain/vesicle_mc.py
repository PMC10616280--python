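"""Metropolis Monte Carlo of a two-component dynamically triangulated vesicle.

The membrane is a closed, self-avoiding triangulated network of N vertices
linked by tethers whose lengths stay within [l_min, l_max].  Lateral fluidity
comes from the bond-flip move: the shared edge of two adjacent triangles is
cut and re-established across the other diagonal.  One Monte Carlo sweep is
N vertex-displacement attempts (uniform in a ball of radius s) followed by
R_B * N bond-flip attempts, each accepted with the Metropolis probability
min[1, exp(-dE/k_BT)].

The energy is the Gompper-Kroll discretized Helfrich bending energy with a
per-vertex rigidity (kappa_matrix for the background lipid, kappa_domain for
domain-forming lipid) plus a nearest-neighbour attraction between domain
vertices, W = -w * #(domain-domain bonds), the discrete contact form of
-w sum_{i<j} H(r0 - r_ij).  Vertex types never swap: mixing happens only
through bond flips, and composition is conserved exactly.

Lengths are in units of l_min = 1 and energies in k_BT = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from . import _mc_kernel as _k
from ._mc_kernel import MAXD

__all__ = [
    "MCParams",
    "TriangulatedVesicle",
    "EnergyBreakdown",
    "MeshInvariantError",
    "build_vesicle",
    "bending_energy",
    "interaction_energy",
    "energy_breakdown",
    "metropolis_probability",
    "mc_sweep",
    "run_simulation",
    "validate_mesh",
]


class MeshInvariantError(AssertionError):
    """A mesh invariant (topology, edge bounds, self-avoidance) was violated."""


@dataclass
class MCParams:
    """All control parameters of a simulation run.

    Defaults reproduce the reference study conditions: N=1447 vertices, bond-flip ratio
    R_B=3, step radius s = 0.15 l_min, l_max = 1.7 l_min, kappa = 27.3 k_BT
    for the matrix and 32.6 (fluid-like) or 96.3 (gel-like) k_BT for domains,
    ensemble averaging over 200 microstates.
    """

    n_vertices: int = 1447
    rho: float = 0.0                  # domain coverage as vertex fraction
    w: float = 0.0                    # k_BT, nearest-neighbour attraction
    r0: Optional[float] = None        # Euclidean cutoff; None = bonded contact
    kappa_matrix: float = 27.3        # k_BT
    kappa_domain: float = 32.6        # k_BT (96.3 for the gel-like lipid)
    rb: int = 3
    s_over_lmin: float = 0.15
    lmax_over_lmin: float = 1.7
    kT: float = 1.0
    sweeps_thermalize: int = 50_000
    n_samples: int = 200
    sample_interval: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_vertices < 12:
            raise ValueError("need at least 12 vertices")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.w < 0:
            raise ValueError("w must be nonnegative")
        if self.kT <= 0 or self.lmax_over_lmin <= 1.0 or self.s_over_lmin <= 0:
            raise ValueError("invalid geometry/temperature parameters")


@dataclass
class TriangulatedVesicle:
    """Closed triangulated two-component mesh with MC bookkeeping arrays."""

    pos: np.ndarray            # (N,3) float64, units of l_min
    nbr: np.ndarray            # (N,MAXD) int32
    enb: np.ndarray            # (N,MAXD) int32, edge ids per neighbour slot
    deg: np.ndarray            # (N,) int32
    ev: np.ndarray             # (E,2) int32
    eop: np.ndarray            # (E,2) int32, opposite vertices per edge
    vertex_type: np.ndarray    # (N,) uint8, 0 = matrix, 1 = domain
    kappa_per_vertex: np.ndarray   # (N,) float64, k_BT
    lmin: float = 1.0
    lmax: float = 1.7

    @property
    def n_vertices(self) -> int:
        return self.pos.shape[0]

    @property
    def n_edges(self) -> int:
        return self.ev.shape[0]

    @property
    def edges(self) -> np.ndarray:
        return np.sort(self.ev, axis=1)

    @property
    def triangles(self) -> np.ndarray:
        """Unique faces recovered from the edge/opposite tables."""
        faces = set()
        for e in range(self.n_edges):
            a, b = self.ev[e]
            for o in self.eop[e]:
                faces.add(tuple(sorted((int(a), int(b), int(o)))))
        return np.array(sorted(faces), dtype=np.int32)

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.pos[self.ev[:, 0]] - self.pos[self.ev[:, 1]],
                              axis=1)

    def copy(self) -> "TriangulatedVesicle":
        return TriangulatedVesicle(
            pos=self.pos.copy(), nbr=self.nbr.copy(), enb=self.enb.copy(),
            deg=self.deg.copy(), ev=self.ev.copy(), eop=self.eop.copy(),
            vertex_type=self.vertex_type.copy(),
            kappa_per_vertex=self.kappa_per_vertex.copy(),
            lmin=self.lmin, lmax=self.lmax)

    def to_trimesh(self):
        """Export as a trimesh.Trimesh (vertex colour encodes type)."""
        import trimesh
        mesh = trimesh.Trimesh(vertices=self.pos, faces=self.triangles,
                               process=False)
        colors = np.where(self.vertex_type[:, None] == 1,
                          np.array([[220, 40, 40, 255]]),
                          np.array([[60, 60, 220, 255]]))
        mesh.visual.vertex_colors = colors.astype(np.uint8)
        return mesh


@dataclass
class EnergyBreakdown:
    bending: float        # k_BT
    interaction: float    # k_BT, <= 0 for w >= 0
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.bending + self.interaction


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

def _hull_mesh(points: np.ndarray):
    """Adjacency/edge/opposite tables from the convex hull of sphere points."""
    hull = ConvexHull(points)
    n = points.shape[0]
    edge_ids = {}
    ev_list = []
    eop_list = []
    for tri in hull.simplices:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])):
            key = (min(a, b), max(a, b))
            o = int(tri[0] + tri[1] + tri[2] - a - b)
            if key not in edge_ids:
                edge_ids[key] = len(ev_list)
                ev_list.append(key)
                eop_list.append([o, -1])
            else:
                eop_list[edge_ids[key]][1] = o
    ev = np.array(ev_list, dtype=np.int32)
    eop = np.array(eop_list, dtype=np.int32)
    if np.any(eop < 0):
        raise MeshInvariantError("convex hull produced a non-closed surface")
    nbr = np.full((n, MAXD), -1, dtype=np.int32)
    enb = np.full((n, MAXD), -1, dtype=np.int32)
    deg = np.zeros(n, dtype=np.int32)
    for e, (a, b) in enumerate(ev):
        for i, j in ((a, b), (b, a)):
            if deg[i] >= MAXD:
                raise MeshInvariantError("vertex degree exceeds MAXD")
            nbr[i, deg[i]] = j
            enb[i, deg[i]] = e
            deg[i] += 1
    return nbr, enb, deg, ev, eop


def build_vesicle(params: MCParams) -> TriangulatedVesicle:
    """Initial spherical vesicle: Fibonacci lattice + convex-hull triangulation.

    The lattice radius is chosen so that the edge-length band sits centred
    (geometrically) inside [l_min, l_max]; round(rho * N) vertices are then
    labelled as domain type uniformly at random under the run seed.
    """
    from .synthetic import fibonacci_sphere

    n = params.n_vertices
    lmin, lmax = 1.0, params.lmax_over_lmin
    rng = np.random.default_rng(params.seed)
    for attempt in range(20):
        unit = fibonacci_sphere(n)
        if attempt > 0:
            unit = unit + 1e-3 * rng.standard_normal(unit.shape)
            unit /= np.linalg.norm(unit, axis=1, keepdims=True)
        nbr, enb, deg, ev, eop = _hull_mesh(unit)
        lengths = np.linalg.norm(unit[ev[:, 0]] - unit[ev[:, 1]], axis=1)
        # centre the band: scaled_min/lmin == lmax/scaled_max
        scale = np.sqrt(lmin * lmax / (lengths.min() * lengths.max()))
        pos = unit * scale
        lengths = lengths * scale
        if lengths.min() >= lmin and lengths.max() <= lmax:
            break
    else:
        raise MeshInvariantError(
            f"could not fit edge lengths in [{lmin}, {lmax}] for N={n}: "
            f"spread {lengths.max() / lengths.min():.3f}")

    vtype = np.zeros(n, dtype=np.uint8)
    n_dom = int(round(params.rho * n))
    if n_dom:
        vtype[rng.choice(n, size=n_dom, replace=False)] = 1
    kappa = np.where(vtype == 1, params.kappa_domain,
                     params.kappa_matrix).astype(float)
    ves = TriangulatedVesicle(
        pos=np.ascontiguousarray(pos), nbr=nbr, enb=enb, deg=deg, ev=ev,
        eop=eop, vertex_type=vtype, kappa_per_vertex=kappa,
        lmin=lmin, lmax=lmax)
    validate_mesh(ves)
    return ves


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------

def bending_energy(vesicle: TriangulatedVesicle) -> float:
    """Total Gompper-Kroll bending energy, sum_i (kappa_i/2) A_i |K_i|^2 (k_BT)."""
    areas = _triangle_areas(vesicle)
    if np.any(areas < 1e-12):
        bad = int(np.argmin(areas))
        raise MeshInvariantError(f"degenerate triangle {bad} with near-zero area")
    return float(_k.total_bending(vesicle.pos, vesicle.nbr, vesicle.enb,
                                  vesicle.deg, vesicle.eop,
                                  vesicle.kappa_per_vertex))


def _triangle_areas(vesicle: TriangulatedVesicle) -> np.ndarray:
    tris = vesicle.triangles
    p = vesicle.pos
    cross = np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def interaction_energy(vesicle: TriangulatedVesicle, w: float,
                       r0: Optional[float] = None) -> float:
    """Domain-domain attraction W = -w * #(contacting domain pairs), k_BT.

    The default contact set is mesh-bonded adjacency (the tether network
    realizes the in-plane neighbour relation).  Passing ``r0`` switches to a
    Euclidean cutoff: every non-identical domain pair with r_ij < r0 counts
    once, for sensitivity analysis.
    """
    if w < 0:
        raise ValueError("w must be nonnegative")
    dom = vesicle.vertex_type == 1
    if r0 is None:
        n_pairs = int(_k.count_domain_bonds(vesicle.ev, vesicle.vertex_type))
    else:
        idx = np.nonzero(dom)[0]
        if idx.size < 2:
            return 0.0
        tree = cKDTree(vesicle.pos[idx])
        n_pairs = len(tree.query_pairs(r0))
    return -w * n_pairs


def energy_breakdown(vesicle: TriangulatedVesicle, w: float,
                     r0: Optional[float] = None) -> EnergyBreakdown:
    return EnergyBreakdown(bending=bending_energy(vesicle),
                           interaction=interaction_energy(vesicle, w, r0))


def metropolis_probability(delta_e: float, kT: float = 1.0) -> float:
    """Metropolis acceptance probability min[1, exp(-dE/kT)]."""
    return float(min(1.0, np.exp(-delta_e / kT)))


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

@dataclass
class SweepStats:
    accepted_moves: int
    attempted_moves: int
    accepted_flips: int
    attempted_flips: int
    energy: float            # running total energy after the last sweep
    domain_bonds: int


def _run_chunk(vesicle: TriangulatedVesicle, params: MCParams, eb: np.ndarray,
               state: np.ndarray, n_sweeps: int, seed: int):
    trace = np.empty(n_sweeps)
    am, tm, af, tf = _k.run_sweeps(
        vesicle.pos, vesicle.nbr, vesicle.enb, vesicle.deg, vesicle.ev,
        vesicle.eop, vesicle.vertex_type, vesicle.kappa_per_vertex, eb, state,
        vesicle.lmin, vesicle.lmax, params.s_over_lmin * vesicle.lmin,
        params.w, params.kT, params.rb, n_sweeps, seed, trace)
    return SweepStats(am, tm, af, tf, float(state[0]), int(state[1])), trace


def _init_state(vesicle: TriangulatedVesicle, params: MCParams):
    eb = np.empty(vesicle.n_vertices)
    _k.fill_eb(vesicle.pos, vesicle.nbr, vesicle.enb, vesicle.deg,
               vesicle.eop, vesicle.kappa_per_vertex, eb)
    nd = _k.count_domain_bonds(vesicle.ev, vesicle.vertex_type)
    state = np.array([eb.sum() - params.w * nd, float(nd)])
    return eb, state


def mc_sweep(vesicle: TriangulatedVesicle, params: MCParams,
             seed: int = 0, n_sweeps: int = 1):
    """Run ``n_sweeps`` sweeps in place; returns (stats, energy_trace).

    Each sweep: N vertex-move attempts then R_B*N bond-flip attempts, with
    tether-length, self-avoidance and Metropolis acceptance rules.
    """
    eb, state = _init_state(vesicle, params)
    stats, trace = _run_chunk(vesicle, params, eb, state, n_sweeps, seed)
    return stats, trace


@dataclass
class SimulationResult:
    snapshots: List[TriangulatedVesicle]
    energies: List[EnergyBreakdown]          # recomputed per snapshot
    energy_trace: np.ndarray                 # running total per sweep
    params: MCParams
    stats: SweepStats


def run_simulation(params: MCParams,
                   vesicle: Optional[TriangulatedVesicle] = None,
                   validate_samples: bool = False) -> SimulationResult:
    """Thermalize, then record ``n_samples`` snapshots every ``sample_interval``.

    Fully seeded: the run seed derives per-chunk kernel seeds, so reruns are
    bitwise reproducible.  With ``validate_samples`` every snapshot is checked
    against the full set of mesh invariants (slower).
    """
    if vesicle is None:
        vesicle = build_vesicle(params)
    eb, state = _init_state(vesicle, params)
    traces = []
    seed_seq = np.random.SeedSequence(params.seed)
    kernel_seeds = seed_seq.generate_state(params.n_samples + 1) % (2**31 - 1)

    if params.sweeps_thermalize > 0:
        stats, tr = _run_chunk(vesicle, params, eb, state,
                               params.sweeps_thermalize, int(kernel_seeds[0]))
        traces.append(tr)

    snapshots: List[TriangulatedVesicle] = []
    energies: List[EnergyBreakdown] = []
    stats = None
    for i in range(params.n_samples):
        stats, tr = _run_chunk(vesicle, params, eb, state,
                               params.sample_interval, int(kernel_seeds[i + 1]))
        traces.append(tr)
        snap = vesicle.copy()
        snapshots.append(snap)
        energies.append(energy_breakdown(snap, params.w))
        if validate_samples:
            validate_mesh(snap)

    return SimulationResult(snapshots=snapshots, energies=energies,
                            energy_trace=np.concatenate(traces),
                            params=params, stats=stats)


# --------------------------------------------------------------------------
# invariants
# --------------------------------------------------------------------------

def validate_mesh(vesicle: TriangulatedVesicle) -> None:
    """Assert every mesh invariant; raises MeshInvariantError on violation.

    Checks: symmetric adjacency consistent with the edge table, degree >= 3,
    every edge's opposites adjacent to both endpoints, F = 2(V-2) faces and
    Euler characteristic 2, edge lengths within [l_min, l_max], minimum
    distance >= l_min between non-bonded vertices, single connected component.
    """
    v = vesicle
    n, ne = v.n_vertices, v.n_edges
    if ne != 3 * (n - 2):
        raise MeshInvariantError(f"E={ne} != 3(V-2)={3 * (n - 2)}")
    if np.any(v.deg[:n] < 3):
        raise MeshInvariantError("vertex with degree < 3")
    # adjacency <-> edge table consistency
    pair_seen = set()
    for e in range(ne):
        a, b = int(v.ev[e, 0]), int(v.ev[e, 1])
        if a == b:
            raise MeshInvariantError(f"edge {e} is a loop")
        key = (min(a, b), max(a, b))
        if key in pair_seen:
            raise MeshInvariantError(f"duplicate edge {key}")
        pair_seen.add(key)
        for i, j in ((a, b), (b, a)):
            slots = np.nonzero(v.nbr[i, :v.deg[i]] == j)[0]
            if slots.size != 1 or v.enb[i, slots[0]] != e:
                raise MeshInvariantError(f"adjacency inconsistent at edge {e}")
        for o in v.eop[e]:
            o = int(o)
            if o == a or o == b:
                raise MeshInvariantError(f"edge {e} opposite equals endpoint")
            if (o not in v.nbr[a, :v.deg[a]]) or (o not in v.nbr[b, :v.deg[b]]):
                raise MeshInvariantError(f"edge {e} opposite not adjacent")
        if v.eop[e, 0] == v.eop[e, 1]:
            raise MeshInvariantError(f"edge {e} has identical opposites")
    faces = vesicle.triangles
    if faces.shape[0] != 2 * (n - 2):
        raise MeshInvariantError(f"F={faces.shape[0]} != 2(V-2)={2 * (n - 2)}")
    if n - ne + faces.shape[0] != 2:
        raise MeshInvariantError("Euler characteristic != 2")
    lengths = v.edge_lengths()
    if lengths.min() < v.lmin - 1e-12 or lengths.max() > v.lmax + 1e-12:
        raise MeshInvariantError(
            f"edge length out of bounds: [{lengths.min():.4f}, {lengths.max():.4f}]")
    # self-avoidance between non-bonded pairs
    tree = cKDTree(v.pos)
    for i, j in tree.query_pairs(v.lmin * (1 - 1e-12)):
        if j not in v.nbr[i, :v.deg[i]]:
            raise MeshInvariantError(
                f"non-bonded vertices {i},{j} closer than l_min")
    # connectivity
    import networkx as nx
    g = nx.Graph(map(tuple, v.ev))
    if g.number_of_nodes() != n or not nx.is_connected(g):
        raise MeshInvariantError("mesh is not a single connected component")
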