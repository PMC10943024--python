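"""Modular spatial landscapes and stochastic site-activation schedules.

A landscape is a connected, weighted, undirected graph of habitat sites on the
unit square.  Sites are grouped into ``n_C`` spatial modules whose tightness is
controlled by the excess factor ``F`` (``F = 1`` recovers uniform coverage of
the square; large ``F`` collapses each module onto its center).  The graph is
the Euclidean minimum spanning tree plus extra edges sampled with probability
proportional to ``d^-x``, so larger ``x`` favors short edges and therefore
higher spatial modularity.  One site of a randomly chosen module is the
*mainland*: it is permanently active and permanently holds the whole regional
species pool.

Every other site is temporary.  Each year ``k`` it activates at
``start = k + z`` with ``z ~ U(-A, +A)`` (clipped at 0) and stays active for a
site-specific nominal length ``w_p ~ U(0.2, 0.3)`` years; overlapping yearly
intervals are merged.  ``A`` is the landscape-asynchrony parameter: ``A = 0``
means all sites flood and dry in perfect synchrony.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .exceptions import GenerationError

__all__ = [
    "Landscape",
    "ActivationSchedule",
    "generate_landscape",
    "generate_star_landscape",
    "sample_activation_schedule",
    "paired_schedules",
    "is_active",
    "intra_module_dispersion",
]

#: Base module radius; site positions contract toward their module center by 1/F.
_MODULE_RADIUS = 0.5

#: Bounds of the nominal yearly active-period length (years).
W_LOW, W_HIGH = 0.2, 0.3


@dataclass
class Landscape:
    """A static spatial graph of habitat sites.

    Attributes
    ----------
    coords : (n_P, 2) float array
        Site positions on the unit square.
    module_of : (n_P,) int array
        Module label of each site, in ``1..n_C``.
    edges : (n_E, 2) int array
        Undirected edges, each row ``(u, v)`` with ``u < v``.
    weights : (n_E,) float array
        Edge weights; always the Euclidean distance between the endpoints.
    tree_mask : (n_E,) bool array
        Marks the edges belonging to the minimum spanning tree used during
        construction.
    mainland : int
        Index of the permanently active mainland site.
    params : dict
        Generation parameters, kept for provenance.
    """

    coords: np.ndarray
    module_of: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    tree_mask: np.ndarray
    mainland: int
    params: dict = field(default_factory=dict)

    @property
    def n_P(self) -> int:
        return self.coords.shape[0]

    @property
    def n_E(self) -> int:
        return self.edges.shape[0]

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_P))
        g.add_edges_from(map(tuple, self.edges))
        return nx.is_connected(g)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for p in range(self.n_P):
            g.add_node(
                p,
                x=float(self.coords[p, 0]),
                y=float(self.coords[p, 1]),
                module=int(self.module_of[p]),
                is_mainland=bool(p == self.mainland),
            )
        for (u, v), w in zip(self.edges, self.weights):
            g.add_edge(int(u), int(v), distance=float(w))
        return g

    def to_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_csv(self, node_path: str, edge_path: str) -> None:
        with open(node_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["site", "x", "y", "module", "is_mainland"])
            for p in range(self.n_P):
                w.writerow(
                    [p, self.coords[p, 0], self.coords[p, 1],
                     int(self.module_of[p]), int(p == self.mainland)]
                )
        with open(edge_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["u", "v", "distance", "in_mst"])
            for (u, v), d, m in zip(self.edges, self.weights, self.tree_mask):
                w.writerow([int(u), int(v), float(d), int(m)])

    @classmethod
    def from_graphml(cls, path: str) -> "Landscape":
        g = nx.read_graphml(path)
        nodes = sorted(g.nodes, key=lambda s: int(s))
        idx = {s: i for i, s in enumerate(nodes)}
        coords = np.array([[float(g.nodes[s]["x"]), float(g.nodes[s]["y"])] for s in nodes])
        module_of = np.array([int(g.nodes[s]["module"]) for s in nodes])
        mainland = next(i for i, s in enumerate(nodes) if g.nodes[s].get("is_mainland"))
        edges, weights = [], []
        for u, v, data in g.edges(data=True):
            a, b = sorted((idx[u], idx[v]))
            edges.append((a, b))
            weights.append(float(data["distance"]))
        order = np.lexsort((np.array(edges)[:, 1], np.array(edges)[:, 0]))
        edges = np.array(edges)[order]
        weights = np.array(weights)[order]
        tree = np.zeros(len(edges), dtype=bool)  # provenance lost on import
        return cls(coords, module_of, edges, weights, tree, mainland)


def _euclidean_mst_edges(coords: np.ndarray) -> np.ndarray:
    """Edges (u < v) of the Euclidean minimum spanning tree."""
    d = squareform(pdist(coords))
    tree = minimum_spanning_tree(d).tocoo()
    uv = np.sort(np.stack([tree.row, tree.col], axis=1), axis=1)
    return uv[np.lexsort((uv[:, 1], uv[:, 0]))]


def generate_landscape(
    n_P: int, n_E: int, n_C: int, F: float, x: float, seed: int
) -> Landscape:
    """Generate a connected modular landscape.

    Parameters
    ----------
    n_P, n_E, n_C
        Number of sites, edges, and spatial modules.
    F
        Excess factor, >= 1. Module tightness: each site is drawn as
        ``center + (raw - center)/F`` with ``raw`` uniform on the square, so
        ``F = 1`` gives exactly uniform site placement and large ``F`` gives
        tight clusters of diameter ~ ``1/F``.
    x
        Distance exponent, >= 0. Non-tree edges are sampled without
        replacement with probability proportional to ``d^-x``; ``x = 0``
        ignores distance.
    seed
        Root seed; placement, edge addition and mainland choice use
        independent child streams.
    """
    if n_P < 2:
        raise ValueError("n_P must be at least 2")
    if n_E < n_P - 1:
        raise GenerationError(
            f"infeasible edge count: n_E={n_E} < n_P-1={n_P - 1} (graph cannot be connected)"
        )
    max_edges = n_P * (n_P - 1) // 2
    if n_E > max_edges:
        raise GenerationError(f"n_E={n_E} exceeds the maximum {max_edges} for n_P={n_P}")
    if not 1 <= n_C <= n_P:
        raise ValueError("n_C must satisfy 1 <= n_C <= n_P")
    if F < 1:
        raise ValueError("F must be >= 1")
    if x < 0:
        raise ValueError("x must be >= 0")

    ss = np.random.SeedSequence(seed)
    rng_place, rng_edges, rng_main = (np.random.default_rng(s) for s in ss.spawn(3))

    centers = rng_place.uniform(size=(n_C, 2))
    # Balanced module sizes (differ by at most one site).
    module_of = np.sort(np.arange(n_P) % n_C) + 1
    raw = rng_place.uniform(size=(n_P, 2))
    c = centers[module_of - 1]
    coords = c + (raw - c) / F  # convex combination: stays in the square

    tree_edges = _euclidean_mst_edges(coords)
    n_extra = n_E - (n_P - 1)
    iu, ju = np.triu_indices(n_P, k=1)
    in_tree = np.zeros((n_P, n_P), dtype=bool)
    in_tree[tree_edges[:, 0], tree_edges[:, 1]] = True
    cand = ~in_tree[iu, ju]
    cu, cv = iu[cand], ju[cand]
    dists = np.linalg.norm(coords[cu] - coords[cv], axis=1)
    if n_extra > 0:
        # Weighted sampling without replacement via exponential races:
        # the n_extra smallest Exp(1)/weight keys are a draw with
        # probability proportional to d^-x.
        log_keys = np.log(rng_edges.exponential(size=cu.size)) + x * np.log(dists)
        pick = np.argpartition(log_keys, n_extra - 1)[:n_extra]
    else:
        pick = np.array([], dtype=int)

    extra = np.stack([cu[pick], cv[pick]], axis=1)
    edges = np.vstack([tree_edges, extra])
    tree_mask = np.zeros(len(edges), dtype=bool)
    tree_mask[: len(tree_edges)] = True
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, tree_mask = edges[order], tree_mask[order]
    weights = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)

    main_module = int(rng_main.integers(1, n_C + 1))
    members = np.flatnonzero(module_of == main_module)
    mainland = int(rng_main.choice(members))

    return Landscape(
        coords=coords,
        module_of=module_of,
        edges=edges,
        weights=weights,
        tree_mask=tree_mask,
        mainland=mainland,
        params={"n_E": n_E, "n_C": n_C, "F": F, "x": x, "seed": seed},
    )


def generate_star_landscape(n_leaves: int, radius: float, seed: int = 0) -> Landscape:
    """Idealized star landscape: mainland at the hub, leaves at equal distance.

    Useful as a minimal fixture where every site is directly reachable from
    the mainland at one common dispersal rate.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    center = np.array([0.5, 0.5])
    angles = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.arange(n_leaves) / n_leaves
    coords = np.vstack([center, center + radius * np.stack([np.cos(angles), np.sin(angles)], 1)])
    edges = np.array([[0, p] for p in range(1, n_leaves + 1)])
    weights = np.full(n_leaves, float(radius))
    return Landscape(
        coords=coords,
        module_of=np.ones(n_leaves + 1, dtype=int),
        edges=edges,
        weights=weights,
        tree_mask=np.ones(n_leaves, dtype=bool),
        mainland=0,
        params={"star": True, "radius": radius},
    )


@dataclass
class ActivationSchedule:
    """Per-site activation intervals over a multi-year horizon.

    ``intervals[p]`` is a (k, 2) array of merged, disjoint, sorted closed
    intervals ``[start, end]``. The mainland is always active regardless of
    its stored intervals.
    """

    years: int
    A: float
    w: np.ndarray
    intervals: list
    mainland: int

    @property
    def n_P(self) -> int:
        return len(self.intervals)

    def is_active(self, p: int, t: float) -> bool:
        return is_active(self, p, t)

    def events(self, horizon: float) -> list:
        """Deterministic (time, kind, site) schedule events in (0, horizon).

        Activations at interval starts, deactivations at interval ends; the
        initial state at t=0 (intervals covering 0) is the caller's job.
        Sorted by (time, kind-priority deactivate < activate, site).
        """
        out = []
        for p in range(self.n_P):
            if p == self.mainland:
                continue
            for s, e in self.intervals[p]:
                if 0.0 < s < horizon:
                    out.append((float(s), "activate", p))
                if 0.0 < e < horizon:
                    out.append((float(e), "deactivate", p))
        prio = {"deactivate": 0, "activate": 1}
        out.sort(key=lambda ev: (ev[0], prio[ev[1]], ev[2]))
        return out

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["site", "interval_index", "start", "end"])
            for p, iv in enumerate(self.intervals):
                for k, (s, e) in enumerate(iv):
                    w.writerow([p, k, float(s), float(e)])


def _merge_closed_intervals(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    order = np.argsort(starts)
    merged: list[list[float]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([float(s), float(e)])
    return np.array(merged).reshape(-1, 2)


def sample_activation_schedule(
    L: Landscape,
    A: float,
    years: int,
    seed: int,
    w: np.ndarray | None = None,
) -> ActivationSchedule:
    """Draw an activation schedule for every site of ``L``.

    Per site p, the nominal active length is ``w_p ~ U(0.2, 0.3)``; the year-k
    interval is ``[max(0, k + z), max(0, k + z) + w_p]`` with ``z ~ U(-A, A)``.
    Overlapping yearly intervals are merged. ``w`` may be supplied to share
    nominal lengths between paired schedules differing only in asynchrony.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if A < 0:
        raise ValueError("A must be >= 0")
    rng = np.random.default_rng(seed)
    n_P = L.n_P
    if w is None:
        w = rng.uniform(W_LOW, W_HIGH, size=n_P)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != (n_P,):
            raise ValueError("w must have one entry per site")

    intervals = []
    for p in range(n_P):
        z = rng.uniform(-A, A, size=years) if A > 0 else np.zeros(years)
        starts = np.maximum(0.0, np.arange(years) + z)
        ends = starts + w[p]
        intervals.append(_merge_closed_intervals(starts, ends))
    # The mainland is permanently active; keep a covering interval for export.
    intervals[L.mainland] = np.array([[0.0, years + A + W_HIGH]])
    return ActivationSchedule(years=years, A=A, w=w, intervals=intervals, mainland=L.mainland)


def paired_schedules(
    L: Landscape, A_low: float, A_high: float, years: int, seed: int
) -> tuple[ActivationSchedule, ActivationSchedule]:
    """Two schedules sharing the w_p draws, differing only in jitter.

    Used for paired asynchrony contrasts: the low- and high-A runs of one
    replicate see identical nominal active lengths.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    w = np.random.default_rng(ss[0]).uniform(W_LOW, W_HIGH, size=L.n_P)
    lo = sample_activation_schedule(L, A_low, years, seed=ss[1].generate_state(1)[0] % 2**31, w=w)
    hi = sample_activation_schedule(L, A_high, years, seed=ss[2].generate_state(1)[0] % 2**31, w=w)
    return lo, hi


def is_active(S: ActivationSchedule, p: int, t: float) -> bool:
    """Whether site ``p`` is active at time ``t`` (closed-interval convention)."""
    if not 0 <= p < S.n_P:
        raise IndexError(f"unknown site index {p}")
    if t < 0:
        raise ValueError("t must be nonnegative")
    if p == S.mainland:
        return True
    iv = S.intervals[p]
    if iv.size == 0:
        return False
    k = np.searchsorted(iv[:, 0], t, side="right") - 1
    return bool(k >= 0 and t <= iv[k, 1])


def intra_module_dispersion(L: Landscape) -> float:
    """Mean distance of sites to their module centroid (clustering tightness)."""
    total = 0.0
    for m in np.unique(L.module_of):
        pts = L.coords[L.module_of == m]
        total += float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).sum())
    return total / L.n_P
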