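"""Regional food webs with controlled trophic coherence.

The generator follows the generalized preferential-preying family of models:
species are created basal-first; every consumer takes a first prey uniformly
from the species created before it (fixing a provisional integer trophic
level), and the remaining link budget is placed by sampling (prey, consumer)
pairs with weight ``exp(-(s_c - s_p - 1)^2 / (2 T^2))``.  The temperature
``T`` therefore controls trophic coherence: ``T -> 0`` admits only links that
span exactly one level (maximally coherent webs, no omnivory), while large
``T`` allows links across any level gap (incoherent, omnivorous webs).

Coherence is measured by the incoherence parameter ``q``: the standard
deviation of the trophic-level gap ``s_predator - s_prey`` over all links,
with prey-averaged trophic levels recomputed from the final adjacency.
``q = 0`` iff every link spans exactly one level.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .exceptions import GenerationError

__all__ = [
    "FoodWeb",
    "generate_foodweb",
    "trophic_levels",
    "incoherence",
    "connectance",
    "links_for_connectance",
]

#: Temperature floor so T = 0 degenerates cleanly to gap-1 links only.
_T_FLOOR = 1e-6
#: log-weight cutoff below which a candidate link is treated as impossible.
_LOG_W_MIN = -700.0


@dataclass
class FoodWeb:
    """A directed predation network over ``n_S`` species.

    ``links`` rows are ``(prey, predator)`` pairs; ``basal`` flags species
    with no prey (primary producers). Cannibalism is excluded.
    """

    n_S: int
    basal: np.ndarray
    links: np.ndarray
    T: float
    params: dict = field(default_factory=dict)

    @property
    def n_B(self) -> int:
        return int(self.basal.sum())

    @property
    def n_L(self) -> int:
        return self.links.shape[0]

    @property
    def C(self) -> float:
        return connectance(self.n_S, self.n_B, self.n_L)

    @cached_property
    def prey_matrix(self) -> np.ndarray:
        """Boolean (n_S, n_S); entry (i, j) true iff i is prey of j."""
        m = np.zeros((self.n_S, self.n_S), dtype=bool)
        if self.n_L:
            m[self.links[:, 0], self.links[:, 1]] = True
        return m

    def prey_of(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.prey_matrix[:, j])

    def to_csv(self, link_path: str, species_path: str) -> None:
        with open(link_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["prey", "predator"])
            w.writerows(self.links.tolist())
        with open(species_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "is_basal"])
            for i in range(self.n_S):
                w.writerow([i, int(self.basal[i])])

    @classmethod
    def from_csv(cls, link_path: str, species_path: str, T: float = float("nan")) -> "FoodWeb":
        with open(species_path) as fh:
            rows = list(csv.DictReader(fh))
        n_S = len(rows)
        basal = np.zeros(n_S, dtype=bool)
        for r in rows:
            basal[int(r["id"])] = bool(int(r["is_basal"]))
        with open(link_path) as fh:
            links = np.array(
                [[int(r["prey"]), int(r["predator"])] for r in csv.DictReader(fh)],
                dtype=int,
            ).reshape(-1, 2)
        return cls(n_S=n_S, basal=basal, links=links, T=T)


def connectance(n_S: int, n_B: int, n_L: int) -> float:
    """Realized links over the maximum possible with ``n_B`` basal species and
    no cannibals: ``n_L / (n_S (n_S - n_B - 1) + n_B)``."""
    denom = n_S * (n_S - n_B - 1) + n_B
    if denom <= 0:
        raise ValueError("connectance denominator must be positive")
    return n_L / denom


def links_for_connectance(n_S: int, n_B: int, C: float) -> int:
    """Link budget realizing connectance ``C`` (rounded to nearest integer)."""
    return int(round(C * (n_S * (n_S - n_B - 1) + n_B)))


def _feasible_link_range(n_S: int, n_B: int) -> tuple[int, int]:
    return n_S - n_B, n_S * (n_S - n_B - 1) + n_B


def generate_foodweb(
    n_S: int, n_B: int, n_L: int, T: float, seed: int, max_tries: int = 200
) -> FoodWeb:
    """Generate a food web with exactly ``n_L`` links at temperature ``T``.

    Species ``0..n_B-1`` are basal. Each consumer picks a uniformly random
    first prey among the species preceding it, then the remaining
    ``n_L - (n_S - n_B)`` links are drawn without replacement among all
    remaining non-cannibal (prey, consumer) pairs with weight
    ``exp(-(gap - 1)^2 / (2 max(T, 1e-6)^2))``, where the gap uses the
    provisional levels. If too few pairs have non-negligible weight (common
    at very low T with a high link budget), the attempt is rejected and the
    construction restarts with fresh randomness, up to ``max_tries``.
    """
    if n_B < 1:
        raise ValueError("n_B must be >= 1")
    if n_S <= n_B:
        raise ValueError("n_S must exceed n_B")
    if T < 0:
        raise ValueError("T must be >= 0")
    lo, hi = _feasible_link_range(n_S, n_B)
    if not lo <= n_L <= hi:
        raise GenerationError(
            f"link budget n_L={n_L} outside feasible range [{lo}, {hi}] "
            f"for n_S={n_S}, n_B={n_B}"
        )

    sigma = max(T, _T_FLOOR)
    children = np.random.SeedSequence(seed).spawn(max_tries)
    for attempt in range(max_tries):
        rng = np.random.default_rng(children[attempt])
        levels = np.ones(n_S)
        first_prey = np.empty(n_S - n_B, dtype=int)
        for idx, j in enumerate(range(n_B, n_S)):
            first_prey[idx] = rng.integers(0, j)
            levels[j] = levels[first_prey[idx]] + 1
        links = [(int(first_prey[idx]), j) for idx, j in enumerate(range(n_B, n_S))]

        n_extra = n_L - len(links)
        if n_extra > 0:
            taken = np.zeros((n_S, n_S), dtype=bool)
            for i, j in links:
                taken[i, j] = True
            prey_idx, cons_idx = np.meshgrid(
                np.arange(n_S), np.arange(n_B, n_S), indexing="ij"
            )
            prey_idx, cons_idx = prey_idx.ravel(), cons_idx.ravel()
            ok = (prey_idx != cons_idx) & ~taken[prey_idx, cons_idx]
            prey_idx, cons_idx = prey_idx[ok], cons_idx[ok]
            gap = levels[cons_idx] - levels[prey_idx]
            log_w = -((gap - 1.0) ** 2) / (2.0 * sigma**2)
            eligible = log_w > _LOG_W_MIN
            if int(eligible.sum()) < n_extra:
                continue  # not enough coherent slots; restart
            prey_idx, cons_idx, log_w = prey_idx[eligible], cons_idx[eligible], log_w[eligible]
            # Weighted sampling without replacement (exponential races, log space).
            keys = np.log(rng.exponential(size=prey_idx.size)) - log_w
            pick = np.argpartition(keys, n_extra - 1)[:n_extra]
            links.extend(zip(prey_idx[pick].tolist(), cons_idx[pick].tolist()))

        basal = np.zeros(n_S, dtype=bool)
        basal[:n_B] = True
        web = FoodWeb(
            n_S=n_S,
            basal=basal,
            links=np.array(sorted(links), dtype=int),
            T=T,
            params={"seed": seed, "attempt": attempt},
        )
        return web

    raise GenerationError(
        f"failed to place {n_L} links at T={T} after {max_tries} attempts",
        details={"n_S": n_S, "n_B": n_B, "n_L": n_L, "T": T},
    )


def trophic_levels(W: FoodWeb) -> np.ndarray:
    """Prey-averaged trophic levels from the final adjacency.

    Solves the linear system ``s_i = 1`` for basal ``i`` and
    ``s_j = 1 + mean(s over prey of j)`` for consumers. Unique because every
    consumer chain grounds in a basal species.
    """
    n = W.n_S
    pm = W.prey_matrix
    indeg = pm.sum(axis=0)
    if np.any(~W.basal & (indeg == 0)):
        orphan = np.flatnonzero(~W.basal & (indeg == 0))
        raise ValueError(f"consumers with no prey: {orphan.tolist()}")
    A = np.eye(n)
    consumers = np.flatnonzero(~W.basal)
    # s_j - (1/indeg_j) * sum_prey s_i = 1
    A[np.ix_(consumers, range(n))] -= (pm[:, consumers] / indeg[consumers]).T
    return np.linalg.solve(A, np.ones(n))


def incoherence(W: FoodWeb, ddof: int = 0) -> float:
    """Incoherence ``q``: std of the per-link trophic-level gap.

    ``ddof=0`` (population std) is the default convention; pass ``ddof=1``
    for the sample-std variant.
    """
    if W.n_L < 1:
        raise ValueError("incoherence requires at least one link")
    s = trophic_levels(W)
    gaps = s[W.links[:, 1]] - s[W.links[:, 0]]
    return float(np.std(gaps, ddof=ddof))
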