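"""Lotka-Volterra community matrices, LP growth-rate parameterization,
stability screening, and local equilibria with extinction cascades.

Local dynamics at a site follow generalized Lotka-Volterra equations

    dx_i/dt = (r_i + sum_j M_ij x_j) x_i ,

where the community matrix ``M`` has ``M_ii = -lambda`` (self-limitation) and,
for each predation link prey ``i`` <- predator ``j``, ``M_ij = -X`` and
``M_ji = 0.4 X`` with ``X`` lognormal (mean 1, sd 0.25).  Growth rates are not
free parameters: they are chosen by a linear program that maximizes the
smallest equilibrium abundance ``y*`` subject to the equilibrium condition
``r + M x* = 0``, ``x*_i >= y* >= 0``, ``r_i <= rho`` for basal species and
``r_i <= -mu`` for consumers.  Webs whose LP is infeasible, or whose interior
equilibrium fails the Lyapunov test on ``J = diag(x*) M``, are discarded and
regenerated.

Because local dynamics are assumed fast relative to dispersal, the simulator
never integrates the ODE: after every compositional change the site is placed
at the equilibrium of its surviving subsystem, species below the extinction
threshold (0.001) are removed, and the solve is repeated until no further
secondary extinctions occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .exceptions import GenerationError
from .foodweb import FoodWeb, generate_foodweb

__all__ = [
    "LocalDynamics",
    "EquilibriumResult",
    "build_community_matrix",
    "parameterize_growth_rates",
    "is_locally_stable",
    "generate_stable_regional_community",
    "local_equilibrium",
    "full_pool_persistence",
    "EXTINCTION_THRESHOLD",
    "RHO",
    "MU",
]

#: Biomass below which a species is removed from a site.
EXTINCTION_THRESHOLD = 1e-3
#: Cap on basal intrinsic growth rates.
RHO = 1.0
#: Minimum mortality rate (consumers have r <= -MU).
MU = 0.01
#: Predator gain per unit of prey loss.
CONVERSION = 0.4


def draw_interaction_strengths(
    rng: np.random.Generator, size: int, moments: str = "variate"
) -> np.ndarray:
    """Lognormal interaction strengths X.

    ``moments="variate"`` (default): mean(X) = 1 and std(X) = 0.25, i.e. the
    underlying normal has sigma0^2 = ln(1 + 0.25^2) and mu0 = -sigma0^2 / 2.
    ``moments="log"``: ln X ~ N(0, 0.25^2).
    """
    if moments == "variate":
        s2 = np.log(1.0 + 0.25**2)
        return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)
    if moments == "log":
        return rng.lognormal(mean=0.0, sigma=0.25, size=size)
    raise ValueError("moments must be 'variate' or 'log'")


def build_community_matrix(
    W: FoodWeb, lam: float, seed: int, moments: str = "variate"
) -> np.ndarray:
    """Community matrix for web ``W`` with self-limitation ``lam > 0``."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    rng = np.random.default_rng(seed)
    M = np.zeros((W.n_S, W.n_S))
    np.fill_diagonal(M, -lam)
    X = draw_interaction_strengths(rng, W.n_L, moments=moments)
    prey, pred = W.links[:, 0], W.links[:, 1]
    M[prey, pred] = -X
    M[pred, prey] = CONVERSION * X
    return M


@dataclass
class GrowthRates:
    r: np.ndarray
    x_star: np.ndarray
    y_star: float


def parameterize_growth_rates(
    M: np.ndarray, basal: np.ndarray, rho: float = RHO, mu: float = MU
) -> GrowthRates | None:
    """Choose growth rates maximizing the smallest equilibrium abundance.

    Substituting the equilibrium condition ``r = -M x`` the LP reads:
    maximize ``y`` over ``(x, y)`` with ``x_i >= y >= 0``,
    ``(-M x)_i <= rho`` (basal) and ``(-M x)_i <= -mu`` (consumers).
    Returns ``None`` when infeasible (the caller discards the web).
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    basal = np.asarray(basal, dtype=bool)
    c = np.zeros(n + 1)
    c[-1] = -1.0  # maximize y
    # x_i >= y  ->  -x_i + y <= 0
    A1 = np.hstack([-np.eye(n), np.ones((n, 1))])
    b1 = np.zeros(n)
    # growth-rate caps on r = -M x
    A2 = np.hstack([-M, np.zeros((n, 1))])
    b2 = np.where(basal, rho, -mu)
    res = linprog(
        c,
        A_ub=np.vstack([A1, A2]),
        b_ub=np.concatenate([b1, b2]),
        bounds=[(0, None)] * n + [(0, None)],
        method="highs",
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    x = res.x[:n]
    y = float(res.x[n])
    r = -M @ x
    return GrowthRates(r=r, x_star=x, y_star=y)


def is_locally_stable(M: np.ndarray, x_star: np.ndarray) -> bool:
    """Lyapunov test at an interior equilibrium: all eigenvalues of
    ``J = diag(x*) M`` must have negative real part."""
    x_star = np.asarray(x_star, dtype=float)
    if np.any(x_star <= 0):
        raise ValueError("x_star must be positive elementwise")
    J = x_star[:, None] * np.asarray(M, dtype=float)
    return bool(np.max(np.linalg.eigvals(J).real) < 0)


@dataclass
class LocalDynamics:
    """A fully parameterized regional community."""

    web: FoodWeb
    M: np.ndarray
    r: np.ndarray
    lam: float
    x_star: np.ndarray
    y_star: float
    rho: float = RHO
    mu: float = MU
    attempts: int = 1
    params: dict = field(default_factory=dict)

    @property
    def n_S(self) -> int:
        return self.web.n_S

    @property
    def basal(self) -> np.ndarray:
        return self.web.basal


def generate_stable_regional_community(
    n_S: int,
    n_B: int,
    n_L: int,
    T: float,
    lam: float,
    seed: int,
    max_tries: int = 100,
    moments: str = "variate",
) -> tuple[FoodWeb, LocalDynamics]:
    """Sample (web, M, r) until the LP is feasible and the equilibrium stable.

    Each attempt draws a fresh topology and fresh interaction strengths.
    Raises :class:`GenerationError` with attempt diagnostics when
    ``max_tries`` is exhausted.
    """
    if max_tries < 1:
        raise ValueError("max_tries must be >= 1")
    children = np.random.SeedSequence(seed).spawn(max_tries)
    n_infeasible = n_unstable = n_webfail = 0
    for attempt in range(1, max_tries + 1):
        sub = children[attempt - 1].spawn(2)
        try:
            web = generate_foodweb(
                n_S, n_B, n_L, T, seed=int(sub[0].generate_state(1)[0] % 2**31)
            )
        except GenerationError:
            n_webfail += 1
            continue
        M = build_community_matrix(
            web, lam, seed=int(sub[1].generate_state(1)[0] % 2**31), moments=moments
        )
        sol = parameterize_growth_rates(M, web.basal)
        if sol is None:
            n_infeasible += 1
            continue
        if not np.all(sol.x_star > 0) or not is_locally_stable(M, sol.x_star):
            n_unstable += 1
            continue
        return web, LocalDynamics(
            web=web,
            M=M,
            r=sol.r,
            lam=lam,
            x_star=sol.x_star,
            y_star=sol.y_star,
            attempts=attempt,
            params={"T": T, "lam": lam, "seed": seed},
        )
    raise GenerationError(
        f"no feasible & stable community in {max_tries} tries "
        f"(web failures: {n_webfail}, LP-infeasible: {n_infeasible}, unstable: {n_unstable})",
        details={
            "n_S": n_S, "n_B": n_B, "n_L": n_L, "T": T, "lam": lam,
            "web_failures": n_webfail, "infeasible": n_infeasible, "unstable": n_unstable,
        },
    )


@dataclass
class EquilibriumResult:
    """Survivor set, biomasses, and the extinction-cascade record of a site.

    ``biomass`` has length n_S with zeros for non-survivors. ``extinctions``
    lists ``(species, reason)`` in removal order; reasons are ``"no_prey"``,
    ``"threshold"`` or ``"singular"``.
    """

    survivors: np.ndarray
    biomass: np.ndarray
    extinctions: list

    @property
    def n_survivors(self) -> int:
        return self.survivors.size


def local_equilibrium(
    D: LocalDynamics,
    present,
    threshold: float = EXTINCTION_THRESHOLD,
    invader: int | None = None,
) -> EquilibriumResult:
    """Equilibrium of the subsystem restricted to ``present``, with cascades.

    Iterates: (i) structurally prune consumers with no present prey;
    (ii) solve ``M_SS x_S = -r_S``; (iii) remove every species with biomass
    below ``threshold`` (all at once); until a fixed point. Termination is
    guaranteed because each round removes at least one species.

    Singular subsystems are non-generic (lam > 0); if a solve fails, the
    invading species (when given) is declared extinct and the solve retried,
    otherwise the whole offending set fails the threshold test for that
    iteration.
    """
    n = D.n_S
    present = np.asarray(present, dtype=bool).copy()
    if present.shape != (n,):
        raise ValueError("present must be a boolean vector over the species pool")
    if not present.any():
        raise ValueError("present must be non-empty")
    pm = D.web.prey_matrix
    extinctions: list[tuple[int, str]] = []
    biomass = np.zeros(n)

    while True:
        # structural pruning: consumers whose last present prey is gone
        while True:
            support = (pm & present[:, None]).any(axis=0)
            doomed = present & ~D.basal & ~support
            if not doomed.any():
                break
            for s in np.flatnonzero(doomed):
                extinctions.append((int(s), "no_prey"))
            present &= ~doomed

        S = np.flatnonzero(present)
        if S.size == 0:
            return EquilibriumResult(S, biomass, extinctions)

        sub = D.M[np.ix_(S, S)]
        try:
            x = np.linalg.solve(sub, -D.r[S])
        except np.linalg.LinAlgError:
            if invader is not None and present[invader]:
                extinctions.append((int(invader), "singular"))
                present[invader] = False
                continue
            for s in S:
                extinctions.append((int(s), "singular"))
            present[S] = False
            continue
        if not np.all(np.isfinite(x)):
            x = np.full(S.size, -np.inf)

        below = x < threshold
        if not below.any():
            biomass[:] = 0.0
            biomass[S] = x
            return EquilibriumResult(S, biomass, extinctions)
        for s in S[below]:
            extinctions.append((int(s), "threshold"))
        present[S[below]] = False


def full_pool_persistence(dyn: LocalDynamics) -> float:
    """Survivor fraction when the whole regional pool is placed at equilibrium
    and the extinction threshold cascades."""
    res = local_equilibrium(dyn, np.ones(dyn.n_S, dtype=bool))
    return res.n_survivors / dyn.n_S
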