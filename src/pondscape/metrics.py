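"""Diversity and biomass responses, asynchrony sensitivities, and
standardized effect-size regressions.

Instantaneous responses (mainland excluded throughout, since the mainland is
a fixed boundary condition rather than part of the assembling metacommunity):

* ``P_alpha(t)`` -- mean over *active* non-mainland sites of site richness
  divided by pool size (missing when no such site is active);
* ``P_gamma(t)`` -- richness of the union over non-mainland sites / pool size;
* ``B_gamma(t)`` -- summed biomass over non-mainland sites;
* ``B_beta(t)``  -- coefficient of variation of site biomasses over active
  non-mainland sites (missing with < 2 active sites or zero mean).

Scalars are continuous power means over the run (p = 1 by default, i.e. the
time average, with missing intervals excluded from the measure), and beta
persistence is the ratio ``P_beta = P_gamma / P_alpha``.  The sensitivity of
any response ``x`` to landscape asynchrony is the finite difference
``S[x] = (x_H - x_L) / (A_H - A_L)`` between a high- and a low-asynchrony run
(referential values A_L = 0, A_H = 0.5, so S = 2 (x_H - x_L)).

Effect sizes of the stabilizing factors on the sensitivities come from an OLS
regression of S on the z-scored predictors T (food-web temperature), lambda
(self-limitation) and a_hat = log10(a) (dispersal ability), their three
pairwise products and three squares; AICc compares all 512 term subsets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _stats

from . import community as _community
from . import foodweb as _foodweb
from . import landscape as _landscape
from . import simulate as _simulate
from .exceptions import GenerationError

__all__ = [
    "ResponseSet",
    "SensitivityRecord",
    "EffectSizeTable",
    "SweepConfig",
    "instantaneous_persistence",
    "instantaneous_biomass",
    "assembly_persistence",
    "power_mean",
    "summarize_run",
    "sensitivity",
    "monotone_trend_pvalue",
    "effect_sizes",
    "run_sweep",
    "effect_tables",
    "RESPONSES",
    "A_LOW",
    "A_HIGH",
]

#: Referential asynchrony values for sensitivities.
A_LOW, A_HIGH = 0.0, 0.5

RESPONSES = ("P_alpha", "P_gamma", "P_beta", "B_gamma", "B_beta")

TERM_NAMES = ("T", "lam", "ahat", "T:lam", "T:ahat", "lam:ahat", "T^2", "lam^2", "ahat^2")


# ---------------------------------------------------------------------------
# instantaneous responses


def instantaneous_persistence(
    present: np.ndarray,
    active: np.ndarray,
    mainland: int,
    scope: str,
) -> float:
    """Alpha or gamma persistence of one occupancy snapshot.

    ``present`` is the (n_P, n_S) occupancy matrix. Alpha averages site
    richness / n_S over active non-mainland sites and is NaN when none is
    active; gamma is the union richness over non-mainland sites / n_S.
    """
    n_P, n_S = present.shape
    nm = np.arange(n_P) != mainland
    if scope == "alpha":
        sites = nm & np.asarray(active, dtype=bool)
        if not sites.any():
            return float("nan")
        return float(present[sites].sum(axis=1).mean() / n_S)
    if scope == "gamma":
        return float(present[nm].any(axis=0).sum() / n_S)
    raise ValueError("scope must be 'alpha' or 'gamma'")


def instantaneous_biomass(
    site_biomass: np.ndarray,
    active: np.ndarray,
    mainland: int,
    scope: str,
    ddof: int = 0,
) -> float:
    """Gamma (summed) or beta (CV across active sites) biomass of a snapshot."""
    n_P = site_biomass.shape[0]
    nm = np.arange(n_P) != mainland
    if scope == "gamma":
        return float(site_biomass[nm].sum())
    if scope == "beta":
        sites = nm & np.asarray(active, dtype=bool)
        vals = site_biomass[sites]
        if vals.size < 2:
            return float("nan")
        mean = vals.mean()
        if mean == 0:
            return float("nan")
        return float(np.std(vals, ddof=ddof) / mean)
    raise ValueError("scope must be 'gamma' or 'beta'")


def power_mean(values, weights, p: float = 1.0) -> float:
    """Continuous power mean of a piecewise-constant series.

    ``values[k]`` holds on an interval of length ``weights[k]``; NaN values
    are treated as missing and excluded from the measure. ``p = 0`` is the
    geometric-mean limit. Returns NaN when the non-missing measure is empty.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must align")
    ok = ~np.isnan(v) & (w > 0)
    v, w = v[ok], w[ok]
    W = w.sum()
    if W == 0:
        return float("nan")
    if abs(p) < 1e-9:  # geometric-mean limit; avoids v**p cancellation
        if np.any(v <= 0):
            return 0.0
        return float(np.exp(np.sum(w * np.log(v)) / W))
    if p < 0 and np.any(v == 0):
        return 0.0
    return float((np.sum(w * v**p) / W) ** (1.0 / p))


@dataclass
class ResponseSet:
    """Time-averaged responses of one run (NaN marks undefined values)."""

    P_alpha: float
    P_gamma: float
    P_beta: float
    B_gamma: float
    B_beta: float
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in RESPONSES}


def summarize_run(
    traj,
    p_exponent: float = 1.0,
    count_empty_as_zero: bool = False,
    cv_ddof: int = 0,
) -> ResponseSet:
    """Collapse a trajectory into the five scalar responses.

    Instantaneous responses are evaluated on every inter-event interval and
    averaged with the continuous power mean; intervals where alpha (or beta
    biomass) is undefined are excluded from that response's measure unless
    ``count_empty_as_zero``.
    """
    t0, t1 = traj.intervals[:, 0], traj.intervals[:, 1]
    lengths = t1 - t0
    n_int, n_P = traj.richness.shape
    nm = np.arange(n_P) != traj.mainland
    n_S = traj.n_S

    act = traj.active[:, nm]
    n_active = act.sum(axis=1)
    rich = traj.richness[:, nm].astype(float)
    biom = traj.site_biomass[:, nm]

    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(
            n_active > 0,
            np.where(act, rich, 0.0).sum(axis=1) / np.maximum(n_active, 1) / n_S,
            np.nan,
        )
        gamma = traj.gamma_richness / n_S
        b_gamma = biom.sum(axis=1)
        sums = np.where(act, biom, 0.0)
        mean_b = sums.sum(axis=1) / np.maximum(n_active, 1)
        var_b = (
            np.where(act, (biom - mean_b[:, None]) ** 2, 0.0).sum(axis=1)
            / np.maximum(n_active - cv_ddof, 1)
        )
        b_beta = np.where(
            (n_active >= 2) & (mean_b > 0), np.sqrt(var_b) / mean_b, np.nan
        )
    if count_empty_as_zero:
        alpha = np.nan_to_num(alpha)
        b_beta = np.nan_to_num(b_beta)

    P_alpha = power_mean(alpha, lengths, p_exponent)
    P_gamma = power_mean(gamma, lengths, p_exponent)
    B_gamma = power_mean(b_gamma, lengths, p_exponent)
    B_beta = power_mean(b_beta, lengths, p_exponent)
    P_beta = P_gamma / P_alpha if P_alpha and not np.isnan(P_alpha) else float("nan")
    return ResponseSet(
        P_alpha=P_alpha, P_gamma=P_gamma, P_beta=P_beta,
        B_gamma=B_gamma, B_beta=B_beta,
        provenance=dict(getattr(traj, "params", {})),
    )


@dataclass
class SensitivityRecord:
    response: str
    x_L: float
    x_H: float
    S: float
    A_L: float = A_LOW
    A_H: float = A_HIGH


def monotone_trend_pvalue(levels, values, increasing: bool = True) -> float:
    """One-sided Kendall trend test of ``values`` against ordered ``levels``.

    Small p supports a monotone (increasing or decreasing) trend across the
    ordered factor levels; ties are handled by the tau-b statistic.
    """
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    tau, p = _stats.kendalltau(levels[ok], values[ok])
    if np.isnan(tau):
        return 1.0
    return p / 2 if (tau > 0) == increasing else 1 - p / 2


def sensitivity(x_L: float, x_H: float, A_L: float = A_LOW, A_H: float = A_HIGH) -> float:
    """Finite-difference sensitivity ``(x_H - x_L) / (A_H - A_L)``."""
    if A_H <= A_L:
        raise ValueError("A_H must exceed A_L")
    return (x_H - x_L) / (A_H - A_L)


# ---------------------------------------------------------------------------
# effect sizes


@dataclass
class EffectSizeTable:
    """OLS coefficients on z-scored predictors plus AICc model selection."""

    coef: pd.Series
    se: pd.Series
    aicc: pd.DataFrame  # columns: terms (tuple), k, aicc
    best_terms: tuple
    full_model_best: bool
    n: int


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a Gaussian linear model with
    ``k`` parameters (including the intercept)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    rss = max(rss, n * 1e-12)  # floor so ~exact fits compare by the penalty
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _design_matrix(T, lam, ahat) -> np.ndarray:
    z = lambda v: (v - v.mean()) / v.std(ddof=0)
    zT, zl, za = z(np.asarray(T, float)), z(np.asarray(lam, float)), z(np.asarray(ahat, float))
    return np.column_stack(
        [zT, zl, za, zT * zl, zT * za, zl * za, zT**2, zl**2, za**2]
    )


def effect_sizes(design: pd.DataFrame, response: str = "S") -> EffectSizeTable:
    """Standardized effect sizes of (T, lam, ahat) and their quadratic terms.

    ``design`` needs columns T, lam, ahat and the response. Predictors are
    z-scored before products and squares are formed; the full model is fit by
    OLS and every subset of the nine terms (intercept always included) is
    ranked by AICc.
    """
    needed = {"T", "lam", "ahat", response}
    if not needed.issubset(design.columns):
        raise ValueError(f"design must contain columns {sorted(needed)}")
    df = design.dropna(subset=[response])
    n = len(df)
    if n < 11:
        raise ValueError("need at least 11 rows to fit the full model")
    X = _design_matrix(df["T"].values, df["lam"].values, df["ahat"].values)
    y = df[response].values.astype(float)

    X_full = sm.add_constant(X)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        # identify (approximately) collinear columns via QR
        _, R = np.linalg.qr(X_full)
        bad = [TERM_NAMES[i - 1] for i in range(1, X_full.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear terms: {bad}")

    fit = sm.OLS(y, X_full).fit()
    coef = pd.Series(fit.params[1:], index=TERM_NAMES)
    se = pd.Series(fit.bse[1:], index=TERM_NAMES)

    rows = []
    ones = np.ones((n, 1))
    for mask in itertools.product([False, True], repeat=9):
        terms = tuple(t for t, m in zip(TERM_NAMES, mask) if m)
        cols = np.hstack([ones, X[:, list(np.flatnonzero(mask))]]) if any(mask) else ones
        k = cols.shape[1]
        if n - k - 1 <= 0:
            warnings.warn(f"skipping subset {terms}: n - k - 1 <= 0")
            continue
        beta, *_ = np.linalg.lstsq(cols, y, rcond=None)
        rss = float(np.sum((y - cols @ beta) ** 2))
        rows.append({"terms": terms, "k": k, "aicc": aicc(rss, n, k)})
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    best = tuple(table.loc[0, "terms"])
    return EffectSizeTable(
        coef=coef,
        se=se,
        aicc=table,
        best_terms=best,
        full_model_best=(best == TERM_NAMES),
        n=n,
    )


# ---------------------------------------------------------------------------
# single-site assembly (stability-surface experiment)


def assembly_persistence(
    n_S: int,
    n_B: int,
    n_L: int,
    T: float,
    lam: float,
    seed: int,
    a: float = 3000.0,
    years: int = 6,
    max_tries: int = 30,
    mode: str = "assembly",
) -> float:
    """Species persistence of a single community assembled from the pool.

    One permanently active site is colonized from the mainland with unlimited
    access to the regional pool (a two-site star landscape with fast
    dispersal).  Persistence is the time-averaged site richness divided by
    n_S: sequential invasions, failed establishments and secondary-extinction
    cascades leave hot (high-T) or weakly self-limited (low-lambda) webs stuck
    below full richness.  If no feasible & stable parameterization exists
    within ``max_tries``, assembly fails and persistence is 0.

    ``mode="equilibrium"`` instead scores the survivor fraction when the
    whole pool is dropped at equilibrium at once (the algebraic shortcut;
    blind to invasion resistance).
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    try:
        _, dyn = _community.generate_stable_regional_community(
            n_S, n_B, n_L, T, lam,
            seed=int(ss[0].generate_state(1)[0] % 2**31),
            max_tries=max_tries,
        )
    except GenerationError:
        return 0.0  # no feasible & stable parameterization: assembly fails
    if mode == "equilibrium":
        return _community.full_pool_persistence(dyn)
    if mode != "assembly":
        raise ValueError("mode must be 'assembly' or 'equilibrium'")
    L = _landscape.generate_star_landscape(1, 0.2, seed=0)
    sched = _landscape.sample_activation_schedule(L, 0.0, years, seed=0)
    sched.intervals[1] = np.array([[0.0, float(years)]])  # permanently active
    traj = _simulate.simulate_run(
        L, sched, dyn.web, dyn, a, float(years),
        seed=int(ss[1].generate_state(1)[0] % 2**31),
        record_events=False,
    )
    lengths = traj.intervals[:, 1] - traj.intervals[:, 0]
    return float(traj.richness[:, 1] @ lengths / years / n_S)


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepConfig:
    """Grid and problem sizes for an asynchrony-sensitivity experiment.

    Defaults mirror the study conditions at desk scale: food webs with 20%
    basal species, landscapes with n_E = 2 n_P and n_C = 5 modules on the
    unit square, x = 2, 6 simulated years, and the referential asynchrony
    contrast A in {0, 0.5}.
    """

    T_values: tuple = (0.2,)
    lam_values: tuple = (0.47,)
    a_values: tuple = (3000.0,)
    replicates: int = 20
    years: int = 6
    n_S: int = 30
    C: float = 0.2
    n_P: int = 25
    F: float = 50.0
    x: float = 2.0
    n_C: int = 5
    A_low: float = A_LOW
    A_high: float = A_HIGH
    seed: int = 0
    max_tries: int = 100
    basal_fraction: float = 0.2

    @property
    def n_B(self) -> int:
        return max(1, round(self.basal_fraction * self.n_S))

    @property
    def n_L(self) -> int:
        return _foodweb.links_for_connectance(self.n_S, self.n_B, self.C)

    @property
    def n_E(self) -> int:
        return 2 * self.n_P


def _replicate_runs(cfg: SweepConfig, T, lam, a_list, seed_seq):
    """One replicate: shared community/landscape/w across a values and A pair."""
    s = seed_seq.spawn(5)
    ints = [int(x.generate_state(1)[0] % 2**31) for x in s]
    _, dyn = _community.generate_stable_regional_community(
        cfg.n_S, cfg.n_B, cfg.n_L, T, lam, seed=ints[0], max_tries=cfg.max_tries
    )
    L = _landscape.generate_landscape(cfg.n_P, cfg.n_E, cfg.n_C, cfg.F, cfg.x, seed=ints[1])
    lo, hi = _landscape.paired_schedules(L, cfg.A_low, cfg.A_high, cfg.years, seed=ints[2])
    out = {}
    for j, a in enumerate(a_list):
        run_lo = _simulate.simulate_run(
            L, lo, dyn.web, dyn, a, cfg.years, seed=(ints[3] + j) % 2**31,
            record_events=False,
        )
        run_hi = _simulate.simulate_run(
            L, hi, dyn.web, dyn, a, cfg.years, seed=(ints[4] + j) % 2**31,
            record_events=False,
        )
        out[a] = (summarize_run(run_lo), summarize_run(run_hi))
    return out


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Paired low/high-asynchrony simulations over the (T, lam, a) grid.

    Returns a tidy table with one row per cell x replicate x response holding
    the low- and high-asynchrony values and the sensitivity S. Within a
    replicate the community, landscape and nominal active lengths are shared
    between the two asynchrony levels (and across dispersal abilities), so S
    isolates the asynchrony contrast.
    """
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    cells = list(itertools.product(cfg.T_values, cfg.lam_values))
    children = root.spawn(len(cells) * cfg.replicates)
    for ci, (T, lam) in enumerate(cells):
        for rep in range(cfg.replicates):
            seq = children[ci * cfg.replicates + rep]
            res = _replicate_runs(cfg, T, lam, cfg.a_values, seq)
            for a, (lo, hi) in res.items():
                for name in RESPONSES:
                    x_L, x_H = getattr(lo, name), getattr(hi, name)
                    S = (
                        sensitivity(x_L, x_H, cfg.A_low, cfg.A_high)
                        if np.isfinite(x_L) and np.isfinite(x_H)
                        else float("nan")
                    )
                    rows.append(
                        {"T": T, "lam": lam, "a": a, "ahat": np.log10(a),
                         "replicate": rep, "response": name,
                         "x_low": x_L, "x_high": x_H, "S": S}
                    )
    return pd.DataFrame(rows)


def effect_tables(results: pd.DataFrame) -> dict[str, EffectSizeTable]:
    """Effect-size regression per response from a sweep results table."""
    out = {}
    for name, grp in results.groupby("response"):
        try:
            out[name] = effect_sizes(grp.rename(columns={"S": "S"}), response="S")
        except ValueError:
            continue
    return out
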