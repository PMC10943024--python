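import numpy as np
import pytest

import pondscape as ps
from pondscape.community import LocalDynamics
from pondscape.foodweb import FoodWeb


def make_web(links, n_S, basal_ids, T=0.0):
    """Hand-built food web from an explicit (prey, predator) link list."""
    basal = np.zeros(n_S, dtype=bool)
    basal[list(basal_ids)] = True
    return FoodWeb(n_S=n_S, basal=basal, links=np.array(links, dtype=int).reshape(-1, 2), T=T)


def make_dynamics(web, M, r):
    """LocalDynamics with explicit matrix and rates (x* solved directly)."""
    M = np.asarray(M, dtype=float)
    r = np.asarray(r, dtype=float)
    x = np.linalg.solve(M, -r)
    return LocalDynamics(web=web, M=M, r=r, lam=-M[0, 0], x_star=x, y_star=float(x.min()))


@pytest.fixture
def single_basal_dynamics():
    """One basal species, lam = 0.5, r = 1: equilibrium biomass 2."""
    web = make_web(np.empty((0, 2), int), 1, [0])
    return make_dynamics(web, [[-0.5]], [1.0])


@pytest.fixture
def pair_dynamics():
    """Basal + consumer with M = [[-0.5, -1], [0.4, -0.5]], r = (1, -0.01)."""
    web = make_web([(0, 1)], 2, [0])
    return make_dynamics(web, [[-0.5, -1.0], [0.4, -0.5]], [1.0, -0.01])


@pytest.fixture(scope="session")
def stable_community():
    """A moderately sized accepted community reused across tests."""
    web, dyn = ps.generate_stable_regional_community(
        20, 4, 61, 0.2, 0.6, seed=11, max_tries=100
    )
    return web, dyn


@pytest.fixture(scope="session")
def star_setup():
    """Star landscape + tiny 3-species chain community for simulator tests."""
    L = ps.generate_star_landscape(4, 0.2, seed=0)
    web = make_web([(0, 1), (1, 2)], 3, [0])
    # chain with strong basal growth; all three coexist
    M = np.array([[-1.0, -1.0, 0.0], [0.4, -1.0, -1.0], [0.0, 0.4, -1.0]])
    sol = ps.parameterize_growth_rates(M, web.basal)
    dyn = LocalDynamics(web=web, M=M, r=sol.r, lam=1.0, x_star=sol.x_star, y_star=sol.y_star)
    return L, web, dyn
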