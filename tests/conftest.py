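import numpy as np
import pytest

import stepwedge as sw

MASTER_SEED = 20181206


@pytest.fixture(scope="session")
def design12():
    """The simulation study's design: 12 clusters x 20 participants x 13 steps."""
    return sw.standard_design(12, 20)


@pytest.fixture(scope="session")
def small_design():
    return sw.standard_design(4, 5)


@pytest.fixture(scope="session")
def d17_dataset(design12):
    """One simulated replicate of the step + linear calendar/exposure scenario."""
    return sw.simulate_trial(design12, sw.get_scenario("D17"), MASTER_SEED)


@pytest.fixture(scope="session")
def d1_small(small_design):
    """A small null-scenario dataset (flat mean, no intervention effect)."""
    return sw.simulate_trial(small_design, sw.get_scenario("D1"), MASTER_SEED)


@pytest.fixture(scope="session")
def d17_small(small_design):
    return sw.simulate_trial(small_design, sw.get_scenario("D17"), MASTER_SEED)


@pytest.fixture(scope="session")
def d17_mid():
    """7-step design: the smallest supporting the six-month estimand."""
    return sw.simulate_trial(sw.standard_design(6, 4), sw.get_scenario("D17"), MASTER_SEED)


@pytest.fixture(scope="session")
def m4_fit_small(d17_small):
    return sw.fit_formulation(d17_small, "M4", structure="CS")


def random_tiny_instance(rng, unbalanced=False):
    """Random small grouped dataset plus admissible variance components."""
    K = int(rng.integers(2, 4))
    m = int(rng.integers(1, 4))
    n = int(rng.integers(2, 5))
    rows = []
    sid = 0
    for k in range(K):
        for _ in range(m):
            sid += 1
            for t in range(1, n + 1):
                rows.append((k + 1, sid, t))
    rows = np.array(rows)
    if unbalanced and len(rows) > 6:
        keep = rng.permutation(len(rows))[: len(rows) - 3]
        rows = rows[np.sort(keep)]
    N = len(rows)
    X = np.column_stack([np.ones(N), rng.normal(size=N), rng.normal(size=N)])
    y = rng.normal(size=N)
    vc = sw.VarianceComponents(
        sigma_gamma=float(rng.uniform(0.1, 2.0)),
        sigma_h=float(rng.uniform(0.1, 2.0)),
        sigma=float(rng.uniform(0.5, 2.0)),
        rho=float(rng.uniform(-0.8, 0.8)),
    )
    return rows, X, y, vc


def dense_gaussian_loglik(rows, X, y, vc, structure):
    """Independent oracle: profile beta and evaluate the dense MVN density."""
    from scipy.stats import multivariate_normal

    cl, su, ti = rows[:, 0], rows[:, 1], rows[:, 2]
    same_c = cl[:, None] == cl[None, :]
    same_s = su[:, None] == su[None, :]
    lag = np.abs(ti[:, None] - ti[None, :])
    V = vc.sigma_gamma**2 * same_c + vc.sigma_h**2 * same_s
    if structure == "AR1":
        V = V + vc.sigma**2 * (vc.rho**lag) * same_s
    else:
        V = V + vc.sigma**2 * np.eye(len(y))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return multivariate_normal(mean=X @ beta, cov=V).logpdf(y), beta
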