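"""Shared fixtures and independent oracles.

The QP oracle solves the SVM dual directly with scipy's SLSQP on the
full quadratic program (feasible for the small problems used in tests);
it shares no code with the package's SMO solver.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from mklsvm_pso import FeatureDataset, KernelParams, gram_matrix


def qp_dual_oracle(K, y, C, tol=1e-12):
    """Brute-force dual solution: min 1/2 a'Qa - e'a, y'a = 0, 0 <= a <= C.

    Returns (alpha, objective).  Independent of the SMO path.
    """
    K = np.asarray(K, float)
    y = np.asarray(y, float)
    l = y.shape[0]
    Q = np.outer(y, y) * K

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(l)

    res = minimize(
        obj,
        x0=np.full(l, min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0.0, C)] * l,
        constraints=[{"type": "eq", "fun": lambda a: y @ a, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": tol},
    )
    assert res.success, res.message
    return res.x, float(obj(res.x))


@pytest.fixture(scope="session")
def xor_problem():
    """The 4-point XOR fixture: RBF g=0.5, C=10 separates it perfectly."""
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([-1, -1, 1, 1])
    p = KernelParams(m=0.0, d=2, g=0.5)
    K = gram_matrix(X, X, p)
    return X, y, p, K


@pytest.fixture(scope="session")
def random_small_duals():
    """20 random small dual problems (l <= 12) with mixed-kernel Grams."""
    rng = np.random.default_rng(20240901)
    problems = []
    for _ in range(20):
        l = int(rng.integers(6, 13))
        X = rng.standard_normal((l, 3))
        n_pos = int(rng.integers(2, l - 1))
        y = np.concatenate([np.ones(n_pos, int), -np.ones(l - n_pos, int)])
        p = KernelParams(
            m=float(rng.uniform(0.1, 0.9)),
            d=int(rng.choice([2, 3])),
            g=float(rng.uniform(0.5, 3.0)),
        )
        C = float(rng.uniform(0.5, 20.0))
        problems.append((gram_matrix(X, X, p), y, C))
    return problems


@pytest.fixture(scope="session")
def separable_gaussian():
    """Well-separated 30-point two-Gaussian table (training-error checks)."""
    from mklsvm_pso import generate_gaussian_classes

    return generate_gaussian_classes(n_pos=15, n_neg=15, dims=3, separation=6.0, seed=2)
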