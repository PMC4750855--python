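"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: variance
components come from solving the full commonality-analysis linear system
over all predictor subsets, and regression coefficients from the normal
equations assembled by hand.
"""

from itertools import combinations

import numpy as np


def r_squared_subset(y, X, cols):
    """Plain R^2 of y on the listed predictor columns (with intercept)."""
    y = np.asarray(y, float)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if not cols:
        return 0.0
    A = np.column_stack([np.ones(len(y)), X[:, list(cols)]])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return 1.0 - float(resid @ resid) / sst


def commonality_partition(y, X):
    """All-subsets commonality analysis.

    Solves R^2(A) = sum over subsets S intersecting A of c(S), for every
    nonempty predictor subset A, giving the unique (singleton) and common
    (higher-order) variance components exactly.  Returns (unique SS per
    predictor, pooled common SS, error SS, total SS).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    k = X.shape[1]
    yc = y - y.mean()
    sst = float(yc @ yc)
    subsets = [frozenset(c) for r in range(1, k + 1) for c in combinations(range(k), r)]
    M = np.array([[1.0 if s & a else 0.0 for s in subsets] for a in subsets])
    rhs = np.array([r_squared_subset(y, X, sorted(a)) for a in subsets])
    coef = np.linalg.solve(M, rhs)
    c = dict(zip(subsets, coef))
    unique = np.array([c[frozenset({j})] * sst for j in range(k)])
    common = sum(v for s, v in c.items() if len(s) > 1) * sst
    error = (1.0 - r_squared_subset(y, X, range(k))) * sst
    return unique, common, error, sst


def normal_equations_fit(y, X):
    """OLS coefficients straight from the normal equations."""
    A = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, float))


def correlated_regression_instance(rng, n, k, rho=0.6):
    """Random y, X with correlated predictors and a planted linear signal."""
    cov = rho * np.ones((k, k)) + (1 - rho) * np.eye(k)
    X = rng.multivariate_normal(np.zeros(k), cov, size=n)
    beta = rng.normal(0, 1, size=k)
    y = X @ beta + rng.normal(0, 1.0, size=n)
    return y, X
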