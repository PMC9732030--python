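"""Independent numerical oracles shared by the unit and acceptance tests.

The proximal operators are checked against direct L-BFGS minimization of
their defining objectives.  The non-smooth norm terms are smoothed with a
tiny eps (1e-8) inside the square roots so the objective is differentiable
at thresholded solutions; this perturbs the minimizer by O(eps), far below
the comparison tolerances.  Because the prox objective is 1-strongly
convex, the gradient norm at the returned point bounds its distance to the
smoothed minimizer; L-BFGS is restarted until that certificate is small.
"""

import numpy as np
from scipy.optimize import minimize

_OPTS = {"maxiter": 2000, "ftol": 1e-18, "gtol": 1e-10, "maxls": 100}


def _minimize_restarted(fg, x0, cert: float = 1e-8, max_restarts: int = 20):
    x = x0
    for _ in range(max_restarts):
        x = minimize(fg, x, jac=True, method="L-BFGS-B", options=_OPTS).x
        if np.linalg.norm(fg(x)[1]) < cert:
            break
    return x


def prox_nuclear_bruteforce(M: np.ndarray, tau: float, eps: float = 1e-8) -> np.ndarray:
    """argmin_J tau*||J||_* + 0.5*||J - M||_F^2 by direct minimization."""
    shape = M.shape

    def fg(x):
        J = x.reshape(shape)
        U, s, Vt = np.linalg.svd(J, full_matrices=False)
        ss = np.sqrt(s ** 2 + eps ** 2)
        f = tau * ss.sum() + 0.5 * np.sum((J - M) ** 2)
        g = tau * (U * (s / ss)) @ Vt + (J - M)
        return f, g.ravel()

    return _minimize_restarted(fg, M.ravel()).reshape(shape)


def prox_l21_bruteforce(M: np.ndarray, tau: float, eps: float = 1e-8) -> np.ndarray:
    """argmin_E tau*||E||_{2,1} + 0.5*||E - M||_F^2 by direct minimization."""
    shape = M.shape

    def fg(x):
        E = x.reshape(shape)
        norms = np.sqrt((E ** 2).sum(axis=0) + eps ** 2)
        f = tau * norms.sum() + 0.5 * np.sum((E - M) ** 2)
        g = tau * E / norms[None, :] + (E - M)
        return f, g.ravel()

    return _minimize_restarted(fg, M.ravel()).reshape(shape)


def pairwise_auc(test_scores, candidate_scores) -> float:
    """O(n^2) Mann-Whitney count: (#{t > c} + 0.5 #{t == c}) / (n_t n_c)."""
    t = np.asarray(test_scores, dtype=float).ravel()
    c = np.asarray(candidate_scores, dtype=float).ravel()
    wins = ties = 0
    for ti in t:
        for ci in c:
            if ti > ci:
                wins += 1
            elif ti == ci:
                ties += 1
    return (wins + 0.5 * ties) / (t.size * c.size)
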