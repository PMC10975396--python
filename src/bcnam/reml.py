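"""Dense EM-REML for Gaussian mixed models with i.i.d. random factors.

Solves y = X b + sum_i Z_i u_i + e with u_i ~ N(0, I s2_i), e ~ N(0, I s2_e)
through Henderson's mixed-model equations.  The EM update keeps every
variance component non-negative by construction, which is why it is preferred
here over faster Newton-type REML at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MixedModelFit", "design_matrix", "emreml"]

_VAR_FLOOR = 1e-10


def design_matrix(labels: Sequence) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix (unit row sums) and the level order."""
    cat = pd.Categorical(labels)
    Z = np.zeros((len(cat), len(cat.categories)))
    Z[np.arange(len(cat)), cat.codes] = 1.0
    return Z, list(cat.categories)


@dataclass
class MixedModelFit:
    """Result of :func:`emreml`."""

    beta: np.ndarray
    u: dict                      # factor name -> BLUP vector
    varcomp: dict                # factor name (+ "e") -> variance estimate
    beta_cov: np.ndarray         # sampling covariance of beta (GLS)
    n_obs: int
    rank_x: int
    converged: bool
    n_iter: int

    @property
    def residual_df(self) -> int:
        return self.n_obs - self.rank_x


def emreml(
    y: np.ndarray,
    X: np.ndarray,
    Z: Mapping[str, np.ndarray],
    max_iter: int = 500,
    tol: float = 1e-6,
    init: Mapping[str, float] | None = None,
    fixed_varcomp: Mapping[str, float] | None = None,
) -> MixedModelFit:
    """EM-REML variance components + mixed-model solutions.

    ``Z`` maps factor names to incidence matrices.  ``fixed_varcomp`` pins
    selected components (including ``"e"``) and estimates the rest; with all
    components pinned a single mixed-model solve is performed.  Convergence is
    declared when the largest relative change of any variance estimate falls
    below ``tol``.  EM approaches the optimum linearly, so the default
    tolerance is a compromise between accuracy and iteration count.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    names = list(Z.keys())
    Zmats = [np.asarray(Z[k], dtype=float) for k in names]
    q = [z.shape[1] for z in Zmats]
    p = X.shape[1]
    rank_x = int(np.linalg.matrix_rank(X))

    # precompute cross-products
    Zfull = np.hstack(Zmats) if Zmats else np.zeros((n, 0))
    W = np.hstack([X, Zfull])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    var_y = float(np.var(y)) if n > 1 else 1.0
    var_y = max(var_y, _VAR_FLOOR)
    k_terms = len(names) + 1
    s2 = {name: var_y / k_terms for name in names}
    s2["e"] = var_y / k_terms
    if init:
        s2.update({k: max(float(v), _VAR_FLOOR) for k, v in init.items()})
    fixed = dict(fixed_varcomp or {})
    s2.update({k: max(float(v), _VAR_FLOOR) for k, v in fixed.items()})
    all_fixed = set(fixed) >= set(names) | {"e"}

    u_slices = []
    start = p
    for qi in q:
        u_slices.append(slice(start, start + qi))
        start += qi

    converged = False
    it = 0
    sol = np.zeros(W.shape[1])
    Cinv = np.eye(W.shape[1])
    for it in range(1, max_iter + 1):
        lam = np.concatenate(
            [np.full(qi, s2["e"] / max(s2[name], _VAR_FLOOR)) for name, qi in zip(names, q)]
        ) if names else np.zeros(0)
        M = WtW.copy()
        if len(lam):
            idx = np.arange(p, M.shape[0])
            M[idx, idx] += lam
        Cinv = np.linalg.pinv(M, hermitian=True)
        sol = Cinv @ Wty

        if all_fixed:
            converged = True
            break

        s2_new = dict(s2)
        resid_ss = max(yty - float(sol @ Wty), 0.0)
        if "e" not in fixed:
            s2_new["e"] = max(resid_ss / max(n - rank_x, 1), _VAR_FLOOR)
        for name, sl, qi in zip(names, u_slices, q):
            if name in fixed:
                continue
            u_i = sol[sl]
            tr = float(np.trace(Cinv[sl, sl]))
            s2_new[name] = max((float(u_i @ u_i) + s2["e"] * tr) / qi, _VAR_FLOOR)
        # change scaled by the phenotypic variance: components collapsing to
        # the floor otherwise keep large *relative* changes forever
        delta = max(abs(s2_new[k] - s2[k]) for k in s2_new) / var_y
        s2 = s2_new
        if delta < tol:
            converged = True
            break

    if not all_fixed:
        # final solve at the converged variance estimates
        lam = np.concatenate(
            [np.full(qi, s2["e"] / max(s2[name], _VAR_FLOOR)) for name, qi in zip(names, q)]
        ) if names else np.zeros(0)
        M = WtW.copy()
        if len(lam):
            idx = np.arange(p, M.shape[0])
            M[idx, idx] += lam
        Cinv = np.linalg.pinv(M, hermitian=True)
        sol = Cinv @ Wty

    beta = sol[:p]
    u = {name: sol[sl] for name, sl in zip(names, u_slices)}
    beta_cov = s2["e"] * Cinv[:p, :p]
    return MixedModelFit(
        beta=beta,
        u=u,
        varcomp=dict(s2),
        beta_cov=beta_cov,
        n_obs=n,
        rank_x=rank_x,
        converged=converged,
        n_iter=it,
    )
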