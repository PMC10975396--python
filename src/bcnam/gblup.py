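"""Bayesian multi-kernel GBLUP fit by Gibbs sampling.

The model for environment-wise hybrid values y (length n) is

    y = Z_E beta + u_A + u_D + u_AE + u_DE + e

with environment means beta fixed (flat prior), main additive and dominance
effects shared across environments (covariance Z K Z' sigma2), independent
within-environment interaction deviations (environment-masked kernels), and
i.i.d. residuals.  Every random-effect vector is sampled in the eigenbasis of
its observation-level kernel, where the full conditionals are diagonal;
variances get scaled-inverse-chi-square updates with a weakly informative
prior (df 5, prior mean an equal share of the phenotypic variance).

The public surface is a scikit-learn style estimator, ``GBLUPRegressor``,
plus thin functional wrappers (``gibbs_fit``, ``predict_hybrids``).
Held-out hybrids never enter the likelihood; their predictions borrow
information purely through kernel covariances with the training observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["eigen_prepare", "GBLUPRegressor", "gibbs_fit", "predict_hybrids"]


def eigen_prepare(K: np.ndarray, floor: float = 1e-10,
                  sym_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a kernel, dropping the (floored) null space.

    Returns ``(U, s)`` with only eigenvalues above ``floor`` (relative to the
    largest) retained; the prior for the dropped directions is a point mass at
    zero, so sampling in the retained basis is exact.
    """
    K = np.asarray(K, dtype=float)
    scale = max(1.0, float(np.abs(K).max()))
    if np.abs(K - K.T).max() > sym_tol * scale:
        raise ValueError("kernel is not symmetric")
    w, v = np.linalg.eigh((K + K.T) / 2.0)
    cut = floor * max(1.0, float(w.max())) if w.size else floor
    keep = w > cut
    return v[:, keep], w[keep]


def _labels_from_X(X) -> pd.DataFrame:
    """Normalize the observation frame: columns ``hybrid`` and ``env``."""
    if isinstance(X, pd.DataFrame):
        if not {"hybrid", "env"}.issubset(X.columns):
            raise ValueError("X must have 'hybrid' and 'env' columns")
        return pd.DataFrame(
            {"hybrid": X["hybrid"].astype(str), "env": X["env"].astype(str)}
        ).reset_index(drop=True)
    arr = np.asarray(X)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("array X must be (n, 2): hybrid index, env index")
    return pd.DataFrame(
        {
            "hybrid": [f"h{int(i):06d}" for i in arr[:, 0]],
            "env": [f"e{int(j):04d}" for j in arr[:, 1]],
        }
    )


def _as_kernel_frame(K, prefix: str = "h") -> pd.DataFrame:
    if K is None:
        return None
    if isinstance(K, pd.DataFrame):
        out = K.copy()
        out.index = out.index.astype(str)
        out.columns = out.columns.astype(str)
        return out
    K = np.asarray(K, dtype=float)
    ids = [f"{prefix}{i:06d}" for i in range(K.shape[0])]
    return pd.DataFrame(K, index=ids, columns=ids)


class GBLUPRegressor(BaseEstimator, RegressorMixin):
    """Multi-kernel Bayesian GBLUP for multi-environment hybrid values.

    Parameters
    ----------
    K_A, K_D : array or DataFrame (hybrids x hybrids)
        Additive and (optional) dominance relationship kernels.  DataFrames
        carry hybrid ids on the index; plain arrays are addressed by row
        number.
    use_interactions : bool
        Include environment-interaction kernels (only meaningful with more
        than one environment).
    n_iter, burn_in, thin : int
        Gibbs sampler schedule; posterior summaries use the thinned
        post-burn-in draws.
    prior_df : float
        Degrees of freedom of the scaled-inverse-chi-square variance priors;
        each prior scale is set so the prior mean is an equal share of the
        sample variance of ``y``.
    fixed_variances : dict or None
        Pin variance components (keys among ``A``, ``D``, ``AE``, ``DE``,
        ``e``) instead of sampling them; used for oracle checks against
        closed-form BLUP.
    random_state : int or None
        Seed; identical seeds give identical chains.
    """

    def __init__(self, K_A=None, K_D=None, use_interactions=True,
                 n_iter=10_000, burn_in=1_000, thin=2, prior_df=5.0,
                 fixed_variances=None, random_state=None):
        self.K_A = K_A
        self.K_D = K_D
        self.use_interactions = use_interactions
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_df = prior_df
        self.fixed_variances = fixed_variances
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _obs_kernels(self, obs: pd.DataFrame, KA: pd.DataFrame,
                     KD: pd.DataFrame | None):
        hyb_pos = {h: i for i, h in enumerate(KA.index)}
        unknown = [h for h in obs["hybrid"].unique() if h not in hyb_pos]
        if unknown:
            raise KeyError(f"hybrids missing from kernel: {unknown[:5]}")
        h_idx = np.array([hyb_pos[h] for h in obs["hybrid"]])
        KA_arr = KA.to_numpy(dtype=float)
        kernels = {"A": KA_arr[np.ix_(h_idx, h_idx)]}
        if KD is not None:
            KD_arr = KD.loc[KA.index, KA.index].to_numpy(dtype=float)
            kernels["D"] = KD_arr[np.ix_(h_idx, h_idx)]
        else:
            KD_arr = None
        env = pd.Categorical(obs["env"], categories=sorted(obs["env"].unique()))
        e_idx = env.codes.astype(int)
        q = len(env.categories)
        if self.use_interactions and q > 1:
            mask = (e_idx[:, None] == e_idx[None, :]).astype(float)
            kernels["AE"] = mask * kernels["A"]
            if KD_arr is not None:
                kernels["DE"] = mask * kernels["D"]
        return kernels, h_idx, e_idx, list(env.categories), KA_arr, KD_arr

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        obs = _labels_from_X(X)
        if len(obs) != len(y):
            raise ValueError("X and y lengths differ")
        if np.isnan(y).any():
            raise ValueError("y must be complete; drop missing rows before fit")
        if self.K_A is None:
            raise ValueError("an additive kernel K_A is required")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        KA = _as_kernel_frame(self.K_A)
        KD = _as_kernel_frame(self.K_D)
        kernels, h_idx, e_idx, env_levels, KA_arr, KD_arr = self._obs_kernels(
            obs, KA, KD
        )
        n = len(y)
        q = len(env_levels)
        counts = np.bincount(e_idx, minlength=q).astype(float)
        decomp = {name: eigen_prepare(K) for name, K in kernels.items()}

        rng = np.random.default_rng(self.random_state)
        names = list(kernels)
        k_terms = len(names) + 1
        var_y = max(float(np.var(y)), 1e-12)
        df0 = float(self.prior_df)
        share = var_y / k_terms
        S0 = share * (df0 - 2.0) / df0 if df0 > 2 else share
        fixed = dict(self.fixed_variances or {})
        s2 = {name: float(fixed.get(name, share)) for name in names}
        s2e = float(fixed.get("e", share))

        beta = np.zeros(q)
        u = {name: np.zeros(n) for name in names}
        resid = y.copy()

        n_samples = 0
        beta_sum = np.zeros(q)
        u_sum = {name: np.zeros(n) for name in names}
        var_draws = {name: [] for name in (*names, "e")}

        for it in range(self.n_iter):
            # environment means (flat prior)
            r = resid + beta[e_idx]
            means = np.bincount(e_idx, weights=r, minlength=q) / counts
            beta = means + rng.standard_normal(q) * np.sqrt(s2e / counts)
            resid = r - beta[e_idx]
            # random effects, one kernel at a time, in the eigenbasis
            for name in names:
                U, s = decomp[name]
                r = resid + u[name]
                et = U.T @ r
                d = s * s2[name]
                denom = d + s2e
                b = et * d / denom + rng.standard_normal(len(s)) * np.sqrt(
                    d * s2e / denom
                )
                u_new = U @ b
                resid = r - u_new
                u[name] = u_new
                if name not in fixed:
                    ss = float(np.sum(b * b / s))
                    s2[name] = (ss + df0 * S0) / rng.chisquare(df0 + len(s))
            if "e" not in fixed:
                s2e = (float(resid @ resid) + df0 * S0) / rng.chisquare(df0 + n)
            if not np.isfinite(s2e) or s2e > 1e12 or any(
                not np.isfinite(v) or v > 1e12 for v in s2.values()
            ):
                raise RuntimeError(
                    f"variance draw diverged at iteration {it}: "
                    f"{ {**s2, 'e': s2e} }"
                )
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                n_samples += 1
                beta_sum += beta
                for name in names:
                    u_sum[name] += u[name]
                for name in names:
                    var_draws[name].append(s2[name])
                var_draws["e"].append(s2e)

        self.env_levels_ = env_levels
        self.hybrid_ids_ = list(KA.index)
        self.beta_ = beta_sum / n_samples
        self.u_mean_ = {name: u_sum[name] / n_samples for name in names}
        self.var_draws_ = pd.DataFrame(var_draws)
        self.var_mean_ = self.var_draws_.mean().to_dict()
        self.fitted_ = self.beta_[e_idx] + sum(self.u_mean_.values())
        self.n_chain_samples_ = n_samples
        self._train_obs = obs
        self._train_h_idx = h_idx
        self._train_e_idx = e_idx
        self._KA_arr = KA_arr
        self._KD_arr = KD_arr
        # projection weights for kernel-covariance prediction:
        # w = K_train^+ u_mean, computed in the eigenbasis
        self._weights = {}
        for name in names:
            U, s = decomp[name]
            self._weights[name] = U @ ((U.T @ self.u_mean_[name]) / s)
        return self

    # ------------------------------------------------------------------
    def _cross_kernels(self, obs_t: pd.DataFrame):
        hyb_pos = {h: i for i, h in enumerate(self.hybrid_ids_)}
        unknown = [h for h in obs_t["hybrid"].unique() if h not in hyb_pos]
        if unknown:
            raise KeyError(f"target hybrids missing from kernel: {unknown[:5]}")
        ht = np.array([hyb_pos[h] for h in obs_t["hybrid"]])
        env_pos = {e: i for i, e in enumerate(self.env_levels_)}
        bad_env = [e for e in obs_t["env"].unique() if e not in env_pos]
        if bad_env:
            raise KeyError(f"environments not seen in training: {bad_env}")
        et = np.array([env_pos[e] for e in obs_t["env"]])
        cross = {"A": self._KA_arr[np.ix_(ht, self._train_h_idx)]}
        if self._KD_arr is not None and "D" in self.u_mean_:
            cross["D"] = self._KD_arr[np.ix_(ht, self._train_h_idx)]
        if "AE" in self.u_mean_:
            mask = (et[:, None] == self._train_e_idx[None, :]).astype(float)
            cross["AE"] = mask * cross["A"]
            if "DE" in self.u_mean_:
                cross["DE"] = mask * cross["D"]
        return cross, et

    def predict(self, X):
        """Predict observation values (env mean + all genetic components)."""
        if not hasattr(self, "beta_"):
            raise RuntimeError("estimator is not fitted")
        obs_t = _labels_from_X(X)
        cross, et = self._cross_kernels(obs_t)
        pred = self.beta_[et].astype(float)
        for name, C in cross.items():
            pred = pred + C @ self._weights[name]
        return pred

    def summary(self) -> pd.DataFrame:
        """Posterior summary of variance components and environment means."""
        if not hasattr(self, "beta_"):
            raise RuntimeError("estimator is not fitted")
        rows = [
            {"parameter": f"sigma2_{name}", "posterior_mean": self.var_draws_[name].mean(),
             "posterior_sd": self.var_draws_[name].std()}
            for name in self.var_draws_.columns
        ]
        rows += [
            {"parameter": f"beta[{env}]", "posterior_mean": b, "posterior_sd": np.nan}
            for env, b in zip(self.env_levels_, self.beta_)
        ]
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        """Sampler settings and chain bookkeeping, JSON-serializable."""
        if not hasattr(self, "beta_"):
            raise RuntimeError("estimator is not fitted")
        return {
            "n_iter": int(self.n_iter),
            "burn_in": int(self.burn_in),
            "thin": int(self.thin),
            "prior_df": float(self.prior_df),
            "random_state": self.random_state,
            "n_chain_samples": int(self.n_chain_samples_),
            "kernels": list(self.u_mean_),
            "environments": list(self.env_levels_),
            "n_train_obs": int(len(self._train_obs)),
        }

    def genetic_values(self, X) -> np.ndarray:
        """Total genetic value (no environment mean) for target observations."""
        obs_t = _labels_from_X(X)
        cross, _ = self._cross_kernels(obs_t)
        out = np.zeros(len(obs_t))
        for name, C in cross.items():
            out += C @ self._weights[name]
        return out


def gibbs_fit(X, y, K_A, K_D=None, **settings) -> GBLUPRegressor:
    """Functional wrapper: fit a :class:`GBLUPRegressor` and return it."""
    return GBLUPRegressor(K_A=K_A, K_D=K_D, **settings).fit(X, y)


def predict_hybrids(fit: GBLUPRegressor, X_target) -> np.ndarray:
    """Predict held-out observations from a fitted model."""
    return fit.predict(X_target)
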