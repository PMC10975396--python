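"""Genomic relationship kernels for hybrid prediction.

The additive kernel is VanRaden's method 1 on -1/0/1 genotype codes:
K_A = W W' / (2 * sum_j p_j (1 - p_j)) with W the column-centered code matrix
and p_j the major-allele frequency.  The dominance kernel uses the classical
recoding of the three genotype classes to (-2q^2, 2pq, -2p^2) and denominator
sum_j (2 p_j q_j)^2.  Environment-interaction kernels are the Hadamard
product of an environment-match mask with the observation-expanded genetic
kernel, i.e. entry (i,j) is K[hyb(i), hyb(j)] when the observations share an
environment and 0 otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml import design_matrix

__all__ = [
    "additive_kernel",
    "dominance_kernel",
    "interaction_kernel",
    "main_effect_expansion",
    "KernelSet",
    "build_kernel_set",
]


def _as_array(m) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("kernel construction requires a complete genotype matrix")
    return arr


def _major_freq(arr: np.ndarray, p: np.ndarray | None) -> np.ndarray:
    if p is not None:
        p = np.asarray(p, dtype=float)
        if p.shape != (arr.shape[1],):
            raise ValueError("frequency vector length must match marker count")
        return p
    return (arr + 1.0).mean(axis=0) / 2.0


def additive_kernel(m, p: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 additive relationship matrix.

    ``p`` overrides the per-marker major-allele frequencies (default:
    computed from the rows of ``m``, i.e. among the hybrids entering the
    model).
    """
    arr = _as_array(m)
    p = _major_freq(arr, p)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: additive kernel undefined")
    W = arr - (2.0 * p - 1.0)  # column mean under frequency p
    K = W @ W.T / denom
    return (K + K.T) / 2.0


def dominance_kernel(m, p: np.ndarray | None = None) -> np.ndarray:
    """Classical dominance relationship matrix.

    Genotype classes (major hom, het, minor hom) are recoded per marker to
    (-2q^2, 2pq, -2p^2); K_D = H H' / sum_j (2 p_j q_j)^2.  A matrix with no
    heterozygous calls carries no dominance information and yields a zero
    kernel with a warning.
    """
    arr = _as_array(m)
    if not (arr == 0.0).any():
        warnings.warn("no heterozygous genotypes: dominance kernel is zero",
                      stacklevel=2)
        return np.zeros((arr.shape[0], arr.shape[0]))
    p = _major_freq(arr, p)
    q = 1.0 - p
    denom = float(np.sum((2.0 * p * q) ** 2))
    if denom <= 0:
        warnings.warn("no polymorphic markers: dominance kernel is zero",
                      stacklevel=2)
        return np.zeros((arr.shape[0], arr.shape[0]))
    H = np.where(arr == 1.0, -2.0 * q**2,
                 np.where(arr == 0.0, 2.0 * p * q, -2.0 * p**2))
    K = H @ H.T / denom
    return (K + K.T) / 2.0


def interaction_kernel(Z_E: np.ndarray, Z_X: np.ndarray, K_X: np.ndarray) -> np.ndarray:
    """Environment-interaction kernel (Z_E Z_E') Hadamard (Z_X K_X Z_X')."""
    Z_E = np.asarray(Z_E, dtype=float)
    Z_X = np.asarray(Z_X, dtype=float)
    if not np.allclose(Z_E.sum(axis=1), 1.0):
        raise ValueError("every observation needs exactly one environment")
    mask = Z_E @ Z_E.T
    return mask * main_effect_expansion(K_X, Z_X)


def main_effect_expansion(K_X: np.ndarray, Z_X: np.ndarray) -> np.ndarray:
    """Observation-level covariance of a main genetic effect: Z K Z'.

    Under environment-sorted ordering this equals the Kronecker product of an
    all-ones environment block matrix with K (the effect is shared across
    environments).
    """
    Z_X = np.asarray(Z_X, dtype=float)
    K = Z_X @ np.asarray(K_X, dtype=float) @ Z_X.T
    return (K + K.T) / 2.0


@dataclass
class KernelSet:
    """Hybrid-level and observation-level kernels for one observation frame."""

    hybrids: list
    envs: list
    Z_A: np.ndarray
    Z_E: np.ndarray
    K_A: np.ndarray
    K_D: np.ndarray | None
    obs_kernels: dict  # name -> n x n covariance over observations

    @property
    def n_obs(self) -> int:
        return self.Z_A.shape[0]


def build_kernel_set(
    obs: pd.DataFrame,
    K_A: pd.DataFrame | np.ndarray,
    K_D: pd.DataFrame | np.ndarray | None = None,
    use_interactions: bool = True,
) -> KernelSet:
    """Expand hybrid-level kernels over an observation frame.

    ``obs`` needs columns ``hybrid`` and ``env``.  When ``K_A``/``K_D`` are
    DataFrames the hybrid labels are matched by index; plain arrays must
    already be ordered consistently with the categorical order of
    ``obs['hybrid']``.  Interaction kernels are only built with more than one
    environment (with a single environment they coincide with the main-effect
    expansions).
    """
    hyb_labels = obs["hybrid"].astype(str)
    if isinstance(K_A, pd.DataFrame):
        hybrids = list(K_A.index.astype(str))
        missing = set(hyb_labels) - set(hybrids)
        if missing:
            raise KeyError(f"hybrids not present in kernel: {sorted(missing)[:5]}")
        K_A_arr = K_A.to_numpy(dtype=float)
        idx = {h: i for i, h in enumerate(hybrids)}
        codes = np.array([idx[h] for h in hyb_labels])
        Z_A = np.zeros((len(obs), len(hybrids)))
        Z_A[np.arange(len(obs)), codes] = 1.0
    else:
        Z_A, hybrids = design_matrix(hyb_labels)
        K_A_arr = np.asarray(K_A, dtype=float)
        if K_A_arr.shape[0] != len(hybrids):
            raise ValueError("kernel size does not match number of hybrids")
    if K_D is not None:
        K_D_arr = K_D.loc[hybrids, hybrids].to_numpy(dtype=float) if isinstance(
            K_D, pd.DataFrame) else np.asarray(K_D, dtype=float)
    else:
        K_D_arr = None

    Z_E, envs = design_matrix(obs["env"].astype(str))
    kernels = {"A": main_effect_expansion(K_A_arr, Z_A)}
    if K_D_arr is not None:
        kernels["D"] = main_effect_expansion(K_D_arr, Z_A)
    if use_interactions and len(envs) > 1:
        mask = Z_E @ Z_E.T
        kernels["AE"] = mask * kernels["A"]
        if K_D_arr is not None:
            kernels["DE"] = mask * kernels["D"]
    return KernelSet(
        hybrids=hybrids, envs=envs, Z_A=Z_A, Z_E=Z_E,
        K_A=K_A_arr, K_D=K_D_arr, obs_kernels=kernels,
    )
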