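"""Per-environment trial models, BLUEs, repeatability, CVe, and the
multi-environment general-combining-ability (GCA) model.

Each environment is adjusted separately with
``Y = mu + Gen + Blk + Ra + Ro + e``: variance components come from a REML
fit with every factor random; genotype BLUEs come from the mixed model with
genotype fixed and the design factors (block, range, row) random.
Repeatability on a plot basis is R = s2_g / (s2_g + s2_e / r) and the
residual coefficient of variation is CVe = 100 * sqrt(MSE) / mean — the
root-MSE convention, which keeps CVe unitless and on the familiar percent
scale.

The multi-environment model treats the pollinator (male) line as fixed —
its BLUE is the line's GCA — with environments, females, design factors
nested in environment, and all interactions random.  Each male is compared
to a named check by a Student's t-test on the GLS contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reml import MixedModelFit, design_matrix, emreml

logger = logging.getLogger(__name__)

__all__ = [
    "EnvFitResult",
    "GcaResult",
    "fit_env_varcomp",
    "fit_env_blues",
    "repeatability",
    "cve",
    "fit_gca_multienv",
]

DESIGN_COLS = ("block", "range", "row")


@dataclass
class EnvFitResult:
    env: str
    trait: str
    blues: pd.Series                # genotype -> BLUE (mu + genotype effect)
    varcomp: dict                   # from the all-random fit: g, block, range, row, e
    mse: float                      # residual variance of the fixed-genotype fit
    mean: float                     # raw trait mean in the environment
    repeatability: float            # NaN when g and e are not separable
    cve: float
    n_reps: float                   # mean plots per genotype
    identifiable: bool              # any genotype replicated?
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        out = self.blues.rename("blue").rename_axis("genotype").reset_index()
        out.insert(0, "env", self.env)
        out.insert(1, "trait", self.trait)
        return out


def _env_subset(records: pd.DataFrame, env: str, trait: str,
                genotype_col: str) -> pd.DataFrame:
    sub = records.loc[records["env"] == env, [genotype_col, *DESIGN_COLS, trait]]
    sub = sub.dropna(subset=[trait])
    if sub.empty:
        raise ValueError(f"no records with trait {trait!r} in environment {env!r}")
    if sub[genotype_col].nunique() < 2:
        raise ValueError(f"need >= 2 genotypes with data in environment {env!r}")
    return sub


def _design_Z(sub: pd.DataFrame) -> dict:
    Zs = {}
    for col in DESIGN_COLS:
        if sub[col].nunique() > 1:
            Zs[col], _ = design_matrix(sub[col])
        else:
            logger.warning("design factor %r constant; dropped from model", col)
    return Zs


def fit_env_varcomp(records: pd.DataFrame, env: str, trait: str,
                    genotype_col: str = "hybrid",
                    max_iter: int = 500) -> MixedModelFit:
    """REML variance components with genotype and design factors all random."""
    sub = _env_subset(records, env, trait, genotype_col)
    y = sub[trait].to_numpy(dtype=float)
    X = np.ones((len(sub), 1))
    Z = {"g": design_matrix(sub[genotype_col])[0], **_design_Z(sub)}
    return emreml(y, X, Z, max_iter=max_iter)


def fit_env_blues(records: pd.DataFrame, env: str, trait: str,
                  genotype_col: str = "hybrid",
                  max_iter: int = 500) -> EnvFitResult:
    """Genotype BLUEs and quality statistics for one environment and trait.

    Sum-to-zero genotype coding makes the intercept the environment mean, so
    the reported BLUE of genotype i is ``intercept + effect_i``.  In an
    unreplicated layout without duplicated entries, genotypic and residual
    variance are confounded; repeatability is then reported as NaN and the
    result flagged non-identifiable.
    """
    sub = _env_subset(records, env, trait, genotype_col)
    y = sub[trait].to_numpy(dtype=float)

    # all-random fit for variance components / repeatability
    vc_fit = emreml(y, np.ones((len(sub), 1)),
                    {"g": design_matrix(sub[genotype_col])[0], **_design_Z(sub)},
                    max_iter=max_iter)

    # fixed-genotype solve at the REML variance components
    cat = pd.Categorical(sub[genotype_col])
    levels = list(cat.categories)
    G = len(levels)
    codes = cat.codes
    X = np.zeros((len(sub), G))  # sum-to-zero: last level = -(others)
    X[:, 0] = 1.0
    for i, c in enumerate(codes):
        if c < G - 1:
            X[i, c + 1] = 1.0
        else:
            X[i, 1:] = -1.0
    Zs = _design_Z(sub)
    pinned = {name: vc_fit.varcomp[name] for name in Zs}
    pinned["e"] = vc_fit.varcomp["e"]
    blue_fit = emreml(y, X, Zs, fixed_varcomp=pinned)

    mu = blue_fit.beta[0]
    effects = np.concatenate([blue_fit.beta[1:], [-np.sum(blue_fit.beta[1:])]])
    blues = pd.Series(mu + effects, index=pd.Index(levels, name=genotype_col))

    # residual mean square of the fixed-genotype model
    fitted = X @ blue_fit.beta
    for name in Zs:
        fitted = fitted + Zs[name] @ blue_fit.u[name]
    rss = float(np.sum((y - fitted) ** 2))
    mse = rss / max(len(y) - blue_fit.rank_x, 1)

    counts = sub[genotype_col].value_counts()
    n_reps = float(counts.mean())
    identifiable = bool((counts > 1).any())
    s2g, s2e = vc_fit.varcomp["g"], vc_fit.varcomp["e"]
    R = repeatability(s2g, s2e, n_reps) if identifiable else float("nan")
    if not identifiable:
        logger.warning(
            "env %s: no genotype replicated; s2_g and s2_e not separable, "
            "repeatability undefined", env,
        )
    mean = float(np.mean(y))
    return EnvFitResult(
        env=env, trait=trait, blues=blues,
        varcomp={k: vc_fit.varcomp[k] for k in vc_fit.varcomp},
        mse=mse, mean=mean,
        repeatability=R, cve=cve(mse, mean),
        n_reps=n_reps, identifiable=identifiable,
        converged=vc_fit.converged and blue_fit.converged,
    )


def repeatability(s2g: float, s2e: float, r: float) -> float:
    """Entry-level repeatability R = s2_g / (s2_g + s2_e / r)."""
    if s2g < 0 or s2e < 0:
        raise ValueError("variances must be >= 0")
    if r < 1:
        raise ValueError("r must be >= 1")
    denom = s2g + s2e / r
    if denom == 0:
        return float("nan")
    return s2g / denom


def cve(mse: float, mean: float) -> float:
    """Residual coefficient of variation, percent: 100 * sqrt(MSE) / mean."""
    if mean <= 0:
        warnings.warn("trait mean <= 0; CVe undefined", stacklevel=2)
        return float("nan")
    return 100.0 * float(np.sqrt(mse)) / float(mean)


@dataclass
class GcaResult:
    trait: str
    check: str
    table: pd.DataFrame  # male, gca, diff_vs_check, se, t, p, higher_than_check
    varcomp: dict
    converged: bool

    @property
    def n_higher(self) -> int:
        return int(self.table["higher_than_check"].sum())


def fit_gca_multienv(
    records: pd.DataFrame,
    trait: str,
    check: str,
    alpha: float = 0.05,
    max_iter: int = 200,
) -> GcaResult:
    """Multi-environment GCA model with pollinator lines fixed.

    Fits ``Y = mu + Blk(Env) + Ra(Env) + Ro(Env) + Env + Mal + Fem + Mal.Fem
    + Mal.Env + Fem.Env + Mal.Fem.Env + e`` with the male (pollinator) effects
    fixed and everything else random.  Treatment coding with the check male as
    the reference makes each fixed coefficient the GLS contrast male - check,
    tested with a Student's t (residual df) at ``alpha``.
    """
    sub = records.dropna(subset=[trait]).copy()
    if sub["env"].nunique() < 2:
        raise ValueError("multi-environment model needs >= 2 environments")
    if check not in set(sub["male"]):
        raise ValueError(f"check male {check!r} has no data")
    y = sub[trait].to_numpy(dtype=float)
    n = len(sub)

    males = [check] + sorted(m for m in sub["male"].unique() if m != check)
    male_idx = {m: i for i, m in enumerate(males)}
    X = np.zeros((n, len(males)))
    X[:, 0] = 1.0
    for i, m in enumerate(sub["male"]):
        j = male_idx[m]
        if j > 0:
            X[i, j] = 1.0

    env = sub["env"].astype(str)
    fem = sub["female"].astype(str)
    mal = sub["male"].astype(str)
    combos = {
        "env": env,
        "fem": fem,
        "mal_fem": mal + ":" + fem,
        "mal_env": mal + ":" + env,
        "fem_env": fem + ":" + env,
        "mal_fem_env": mal + ":" + fem + ":" + env,
        "blk_env": env + ":" + sub["block"].astype(str),
        "ra_env": env + ":" + sub["range"].astype(str),
        "ro_env": env + ":" + sub["row"].astype(str),
    }
    Z = {}
    for name, labels in combos.items():
        if labels.nunique() > 1:
            Z[name], _ = design_matrix(labels)
        else:
            logger.warning("GCA model: factor %r has a single level; dropped", name)

    fit = emreml(y, X, Z, max_iter=max_iter)
    if not fit.converged:
        logger.warning("GCA REML hit the iteration cap; using last iterate")

    mu = fit.beta[0]
    diffs = np.concatenate([[0.0], fit.beta[1:]])
    ses = np.sqrt(np.maximum(np.diag(fit.beta_cov), 0.0))
    # SE of the contrast male - check is the SE of the treatment coefficient
    se_diff = np.concatenate([[np.nan], ses[1:]])
    df = max(fit.residual_df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diffs / se_diff
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    table = pd.DataFrame(
        {
            "male": males,
            "gca": mu + diffs,
            "diff_vs_check": diffs,
            "se": se_diff,
            "t": t,
            "p": pvals,
            "higher_than_check": (diffs > 0) & (pvals <= alpha),
        }
    )
    return GcaResult(trait=trait, check=check, table=table,
                     varcomp=fit.varcomp, converged=fit.converged)
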