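"""Family-representation cross-validation for BC1-NAM genomic prediction.

The CV0..CV7 ladder measures how much training-set representation of each
family is worth: the training set always contains every hybrid of the core
(fully phenotyped) families and of the check lines, plus ``k`` randomly
chosen lines from every remaining family (k = 0 for CV0, up to 7 for CV7).
All hybrids of a line move together, so no validation hybrid shares its male
line with any training observation.  Each scheme is repeated with fresh
random line draws and sampler seeds; scheme means are compared with Tukey's
honestly significant difference test and schemes statistically
indistinguishable from the best are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .gblup import GBLUPRegressor

logger = logging.getLogger(__name__)

__all__ = ["CVScheme", "build_scheme", "accuracy", "run_cv", "tukey_hsd"]


@dataclass(frozen=True)
class CVScheme:
    """A train/validation split of lines for one repeat of one scheme."""

    scheme_id: str
    k: int
    core_families: tuple
    check_lines: tuple
    training_lines: tuple
    validation_lines: tuple
    repeat: int
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.training_lines) & set(self.validation_lines)
        if overlap:
            raise ValueError(f"lines in both sets: {sorted(overlap)[:5]}")
        if not self.validation_lines:
            raise ValueError("validation set is empty")


def build_scheme(
    line_families: Mapping[str, str],
    k: int,
    seed: int,
    core_families: Sequence = (22, 48),
    check_lines: Sequence[str] = (),
    repeat: int = 0,
) -> CVScheme:
    """Build one CV-k split at the line level.

    ``line_families`` maps line id -> family id.  Non-core families with at
    most ``k`` lines contribute all of them to training (and none to
    validation).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    core = {str(f) for f in core_families}
    checks = tuple(str(c) for c in check_lines)
    rng = np.random.default_rng([int(seed), int(repeat), int(k)])
    fam_lines: dict[str, list[str]] = {}
    for line, fam in line_families.items():
        fam_lines.setdefault(str(fam), []).append(str(line))

    training: list[str] = list(checks)
    validation: list[str] = []
    for fam in sorted(fam_lines):
        lines = sorted(fam_lines[fam])
        if fam in core:
            training.extend(lines)
            continue
        if len(lines) <= k:
            if k > 0:
                logger.info(
                    "family %s has %d <= k=%d lines; all go to training",
                    fam, len(lines), k,
                )
            training.extend(lines)
            continue
        chosen = sorted(rng.choice(lines, size=k, replace=False)) if k else []
        training.extend(chosen)
        validation.extend(sorted(set(lines) - set(chosen)))
    return CVScheme(
        scheme_id=f"CV{k}", k=k,
        core_families=tuple(sorted(core)), check_lines=checks,
        training_lines=tuple(sorted(set(training))),
        validation_lines=tuple(sorted(validation)),
        repeat=repeat, seed=int(seed),
    )


def accuracy(pred: np.ndarray, obs: np.ndarray) -> float:
    """Prediction accuracy: Pearson r between predicted and observed values."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[ok], obs[ok]
    if len(pred) < 3:
        raise ValueError("accuracy needs >= 3 paired values")
    if np.std(pred) == 0 or np.std(obs) == 0:
        warnings.warn("zero variance in predictions or observations", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(pred, obs)[0])


def run_cv(
    obs: pd.DataFrame,
    K_A,
    line_families: Mapping[str, str],
    traits: Sequence[str],
    K_D=None,
    ks: Sequence[int] = (0, 1, 2, 3, 4, 5, 6, 7),
    repeats: int = 50,
    seed: int = 0,
    core_families: Sequence = (22, 48),
    check_lines: Sequence[str] = (),
    sampler: Mapping | None = None,
) -> pd.DataFrame:
    """Run the CV ladder and return the long accuracy table.

    ``obs`` holds one row per observation with columns ``hybrid``, ``env``,
    ``male`` and one column per trait (the per-environment hybrid values).
    Kernels are precomputed once on the union of all hybrids and sub-indexed
    per split.  Returns columns trait, scheme, k, repeat, r, n_val.
    """
    sampler = dict(sampler or {})
    missing = [t for t in traits if t not in obs.columns]
    if missing:
        raise KeyError(f"traits not in observation frame: {missing}")
    rows = []
    for k in ks:
        for rep in range(repeats):
            scheme = build_scheme(
                line_families, k, seed, core_families=core_families,
                check_lines=check_lines, repeat=rep,
            )
            train_set = set(scheme.training_lines)
            val_set = set(scheme.validation_lines)
            is_train = obs["male"].astype(str).isin(train_set)
            is_val = obs["male"].astype(str).isin(val_set)
            train, val = obs[is_train], obs[is_val]
            fit_seed = int(
                np.random.SeedSequence([int(seed), int(rep), int(k)]).generate_state(1)[0]
                % (2**31)
            )
            for trait in traits:
                tr = train.dropna(subset=[trait])
                va = val.dropna(subset=[trait])
                try:
                    model = GBLUPRegressor(
                        K_A=K_A, K_D=K_D, random_state=fit_seed, **sampler
                    ).fit(tr[["hybrid", "env"]], tr[trait].to_numpy())
                    pred = model.predict(va[["hybrid", "env"]])
                    r = accuracy(pred, va[trait].to_numpy())
                except Exception as exc:  # noqa: BLE001 - record and move on
                    logger.warning(
                        "CV%d repeat %d trait %s failed: %s", k, rep, trait, exc
                    )
                    r = float("nan")
                rows.append(
                    {
                        "trait": trait, "scheme": scheme.scheme_id, "k": k,
                        "repeat": rep, "r": r, "n_val": len(va),
                    }
                )
    return pd.DataFrame(rows)


def tukey_hsd(acc: pd.DataFrame, trait: str, alpha: float = 0.05) -> pd.DataFrame:
    """Compare CV schemes with Tukey's HSD (Tukey-Kramer for unequal ns).

    Returns one row per scheme with its mean accuracy and ``same_as_best``:
    whether the scheme is statistically indistinguishable from the
    highest-mean scheme at ``alpha``.
    """
    sub = acc.loc[(acc["trait"] == trait) & acc["r"].notna(), ["scheme", "r"]]
    if sub["scheme"].nunique() < 2:
        raise ValueError("need >= 2 schemes")
    if (sub.groupby("scheme").size() < 2).any():
        raise ValueError("need >= 2 repeats per scheme")
    res = pairwise_tukeyhsd(sub["r"].to_numpy(), sub["scheme"].to_numpy(),
                            alpha=alpha)
    pairs = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    means = sub.groupby("scheme")["r"].mean().sort_values(ascending=False)
    best = means.index[0]
    same = {best: True}
    for scheme in means.index[1:]:
        row = pairs[
            ((pairs["group1"] == best) & (pairs["group2"] == scheme))
            | ((pairs["group1"] == scheme) & (pairs["group2"] == best))
        ]
        same[scheme] = not bool(row["reject"].iloc[0])
    out = means.rename("mean_r").reset_index()
    out["same_as_best"] = out["scheme"].map(same)
    out["best"] = out["scheme"] == best
    return out
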