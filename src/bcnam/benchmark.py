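"""Study-structure constants and the packaged synthetic benchmark.

``STUDY_FAMILY_SIZES`` records the 18-family BC1-NAM hybrid evaluation
structure that the simulator emulates by default: families sharing the elite
recurrent parent R.Tx436, with between 2 and 73 tested lines per family
(287 lines in total), testcrossed to A-line seed-parent testers across Texas
environments.

``make_benchmark`` builds the smaller self-contained benchmark used for
cross-validation experiments: about ten families of a dozen lines each on a
10-chromosome, 1500-marker map, testcrossed to two testers and evaluated in
three replicated environments for one high- and one low-heritability trait,
with the full pipeline (QC, per-environment BLUEs, kernels) applied and the
generative truth retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genotypes, kernels, phenostats, simpop
from ._seeds import derive_seed

__all__ = [
    "STUDY_FAMILY_SIZES",
    "RECURRENT_PARENT",
    "STUDY_TESTERS",
    "study_family_table",
    "Benchmark",
    "make_benchmark",
]

# tested lines per BC1-NAM family (family id -> count); all share R.Tx436
STUDY_FAMILY_SIZES = {
    "2": 2, "12": 6, "21": 11, "22": 67, "23": 11, "24": 18, "26": 14,
    "27": 9, "29": 6, "30": 13, "31": 2, "32": 10, "33": 5, "34": 7,
    "42": 6, "44": 13, "45": 14, "48": 73,
}
RECURRENT_PARENT = "R.Tx436"
STUDY_TESTERS = ("A.Tx2928", "A.Tx3408", "A.Tx378", "A.03017", "A.05071", "A.08140")
STUDY_CHECKS = ("R.Tx436", "R.Tx437", "R.Tx2783")


def study_family_table() -> pd.DataFrame:
    """Family sizes of the emulated study as a DataFrame."""
    return pd.DataFrame(
        {"family": list(STUDY_FAMILY_SIZES), "n_lines": list(STUDY_FAMILY_SIZES.values())}
    )


@dataclass
class Benchmark:
    """A fully simulated benchmark with known generative truth."""

    gmap: simpop.GenomeMap
    founders: simpop.FounderSet
    lines: list
    pedigree: pd.DataFrame
    hybrids: pd.DataFrame          # hybrid, male, female (includes checks)
    parent_codes: pd.DataFrame     # line/tester/check x marker -1/0/1
    hybrid_codes: pd.DataFrame     # hybrid x marker codes (may contain +-0.5)
    K_A: pd.DataFrame
    K_D: pd.DataFrame
    plots: pd.DataFrame            # long-format trial table
    truth: pd.DataFrame            # env x hybrid x trait genetic values
    blues: pd.DataFrame            # per-env hybrid BLUEs, wide by trait
    line_families: dict            # male line -> family
    check_lines: tuple
    core_families: tuple
    traits: tuple                  # TraitSpec tuple


DEFAULT_TRAITS = (
    # high-heritability trait (anthesis/height-like): strong additive signal
    # from ~60 family-private introgressed QTL
    simpop.TraitSpec("trait_high_h2", var_a=1.0, var_d=0.1, var_ae=0.2,
                     var_de=0.05, var_e=0.4, env_means={}, n_qtl=60,
                     family_var_share=0.7),
    # low-heritability trait (grain-yield-like): more GxE and residual noise
    simpop.TraitSpec("trait_low_h2", var_a=0.3, var_d=0.15, var_ae=0.4,
                     var_de=0.1, var_e=1.5, env_means={}, n_qtl=60,
                     family_var_share=0.2),
)


def make_benchmark(
    seed: int = 0,
    n_families: int = 10,
    lines_per_family: int = 12,
    n_chrom: int = 10,
    markers_per_chrom: int = 150,
    n_envs: int = 3,
    n_testers: int = 2,
    donor_divergence: float = 0.12,
    private_fraction: float = 0.8,
    selfing_generations: int = 3,
    n_bc1_plants: int | None = 2,
    traits: tuple = DEFAULT_TRAITS,
    compute_blues: bool = True,
) -> Benchmark:
    """Simulate the packaged benchmark population, trial, and kernels.

    Environment means are staggered (10, 11, 12, ...) so environment effects
    are non-trivial; trials are RCBD with two replications.  The first two
    families are designated the fully phenotyped core for CV experiments, and
    the recurrent parent itself is testcrossed as a check male.
    """
    gmap = simpop.make_genetic_map(n_chrom, markers_per_chrom, 150.0)
    donor_ids = [f"D{i + 1:02d}" for i in range(n_families)]
    founders = simpop.make_founders(
        gmap, {d: donor_divergence for d in donor_ids},
        seed=derive_seed(seed, "founders"),
        private_fraction=private_fraction,
    )
    families = [
        simpop.FamilySpec(family_id=f"F{i + 1:02d}", donor_id=d,
                          n_lines=lines_per_family)
        for i, d in enumerate(donor_ids)
    ]
    lines, pedigree = simpop.simulate_population(
        gmap, founders, families, selfing_generations=selfing_generations,
        seed=derive_seed(seed, "population"), n_bc1_plants=n_bc1_plants,
    )

    # genotype codes for lines, checks (recurrent parent) and testers
    line_codes = simpop.lines_to_codes(lines, gmap)
    rng = np.random.default_rng(derive_seed(seed, "testers"))
    tester_ids = [f"A{i + 1:02d}" for i in range(n_testers)]
    tester_codes = {}
    for t in tester_ids:
        # testers are elite inbreds moderately diverged from the recurrent pool
        flip = rng.random(gmap.n_markers) < 0.15
        tester_codes[t] = np.where(flip, -1, 1).astype(np.int8)
    check_id = founders.recurrent.line_id  # "REC"
    parent_codes = pd.concat(
        [
            line_codes,
            pd.DataFrame([np.ones(gmap.n_markers, dtype=np.int8)],
                         index=[check_id], columns=gmap.marker_ids),
            pd.DataFrame(tester_codes, index=gmap.marker_ids).T,
        ]
    )

    # testcrosses: each line to one tester (alternating); checks to all testers
    male_ids = [ln.line_id for ln in lines]
    assignment = {m: [tester_ids[i % n_testers]] for i, m in enumerate(male_ids)}
    assignment[check_id] = list(tester_ids)
    hybrids = simpop.make_testcross_hybrids(
        male_ids + [check_id], tester_ids, assignment
    )
    fam_of = dict(zip(pedigree["line"], pedigree["family"]))
    hybrids["family"] = hybrids["male"].map(fam_of)  # NaN for check males
    mm = genotypes.MarkerMatrix(
        parent_codes.astype(float),
        pd.DataFrame(
            {
                "chrom": gmap.markers["chrom"],
                "pos": gmap.markers["pos_cM"],
                "is_indel": False,
            }
        ),
    )
    hybrid_codes = genotypes.make_hybrid_matrix(mm, hybrids)

    envs = tuple(
        simpop.EnvDesign(env_id=f"E{j + 1}", design="rcbd-r2", n_blocks=2,
                         n_rows=12)
        for j in range(n_envs)
    )
    traits = tuple(
        simpop.TraitSpec(
            t.name, t.var_a, t.var_d, t.var_ae, t.var_de, t.var_e,
            env_means={f"E{j + 1}": 10.0 + j for j in range(n_envs)},
            n_qtl=t.n_qtl, family_var_share=t.family_var_share,
        )
        for t in traits
    )
    spec = simpop.TrialSpec(environments=envs, traits=traits,
                            design_variances=(0.05, 0.02, 0.02))
    plots, truth = simpop.simulate_trial(
        hybrids, hybrid_codes, spec, seed=derive_seed(seed, "trial")
    )

    K_A = pd.DataFrame(kernels.additive_kernel(hybrid_codes.to_numpy(dtype=float)),
                       index=hybrid_codes.index, columns=hybrid_codes.index)
    K_D = pd.DataFrame(kernels.dominance_kernel(hybrid_codes.to_numpy(dtype=float)),
                       index=hybrid_codes.index, columns=hybrid_codes.index)

    blues = pd.DataFrame()
    if compute_blues:
        frames = []
        for env in (e.env_id for e in envs):
            per_env = None
            for t in traits:
                res = phenostats.fit_env_blues(plots, env, t.name)
                f = res.blues.rename(t.name)
                per_env = f.to_frame() if per_env is None else per_env.join(f)
            per_env = per_env.rename_axis("hybrid").reset_index()
            per_env.insert(0, "env", env)
            frames.append(per_env)
        blues = pd.concat(frames, ignore_index=True)
        blues = blues.merge(hybrids[["hybrid", "male", "female"]], on="hybrid")

    line_families = dict(zip(pedigree["line"], pedigree["family"]))
    return Benchmark(
        gmap=gmap, founders=founders, lines=lines, pedigree=pedigree,
        hybrids=hybrids, parent_codes=parent_codes.astype(float),
        hybrid_codes=hybrid_codes, K_A=K_A, K_D=K_D,
        plots=plots, truth=truth, blues=blues, line_families=line_families,
        check_lines=(check_id,),
        core_families=("F01", "F02"),
        traits=traits,
    )
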