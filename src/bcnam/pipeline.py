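"""Configured, logged, resumable orchestration of the analysis pipeline.

Stages run in dependency order: ``simulate`` (synthetic population + trial)
-> ``qc`` (marker filtering and imputation) -> ``blues`` (per-environment
hybrid BLUEs) -> ``kernels`` (additive/dominance relationship matrices) ->
``crossval`` (the CV-ladder accuracy experiment).  A manifest records the
config hash, per-stage outputs with SHA-256 digests, and wall times; a rerun
with the same config skips stages whose outputs already exist with matching
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmark, crossval, genotypes, io, kernels, phenostats, simpop
from ._seeds import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

STAGES = ("simulate", "qc", "blues", "kernels", "crossval")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the published analysis
    settings (10,000 sampler iterations, 1,000 burn-in, thin 2, 50 repeats).
    """

    out_dir: str = "bcnam_run"
    seed: int = 0
    stages: tuple = STAGES
    simulate: dict = field(default_factory=dict)   # make_benchmark kwargs
    sampler: dict = field(default_factory=lambda: {
        "n_iter": 10_000, "burn_in": 1_000, "thin": 2,
    })
    crossval: dict = field(default_factory=lambda: {
        "ks": [0, 1, 2, 3, 4, 5, 6, 7], "repeats": 50,
    })

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not set(cfg.stages) <= set(STAGES):
            raise ValueError(f"stages must be among {STAGES}")
        return cfg

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": int(self.seed),
            "stages": list(self.stages),
            "simulate": dict(self.simulate),
            "sampler": dict(self.sampler),
            "crossval": dict(self.crossval),
        }

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(manifest_prev: dict, stage: str, cfg_hash: str, out: Path) -> bool:
    rec = (manifest_prev or {}).get("stages", {}).get(stage)
    if not rec or manifest_prev.get("config_hash") != cfg_hash:
        return False
    for fname, digest in rec.get("outputs", {}).items():
        p = out / fname
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = out / "manifest.json"
    manifest_prev = {}
    if manifest_path.exists():
        manifest_prev = json.loads(manifest_path.read_text())
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "stages": {},
    }
    logger.info("pipeline seed=%s config_hash=%s", config.seed, cfg_hash)

    bench = None

    def _get_bench():
        nonlocal bench
        if bench is None:
            bench = benchmark.make_benchmark(
                seed=derive_seed(config.seed, "simulate"),
                compute_blues=False, **config.simulate,
            )
        return bench

    def _record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(time.time() - t0, 3),
        }

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        if _stage_done(manifest_prev, stage, cfg_hash, out):
            logger.info("stage %s: outputs up to date, skipped", stage)
            manifest["stages"][stage] = manifest_prev["stages"][stage]
            continue

        if stage == "simulate":
            b = _get_bench()
            io.write_codes_csv(
                simpop.lines_to_codes(b.lines, b.gmap), out / "line_codes.csv"
            )
            calls = simpop.lines_to_calls(b.lines, b.gmap)
            meta = pd.DataFrame(
                {"chrom": b.gmap.markers["chrom"], "pos": b.gmap.markers["pos_cM"],
                 "major_allele": "A"}
            )
            io.write_vcf(calls, meta, out / "lines.vcf")
            b.pedigree.to_csv(out / "pedigree.csv", index=False)
            io.write_codes_csv(b.parent_codes, out / "parent_codes.csv")
            b.hybrids.to_csv(out / "hybrids.csv", index=False)
            io.write_codes_csv(b.hybrid_codes, out / "hybrid_codes.csv")
            b.plots.to_csv(out / "trial.csv", index=False)
            b.truth.to_csv(out / "truth.csv", index=False)
            _record(stage, [out / f for f in (
                "line_codes.csv", "lines.vcf", "pedigree.csv", "hybrids.csv",
                "parent_codes.csv", "hybrid_codes.csv", "trial.csv",
                "truth.csv")], t0)

        elif stage == "qc":
            calls, meta = io.read_vcf_calls(out / "lines.vcf")
            mm = genotypes.encode_numeric(calls, meta)
            parents = list(calls.index)  # inbred lines are their own parents here
            filtered, report = genotypes.filter_markers(mm, parents)
            filtered = genotypes.impute_simple(filtered)
            io.write_codes_csv(filtered.values, out / "filtered_codes.csv")
            (out / "filter_report.json").write_text(
                json.dumps(report.to_dict(), indent=2)
            )
            # diversity view of the genotyped material
            dist = genotypes.nei_distance(filtered)
            dist.to_csv(out / "nei_distance.csv")
            coords, shares = genotypes.pcoa(dist, k=2)
            coords.to_csv(out / "pcoa_coordinates.csv")
            _record(stage, [out / "filtered_codes.csv",
                            out / "filter_report.json",
                            out / "nei_distance.csv",
                            out / "pcoa_coordinates.csv"], t0)

        elif stage == "blues":
            plots = pd.read_csv(out / "trial.csv")
            trait_cols = [c for c in plots.columns if c.startswith("trait")]
            frames = []
            env_stats: dict = {"cve_convention": "100*sqrt(MSE)/mean"}
            for env in sorted(plots["env"].unique()):
                per_env = None
                for t in trait_cols:
                    res = phenostats.fit_env_blues(plots, env, t)
                    f = res.blues.rename(t)
                    per_env = f.to_frame() if per_env is None else per_env.join(f)
                    env_stats[f"{env}:{t}"] = {
                        "varcomp": {k: float(v) for k, v in res.varcomp.items()},
                        "repeatability": float(res.repeatability),
                        "cve": float(res.cve),
                        "mse": float(res.mse),
                        "mean": float(res.mean),
                        "converged": bool(res.converged),
                    }
                per_env = per_env.rename_axis("hybrid").reset_index()
                per_env.insert(0, "env", env)
                frames.append(per_env)
            blues = pd.concat(frames, ignore_index=True)
            hyb = pd.read_csv(out / "hybrids.csv")
            blues = blues.merge(hyb[["hybrid", "male", "female"]], on="hybrid")
            blues.to_csv(out / "blues.csv", index=False)
            (out / "env_stats.json").write_text(json.dumps(env_stats, indent=2))
            outputs = [out / "blues.csv", out / "env_stats.json"]
            # multi-environment GCA against the first non-population male
            ped = pd.read_csv(out / "pedigree.csv")
            checks = sorted(set(plots["male"]) - set(ped["line"]))
            if checks and plots["env"].nunique() > 1:
                gca_frames = []
                for t in trait_cols:
                    res = phenostats.fit_gca_multienv(plots, t, checks[0])
                    tab = res.table.copy()
                    tab.insert(0, "trait", t)
                    gca_frames.append(tab)
                pd.concat(gca_frames, ignore_index=True).to_csv(
                    out / "gca.csv", index=False
                )
                outputs.append(out / "gca.csv")
            _record(stage, outputs, t0)

        elif stage == "kernels":
            codes = io.read_codes_csv(out / "hybrid_codes.csv")
            K_A = pd.DataFrame(kernels.additive_kernel(codes.to_numpy(float)),
                               index=codes.index, columns=codes.index)
            K_D = pd.DataFrame(kernels.dominance_kernel(codes.to_numpy(float)),
                               index=codes.index, columns=codes.index)
            K_A.to_csv(out / "K_A.csv")
            K_D.to_csv(out / "K_D.csv")
            _record(stage, [out / "K_A.csv", out / "K_D.csv"], t0)

        elif stage == "crossval":
            blues = pd.read_csv(out / "blues.csv")
            K_A = pd.read_csv(out / "K_A.csv", index_col=0)
            K_D = pd.read_csv(out / "K_D.csv", index_col=0)
            ped = pd.read_csv(out / "pedigree.csv")
            line_families = dict(zip(ped["line"], ped["family"]))
            trait_cols = [c for c in blues.columns if c.startswith("trait")]
            cv_cfg = dict(config.crossval)
            ks = cv_cfg.pop("ks", [0, 1, 2, 3, 4, 5, 6, 7])
            repeats = cv_cfg.pop("repeats", 50)
            core = cv_cfg.pop("core_families", None)
            if core is None:
                fams = sorted(set(line_families.values()))
                core = fams[:2]
            checks = sorted(set(blues["male"]) - set(line_families))
            acc = crossval.run_cv(
                blues, K_A, line_families, trait_cols, K_D=K_D, ks=ks,
                repeats=repeats, seed=derive_seed(config.seed, "crossval"),
                core_families=core, check_lines=checks,
                sampler=config.sampler, **cv_cfg,
            )
            acc.to_csv(out / "accuracy.csv", index=False)
            summaries = []
            for t in trait_cols:
                s = crossval.tukey_hsd(acc, t)
                s.insert(0, "trait", t)
                summaries.append(s)
            pd.concat(summaries, ignore_index=True).to_csv(
                out / "accuracy_summary.csv", index=False
            )
            _record(stage, [out / "accuracy.csv",
                            out / "accuracy_summary.csv"], t0)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_inputs(genotypes_csv, phenotypes_csv, pedigree_csv) -> dict:
    """Cross-consistency checks on pipeline input files.

    Returns ``{"errors": [...], "warnings": [...]}``; errors are violations
    that make the pipeline unrunnable (unknown parents, bad genotype codes).
    """
    errors: list[str] = []
    warnings_: list[str] = []
    codes = io.read_codes_csv(genotypes_csv)
    pheno = pd.read_csv(phenotypes_csv)
    ped = pd.read_csv(pedigree_csv)

    arr = codes.to_numpy(dtype=float)
    bad = ~(np.isnan(arr) | np.isin(arr, (-1.0, -0.5, 0.0, 0.5, 1.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        errors.append(
            f"genotype coding-domain violation at line {codes.index[i]!r}, "
            f"marker {codes.columns[j]!r}: {arr[i, j]!r}"
        )
    genotyped = set(codes.index.astype(str))
    for col in ("male", "female"):
        if col in pheno.columns:
            unknown = sorted(set(pheno[col].astype(str)) - genotyped)
            for uid in unknown:
                errors.append(f"phenotype references ungenotyped {col} {uid!r}")
    if {"line", "family"} <= set(ped.columns):
        orphan = ped.loc[ped["family"].isna(), "line"].tolist()
        for line in orphan:
            errors.append(f"line {line!r} has no family in the pedigree")
    plot_keys = [c for c in ("env", "block", "range", "row") if c in pheno.columns]
    if plot_keys:
        dup = pheno.duplicated(subset=plot_keys, keep=False)
        grid_dup = pheno[dup]
        if len(grid_dup):
            warnings_.append(
                f"{int(dup.sum())} plot records share a field position "
                f"({', '.join(plot_keys)})"
            )
    return {"errors": errors, "warnings": warnings_}
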