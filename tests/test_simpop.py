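"""Population and trial simulator: Mendelian expectations, selection,
selfing, and trial generation."""

import numpy as np
import pandas as pd
import pytest

from bcnam import simpop


class TestGeneticMap:
    def test_minimal_map(self):
        gm = simpop.make_genetic_map(1, 1, 100.0, seed=7)
        assert gm.n_markers == 1
        assert len(gm.chromosomes) == 1

    def test_marker_counts_and_bounds(self):
        gm = simpop.make_genetic_map(10, 100, 150.0, seed=1)
        assert gm.n_markers == 1000
        assert (gm.markers.groupby("chrom").size() == 100).all()
        assert (gm.markers["pos_cM"] <= 150.0).all()
        assert (gm.markers["pos_cM"] >= 0.0).all()

    def test_seeded_determinism(self):
        a = simpop.make_genetic_map(2, 5, 50.0, seed=3, random_positions=True)
        b = simpop.make_genetic_map(2, 5, 50.0, seed=3, random_positions=True)
        pd.testing.assert_frame_equal(a.markers, b.markers)

    @pytest.mark.parametrize("bad", [(0, 5, 50.0), (2, 0, 50.0), (2, 5, 0.0)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            simpop.make_genetic_map(*bad)


class TestFounders:
    def test_divergence_realized(self, small_map):
        fs = simpop.make_founders(small_map, {"D1": 0.3}, seed=5)
        assert abs(fs.divergence["D1"] - 0.3) < 0.05
        assert fs.recurrent.haplotype.sum() == 0  # homozygous reference

    def test_private_partition_disjoint(self):
        gm = simpop.make_genetic_map(5, 100, 100.0)
        fs = simpop.make_founders(
            gm, {f"D{i}": 0.1 for i in range(5)}, seed=2, private_fraction=1.0
        )
        haps = np.stack([d.haplotype for d in fs.donors])
        # fully private divergence: no marker flipped in two donors
        assert (haps.sum(axis=0) <= 1).all()


class TestBC1Family:
    def test_degenerate_cross_identical_donor(self, small_map):
        rec = simpop.make_founders(small_map, {"D": 0.0}, seed=1)
        lines = simpop.simulate_bc1_family(
            rec.recurrent, rec.donors[0], small_map, 5, seed=2
        )
        for ln in lines:
            assert (ln.states == 0).all()
            # origins still track the donor genome even if states coincide
            assert 0.0 <= ln.ibd_fraction <= 1.0

    def test_bc1_expectation_three_quarters(self):
        # Mendelian oracle: at a single marker the BC1 plant transmits the
        # recurrent allele with probability 3/4 (enumerate the four gamete
        # combinations of F1 x recurrent), and selfing leaves the expected
        # dosage unchanged.
        gm = simpop.make_genetic_map(20, 50, 100.0)
        fs = simpop.make_founders(gm, {"D1": 1.0}, seed=4)
        lines = simpop.simulate_bc1_family(
            fs.recurrent, fs.donors[0], gm, 500, selfing_generations=0, seed=9
        )
        ibd = np.array([ln.ibd_fraction for ln in lines])
        assert abs(ibd.mean() - 0.75) < 3 * ibd.std() / np.sqrt(len(ibd))
        assert abs(ibd.mean() - 0.75) < 0.01

    def test_selection_increases_recurrent_fraction(self):
        gm = simpop.make_genetic_map(10, 100, 150.0)
        fs = simpop.make_founders(gm, {"D1": 1.0}, seed=4)
        loci = [f"chr{c}_m50" for c in (1, 3, 5, 7)]
        unsel = simpop.simulate_bc1_family(
            fs.recurrent, fs.donors[0], gm, 300, selfing_generations=3, seed=42
        )
        sel = simpop.simulate_bc1_family(
            fs.recurrent, fs.donors[0], gm, 300, selfing_generations=3,
            selection_loci=loci, seed=42,
        )
        m_un = np.mean([ln.ibd_fraction for ln in unsel])
        m_sel = np.mean([ln.ibd_fraction for ln in sel])
        assert m_sel >= 0.75
        assert m_sel > m_un

    def test_selfing_halves_heterozygosity(self):
        gm = simpop.make_genetic_map(10, 50, 100.0)
        fs = simpop.make_founders(gm, {"D1": 1.0}, seed=4)
        het = {}
        for g in (0, 3):
            lines = simpop.simulate_bc1_family(
                fs.recurrent, fs.donors[0], gm, 400, selfing_generations=g, seed=8
            )
            het[g] = np.mean([ln.heterozygosity for ln in lines])
        # BC1F1 heterozygosity ~0.5; each selfing generation halves it
        assert het[0] == pytest.approx(0.5, abs=0.03)
        assert het[3] == pytest.approx(het[0] / 8, rel=0.25)

    def test_seeded_determinism(self, small_map, founders):
        a = simpop.simulate_bc1_family(
            founders.recurrent, founders.donors[0], small_map, 4, seed=5
        )
        b = simpop.simulate_bc1_family(
            founders.recurrent, founders.donors[0], small_map, 4, seed=5
        )
        for x, y in zip(a, b):
            assert (x.origins == y.origins).all()
            assert (x.states == y.states).all()

    def test_shared_bc1_plant_raises_sib_sharing(self, small_map, founders):
        kw = dict(selfing_generations=2, seed=6)
        solo = simpop.simulate_bc1_family(
            founders.recurrent, founders.donors[0], small_map, 30,
            n_bc1_plants=1, **kw,
        )
        indep = simpop.simulate_bc1_family(
            founders.recurrent, founders.donors[0], small_map, 30, **kw
        )

        def sib_ibs(lines):
            # mean pairwise concordance of donor dosage: a family from one
            # BC1 plant shares its fixed recurrent regions, so sibs agree at
            # far more markers than independently derived lines do
            dos = np.stack([(ln.origins == 1).sum(axis=0) for ln in lines])
            n = len(dos)
            sims = [
                (dos[i] == dos[j]).mean()
                for i in range(n) for j in range(i + 1, n)
            ]
            return float(np.mean(sims))

        assert sib_ibs(solo) > sib_ibs(indep)


class TestTestcross:
    def test_full_factorial(self):
        hyb = simpop.make_testcross_hybrids(["a", "b", "c"], ["T1", "T2"])
        assert len(hyb) == 6

    def test_assignment_subset(self):
        hyb = simpop.make_testcross_hybrids(
            ["a", "b"], ["T1", "T2"], {"a": ["T1"], "b": ["T2"]}
        )
        assert len(hyb) == 2

    def test_duplicates_collapse(self):
        hyb = simpop.make_testcross_hybrids(
            ["a"], ["T1"], {"a": ["T1", "T1"]}
        )
        assert len(hyb) == 1

    def test_unknown_ids_raise(self):
        with pytest.raises(KeyError):
            simpop.make_testcross_hybrids(["a"], ["T1"], {"zz": ["T1"]})
        with pytest.raises(KeyError):
            simpop.make_testcross_hybrids(["a"], ["T1"], {"a": ["T9"]})


def _toy_hybrids(n=12, markers=40, seed=0):
    rng = np.random.default_rng(seed)
    codes = pd.DataFrame(
        rng.choice([-1.0, 0.0, 1.0], size=(n, markers), p=[0.25, 0.2, 0.55]),
        index=[f"h{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(markers)],
    )
    hyb = pd.DataFrame(
        {"hybrid": codes.index, "male": [f"L{i}" for i in range(n)], "female": "T1"}
    )
    return hyb, codes


class TestSimulateTrial:
    def test_all_variances_zero_gives_env_means(self):
        hyb, codes = _toy_hybrids()
        spec = simpop.TrialSpec(
            environments=(simpop.EnvDesign("E1", "rcbd-r2", 2, 4),),
            traits=(simpop.TraitSpec("t", 0.0, var_e=0.0, env_means=5.0),),
        )
        plots, truth = simpop.simulate_trial(hyb, codes, spec, seed=1)
        assert np.allclose(plots["t"], 5.0)
        assert np.allclose(truth["genetic_value"], 0.0)

    def test_noiseless_replicates_identical(self):
        hyb, codes = _toy_hybrids()
        spec = simpop.TrialSpec(
            environments=(simpop.EnvDesign("E1", "rcbd-r2", 2, 4),),
            traits=(simpop.TraitSpec("t", 1.0, var_e=0.0),),
        )
        plots, truth = simpop.simulate_trial(hyb, codes, spec, seed=2)
        spread = plots.groupby("hybrid")["t"].agg(lambda v: v.max() - v.min())
        assert np.allclose(spread, 0.0)
        # truth-table consistency: plot value = env mean (0) + genetic value
        merged = plots.merge(
            truth[truth["trait"] == "t"], on=["env", "hybrid"]
        )
        assert np.allclose(merged["t"], merged["genetic_value"])

    def test_additive_variance_scale(self):
        hyb, codes = _toy_hybrids(n=200, markers=300, seed=3)
        spec = simpop.TrialSpec(
            environments=tuple(
                simpop.EnvDesign(f"E{j}", "rcbd-r2", 2, 10) for j in range(3)
            ),
            traits=(simpop.TraitSpec("t", 1.0, var_e=0.0),),
        )
        from bcnam.kernels import additive_kernel

        _, truth = simpop.simulate_trial(hyb, codes, spec, seed=4)
        K = additive_kernel(codes.to_numpy(float))
        target = np.diag(K).mean()
        g = truth[truth["env"] == "E0"]["genetic_value"].to_numpy()
        assert abs(np.var(g) - target) < 0.25 * target

    def test_seeded_determinism(self):
        hyb, codes = _toy_hybrids()
        spec = simpop.TrialSpec(
            environments=(simpop.EnvDesign("E1", "augmented-unreplicated", 2, 4),),
            traits=(simpop.TraitSpec("t", 1.0, var_e=1.0),),
            design_variances=(0.1, 0.1, 0.1),
        )
        p1, t1 = simpop.simulate_trial(hyb, codes, spec, seed=9)
        p2, t2 = simpop.simulate_trial(hyb, codes, spec, seed=9)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_every_hybrid_has_a_plot(self):
        hyb, codes = _toy_hybrids()
        spec = simpop.TrialSpec(
            environments=(simpop.EnvDesign("E1", "augmented-unreplicated", 3, 4),),
            traits=(simpop.TraitSpec("t", 0.5, var_e=1.0),),
        )
        plots, _ = simpop.simulate_trial(hyb, codes, spec, seed=5)
        assert set(plots["hybrid"]) == set(hyb["hybrid"])
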