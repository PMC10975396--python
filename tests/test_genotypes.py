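"""Marker coding, QC filters, hybrids, Nei distance and PCoA."""

import numpy as np
import pandas as pd
import pytest

from bcnam import genotypes
from bcnam.genotypes import (
    encode_numeric, filter_markers, hybrid_genotype, impute_simple,
    nei_distance, pcoa,
)

from conftest import marker_matrix


class TestEncodeNumeric:
    def test_major_minor_coding(self):
        calls = pd.DataFrame({"m1": ["AA", "AA", "AT", "TT"]},
                             index=list("abcd"))
        m = encode_numeric(calls)
        assert m.values["m1"].tolist() == [1.0, 1.0, 0.0, -1.0]
        assert m.meta.loc["m1", "major_allele"] == "A"

    def test_monomorphic_all_major(self):
        calls = pd.DataFrame({"m1": ["GG", "GG", "GG"]}, index=list("abc"))
        m = encode_numeric(calls)
        assert (m.values["m1"] == 1.0).all()

    def test_tie_break_lexicographic_and_freq_consistency(self):
        # 50/50 tie: C vs T -> C is major
        calls = pd.DataFrame({"m1": ["CC", "TT", "CT", "TC"]}, index=list("abcd"))
        m = encode_numeric(calls)
        assert m.meta.loc["m1", "major_allele"] == "C"
        # frequency recomputed from codes matches raw-call frequency of C
        raw_freq = (2 + 0 + 1 + 1) / 8
        assert m.major_allele_freq()["m1"] == pytest.approx(raw_freq)

    def test_multiallelic_flagged(self):
        calls = pd.DataFrame({"m1": ["AA", "CG", "TT"]}, index=list("abc"))
        m = encode_numeric(calls)
        assert bool(m.meta.loc["m1", "is_multiallelic"])
        assert m.values["m1"].isna().all()

    def test_missing_preserved(self):
        calls = pd.DataFrame({"m1": ["AA", np.nan, "AT"]}, index=list("abc"))
        m = encode_numeric(calls)
        assert m.values["m1"].isna().tolist() == [False, True, False]


class TestFilterMarkers:
    def _fixture(self):
        """Six markers: five failing exactly one rule each, one clean.

        Lines a, b are the designated parents.
        """
        nan = np.nan
        vals = {
            # called in 0/2 parents -> parental_calls
            "m_par": [nan, nan, 1, 1, 1, 1, 1, 1],
            # 5/8 missing (>50%) but called in a parent -> missingness
            "m_mis": [1, nan, nan, nan, nan, nan, 1, -1],
            # clean values, flagged indel -> indel
            "m_ind": [1, 1, -1, 1, 1, -1, 1, 1],
            # MAF = 0 -> maf
            "m_maf": [1, 1, 1, 1, 1, 1, 1, 1],
            # 5/8 hets -> heterozygosity
            "m_het": [0, 0, 0, 0, 0, 1, 1, -1],
            # clean
            "m_ok": [1, 1, -1, -1, 0, 1, 1, -1],
        }
        lines = list("abcdefgh")
        df = pd.DataFrame(vals, index=lines, dtype=float)
        meta = pd.DataFrame(
            {"chrom": ".", "pos": -1,
             "is_indel": [False, False, True, False, False, False]},
            index=df.columns,
        )
        return genotypes.MarkerMatrix(df, meta)

    def test_one_drop_per_rule(self):
        m = self._fixture()
        filtered, report = filter_markers(m, parents=["a", "b"])
        assert filtered.marker_ids.tolist() == ["m_ok"]
        assert report.retained == 1
        assert all(v == 1 for v in report.dropped.values())
        assert sum(report.dropped.values()) + report.retained == 6

    def test_clean_matrix_identity(self):
        m = marker_matrix([[1, -1, 0], [-1, 1, 1], [1, 1, -1], [-1, -1, 1]])
        filtered, report = filter_markers(m, parents=["L0", "L1"])
        assert report.retained == 3
        assert sum(report.dropped.values()) == 0

    def test_idempotent(self):
        m = self._fixture()
        once, _ = filter_markers(m, parents=["a", "b"])
        twice, rep2 = filter_markers(once, parents=["a", "b"])
        assert sum(rep2.dropped.values()) == 0
        assert twice.marker_ids.equals(once.marker_ids)

    def test_exactly_half_missing_retained(self):
        nan = np.nan
        m = marker_matrix(
            [[1], [1], [nan], [nan]],  # exactly 50% missing: strictly-more rule
        )
        filtered, report = filter_markers(
            m, parents=["L0", "L1"], min_maf=0.0
        )
        assert report.dropped["missingness"] == 0
        assert report.retained == 1

    def test_empty_parents_error(self):
        with pytest.raises(ValueError):
            filter_markers(self._fixture(), parents=[])


class TestImpute:
    def test_no_missing_unchanged(self):
        m = marker_matrix([[1, -1], [0, 1]])
        out = impute_simple(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_missing_becomes_major_homozygote(self):
        m = marker_matrix([[1, np.nan], [1, 1]])
        assert impute_simple(m).values.iloc[0, 1] == 1.0

    def test_all_missing_marker_warns(self):
        m = marker_matrix([[np.nan], [np.nan]])
        with pytest.warns(UserWarning):
            out = impute_simple(m)
        assert (out.values == 1.0).all().all()


class TestHybridGenotype:
    def test_identity(self):
        p = pd.Series([1.0, -1.0, 0.0])
        pd.testing.assert_series_equal(hybrid_genotype(p, p), p)

    def test_averaging_rule(self):
        p1 = pd.Series([1.0, 1.0, -1.0])
        p2 = pd.Series([-1.0, 1.0, -1.0])
        assert hybrid_genotype(p1, p2).tolist() == [0.0, 1.0, -1.0]

    def test_commutes(self):
        rng = np.random.default_rng(0)
        p1 = pd.Series(rng.choice([-1.0, 0.0, 1.0], 30))
        p2 = pd.Series(rng.choice([-1.0, 0.0, 1.0], 30))
        pd.testing.assert_series_equal(
            hybrid_genotype(p1, p2), hybrid_genotype(p2, p1)
        )

    def test_homozygous_parents_closed_coding(self):
        rng = np.random.default_rng(1)
        rows = rng.choice([-1.0, 1.0], size=(3, 20))
        out = set()
        for i in range(3):
            for j in range(3):
                out |= set(hybrid_genotype(pd.Series(rows[i]), pd.Series(rows[j])))
        assert out <= {-1.0, 0.0, 1.0}

    def test_mismatched_markers_error(self):
        p1 = pd.Series([1.0], index=["m1"])
        p2 = pd.Series([1.0], index=["m2"])
        with pytest.raises(ValueError):
            hybrid_genotype(p1, p2)


class TestNeiDistance:
    def test_identical_lines_zero(self):
        m = marker_matrix([[1, -1, 0], [1, -1, 0]])
        d = nei_distance(m)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_worked_two_marker_case(self):
        m = marker_matrix([[1, 1], [1, -1]])
        d = nei_distance(m)
        assert d.iloc[0, 1] == pytest.approx(np.log(2))

    def test_disjoint_profiles_capped(self):
        m = marker_matrix([[1, 1], [-1, -1]])
        d = nei_distance(m)
        assert d.iloc[0, 1] == pytest.approx(np.log(1e6))

    def test_symmetric_nonnegative_brute_force(self):
        rng = np.random.default_rng(2)
        m = marker_matrix(rng.choice([-1.0, 0.0, 1.0], size=(5, 40)))
        d = nei_distance(m).to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= 0).all()
        # brute-force oracle for one off-diagonal entry
        P = (m.values.to_numpy() + 1) / 2
        x, y = P[1], P[3]
        jxy = np.mean(x * y + (1 - x) * (1 - y))
        jx = np.mean(x**2 + (1 - x) ** 2)
        jy = np.mean(y**2 + (1 - y) ** 2)
        assert d[1, 3] == pytest.approx(-np.log(jxy / np.sqrt(jx * jy)))


class TestPcoa:
    def test_equilateral_triangle(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        coords, shares = pcoa(d, k=2)
        w = np.sum(coords.to_numpy() ** 2, axis=0)
        assert w[0] == pytest.approx(w[1], abs=1e-9)
        # recovered pairwise distances all equal
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(coords), 1.0, atol=1e-8)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        coords, shares = pcoa(pd.DataFrame(d), k=2)
        assert np.allclose(pdist(coords), pdist(pts), atol=1e-8)
        assert shares.sum() == pytest.approx(1.0, abs=1e-8)

    def test_duplicate_lines_identical_coordinates(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(size=(4, 3)), rng.normal(size=(1, 3))])
        pts[-1] = pts[0]
        from scipy.spatial.distance import pdist, squareform
        coords, _ = pcoa(pd.DataFrame(squareform(pdist(pts))), k=3)
        assert np.allclose(coords.iloc[0], coords.iloc[-1], atol=1e-8)

    def test_truncation_warning(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        with pytest.warns(UserWarning):
            coords, _ = pcoa(d, k=3)
        assert coords.shape[1] == 2

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        m = marker_matrix(rng.choice([-1.0, 0.0, 1.0], size=(6, 60)))
        d = nei_distance(m)
        coords, shares = pcoa(d, k=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        ref_xy = ref.samples.iloc[:, :2].to_numpy()
        ours = coords.to_numpy()
        for j in range(2):  # eigenvector sign is arbitrary
            assert np.allclose(np.abs(ours[:, j]), np.abs(ref_xy[:, j]), atol=1e-6)
        assert np.allclose(
            shares, ref.proportion_explained.iloc[:2].to_numpy(), atol=1e-6
        )


from hypothesis import given, settings
from hypothesis import strategies as st


class TestCodingProperties:
    """Property-based checks of the numeric coding contract."""

    @given(
        st.lists(
            st.sampled_from(["AA", "AT", "TT"]), min_size=2, max_size=12
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_coded_frequency_matches_raw_calls(self, column):
        calls = pd.DataFrame({"m1": column}, index=[f"L{i}" for i in range(len(column))])
        m = encode_numeric(calls)
        major = m.meta.loc["m1", "major_allele"]
        raw = "".join(column)
        raw_freq = raw.count(major) / len(raw)
        assert m.major_allele_freq()["m1"] == pytest.approx(raw_freq)
        assert raw_freq >= 0.5  # the major allele really is the majority

    @given(
        st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=3, max_size=20),
        st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=3, max_size=20),
    )
    @settings(deadline=None, max_examples=50)
    def test_hybrid_average_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        p1, p2 = pd.Series(a[:n]), pd.Series(b[:n])
        h = hybrid_genotype(p1, p2)
        pd.testing.assert_series_equal(h, hybrid_genotype(p2, p1))
        assert h.between(-1, 1).all()
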