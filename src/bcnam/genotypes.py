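"""Marker QC, numeric genotype coding, in-silico hybrids, Nei distance, PCoA.

Genotype calls are coded numerically per marker: 1 for the homozygous major
allele, 0 for heterozygotes, -1 for the homozygous minor allele, with the
major allele defined by frequency among the non-missing calls (ties broken
toward the lexicographically smaller allele).  QC mirrors a standard GBS
pipeline: markers must be scored in at least 25% of the parental lines, have
at most 50% missing calls overall, be SNPs (no indels), have minor allele
frequency >= 0.05 and heterozygosity <= 50%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "FilterReport",
    "encode_numeric",
    "filter_markers",
    "impute_simple",
    "hybrid_genotype",
    "make_hybrid_matrix",
    "nei_distance",
    "pcoa",
    "pca_genotypes",
]

MISSING_CALLS = {"", "NN", "./.", ".", "--", "N"}
NEI_CAP = float(np.log(1e6))  # cap for infinite Nei distance (disjoint profiles)

FILTER_RULES = ("parental_calls", "missingness", "indel", "maf", "heterozygosity")


@dataclass
class MarkerMatrix:
    """Numeric genotypes: lines x markers with values in {-1, 0, 1, NaN}.

    ``meta`` is indexed by marker id with columns ``chrom``, ``pos``,
    ``is_indel`` and ``major_allele``/``minor_allele`` when known.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.meta.index):
            raise ValueError("marker metadata must match value columns")
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise ValueError("genotype codes must be -1, 0, 1 or missing")

    @property
    def line_ids(self) -> pd.Index:
        return self.values.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def major_allele_freq(self, imputed: bool = False) -> pd.Series:
        """Frequency of the (encode-time) major allele per marker.

        With ``imputed`` the missing calls count as homozygous major, matching
        the post-imputation screen of the QC pipeline.
        """
        dos = (self.values + 1.0) / 2.0
        if imputed:
            dos = dos.fillna(1.0)
        return dos.mean(axis=0, skipna=True)

    def heterozygosity(self, imputed: bool = False) -> pd.Series:
        """Per-marker fraction of calls that are heterozygous (code 0)."""
        vals = self.values
        if imputed:
            vals = vals.fillna(1.0)
        het = (vals == 0).sum(axis=0)
        denom = vals.notna().sum(axis=0)
        return het / denom.replace(0, np.nan)

    def subset_markers(self, markers: Sequence[str]) -> "MarkerMatrix":
        return MarkerMatrix(self.values[list(markers)], self.meta.loc[list(markers)])


def _default_meta(markers: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": ".", "pos": -1, "is_indel": False}, index=markers
    )


def encode_numeric(calls: pd.DataFrame, meta: pd.DataFrame | None = None) -> MarkerMatrix:
    """Convert allele-call strings (``AA``, ``AT``, ...) to -1/0/1 codes.

    Per marker the more frequent allele among non-missing calls is "major";
    a 50/50 tie goes to the lexicographically smaller allele.  Markers with
    more than two alleles are flagged ``is_multiallelic`` in the metadata and
    their codes set missing.  Alleles longer than one base (or ``-``) flag the
    marker as an indel.
    """
    if meta is None:
        meta = _default_meta(calls.columns)
    meta = meta.reindex(calls.columns)
    if "is_indel" not in meta.columns:
        meta["is_indel"] = False
    meta["is_indel"] = meta["is_indel"].fillna(False).astype(bool)
    meta["is_multiallelic"] = False
    meta["major_allele"] = ""
    meta["minor_allele"] = ""

    coded = np.full(calls.shape, np.nan)
    for j, marker in enumerate(calls.columns):
        col = calls[marker]
        allele_counts: dict[str, int] = {}
        parsed = []
        for val in col:
            if not isinstance(val, str) or val in MISSING_CALLS:
                parsed.append(None)
                continue
            alleles = val.split("/") if "/" in val else [val[: len(val) // 2], val[len(val) // 2:]]
            parsed.append(tuple(alleles))
            for a in alleles:
                allele_counts[a] = allele_counts.get(a, 0) + 1
        if any(len(a) != 1 or a == "-" for a in allele_counts):
            meta.iloc[j, meta.columns.get_loc("is_indel")] = True
        if len(allele_counts) > 2:
            meta.iloc[j, meta.columns.get_loc("is_multiallelic")] = True
            logger.warning("marker %s has >2 alleles; flagged non-biallelic", marker)
            continue
        if not allele_counts:
            continue
        # major by count, ties toward lexicographically smaller allele
        major = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        minor = next((a for a in sorted(allele_counts) if a != major), major)
        meta.iloc[j, meta.columns.get_loc("major_allele")] = major
        meta.iloc[j, meta.columns.get_loc("minor_allele")] = minor
        for i, pair in enumerate(parsed):
            if pair is None:
                continue
            n_major = sum(a == major for a in pair)
            coded[i, j] = n_major - 1  # 2->1, 1->0, 0->-1
    values = pd.DataFrame(coded, index=calls.index, columns=calls.columns)
    return MarkerMatrix(values, meta)


@dataclass
class FilterReport:
    """Per-rule drop counts from :func:`filter_markers` (rules in order)."""

    input_markers: int
    dropped: dict
    retained: int

    def __post_init__(self) -> None:
        assert sum(self.dropped.values()) + self.retained == self.input_markers

    def to_dict(self) -> dict:
        return {
            "input_markers": self.input_markers,
            "dropped": dict(self.dropped),
            "retained": self.retained,
            "rule_order": list(FILTER_RULES),
        }


def filter_markers(
    m: MarkerMatrix,
    parents: Sequence[str],
    min_parent_call: float = 0.25,
    max_missing: float = 0.50,
    min_maf: float = 0.05,
    max_het: float = 0.50,
) -> tuple[MarkerMatrix, FilterReport]:
    """Apply the marker-retention rules in order; first failing rule attributed.

    Order: (1) called in < 25% of parental lines; (2) > 50% missing overall
    (strictly more than); (3) indel; (4) MAF < 0.05; (5) heterozygosity > 50%.
    MAF and heterozygosity are computed after simple imputation (missing ->
    homozygous major), matching a pipeline that imputes before the second
    screen.
    """
    parents = list(parents)
    if not parents:
        raise ValueError("parent set must be nonempty")
    missing_parents = [p for p in parents if p not in m.line_ids]
    if missing_parents:
        raise KeyError(f"unknown parental lines: {missing_parents}")

    vals = m.values
    parent_called = vals.loc[parents].notna().mean(axis=0)
    overall_missing = vals.isna().mean(axis=0)
    is_indel = m.meta["is_indel"].astype(bool)
    maf_imp = m.major_allele_freq(imputed=True).pipe(lambda p: np.minimum(p, 1 - p))
    het_imp = m.heterozygosity(imputed=True)

    dropped = {rule: 0 for rule in FILTER_RULES}
    keep = []
    for marker in m.marker_ids:
        if parent_called[marker] < min_parent_call:
            dropped["parental_calls"] += 1
        elif overall_missing[marker] > max_missing:
            dropped["missingness"] += 1
        elif bool(is_indel[marker]):
            dropped["indel"] += 1
        elif maf_imp[marker] < min_maf:
            dropped["maf"] += 1
        elif het_imp[marker] > max_het:
            dropped["heterozygosity"] += 1
        else:
            keep.append(marker)
    report = FilterReport(m.n_markers, dropped, len(keep))
    for rule, count in dropped.items():
        if count:
            logger.info("filter_markers: dropped %d markers by %s", count, rule)
    return m.subset_markers(keep), report


def impute_simple(m: MarkerMatrix) -> MarkerMatrix:
    """Replace missing codes by the major-allele homozygote (code 1).

    A deliberately naive fallback: adequate for near-inbred material where
    the major (recurrent-parent) homozygote dominates each marker.
    """
    vals = m.values
    all_missing = vals.isna().all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} marker(s) with no calls imputed to "
            "the major-allele homozygote everywhere",
            stacklevel=2,
        )
    return MarkerMatrix(vals.fillna(1.0), m.meta.copy())


def hybrid_genotype(p1: pd.Series, p2: pd.Series) -> pd.Series:
    """In-silico hybrid: elementwise mean of the two parental genotypes."""
    if not p1.index.equals(p2.index):
        raise ValueError("parental genotypes are on different marker sets")
    if p1.isna().any() or p2.isna().any():
        raise ValueError("parental genotypes contain missing values; impute first")
    return (p1 + p2) / 2.0


def make_hybrid_matrix(m: MarkerMatrix, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Hybrid genotype rows for every (male, female) pair in ``pedigree``.

    ``pedigree`` needs columns ``hybrid``, ``male``, ``female``; both parents
    must be rows of ``m`` with no missing values.
    """
    vals = m.values
    rows = {}
    for rec in pedigree.itertuples(index=False):
        if rec.male not in vals.index or rec.female not in vals.index:
            raise KeyError(f"parent of hybrid {rec.hybrid} not genotyped")
        rows[rec.hybrid] = hybrid_genotype(vals.loc[rec.male], vals.loc[rec.female])
    return pd.DataFrame.from_dict(rows, orient="index")[vals.columns]


def nei_distance(m: MarkerMatrix | pd.DataFrame) -> pd.DataFrame:
    """Nei's (1972) standard genetic distance between all pairs of lines.

    Per line and marker the two allele frequencies are the -1/0/1 code mapped
    to major-allele dosage/2, i.e. {0, 0.5, 1}.  With J_xy the mean over
    markers of the summed allele-frequency products,
    D = -ln( J_xy / sqrt(J_xx * J_yy) ).  Identical lines give 0; fully
    disjoint profiles give +inf, capped at ln(1e6) for downstream ordination.
    """
    vals = m.values if isinstance(m, MarkerMatrix) else m
    if vals.isna().any().any():
        raise ValueError("nei_distance requires a complete matrix; impute first")
    P = (vals.to_numpy(dtype=float) + 1.0) / 2.0
    n_mark = P.shape[1]
    J = (P @ P.T + (1.0 - P) @ (1.0 - P).T) / n_mark
    diag = np.diag(J)
    with np.errstate(divide="ignore"):
        D = -np.log(J / np.sqrt(np.outer(diag, diag)))
    D[np.isinf(D)] = NEI_CAP
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=vals.index, columns=vals.index)


def pcoa(d: pd.DataFrame | np.ndarray, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling (principal coordinates) of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and returns the top-``k``
    coordinates (eigenvectors scaled by sqrt(eigenvalue)) plus the explained
    variance share of each returned axis; negative eigenvalues are excluded
    from the variance total.  If fewer than ``k`` positive eigenvalues exist
    the result is truncated with a warning.
    """
    ids = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(d))
    D = np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = max(1e-12, 1e-10 * max(abs(w[0]), 1.0))
    n_pos = int(np.sum(w > tol))
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = v[:, :k] * np.sqrt(w[:k])
    shares = w[:k] / w[:n_pos].sum() if n_pos else np.zeros(0)
    cols = [f"PCo{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=ids, columns=cols), shares


def pca_genotypes(m: MarkerMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the numeric genotype matrix itself (alternative ordination).

    Whether a published ordination derives from PCoA of a distance matrix or
    PCA of the genotype codes is often ambiguous; :func:`pcoa` on
    :func:`nei_distance` is this package's default and this is the other
    route.  Returns line scores on ``k`` components and explained-variance
    ratios.
    """
    from sklearn.decomposition import PCA

    vals = m.values
    if vals.isna().any().any():
        raise ValueError("pca_genotypes requires a complete matrix; impute first")
    est = PCA(n_components=k)
    scores = est.fit_transform(vals.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=vals.index, columns=cols), est.explained_variance_ratio_
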