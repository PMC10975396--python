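"""Synthetic BC1-NAM populations, testcross hybrids, and hybrid trial phenotypes.

The simulator emulates the structure of an elite-by-exotic backcross nested
association mapping (BC1-NAM) resource: a set of families that share one elite
recurrent parent, each family derived from a single unadapted donor by one
backcross to the recurrent parent followed by several generations of selfing
(BC1F4 by default).  Lines are testcrossed to seed-parent testers and the
resulting hybrids are evaluated in multi-environment trials with additive,
dominance, genotype-by-environment and plot-level residual variation, so the
true genetic values behind every phenotype are known.

Meiosis follows the Haldane model: crossovers are a Poisson process on the
centimorgan map with no interference.  Parental origin of every allele is
tracked, so identity-by-descent with the recurrent parent is exact, not
estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMap",
    "Founder",
    "FounderSet",
    "FamilySpec",
    "LineGenome",
    "EnvDesign",
    "TraitSpec",
    "TrialSpec",
    "make_genetic_map",
    "make_founders",
    "simulate_bc1_family",
    "simulate_population",
    "make_testcross_hybrids",
    "simulate_trial",
    "lines_to_codes",
    "lines_to_calls",
]

RECURRENT_ORIGIN = 0
DONOR_ORIGIN = 1


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeMap:
    """Marker positions on a centimorgan linkage map.

    ``chromosomes`` is a list of ``(chrom_id, length_cM)``; ``markers`` is a
    DataFrame indexed by marker id with columns ``chrom`` and ``pos_cM``,
    strictly increasing within each chromosome.
    """

    chromosomes: tuple
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos_cM"].to_numpy()
            if len(pos) < 1:
                raise ValueError(f"chromosome {chrom} has no markers")
            if np.any(pos < 0) or np.any(pos > lengths[chrom]):
                raise ValueError(f"marker positions outside chromosome {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    def chrom_slices(self) -> list[tuple[str, slice, np.ndarray, float]]:
        """(chrom_id, slice into marker order, positions, length) per chromosome."""
        out = []
        start = 0
        for chrom, length in self.chromosomes:
            sub = self.markers[self.markers["chrom"] == chrom]
            out.append(
                (chrom, slice(start, start + len(sub)), sub["pos_cM"].to_numpy(), length)
            )
            start += len(sub)
        return out


def make_genetic_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_length_cM: float,
    seed: int | None = None,
    random_positions: bool = False,
) -> GenomeMap:
    """Build a genome map with ``n_chrom`` chromosomes of equal length.

    Markers are placed on a uniform deterministic grid by default, or
    uniformly at random (seeded) when ``random_positions`` is set.
    """
    if n_chrom < 1 or markers_per_chrom < 1 or chrom_length_cM <= 0:
        raise ValueError("n_chrom, markers_per_chrom must be >= 1 and length > 0")
    rng = np.random.default_rng(seed)
    chroms = tuple((f"chr{i + 1}", float(chrom_length_cM)) for i in range(n_chrom))
    rows = []
    for chrom, length in chroms:
        if random_positions:
            pos = np.sort(rng.uniform(0.0, length, markers_per_chrom))
            while np.any(np.diff(pos) <= 0):  # ties have measure zero; be safe
                pos = np.sort(rng.uniform(0.0, length, markers_per_chrom))
        else:
            pos = (np.arange(markers_per_chrom) + 1) * length / (markers_per_chrom + 1)
        for j, p in enumerate(pos):
            rows.append((f"{chrom}_m{j + 1}", chrom, float(p)))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"]).set_index("marker")
    return GenomeMap(chromosomes=chroms, markers=markers)


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Founder:
    """A fully inbred founder: one haploid allele-state vector (0/1)."""

    line_id: str
    haplotype: np.ndarray  # int8, 0 = recurrent-parent allele state reference


@dataclass(frozen=True)
class FounderSet:
    recurrent: Founder
    donors: tuple
    divergence: Mapping[str, float]  # realized donor-vs-recurrent difference


def make_founders(
    gmap: GenomeMap,
    donor_divergence: Mapping[str, float],
    seed: int | None = None,
    recurrent_id: str = "REC",
    private_fraction: float = 0.0,
) -> FounderSet:
    """Create the recurrent parent and divergent donors.

    Each donor differs from the recurrent parent at a seeded random fraction
    of markers (``donor_divergence``, per donor id); all founders are
    homozygous.  ``private_fraction`` is the share of each donor's divergent
    markers drawn from a donor-exclusive partition of the marker space, so
    donors carry mostly family-private alleles (exotic accessions of distinct
    geographic origin) rather than a shared deviation from the elite parent.
    """
    if not 0.0 <= private_fraction <= 1.0:
        raise ValueError("private_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    rec = Founder(recurrent_id, np.zeros(m, dtype=np.int8))
    n_donors = len(donor_divergence)
    # donor-exclusive marker partition (round-robin over a seeded permutation)
    perm = rng.permutation(m)
    partition = {d: perm[i::n_donors] for i, d in enumerate(donor_divergence)}
    donors = []
    realized = {}
    for donor_id, div in donor_divergence.items():
        if not 0.0 <= div <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        n_flip = int(round(div * m))
        n_priv = min(int(round(private_fraction * n_flip)), len(partition[donor_id]))
        priv = rng.choice(partition[donor_id], size=n_priv, replace=False)
        pool = np.setdiff1d(np.arange(m), priv)  # remaining flips anywhere else
        n_shared = min(n_flip - n_priv, len(pool))
        shared = rng.choice(pool, size=n_shared, replace=False)
        hap = np.zeros(m, dtype=np.int8)
        hap[np.concatenate([priv, shared]).astype(np.intp)] = 1
        donors.append(Founder(donor_id, hap))
        realized[donor_id] = float(hap.mean())
    return FounderSet(recurrent=rec, donors=tuple(donors), divergence=realized)


@dataclass(frozen=True)
class FamilySpec:
    """One BC1-NAM family: donor, target size, and selected major loci.

    ``selection_loci`` are marker ids at which only recurrent-parent
    homozygotes survive (models selection for dwarfing/maturity genes carried
    by the recurrent parent).
    """

    family_id: str
    donor_id: str
    n_lines: int
    selection_loci: tuple = ()

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")


@dataclass
class LineGenome:
    """A diploid line with tracked parental origin of every allele."""

    line_id: str
    family_id: str
    origins: np.ndarray  # (2, M) int8; 0 = recurrent parent, 1 = donor
    states: np.ndarray   # (2, M) int8 allele states

    @property
    def ibd_fraction(self) -> float:
        """Genome-wide fraction of alleles inherited from the recurrent parent."""
        return float(np.mean(self.origins == RECURRENT_ORIGIN))

    @property
    def heterozygosity(self) -> float:
        """Fraction of markers with differing allele states."""
        return float(np.mean(self.states[0] != self.states[1]))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gamete(rng: np.random.Generator, chrom_layout, n_markers: int, origins, states):
    """One meiotic product under the Haldane (Poisson crossover) model.

    ``chrom_layout`` is the precomputed output of ``GenomeMap.chrom_slices``.
    Crossover counts are Poisson with mean length/100 Morgans, positions
    uniform, no interference; the starting chromatid is a fair coin.
    """
    choice = np.empty(n_markers, dtype=np.intp)
    for _, sl, pos, length in chrom_layout:
        n_x = rng.poisson(length / 100.0)
        xpos = np.sort(rng.uniform(0.0, length, n_x))
        start = rng.integers(2)
        choice[sl] = (start + np.searchsorted(xpos, pos)) % 2
    idx = np.arange(n_markers)
    return origins[choice, idx], states[choice, idx]


class SelectionError(RuntimeError):
    """Raised when selection at major loci cannot be satisfied."""


def simulate_bc1_family(
    recurrent: Founder,
    donor: Founder,
    gmap: GenomeMap,
    n_lines: int,
    selfing_generations: int = 3,
    selection_loci: Sequence[str] = (),
    seed: int | None = None,
    family_id: str = "F1",
    max_attempts_per_line: int = 2000,
    n_bc1_plants: int | None = None,
) -> list[LineGenome]:
    """Simulate BC1F(1+g) lines from one donor family.

    The cross is F1 = recurrent x donor, backcrossed once to the recurrent
    parent, then selfed ``selfing_generations`` times (3 gives BC1F4).  Lines
    not homozygous for the recurrent-parent allele at every ``selection_loci``
    marker are discarded and redrawn until ``n_lines`` survivors are obtained.

    ``n_bc1_plants`` bounds the number of distinct BC1F1 individuals the
    family descends from; breeding programs typically advance a family from
    one or a few backcross plants, which makes sibs share the donor segments
    that happen to be carried by those plants.  The default (``None``) gives
    every line its own BC1F1, the idealized infinite-family expectation.
    """
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    if n_bc1_plants is not None and n_bc1_plants < 1:
        raise ValueError("n_bc1_plants must be >= 1")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    layout = gmap.chrom_slices()
    loci_idx = np.asarray(
        [gmap.marker_ids.get_loc(l) for l in selection_loci], dtype=np.intp
    )
    rec_state = recurrent.haplotype

    f1_origins = np.stack([
        np.full(m, RECURRENT_ORIGIN, dtype=np.int8),
        np.full(m, DONOR_ORIGIN, dtype=np.int8),
    ])
    f1_states = np.stack([recurrent.haplotype, donor.haplotype]).astype(np.int8)

    bc1_pool: list[tuple[np.ndarray, np.ndarray]] = []
    if n_bc1_plants is not None:
        for _ in range(n_bc1_plants):
            g_o, g_s = _gamete(rng, layout, m, f1_origins, f1_states)
            bc1_pool.append((
                np.stack([np.full(m, RECURRENT_ORIGIN, dtype=np.int8), g_o]),
                np.stack([rec_state.astype(np.int8), g_s]),
            ))

    lines: list[LineGenome] = []
    attempts = 0
    budget = max_attempts_per_line * n_lines
    while len(lines) < n_lines:
        attempts += 1
        if attempts > budget:
            raise SelectionError(
                f"could not obtain {n_lines} lines passing selection at "
                f"{list(selection_loci)} within {budget} attempts"
            )
        if bc1_pool:
            origins, states = bc1_pool[attempts % len(bc1_pool)]
        else:
            g_o, g_s = _gamete(rng, layout, m, f1_origins, f1_states)
            origins = np.stack([np.full(m, RECURRENT_ORIGIN, dtype=np.int8), g_o])
            states = np.stack([rec_state.astype(np.int8), g_s])
        for _ in range(selfing_generations):
            o1, s1 = _gamete(rng, layout, m, origins, states)
            o2, s2 = _gamete(rng, layout, m, origins, states)
            origins = np.stack([o1, o2])
            states = np.stack([s1, s2])
        if len(loci_idx):
            ok = np.all(states[:, loci_idx] == rec_state[loci_idx][None, :])
            if not ok:
                continue
        lines.append(
            LineGenome(
                line_id=f"{family_id}_L{len(lines) + 1:03d}",
                family_id=family_id,
                origins=origins,
                states=states,
            )
        )
    return lines


def simulate_population(
    gmap: GenomeMap,
    founders: FounderSet,
    families: Sequence[FamilySpec],
    selfing_generations: int = 3,
    seed: int | None = None,
    n_bc1_plants: int | None = None,
) -> tuple[list[LineGenome], pd.DataFrame]:
    """Simulate every family of a BC1-NAM population.

    Returns the lines and a pedigree table (line, family, donor, recurrent).
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(families))
    donor_by_id = {d.line_id: d for d in founders.donors}
    lines: list[LineGenome] = []
    rows = []
    for fam, cs in zip(families, child_seeds):
        fam_lines = simulate_bc1_family(
            founders.recurrent,
            donor_by_id[fam.donor_id],
            gmap,
            fam.n_lines,
            selfing_generations=selfing_generations,
            selection_loci=fam.selection_loci,
            seed=cs,
            family_id=str(fam.family_id),
            n_bc1_plants=n_bc1_plants,
        )
        lines.extend(fam_lines)
        for ln in fam_lines:
            rows.append((ln.line_id, str(fam.family_id), fam.donor_id,
                         founders.recurrent.line_id))
    pedigree = pd.DataFrame(rows, columns=["line", "family", "donor", "recurrent"])
    return lines, pedigree


# ---------------------------------------------------------------------------
# genotype export
# ---------------------------------------------------------------------------

def lines_to_codes(lines: Sequence[LineGenome], gmap: GenomeMap) -> pd.DataFrame:
    """Allele-state dosage of the non-recurrent allele, coded 1/0/-1.

    A line homozygous for the recurrent-parent allele state is 1, a
    heterozygote 0, homozygous for the alternative state -1.  This matches the
    major/minor convention of the marker-QC module whenever the recurrent
    allele is the majority allele, which holds by construction in a backcross
    population.
    """
    vals = np.stack([1 - ln.states.sum(axis=0) for ln in lines]).astype(np.int8)
    return pd.DataFrame(vals, index=[ln.line_id for ln in lines],
                        columns=gmap.marker_ids)


def lines_to_calls(lines: Sequence[LineGenome], gmap: GenomeMap,
                   ref: str = "A", alt: str = "T") -> pd.DataFrame:
    """Two-character allele calls (e.g. ``AA``/``AT``/``TT``) per line x marker."""
    alleles = np.array([ref, alt])
    rows = {}
    for ln in lines:
        a = alleles[ln.states[0]]
        b = alleles[ln.states[1]]
        # normalize order so AT and TA are the same call
        swap = a > b
        first = np.where(swap, b, a)
        second = np.where(swap, a, b)
        rows[ln.line_id] = np.char.add(first, second)
    return pd.DataFrame.from_dict(rows, orient="index", columns=gmap.marker_ids)


# ---------------------------------------------------------------------------
# testcross hybrids
# ---------------------------------------------------------------------------

def make_testcross_hybrids(
    lines: Sequence[str] | Sequence[LineGenome],
    testers: Sequence[str],
    assignment: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Pedigree of testcross hybrids: one row per (male line, female tester).

    ``assignment`` maps each male line to the subset of testers it is crossed
    to; omit for the full factorial.  Duplicate pairs collapse to one hybrid.
    """
    line_ids = [ln.line_id if isinstance(ln, LineGenome) else str(ln) for ln in lines]
    tester_ids = [str(t) for t in testers]
    tester_set = set(tester_ids)
    pairs: list[tuple[str, str]] = []
    if assignment is None:
        pairs = [(m, f) for m in line_ids for f in tester_ids]
    else:
        for male, fs in assignment.items():
            if male not in set(line_ids):
                raise KeyError(f"unknown male line {male!r}")
            fs = list(fs)
            if not fs:
                raise ValueError(f"empty tester assignment for {male!r}")
            for f in fs:
                if f not in tester_set:
                    raise KeyError(f"unknown tester {f!r}")
                pairs.append((male, f))
    seen = {}
    for male, fem in pairs:
        seen.setdefault((male, fem), None)
    out = pd.DataFrame(list(seen), columns=["male", "female"])
    out.insert(0, "hybrid", out["male"] + "/" + out["female"])
    return out


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvDesign:
    """Field layout of one environment."""

    env_id: str
    design: str = "rcbd-r2"  # or "augmented-unreplicated"
    n_blocks: int = 2
    n_rows: int = 10  # plots per range (row dimension of the field grid)

    def __post_init__(self) -> None:
        if self.design not in ("rcbd-r2", "augmented-unreplicated"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass(frozen=True)
class TraitSpec:
    """Generative variance components of one trait (hybrid-mean scale).

    With ``n_qtl`` set, the main additive values come from that many sparse
    marker effects instead of an infinitesimal (kernel) draw.  In a BC1-NAM
    population the polymorphic markers are dominated by donor introgressions,
    so sparse effects are largely family-private — the architecture that makes
    training-set family representation matter.

    ``family_var_share`` splits the additive variance between a family-level
    (donor-determined) effect and within-family line segregation.  Traits like
    maturity and height, whose major genes are screened during line
    development, are family-mean dominated (high share); unselected complex
    traits like grain yield segregate freely within families (low share).
    """

    name: str
    var_a: float
    var_d: float = 0.0
    var_ae: float = 0.0
    var_de: float = 0.0
    var_e: float = 1.0
    env_means: Mapping[str, float] | float = 0.0
    n_qtl: int | None = None
    family_var_share: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.var_a, self.var_d, self.var_ae, self.var_de, self.var_e):
            if v < 0:
                raise ValueError("variance components must be >= 0")

    def mean_for(self, env: str) -> float:
        if isinstance(self.env_means, Mapping):
            return float(self.env_means.get(env, 0.0))
        return float(self.env_means)


@dataclass(frozen=True)
class TrialSpec:
    environments: tuple
    traits: tuple
    design_variances: tuple = (0.0, 0.0, 0.0)  # block, range, row


def _psd_draw(rng, K: np.ndarray, var: float, floor: float = 1e-8) -> np.ndarray:
    """Draw N(0, K*var) with an eigenvalue floor for numerical PSD safety."""
    if var == 0.0:
        return np.zeros(K.shape[0])
    w, v = np.linalg.eigh((K + K.T) / 2.0)
    w = np.maximum(w, floor)
    z = rng.standard_normal(K.shape[0])
    return (v * np.sqrt(w * var)) @ z


def _qtl_draw(rng, codes: np.ndarray, n_qtl: int, var: float) -> np.ndarray:
    """Sparse additive values: normal effects at seeded polymorphic markers,
    rescaled so the realized variance across hybrids equals ``var``."""
    if var == 0.0:
        return np.zeros(codes.shape[0])
    poly = np.flatnonzero(codes.std(axis=0) > 0)
    if len(poly) == 0:
        return np.zeros(codes.shape[0])
    n_qtl = min(n_qtl, len(poly))
    qtl = rng.choice(poly, size=n_qtl, replace=False)
    u = codes[:, qtl] @ rng.standard_normal(n_qtl)
    u = u - u.mean()
    sd = u.std()
    if sd == 0:
        return np.zeros(codes.shape[0])
    return u * np.sqrt(var) / sd


def simulate_trial(
    hybrids: pd.DataFrame,
    hybrid_codes: pd.DataFrame,
    spec: TrialSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate plot-level phenotypes for a set of testcross hybrids.

    True genetic values are drawn from the additive and dominance kernels of
    the hybrid genotypes: main effects u_A ~ N(0, K_A s2_A) and
    u_D ~ N(0, K_D s2_D) shared across environments, plus independent
    per-environment interaction deviations N(0, K_A s2_AE) and
    N(0, K_D s2_DE) — the block-diagonal covariance that an environment-match
    Hadamard kernel specifies.  Block/range/row effects are i.i.d. normal with
    the ``design_variances``; plot residuals are N(0, s2_e).

    Returns ``(plots, truth)``: the long-format trial table, and the hidden
    per-hybrid, per-environment total genetic values.
    """
    from .kernels import additive_kernel, dominance_kernel

    rng = np.random.default_rng(seed)
    hyb_ids = hybrids["hybrid"].tolist()
    codes = hybrid_codes.loc[hyb_ids].to_numpy(dtype=float)
    n_h = len(hyb_ids)
    need_a = any(t.var_a > 0 or t.var_ae > 0 for t in spec.traits)
    need_d = any(t.var_d > 0 or t.var_de > 0 for t in spec.traits)
    K_A = additive_kernel(codes) if need_a else np.zeros((n_h, n_h))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        K_D = dominance_kernel(codes) if need_d else np.zeros((n_h, n_h))

    fam_codes = None
    if any(t.family_var_share > 0 for t in spec.traits):
        if "family" not in hybrids.columns:
            raise ValueError(
                "family_var_share > 0 requires a 'family' column in the "
                "hybrid pedigree (checks may be NaN)"
            )
        fam_cat = pd.Categorical(hybrids["family"])
        fam_codes = fam_cat.codes  # -1 for NaN (checks): no family effect

    envs = [e.env_id for e in spec.environments]
    truth_vals = {}  # trait -> (n_h, n_env)
    for trait in spec.traits:
        share = trait.family_var_share
        if not 0.0 <= share <= 1.0:
            raise ValueError("family_var_share must be in [0, 1]")
        if trait.n_qtl:
            u_line = _qtl_draw(rng, codes, trait.n_qtl, trait.var_a * (1 - share))
        else:
            u_line = _psd_draw(rng, K_A, trait.var_a * (1 - share))
        if share > 0:
            n_fam = fam_codes.max() + 1
            fam_eff = rng.normal(0.0, np.sqrt(trait.var_a * share), n_fam)
            u_a = u_line + np.where(fam_codes >= 0, fam_eff[fam_codes], 0.0)
        else:
            u_a = u_line
        u_d = _psd_draw(rng, K_D, trait.var_d)
        g = np.empty((n_h, len(envs)))
        for j, env in enumerate(envs):
            u_ae = _psd_draw(rng, K_A, trait.var_ae)
            u_de = _psd_draw(rng, K_D, trait.var_de)
            g[:, j] = u_a + u_d + u_ae + u_de
        truth_vals[trait.name] = g

    s_blk, s_ra, s_ro = spec.design_variances
    plot_rows = []
    for j, env in enumerate(spec.environments):
        if env.design == "rcbd-r2":
            layout = []
            for b in range(env.n_blocks):
                order = rng.permutation(n_h)
                layout.extend((b, i) for i in order)
        else:  # augmented-unreplicated: one plot per hybrid, blocks chunk the field
            order = rng.permutation(n_h)
            chunk = int(np.ceil(n_h / env.n_blocks))
            layout = [(k // chunk, i) for k, i in enumerate(order)]
        n_plots = len(layout)
        n_ranges = int(np.ceil(n_plots / env.n_rows))
        blk_eff = rng.normal(0.0, np.sqrt(s_blk), env.n_blocks) if s_blk > 0 else np.zeros(env.n_blocks)
        ra_eff = rng.normal(0.0, np.sqrt(s_ra), n_ranges) if s_ra > 0 else np.zeros(n_ranges)
        ro_eff = rng.normal(0.0, np.sqrt(s_ro), env.n_rows) if s_ro > 0 else np.zeros(env.n_rows)
        resid = {
            t.name: rng.normal(0.0, np.sqrt(t.var_e), n_plots) if t.var_e > 0 else np.zeros(n_plots)
            for t in spec.traits
        }
        for k, (b, i) in enumerate(layout):
            ra, ro = k // env.n_rows, k % env.n_rows
            row = {
                "env": env.env_id,
                "hybrid": hyb_ids[i],
                "male": hybrids["male"].iloc[i],
                "female": hybrids["female"].iloc[i],
                "block": f"B{b + 1}",
                "range": f"Ra{ra + 1}",
                "row": f"Ro{ro + 1}",
            }
            for t in spec.traits:
                row[t.name] = (
                    t.mean_for(env.env_id)
                    + truth_vals[t.name][i, j]
                    + blk_eff[b] + ra_eff[ra] + ro_eff[ro]
                    + resid[t.name][k]
                )
            plot_rows.append(row)

    plots = pd.DataFrame(plot_rows)
    truth_rows = []
    for t in spec.traits:
        for j, env in enumerate(envs):
            for i, h in enumerate(hyb_ids):
                truth_rows.append((env, h, t.name, truth_vals[t.name][i, j]))
    truth = pd.DataFrame(truth_rows, columns=["env", "hybrid", "trait", "genetic_value"])
    return plots, truth
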