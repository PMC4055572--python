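"""Population-structure inference on (possibly ancestry-partitioned) panels.

Contents
--------
* Gene identity ``J`` — the probability that two randomly drawn alleles are
  identical by state — within and between populations, with a block jackknife
  over loci for uncertainty.
* ``FST`` from gene identities: (mean within J − mean between J)/(1 − mean
  between J).
* Mantel tests of gene identity against geographic distance, with optional
  waypoint-routed great-circle distances.
* Three-level AMOVA (within populations / among populations within groups /
  among groups) with the among-group fixation index Φ_GT and a
  population-permutation p-value.
* Hierarchical population-tree models: expected heterozygosity decays
  multiplicatively along edges (H at a node = H_root·Π r_e, r_e = 1−F_e);
  parameters are fitted by generalised least squares against the observed
  identity statistics, whitened by their block-jackknife covariance, so the
  goodness-of-fit Λ and the nested-improvement statistic K are chi-square
  distributed under the model.
* FST-based minimum divergence times under pure drift with known Ne, and
  Wright's island-model equilibrium migration rate.
* Ancestry-proportion summaries from a Q matrix: per-component coefficients
  of variation and super-population (e.g. non-African) totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import (
    CV_COMPONENT_THRESHOLD,
    DEFAULT_NE,
    GENERATION_YEARS,
    N_PERMUTATIONS,
)
from .sources import FrequencyTable, HaplotypePanel

__all__ = [
    "IdentityMatrix",
    "gene_identity_matrix",
    "fst_from_identity",
    "MantelResult",
    "mantel_test",
    "geographic_distance",
    "AmovaResult",
    "amova_phi_gt",
    "TreeModel",
    "fit_tree_model",
    "TreeComparison",
    "compare_trees",
    "DivergenceParams",
    "divergence_time_from_fst",
    "wright_equilibrium_nm",
    "wright_equilibrium_fst",
    "QMatrix",
    "ancestry_cv",
    "sum_superpopulation",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# gene identity
# ---------------------------------------------------------------------------

@dataclass
class IdentityMatrix:
    """Mean gene identity per population pair with per-block values retained.

    ``j`` is (P, P), symmetric; diagonal entries use the unbiased
    small-sample within-population estimator.  ``block_j`` is (B, P, P) with
    per-block locus counts in ``block_loci`` so leave-one-block-out values
    (and hence a jackknife covariance for tree fitting) can be formed.
    """

    populations: list[str]
    j: np.ndarray
    block_j: np.ndarray
    block_loci: np.ndarray

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return int(self.block_loci.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.j, index=self.populations, columns=self.populations)

    def leave_one_block_out(self) -> np.ndarray:
        """(B, P, P) identity matrices with each block deleted."""
        tot = (self.block_j * self.block_loci[:, None, None]).sum(axis=0)
        n = self.block_loci.sum()
        out = (tot[None] - self.block_j * self.block_loci[:, None, None]) / (
            n - self.block_loci
        )[:, None, None]
        return out


def _per_locus_identity(
    freq: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus within (unbiased) and between identities from frequencies.

    Returns (within (P, L), between (P, P, L) upper usage symmetric).
    """
    p = freq
    within_naive = p**2 + (1 - p) ** 2
    nn = n[:, None].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        within = (nn * within_naive - 1.0) / (nn - 1.0)
    between = p[:, None, :] * p[None, :, :] + (1 - p[:, None, :]) * (1 - p[None, :, :])
    return within, between


def gene_identity_matrix(
    data: Sequence[HaplotypePanel] | FrequencyTable,
    n_blocks: int = 50,
) -> IdentityMatrix:
    """Gene-identity matrix from panels or a frequency table with sample sizes.

    Between-population: ``J_xy = mean_l [x y + (1-x)(1-y)]``.  Within:
    the ``(n J̃ − 1)/(n − 1)`` unbiased correction of the plug-in identity,
    which requires ``n ≥ 2`` chromosomes.  Loci are split into ``n_blocks``
    contiguous equal blocks for the jackknife.
    """
    if isinstance(data, FrequencyTable):
        pops = list(data.populations)
        freq = data.freq
        n = data.n_chromosomes
    else:
        pops = [p.population for p in data]
        freq = np.vstack([p.frequencies() for p in data])
        n = np.array([p.n_haplotypes for p in data])
    if np.any(n < 2):
        raise ValueError("within-population identity needs n >= 2 chromosomes")
    n_loci = freq.shape[1]
    n_blocks = min(n_blocks, n_loci)
    within, between = _per_locus_identity(freq, n)
    per_locus = between.copy()
    P = len(pops)
    per_locus[np.arange(P), np.arange(P), :] = within

    block_id = (np.arange(n_loci) * n_blocks) // n_loci
    block_loci = np.bincount(block_id, minlength=n_blocks).astype(float)
    block_j = np.empty((n_blocks, P, P))
    for b in range(n_blocks):
        block_j[b] = per_locus[:, :, block_id == b].mean(axis=2)
    j = (block_j * block_loci[:, None, None]).sum(axis=0) / block_loci.sum()
    return IdentityMatrix(populations=pops, j=j, block_j=block_j, block_loci=block_loci)


def fst_from_identity(
    j: IdentityMatrix | np.ndarray, populations: Sequence[str] | None = None
) -> float:
    """FST = (mean within J − mean between J) / (1 − mean between J)."""
    if isinstance(j, IdentityMatrix):
        mat = j.j
        if populations is not None:
            idx = [j.populations.index(p) for p in populations]
            mat = mat[np.ix_(idx, idx)]
    else:
        mat = np.asarray(j)
    P = mat.shape[0]
    if P < 2:
        raise ValueError("need at least two populations")
    jw = float(np.mean(np.diag(mat)))
    iu = np.triu_indices(P, k=1)
    jb = float(np.mean(mat[iu]))
    if jb >= 1.0:
        raise ZeroDivisionError("between-population identity is 1; FST undefined")
    return (jw - jb) / (1.0 - jb)


# ---------------------------------------------------------------------------
# Mantel test and geographic distance
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def mantel_test(
    mat1: np.ndarray,
    mat2: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two symmetric matrices.

    Pearson r over the off-diagonal pairs; the p-value permutes the rows and
    columns of ``mat2`` jointly.  The tail is taken in the direction of the
    observed sign and doubled (standard two-sided correction), which keeps the
    null p-value uniform.
    """
    m1 = np.asarray(mat1, dtype=float)
    m2 = np.asarray(mat2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and same shape")
    P = m1.shape[0]
    iu = np.triu_indices(P, k=1)
    x = m1[iu]
    if np.std(x) == 0 or np.std(m2[iu]) == 0:
        return MantelResult(r=np.nan, p_value=np.nan, n_permutations=0)
    rng = np.random.default_rng(seed)

    def corr(y):
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(m2[iu])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(P)
        mp = m2[np.ix_(perm, perm)]
        r_p = corr(mp[iu])
        if r_obs >= 0:
            count += r_p >= r_obs
        else:
            count += r_p <= r_obs
    p = min(1.0, 2.0 * (count + 1) / (n_perm + 1))
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm)


def _haversine(lat1, lon1, lat2, lon2) -> float:
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance(
    points: pd.DataFrame,
    waypoint: tuple[float, float] | None = None,
    waypoint_side: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Great-circle distance matrix (km) between populations.

    ``points`` needs columns population, lat, lon (degrees).  With a
    ``waypoint`` (lat, lon) and ``waypoint_side`` (population labels on one
    side of the waypoint), pairs straddling the partition are routed through
    the waypoint: d(a, w) + d(w, b).
    """
    lat = points["lat"].to_numpy(dtype=float)
    lon = points["lon"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 360):
        raise ValueError("invalid coordinates")
    pops = list(points["population"])
    P = len(pops)
    D = np.zeros((P, P))
    side = set(waypoint_side or [])
    for i in range(P):
        for k in range(i + 1, P):
            crosses = waypoint is not None and ((pops[i] in side) != (pops[k] in side))
            if crosses:
                d = _haversine(lat[i], lon[i], *waypoint) + _haversine(
                    *waypoint, lat[k], lon[k]
                )
            else:
                d = _haversine(lat[i], lon[i], lat[k], lon[k])
            D[i, k] = D[k, i] = d
    return pd.DataFrame(D, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA: among groups / among populations / within populations."""

    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    phi_gt: float
    p_value: float
    n_permutations: int

    @property
    def components(self) -> np.ndarray:
        return np.array(
            [self.sigma_among_groups, self.sigma_among_pops, self.sigma_within]
        )


def amova_phi_gt(
    panels: Mapping[str, HaplotypePanel],
    groups: Mapping[str, str],
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA on haploid allele copies with IBS mismatch distance.

    Squared Euclidean distance over loci on 0/1 alleles makes all sums of
    squares functions of per-population allele frequencies, so permutations
    (which shuffle whole populations among groups, the exchangeable unit for
    the among-group test) are cheap.  Φ_GT is the among-group variance
    component over the total; p is the fraction of permutations with
    Φ_GT at least as large as observed (add-one corrected).
    """
    pops = list(panels)
    group_of = np.array([groups[p] for p in pops])
    glabels = np.unique(group_of)
    if len(glabels) < 2:
        raise ValueError("need at least two groups (one group holds all populations)")
    n_p = np.array([panels[p].n_haplotypes for p in pops], dtype=float)
    M = np.vstack([panels[p].frequencies() for p in pops])  # (P, L)
    N = n_p.sum()
    P = len(pops)

    # locus-wise sums of squares from 0/1 allele copies
    ss_total_within = float(sum((panels[p].n_haplotypes * (panels[p].frequencies() * (1 - panels[p].frequencies()))).sum() for p in pops))
    norm_p = (n_p[:, None] * M**2).sum()
    grand = (n_p[:, None] * M).sum(axis=0) / N
    norm_t = N * float((grand**2).sum())

    gindex = {g: i for i, g in enumerate(glabels)}
    gi = np.array([gindex[g] for g in group_of])

    def components(gi_arr: np.ndarray) -> tuple[float, float, float]:
        G = len(glabels)
        n_g = np.bincount(gi_arr, weights=n_p, minlength=G)
        Sg = np.zeros((G, M.shape[1]))
        np.add.at(Sg, gi_arr, n_p[:, None] * M)
        norm_g = float(((Sg**2).sum(axis=1) / n_g).sum())
        ssd_ag = norm_g - norm_t
        ssd_ap = norm_p - norm_g
        ssd_wp = ss_total_within
        df_wp = N - P
        df_ap = P - G
        df_ag = G - 1
        sigma_c = ssd_wp / df_wp
        sum_np2_over_ng = float(
            (np.bincount(gi_arr, weights=n_p**2, minlength=G) / n_g).sum()
        )
        n1 = (N - sum_np2_over_ng) / df_ap
        n2 = (sum_np2_over_ng - (n_p**2).sum() / N) / df_ag
        n3 = (N - (n_g**2).sum() / N) / df_ag
        ms_ap = ssd_ap / df_ap
        ms_ag = ssd_ag / df_ag
        sigma_b = (ms_ap - sigma_c) / n1
        sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
        return sigma_a, sigma_b, sigma_c

    sigma_a, sigma_b, sigma_c = components(gi)
    total = sigma_a + sigma_b + sigma_c
    phi = sigma_a / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_gi = gi[rng.permutation(P)]
        pa, pb, pc = components(perm_gi)
        if pa / (pa + pb + pc) >= phi:
            count += 1
    return AmovaResult(
        sigma_among_groups=float(sigma_a),
        sigma_among_pops=float(sigma_b),
        sigma_within=float(sigma_c),
        phi_gt=float(phi),
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# hierarchical population-tree models
# ---------------------------------------------------------------------------

def _parse_topology(topology: Mapping) -> tuple[list[str], list[list[int]], list[list[int]], int]:
    """Flatten a nested-dict topology into per-leaf and per-pair level lists.

    Internal (non-root, non-leaf) edges at the same depth share one
    heterozygosity-retention parameter; each leaf edge has its own.  Returns
    (leaf names, internal-level indices per leaf path, internal-level indices
    to each pair's MRCA, number of shared internal levels).
    """
    leaves: list[str] = []
    leaf_paths: list[list[int]] = []
    levels: set[int] = set()
    pair_path: dict[tuple[int, int], list[int]] = {}

    def walk(node: Mapping, depth: int, path: list[int]) -> list[int]:
        children = node.get("children", [])
        if not children:
            leaves.append(str(node["name"]))
            leaf_paths.append(list(path))
            return [len(leaves) - 1]
        groups: list[list[int]] = []
        for child in children:
            if child.get("children"):
                levels.add(depth)
                groups.append(walk(child, depth + 1, path + [depth]))
            else:
                groups.append(walk(child, depth + 1, path))
        # leaf pairs whose MRCA is this node share exactly `path` above it
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for k in groups[b]:
                        pair_path[(min(i, k), max(i, k))] = list(path)
        return [i for g in groups for i in g]

    walk(topology, 0, [])
    level_list = sorted(levels)
    level_index = {lv: i for i, lv in enumerate(level_list)}
    leaf_levels = [[level_index[lv] for lv in p] for p in leaf_paths]
    P = len(leaves)
    pair_levels = [
        [level_index[lv] for lv in pair_path[(i, k)]]
        for i in range(P)
        for k in range(i + 1, P)
    ]
    return leaves, leaf_levels, pair_levels, len(level_list)


@dataclass
class TreeModel:
    """A fitted hierarchical drift-tree model of a gene-identity matrix."""

    topology: dict
    populations: list[str]
    h_root: float
    level_r: np.ndarray  # shared retention per internal level
    leaf_r: np.ndarray  # per-leaf retention
    lambda_stat: float
    df: int
    p_value: float
    n_params: int
    observed: np.ndarray = field(repr=False)
    expected: np.ndarray = field(repr=False)
    data_fingerprint: int = 0

    @property
    def level_f(self) -> np.ndarray:
        """Per-level drift coefficients F = 1 − r."""
        return 1.0 - self.level_r

    @property
    def leaf_f(self) -> np.ndarray:
        return 1.0 - self.leaf_r

    def expected_identity(self) -> np.ndarray:
        """Model-expected J matrix (1 − expected heterozygosity)."""
        P = len(self.populations)
        J = np.zeros((P, P))
        within, between = self.expected[:P], self.expected[P:]
        J[np.arange(P), np.arange(P)] = 1.0 - within
        iu = np.triu_indices(P, k=1)
        J[iu] = 1.0 - between
        J.T[iu] = 1.0 - between
        return J

    def model_fst(self) -> float:
        return fst_from_identity(self.expected_identity())


def _stat_vector(j: IdentityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Observed heterozygosity statistics H = 1−J and their jackknife covariance."""
    P = j.n_populations
    iu = np.triu_indices(P, k=1)

    def vec(mat: np.ndarray) -> np.ndarray:
        return np.concatenate([1.0 - np.diag(mat), 1.0 - mat[iu]])

    v = vec(j.j)
    loo = j.leave_one_block_out()
    B = loo.shape[0]
    vb = np.vstack([vec(loo[b]) for b in range(B)])
    centred = vb - vb.mean(axis=0, keepdims=True)
    cov = (B - 1) / B * centred.T @ centred
    return v, cov


def fit_tree_model(j: IdentityMatrix, topology: Mapping) -> TreeModel:
    """Fit a hierarchical drift tree to an identity matrix by whitened least squares.

    Expected heterozygosity is ``H_root`` times the product of the
    retention parameters ``r_e = 1−F_e`` along the root path (to the leaf for
    within-population statistics, to the pair's MRCA for between-population
    statistics).  The residual vector is whitened by the block-jackknife
    covariance of the statistics, so the minimised quadratic form Λ is
    asymptotically chi-square with ``df = #statistics − #parameters``.
    """
    leaves, leaf_levels, pair_levels, n_levels = _parse_topology(dict(topology))
    if set(leaves) != set(j.populations):
        raise ValueError("topology leaves must match the identity matrix populations")
    # reorder the identity matrix into the topology's leaf order
    perm = [j.populations.index(p) for p in leaves]
    j = IdentityMatrix(
        populations=leaves,
        j=j.j[np.ix_(perm, perm)],
        block_j=j.block_j[:, perm][:, :, perm],
        block_loci=j.block_loci,
    )
    P = j.n_populations
    pair_map: dict[tuple[int, int], list[int]] = {}
    c = 0
    for i in range(P):
        for k in range(i + 1, P):
            pair_map[(i, k)] = pair_levels[c]
            c += 1

    v, cov = _stat_vector(j)
    m = len(v)
    n_params = 1 + n_levels + P
    if n_params >= m:
        raise ValueError("topology is not identifiable: more parameters than statistics")

    # whitening transform from the covariance (eigen floor for stability)
    eva, eve = np.linalg.eigh(cov)
    floor = max(eva.max(), 1e-300) * 1e-10
    eva = np.maximum(eva, floor)
    white = eve @ np.diag(1.0 / np.sqrt(eva)) @ eve.T

    pair_idx = [pair_map[(i, k)] for i in range(P) for k in range(i + 1, P)]

    def expected(theta: np.ndarray) -> np.ndarray:
        h_root = theta[0]
        level_r = theta[1 : 1 + n_levels]
        leaf_r = theta[1 + n_levels :]
        within = np.array(
            [
                h_root * np.prod(level_r[ll]) * leaf_r[i]
                for i, ll in enumerate(leaf_levels)
            ]
        )
        between = np.array([h_root * np.prod(level_r[lv]) for lv in pair_idx])
        return np.concatenate([within, between])

    def resid(theta: np.ndarray) -> np.ndarray:
        return white @ (v - expected(theta))

    h0 = float(np.clip(np.mean(v[P:]) if m > P else np.mean(v), 1e-3, 1 - 1e-3))
    x0 = np.concatenate([[h0], np.full(n_levels, 0.97), np.clip(v[:P] / h0, 0.05, 1.0)])
    lb = np.full(n_params, 1e-6)
    # retention parameters are allowed above 1 so that a true value of 1 (no
    # extra drift at a level) sits in the interior of the parameter space;
    # otherwise the chi-square calibration of Λ and K breaks at the boundary
    ub = np.full(n_params, 2.0)
    ub[0] = 1.0 - 1e-6
    sol = optimize.least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    lam = float(2 * sol.cost)  # cost = 0.5 * sum(resid^2)
    df = m - n_params
    theta = sol.x
    return TreeModel(
        topology=dict(topology),
        populations=list(j.populations),
        h_root=float(theta[0]),
        level_r=theta[1 : 1 + n_levels].copy(),
        leaf_r=theta[1 + n_levels :].copy(),
        lambda_stat=lam,
        df=df,
        p_value=float(stats.chi2.sf(lam, df)) if df > 0 else np.nan,
        n_params=n_params,
        observed=v,
        expected=expected(theta),
        data_fingerprint=hash(cov.tobytes()),
    )


@dataclass
class TreeComparison:
    k_stat: float
    df: int
    p_value: float


def compare_trees(fit_restricted: TreeModel, fit_full: TreeModel) -> TreeComparison:
    """Nested-model improvement K = Λ_restricted − Λ_full, chi-square df = Δparams."""
    if fit_restricted.data_fingerprint != fit_full.data_fingerprint:
        raise ValueError("tree models were fitted to different data")
    df = fit_full.n_params - fit_restricted.n_params
    if df < 0:
        raise ValueError("restricted model must have fewer parameters than full model")
    k = fit_restricted.lambda_stat - fit_full.lambda_stat
    p = float(stats.chi2.sf(max(k, 0.0), df)) if df > 0 else (1.0 if k <= 0 else 0.0)
    return TreeComparison(k_stat=float(k), df=df, p_value=p)


# ---------------------------------------------------------------------------
# divergence time and equilibrium migration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceParams:
    """Effective size and generation time for FST→time conversion."""

    ne: float = DEFAULT_NE
    generation_years: float = GENERATION_YEARS

    def __post_init__(self) -> None:
        if self.ne <= 0 or self.generation_years <= 0:
            raise ValueError("Ne and generation time must be positive")


def divergence_time_from_fst(
    fst: float, params: DivergenceParams = DivergenceParams()
) -> float:
    """Minimum divergence time in years under pure drift with known Ne.

    Uses the pure-drift relationship FST = 1 − exp(−t/2Ne), i.e.
    ``t = −2·Ne·ln(1−FST)`` generations, times the generation time.  This is
    a minimum-time estimate: any post-divergence gene flow depresses FST.
    """
    if not (0.0 <= fst < 1.0):
        raise ValueError("FST must lie in [0, 1)")
    t_gen = -2.0 * params.ne * np.log1p(-fst)
    return float(t_gen * params.generation_years)


def wright_equilibrium_nm(fst: float) -> float:
    """Island-model migration Nm at drift–migration equilibrium: FST = 1/(1+4Nm)."""
    if not (0.0 < fst < 1.0):
        raise ValueError("FST must lie strictly in (0, 1)")
    return (1.0 / fst - 1.0) / 4.0


def wright_equilibrium_fst(nm: float) -> float:
    """Inverse of :func:`wright_equilibrium_nm`."""
    if nm < 0:
        raise ValueError("Nm must be non-negative")
    return 1.0 / (1.0 + 4.0 * nm)


# ---------------------------------------------------------------------------
# ancestry-proportion summaries
# ---------------------------------------------------------------------------

@dataclass
class QMatrix:
    """Per-individual ancestry proportions with population labels."""

    population: np.ndarray  # (N,) labels
    proportions: np.ndarray  # (N, K)
    components: list[str]

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=object)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2 or self.proportions.shape[1] != len(self.components):
            raise ValueError("proportions must be (N, K) matching components")
        if np.any(np.abs(self.proportions.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("ancestry proportions must sum to 1 per individual")


def ancestry_cv(q: QMatrix, threshold: float = CV_COMPONENT_THRESHOLD) -> pd.DataFrame:
    """Coefficient of variation of each ancestry component per population.

    Reported only for components whose population mean exceeds ``threshold``
    (5% by default).  CV = sd/mean across a population's individuals; a
    population needs at least two individuals.
    """
    rows = []
    for pop in dict.fromkeys(q.population):
        sub = q.proportions[q.population == pop]
        if sub.shape[0] < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1)
        for comp, mu, sd in zip(q.components, means, sds):
            if mu > threshold:
                rows.append({"population": pop, "component": comp, "mean": mu, "cv": sd / mu})
    return pd.DataFrame(rows, columns=["population", "component", "mean", "cv"])


def sum_superpopulation(q: QMatrix, group_map: Mapping[str, str]) -> pd.DataFrame:
    """Sum component proportions into super-groups (e.g. African/non-African).

    Every component must be mapped.  Returns one row per individual with the
    population label and one column per super-group.
    """
    missing = [c for c in q.components if c not in group_map]
    if missing:
        raise KeyError(f"unmapped ancestry components: {missing}")
    groups = sorted(set(group_map.values()))
    out = pd.DataFrame({"population": q.population})
    for g in groups:
        cols = [i for i, c in enumerate(q.components) if group_map[c] == g]
        out[g] = q.proportions[:, cols].sum(axis=1)
    return out
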