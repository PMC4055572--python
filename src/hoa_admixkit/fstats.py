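"""Formal admixture tests: f3 (with proportion bounds), D, f4 and f4-ratio.

All statistics are ratios of locus sums and carry weighted block-jackknife
standard errors and Z-scores.  Blocks are contiguous in map order — one block
per chromosome by default — and the jackknife weights are proportional to the
number of loci per block (Busing-style delete-one-group jackknife).

Conventions
-----------
* ``f3(target; refA, refB)``: mean over loci of ``(c-a)(c-b)`` minus the
  finite-sample heterozygosity correction ``c(1-c)/(n_c-1)`` for the target,
  optionally normalised by the target heterozygosity.  A strongly negative
  Z (< -4 by the conventional threshold) signals admixture in the target.
* ``d_stat(w, x, y, z)``: numerator ``(w-x)(y-z)``, denominator
  ``(w+x-2wx)(y+z-2yz)``, summed over loci.  Positive D indicates shared
  drift between ``x`` and ``z`` (equivalently ``w`` and ``y``), so with the
  conventional layout ((African reference, test), (Papuan, non-African
  reference)) a positive Z marks non-African admixture in the test
  population.
* ``f4_ratio(outgroup, refA, target, proxy, other)``: estimated proportion of
  target ancestry deriving from the ``proxy`` side,
  ``f4(refA, outgroup; target, other) / f4(refA, outgroup; proxy, other)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Z_THRESHOLD_F3_D, Z_THRESHOLD_WEIGHTED_LD  # noqa: F401  (re-exported)
from .sources import FrequencyTable, GeneticMap, HaplotypePanel

__all__ = [
    "BlockPartition",
    "FStatResult",
    "PopulationFreqs",
    "f3",
    "f4",
    "d_stat",
    "f4_ratio",
    "f3_bounds",
    "AdmixtureBounds",
    "hudson_fst",
    "block_jackknife_ratio",
]

#: |Z| of the denominator f4 below which an f4-ratio is flagged unreliable.
F4_DENOMINATOR_MIN_Z = 3.0


@dataclass(frozen=True)
class BlockPartition:
    """Assignment of loci to contiguous jackknife blocks."""

    block_id: np.ndarray  # (n_loci,) int, 0..m-1, non-decreasing in map order

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_id", np.asarray(self.block_id, dtype=np.int64))
        if np.any(np.diff(self.block_id) < 0):
            raise ValueError("blocks must be contiguous in map order")

    @property
    def n_blocks(self) -> int:
        return int(self.block_id.max()) + 1

    @property
    def n_loci(self) -> int:
        return len(self.block_id)

    def counts(self) -> np.ndarray:
        return np.bincount(self.block_id, minlength=self.n_blocks)

    @classmethod
    def per_chromosome(cls, genetic_map: GeneticMap) -> "BlockPartition":
        """One block per chromosome (leave-one-chromosome-out jackknife)."""
        _, block = np.unique(genetic_map.chromosome, return_inverse=True)
        return cls(block_id=block)

    @classmethod
    def cm_windows(cls, genetic_map: GeneticMap, size_cm: float = 5.0) -> "BlockPartition":
        """Fixed-size windows of ``size_cm`` centimorgans within chromosomes."""
        size_m = size_cm / 100.0
        block = np.empty(genetic_map.n_loci, dtype=np.int64)
        nxt = 0
        for _, idx in genetic_map.chromosome_indices():
            pos = genetic_map.position_morgans[idx]
            local = ((pos - pos[0]) // size_m).astype(np.int64)
            # renumber densely
            _, dense = np.unique(local, return_inverse=True)
            block[idx] = dense + nxt
            nxt += dense.max() + 1
        return cls(block_id=block)

    @classmethod
    def n_equal_blocks(cls, n_loci: int, n_blocks: int) -> "BlockPartition":
        """Split ``n_loci`` map-ordered loci into ``n_blocks`` near-equal runs."""
        return cls(block_id=(np.arange(n_loci) * n_blocks) // n_loci)


@dataclass(frozen=True)
class PopulationFreqs:
    """Allele-frequency estimates for one population with its chromosome count.

    ``n`` may be 0 to mark exact (parametric) frequencies, in which case no
    finite-sample correction applies.
    """

    name: str
    p: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))

    @classmethod
    def from_panel(cls, panel: HaplotypePanel) -> "PopulationFreqs":
        return cls(name=panel.population, p=panel.frequencies(), n=panel.n_haplotypes)

    @classmethod
    def from_genotypes(cls, name: str, genotypes: np.ndarray) -> "PopulationFreqs":
        g = np.asarray(genotypes)
        return cls(name=name, p=g.mean(axis=0) / 2.0, n=2 * g.shape[0])

    @classmethod
    def from_table(cls, table: FrequencyTable, population: str) -> "PopulationFreqs":
        return cls(name=population, p=table[population], n=table.n_for(population))

    @classmethod
    def monomorphic(cls, name: str, n_loci: int, allele: int = 0) -> "PopulationFreqs":
        """Fixed-allele pseudo-population (e.g. an ancestral outgroup)."""
        return cls(name=name, p=np.full(n_loci, float(allele)), n=0)


@dataclass
class FStatResult:
    """An f-type statistic with its block-jackknife uncertainty."""

    statistic: str
    value: float
    se: float
    z: float
    block_values: np.ndarray  # leave-one-block-out estimates
    populations: tuple[str, ...]
    n_loci: int
    n_blocks: int
    unreliable: bool = False

    def __repr__(self) -> str:  # compact, eyeball-friendly
        flag = " [unreliable]" if self.unreliable else ""
        return (
            f"{self.statistic}({', '.join(self.populations)}) = {self.value:.6g} "
            f"± {self.se:.3g} (Z = {self.z:.2f}){flag}"
        )


def block_jackknife_ratio(
    num: np.ndarray, den: np.ndarray, blocks: BlockPartition
) -> tuple[float, float, np.ndarray]:
    """Weighted delete-one-block jackknife for a ratio-of-sums statistic.

    ``num``/``den`` are per-locus contributions.  Returns
    (estimate, standard error, leave-one-out values).  Weights are the
    per-block locus counts (Busing et al. delete-m_j jackknife).
    """
    m = blocks.n_blocks
    bn = np.bincount(blocks.block_id, weights=num, minlength=m)
    bd = np.bincount(blocks.block_id, weights=den, minlength=m)
    tn, td = bn.sum(), bd.sum()
    if td == 0:
        raise ZeroDivisionError("statistic denominator is zero over all loci")
    theta = tn / td
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = (tn - bn) / (td - bd)
    if not np.all(np.isfinite(loo)):
        raise ZeroDivisionError("statistic denominator vanishes when a block is removed")
    w = blocks.counts().astype(float)
    wtot = w.sum()
    h = wtot / w
    theta_j = m * theta - np.sum((1.0 - w / wtot) * loo)
    pseudo = h * theta - (h - 1.0) * loo
    var = np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / m
    return float(theta), float(np.sqrt(var)), loo


def _result(
    name: str,
    pops: tuple[str, ...],
    num: np.ndarray,
    den: np.ndarray,
    blocks: BlockPartition,
    unreliable: bool = False,
) -> FStatResult:
    value, se, loo = block_jackknife_ratio(num, den, blocks)
    z = value / se if se > 0 else 0.0
    return FStatResult(
        statistic=name,
        value=value,
        se=se,
        z=float(z),
        block_values=loo,
        populations=pops,
        n_loci=blocks.n_loci,
        n_blocks=blocks.n_blocks,
        unreliable=unreliable,
    )


def _het_correction(pop: PopulationFreqs) -> np.ndarray:
    """Unbiased correction for E[p̂²] − p²; zero for exact frequencies."""
    if pop.n < 2:
        return np.zeros_like(pop.p)
    return pop.p * (1.0 - pop.p) / (pop.n - 1)


def f3(
    target: PopulationFreqs,
    ref_a: PopulationFreqs,
    ref_b: PopulationFreqs,
    blocks: BlockPartition,
    normalize: bool = True,
) -> FStatResult:
    """f3(target; refA, refB) admixture test with block-jackknife Z.

    The target's sampled-frequency bias is removed with the unbiased
    ``c(1-c)/(n-1)`` correction; reference frequencies enter as point
    estimates.  With ``normalize`` the statistic is divided by the target's
    (corrected) heterozygosity, which leaves the sign and Z essentially
    unchanged but matches the scale convention of the standard estimator.
    """
    c, a, b = target.p, ref_a.p, ref_b.p
    num = (c - a) * (c - b) - _het_correction(target)
    if normalize:
        den = 2.0 * (c * (1.0 - c) + _het_correction(target))
    else:
        den = np.ones_like(num)
    if normalize and not np.any(den > 0):
        raise ValueError("f3 normalisation undefined: target monomorphic at every locus")
    return _result("f3", (target.name, ref_a.name, ref_b.name), num, den, blocks)


def f4(
    a: PopulationFreqs,
    b: PopulationFreqs,
    c: PopulationFreqs,
    d: PopulationFreqs,
    blocks: BlockPartition,
) -> FStatResult:
    """Plain f4(A, B; C, D) = mean over loci of (a-b)(c-d)."""
    num = (a.p - b.p) * (c.p - d.p)
    return _result("f4", (a.name, b.name, c.name, d.name), num, np.ones_like(num), blocks)


def d_stat(
    w: PopulationFreqs,
    x: PopulationFreqs,
    y: PopulationFreqs,
    z: PopulationFreqs,
    blocks: BlockPartition,
) -> FStatResult:
    """D statistic for the unrooted tree ((W, X), (Y, Z)).

    Positive values indicate shared drift between X and Z (or W and Y),
    i.e. gene flow breaking the tree in that direction.
    """
    names = {w.name, x.name, y.name, z.name}
    if len(names) < 4:
        raise ValueError("d_stat requires four distinct populations")
    num = (w.p - x.p) * (y.p - z.p)
    den = (w.p + x.p - 2 * w.p * x.p) * (y.p + z.p - 2 * y.p * z.p)
    if not np.any(den != 0):
        raise ZeroDivisionError("D denominator is zero at every locus")
    return _result("D", (w.name, x.name, y.name, z.name), num, den, blocks)


def f4_ratio(
    outgroup: PopulationFreqs,
    ref_a: PopulationFreqs,
    target: PopulationFreqs,
    proxy_source: PopulationFreqs,
    other_source: PopulationFreqs,
    blocks: BlockPartition,
) -> FStatResult:
    """Admixture-proportion estimate for the ``proxy_source`` side of the target.

    ``ref_a`` must be a reference related to ``proxy_source`` (a sister clade
    unaffected by the admixture); the outgroup may be monomorphic.  The
    jackknife is taken on the ratio itself.  If the denominator f4 is not
    clearly non-zero (|Z| < 3) the result is flagged unreliable.
    """
    num = (ref_a.p - outgroup.p) * (target.p - other_source.p)
    den = (ref_a.p - outgroup.p) * (proxy_source.p - other_source.p)
    den_check = _result(
        "f4", (ref_a.name, outgroup.name, proxy_source.name, other_source.name),
        den, np.ones_like(den), blocks,
    )
    unreliable = abs(den_check.z) < F4_DENOMINATOR_MIN_Z
    res = _result(
        "f4_ratio",
        (outgroup.name, ref_a.name, target.name, proxy_source.name, other_source.name),
        num, den, blocks, unreliable=unreliable,
    )
    return res


@dataclass
class AdmixtureBounds:
    """Bounds on the introgressing proportion from the second reference's side."""

    alpha_min: float
    alpha_max: float
    se_min: float
    se_max: float
    unreliable: bool

    def contains(self, alpha: float) -> bool:
        return self.alpha_min <= alpha <= self.alpha_max


def f3_bounds(
    target: PopulationFreqs,
    ref_a: PopulationFreqs,
    ref_b: PopulationFreqs,
    outgroup: PopulationFreqs,
    blocks: BlockPartition,
) -> AdmixtureBounds:
    """Lower/upper bounds on the refB-side admixture proportion of the target.

    The two bounds come from the two f4-ratio orientations, swapping which
    reference plays the mixing proxy:

    * lower: ``f4(refB, O; target, refA) / f4(refB, O; refB, refA)`` — the
      reference's private drift shrinks the ratio below the true proportion;
    * upper: ``1 − f4(refA, O; target, refB) / f4(refA, O; refA, refB)`` — the
      same shrinkage applied to the complementary proportion.

    Both ratios use the references themselves as proxy and sister, so each is
    conservative in the direction stated; the true proportion lies between
    them whenever the references flank the real sources.
    """
    lower = f4_ratio(outgroup, ref_b, target, ref_b, ref_a, blocks)
    upper_c = f4_ratio(outgroup, ref_a, target, ref_a, ref_b, blocks)
    lo, hi = lower.value, 1.0 - upper_c.value
    if lo > hi:  # sampling noise can invert; report ordered
        lo, hi = hi, lo
    return AdmixtureBounds(
        alpha_min=float(lo),
        alpha_max=float(hi),
        se_min=lower.se,
        se_max=upper_c.se,
        unreliable=lower.unreliable or upper_c.unreliable,
    )


def hudson_fst(
    a: PopulationFreqs, b: PopulationFreqs, blocks: BlockPartition | None = None
) -> FStatResult | float:
    """Hudson-type FST (ratio of averages) between two sampled populations.

    Per locus: numerator ``(p1-p2)² − p1(1-p1)/(n1-1) − p2(1-p2)/(n2-1)``,
    denominator ``p1(1-p2) + p2(1-p1)``.  With ``blocks`` a full jackknifed
    result is returned, otherwise the plain point estimate.
    """
    num = (a.p - b.p) ** 2 - _het_correction(a) - _het_correction(b)
    den = a.p * (1 - b.p) + b.p * (1 - a.p)
    if blocks is None:
        return float(num.sum() / den.sum())
    return _result("fst_hudson", (a.name, b.name), num, den, blocks)
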