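"""Ancestry partitioning and composite-chromosome construction.

Admixed genomes are split into segments of the two contributing ancestries
(here "A" and "B", e.g. non-African and African) and ancestry-specific
pseudo-panels are assembled so that population structure can be analysed
separately within each ancestry.

The built-in painter is deliberately simple: the genome is tiled into
fixed-size windows of phased loci and each window is scored under a
product-Bernoulli likelihood for the two donor allele-frequency profiles,
giving a two-class posterior with a uniform prior.  Externally produced
segment posteriors (from an HMM-based painter) can be imported instead via
:func:`segment_posterior_from_table`; downstream steps only see posteriors.

Windows at or above the confidence threshold (0.8 by default) are assigned
their ancestry.  Composite panels then sample exactly ``k`` (default 12)
assigned allele observations per locus per ancestry per population, without
replacement, dropping loci with insufficient depth, and the retained locus
set is intersected across all population × ancestry cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import COMPOSITE_K, PAINT_CONFIDENCE, PAINT_WINDOW_LOCI
from .sources import GeneticMap, HaplotypePanel

__all__ = [
    "SegmentPosterior",
    "SegmentAssignment",
    "CompositePanel",
    "IntersectionResult",
    "paint_windows",
    "threshold_segments",
    "assemble_composite",
    "intersect_sites",
    "segment_posterior_from_table",
]


@dataclass
class SegmentPosterior:
    """Per-haploid, per-window posterior of the first ("A") ancestry class.

    ``windows`` holds (chrom, start_locus, end_locus) index ranges, end
    exclusive; ``p_a`` has shape (n_haploids, n_windows).
    """

    windows: pd.DataFrame
    p_a: np.ndarray
    class_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.p_a = np.asarray(self.p_a, dtype=float)
        if np.any((self.p_a < 0) | (self.p_a > 1)):
            raise ValueError("posteriors must lie in [0, 1]")
        if self.p_a.shape[1] != len(self.windows):
            raise ValueError("posterior matrix must have one column per window")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_haploids(self) -> int:
        return self.p_a.shape[0]


@dataclass
class SegmentAssignment:
    """Thresholded window calls: 0 = class A, 1 = class B, -1 = unassigned."""

    windows: pd.DataFrame
    labels: np.ndarray  # (n_haploids, n_windows) int8
    confidence: float

    @property
    def assigned_fraction(self) -> float:
        return float(np.mean(self.labels >= 0))

    def locus_labels(self, n_loci: int) -> np.ndarray:
        """Expand window calls to per-locus labels (-1 outside assigned windows)."""
        out = np.full((self.labels.shape[0], n_loci), -1, dtype=np.int8)
        for w, (start, end) in enumerate(
            zip(self.windows["start_locus"], self.windows["end_locus"])
        ):
            out[:, start:end] = self.labels[:, [w]]
        return out


@dataclass
class CompositePanel:
    """Fixed-depth composite chromosomes for one population × ancestry cell.

    Exactly ``k`` alleles per retained locus, sampled from ancestry-assigned
    observations.  Rows are artificial haplotypes: their along-chromosome
    structure is meaningless and only per-locus frequencies should be used.
    """

    population: str
    ancestry: str
    alleles: np.ndarray  # (k, n_retained)
    locus_indices: np.ndarray  # indices into the original map

    @property
    def k(self) -> int:
        return self.alleles.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def reindex(self, locus_subset: np.ndarray) -> "CompositePanel":
        """Restrict to ``locus_subset`` (original-map indices, must be retained)."""
        lookup = {int(l): i for i, l in enumerate(self.locus_indices)}
        cols = np.array([lookup[int(l)] for l in locus_subset], dtype=int)
        return CompositePanel(
            population=self.population,
            ancestry=self.ancestry,
            alleles=self.alleles[:, cols],
            locus_indices=np.asarray(locus_subset),
        )

    def to_haplotype_panel(self) -> HaplotypePanel:
        return HaplotypePanel(
            population=f"{self.population}.{self.ancestry}",
            haplotypes=self.alleles,
        )


def _tile_windows(genetic_map: GeneticMap, window_loci: int) -> pd.DataFrame:
    rows = []
    for chrom, idx in genetic_map.chromosome_indices():
        start = idx[0]
        stop = idx[-1] + 1
        for s in range(start, stop, window_loci):
            rows.append((chrom, s, min(s + window_loci, stop)))
    return pd.DataFrame(rows, columns=["chrom", "start_locus", "end_locus"])


def paint_windows(
    target: HaplotypePanel,
    donor_a_freq: np.ndarray,
    donor_b_freq: np.ndarray,
    genetic_map: GeneticMap,
    window_loci: int = PAINT_WINDOW_LOCI,
) -> SegmentPosterior:
    """Window-based two-donor painting of a phased panel.

    Each non-overlapping window of ``window_loci`` loci is scored with the
    product-Bernoulli log-likelihood of the haplotype under each donor's
    allele frequencies; the posterior uses a uniform prior.  Donor
    frequencies of exactly 0 or 1 are honoured (a conflicting allele gives
    -inf); windows impossible under both donors fall back to a uniform
    posterior with a warning.
    """
    if window_loci < 5:
        raise ValueError("window_loci must be >= 5")
    pa = np.asarray(donor_a_freq, dtype=float)
    pb = np.asarray(donor_b_freq, dtype=float)
    if len(pa) != genetic_map.n_loci or len(pb) != genetic_map.n_loci:
        raise ValueError("donor frequencies must match the map")
    H = target.haplotypes.astype(np.float64)

    def loglik(p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            l1 = np.log(p)
            l0 = np.log1p(-p)
        ll = np.where(H == 1, l1[None, :], l0[None, :])
        return np.nan_to_num(ll, nan=-np.inf, neginf=-np.inf)

    lla, llb = loglik(pa), loglik(pb)
    windows = _tile_windows(genetic_map, window_loci)
    post = np.empty((target.n_haplotypes, len(windows)))
    n_impossible = 0
    for w, (s, e) in enumerate(zip(windows["start_locus"], windows["end_locus"])):
        wa = lla[:, s:e].sum(axis=1)
        wb = llb[:, s:e].sum(axis=1)
        both_dead = np.isneginf(wa) & np.isneginf(wb)
        n_impossible += int(both_dead.sum())
        m = np.maximum(wa, wb)
        with np.errstate(invalid="ignore"):
            pw = np.exp(wa - m) / (np.exp(wa - m) + np.exp(wb - m))
        pw = np.where(np.isneginf(wa) & ~np.isneginf(wb), 0.0, pw)
        pw = np.where(~np.isneginf(wa) & np.isneginf(wb), 1.0, pw)
        pw = np.where(both_dead, 0.5, pw)
        post[:, w] = pw
    if n_impossible:
        warnings.warn(
            f"{n_impossible} window(s) had zero likelihood under both donors; "
            "posterior set to 0.5",
            stacklevel=2,
        )
    return SegmentPosterior(windows=windows, p_a=post)


def segment_posterior_from_table(
    table: pd.DataFrame, genetic_map: GeneticMap
) -> SegmentPosterior:
    """Import externally painted segments.

    ``table`` columns: haploid, chrom, start_locus, end_locus (end exclusive,
    indices into the map), p_a.  Segment boundaries must agree across
    haploids (a common tiling).
    """
    key = ["chrom", "start_locus", "end_locus"]
    windows = table[key].drop_duplicates().sort_values(key).reset_index(drop=True)
    wid = {tuple(r): i for i, r in enumerate(windows.itertuples(index=False))}
    n_hap = int(table["haploid"].max()) + 1
    post = np.full((n_hap, len(windows)), 0.5)
    for row in table.itertuples(index=False):
        post[int(row.haploid), wid[(row.chrom, row.start_locus, row.end_locus)]] = row.p_a
    return SegmentPosterior(windows=windows, p_a=post)


def threshold_segments(
    post: SegmentPosterior, confidence: float = PAINT_CONFIDENCE
) -> SegmentAssignment:
    """Assign windows whose posterior reaches ``confidence`` for either class."""
    if not (0.5 < confidence <= 1.0):
        raise ValueError("confidence must lie in (0.5, 1]")
    labels = np.full(post.p_a.shape, -1, dtype=np.int8)
    labels[post.p_a >= confidence] = 0
    labels[1.0 - post.p_a >= confidence] = 1
    return SegmentAssignment(windows=post.windows, labels=labels, confidence=confidence)


def assemble_composite(
    panel: HaplotypePanel,
    assignment: SegmentAssignment,
    k: int = COMPOSITE_K,
    seed: int = 0,
    ancestry_names: tuple[str, str] = ("A", "B"),
) -> list[CompositePanel]:
    """Sample ``k`` assigned alleles per locus per ancestry into composite rows.

    Loci with fewer than ``k`` assigned observations for an ancestry are
    dropped for that population × ancestry cell (they feed the later site
    intersection).  Sampling is without replacement; row order within a locus
    is the random sample order, so composite rows have no haplotype meaning.
    """
    rng = np.random.default_rng(seed)
    locus_lab = assignment.locus_labels(panel.n_loci)
    out = []
    for cls, name in enumerate(ancestry_names):
        mask = locus_lab == cls  # (H, L)
        depth = mask.sum(axis=0)
        retained = np.flatnonzero(depth >= k)
        alleles = np.empty((k, len(retained)), dtype=np.int8)
        for j, loc in enumerate(retained):
            obs = panel.haplotypes[mask[:, loc], loc]
            take = rng.choice(len(obs), size=k, replace=False)
            alleles[:, j] = obs[take]
        out.append(
            CompositePanel(
                population=panel.population,
                ancestry=name,
                alleles=alleles,
                locus_indices=retained,
            )
        )
    return out


@dataclass
class IntersectionResult:
    """Composite panels re-indexed to the loci retained by every cell."""

    panels: list[CompositePanel]
    locus_indices: np.ndarray
    empty: bool

    @property
    def n_loci(self) -> int:
        return len(self.locus_indices)


def intersect_sites(panels: list[CompositePanel]) -> IntersectionResult:
    """Retain only loci present in every population × ancestry cell."""
    if not panels:
        raise ValueError("need at least one composite panel")
    common: np.ndarray | None = None
    for p in panels:
        common = (
            p.locus_indices
            if common is None
            else np.intersect1d(common, p.locus_indices)
        )
    if common is None or len(common) == 0:
        return IntersectionResult(panels=[], locus_indices=np.array([], dtype=int), empty=True)
    return IntersectionResult(
        panels=[p.reindex(common) for p in panels],
        locus_indices=common,
        empty=False,
    )
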