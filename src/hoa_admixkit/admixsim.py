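"""Episodic (pulse) admixture simulation with true local-ancestry tracks.

A pulse at ``lambda_gens`` generations before present is simulated by laying
down ancestry transition events along each chromosome: between consecutive
loci separated by ``g`` Morgans an event occurs with probability
``1 - exp(-lambda * g)``, and the ancestry of each inter-event segment is
drawn independently — source B with probability ``alpha``, source A otherwise.
Alleles are copied from one template haplotype per source.  The marginal
introgressed proportion is therefore exactly ``alpha`` at every locus, and the
ancestry autocorrelation at map distance ``d`` is ``exp(-lambda * d)`` — the
decay the weighted-LD dating module recovers.

Two-episode scenarios feed the first pulse's output pool in as the A-side
template pool of the second pulse, mirroring a layered admixture history; the
expected final B fraction is ``alpha1 + (1 - alpha1) * alpha0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sources import GeneticMap, HaplotypePanel

__all__ = [
    "AdmixtureScenario",
    "AncestryTrack",
    "AdmixedCohort",
    "simulate_pulse",
    "simulate_two_episode",
    "pair_into_diploids",
    "ancestry_autocorrelation",
    "fit_autocorrelation_rate",
]

#: Size of the intermediate haploid pool between the two episodes.
DEFAULT_INTERMEDIATE_POOL = 40


@dataclass(frozen=True)
class AdmixtureScenario:
    """Two-episode admixture history.

    ``lambda0``/``alpha0`` describe the older pulse (generations before
    present, introgressing proportion), ``lambda1``/``alpha1`` the more recent
    one.  ``n_out`` is the number of output diploid individuals.
    """

    lambda0: float
    lambda1: float
    alpha0: float
    alpha1: float
    n_out: int = 20

    def __post_init__(self) -> None:
        if not (self.lambda0 >= self.lambda1 >= 0):
            raise ValueError("require lambda0 >= lambda1 >= 0")
        for a in (self.alpha0, self.alpha1):
            if not (0.0 <= a <= 1.0):
                raise ValueError("admixture proportions must lie in [0, 1]")
        if self.n_out < 1:
            raise ValueError("n_out must be >= 1")

    @property
    def expected_b_fraction(self) -> float:
        """Closed-form final introgressed fraction: alpha1 + (1-alpha1)*alpha0."""
        return self.alpha1 + (1.0 - self.alpha1) * self.alpha0


@dataclass
class AncestryTrack:
    """Per-haploid, per-locus source labels (0 = A side, 1 = B side)."""

    labels: np.ndarray  # (n_haploids, n_loci) uint8
    genetic_map: GeneticMap

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape[1] != self.genetic_map.n_loci:
            raise ValueError("track must cover every map locus")

    @property
    def n_haploids(self) -> int:
        return self.labels.shape[0]

    def mean_b_fraction(self) -> np.ndarray:
        """Introgressed (B) fraction per haploid."""
        return self.labels.mean(axis=1)

    def segments(self) -> pd.DataFrame:
        """Contiguous constant-ancestry runs: haploid, chrom, start/end locus index, ancestry."""
        starts = self.genetic_map.chromosome_starts()
        rows = []
        for h in range(self.n_haploids):
            lab = self.labels[h]
            brk = np.flatnonzero(starts | np.r_[True, lab[1:] != lab[:-1]])
            ends = np.r_[brk[1:], len(lab)]
            for s, e in zip(brk, ends):
                rows.append(
                    (h, int(self.genetic_map.chromosome[s]), int(s), int(e - 1), int(lab[s]))
                )
        return pd.DataFrame(
            rows, columns=["haploid", "chrom", "start_locus", "end_locus", "ancestry"]
        )


@dataclass
class AdmixedCohort:
    """Admixed haploid panel plus its truth track and optional diploid pairing."""

    panel: HaplotypePanel
    track: AncestryTrack
    diploid_pairs: np.ndarray | None = None  # (n_diploids, 2) haploid indices
    transition_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.panel.haplotypes.shape != self.track.labels.shape:
            raise ValueError("panel and track must align")
        if self.diploid_pairs is not None:
            pairs = np.asarray(self.diploid_pairs)
            used = pairs.ravel()
            if len(np.unique(used)) != len(used):
                raise ValueError("each haploid may be used in exactly one diploid")
            self.diploid_pairs = pairs

    @property
    def n_haploids(self) -> int:
        return self.panel.n_haplotypes

    def diploid_genotypes(self) -> np.ndarray:
        """(n_diploids, n_loci) genotype dosages 0/1/2."""
        if self.diploid_pairs is None:
            raise ValueError("cohort has no diploid pairing")
        h = self.panel.haplotypes
        return (
            h[self.diploid_pairs[:, 0]].astype(np.int16)
            + h[self.diploid_pairs[:, 1]]
        )

    def diploid_b_fraction(self) -> np.ndarray:
        """Introgressed-ancestry fraction per diploid individual."""
        if self.diploid_pairs is None:
            raise ValueError("cohort has no diploid pairing")
        frac = self.track.mean_b_fraction()
        return frac[self.diploid_pairs].mean(axis=1)


def _simulate_haploids(
    source_a: np.ndarray,
    source_b: np.ndarray,
    genetic_map: GeneticMap,
    lambda_gens: float,
    alpha: float,
    n_haploids: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core pulse mechanism.

    Returns (alleles, labels, event counts per haploid, A-side template index
    per haploid).
    """
    n_loci = genetic_map.n_loci
    gaps = genetic_map.inter_locus_distances()
    p_event = 1.0 - np.exp(-lambda_gens * gaps)
    chrom_start = genetic_map.chromosome_starts()

    templ_a = rng.integers(0, source_a.shape[0], size=n_haploids)
    templ_b = rng.integers(0, source_b.shape[0], size=n_haploids)

    events = rng.random((n_haploids, n_loci)) < p_event[None, :]
    events[:, chrom_start] = False
    n_events = events.sum(axis=1)

    # A fresh ancestry draw happens at every chromosome start and every event;
    # forward-fill the draw made at the most recent segment start.
    seg_start = events | chrom_start[None, :]
    draws = rng.random((n_haploids, n_loci)) < alpha
    col = np.arange(n_loci)[None, :]
    last_start = np.maximum.accumulate(np.where(seg_start, col, 0), axis=1)
    labels = np.take_along_axis(draws, last_start, axis=1).astype(np.uint8)

    alleles = np.where(labels == 1, source_b[templ_b], source_a[templ_a]).astype(np.int8)
    return alleles, labels, n_events, templ_a


def simulate_pulse(
    source_a: HaplotypePanel,
    source_b: HaplotypePanel,
    genetic_map: GeneticMap,
    lambda_gens: float,
    alpha: float,
    n_haploids: int,
    seed: int,
    population: str = "admixed",
) -> AdmixedCohort:
    """Single admixture pulse ``lambda_gens`` generations ago with proportion ``alpha``.

    One template haplotype is drawn (uniformly, with replacement) from each
    source pool per output haploid; alleles are copied from the A or B template
    according to the segment's ancestry label.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if lambda_gens < 0:
        raise ValueError("lambda_gens must be >= 0")
    if source_a.n_loci != genetic_map.n_loci or source_b.n_loci != genetic_map.n_loci:
        raise ValueError("source panels must match the map's locus set")
    rng = np.random.default_rng(seed)
    alleles, labels, n_events, _ = _simulate_haploids(
        source_a.haplotypes, source_b.haplotypes, genetic_map, lambda_gens, alpha,
        n_haploids, rng,
    )
    return AdmixedCohort(
        panel=HaplotypePanel(population=population, haplotypes=alleles),
        track=AncestryTrack(labels=labels, genetic_map=genetic_map),
        transition_counts=n_events,
    )


def simulate_two_episode(
    source_a: HaplotypePanel,
    source_b_first: HaplotypePanel,
    source_b_second: HaplotypePanel,
    genetic_map: GeneticMap,
    scenario: AdmixtureScenario,
    seed: int,
    intermediate_haploids: int = DEFAULT_INTERMEDIATE_POOL,
    population: str = "admixed",
) -> AdmixedCohort:
    """Two layered pulses: an old pulse (lambda0, alpha0) then a recent one
    (lambda1, alpha1) drawing its A-side templates from the first pulse's output.

    The two B-side donor pools should be disjoint haplotype sets.  Output
    haploids are paired randomly into ``scenario.n_out`` diploids; the truth
    track merges both episodes (a locus is labelled B if it traces to either
    donor pool).
    """
    rng = np.random.default_rng(seed)
    s0 = int(rng.integers(2**31))
    s1 = int(rng.integers(2**31))
    s2 = int(rng.integers(2**31))

    episode1 = simulate_pulse(
        source_a, source_b_first, genetic_map,
        scenario.lambda0, scenario.alpha0, intermediate_haploids, seed=s0,
        population=population,
    )

    rng1 = np.random.default_rng(s1)
    n_final = 2 * scenario.n_out
    alleles, labels2, n_events, templ_a = _simulate_haploids(
        episode1.panel.haplotypes, source_b_second.haplotypes, genetic_map,
        scenario.lambda1, scenario.alpha1, n_final, rng1,
    )
    # merge tracks: loci copied from the second donor pool are B; loci copied
    # from an episode-1 template inherit that template's episode-1 ancestry
    merged = np.where(labels2 == 1, 1, episode1.track.labels[templ_a]).astype(np.uint8)

    pairs = pair_into_diploids(n_final, seed=s2)
    return AdmixedCohort(
        panel=HaplotypePanel(population=population, haplotypes=alleles),
        track=AncestryTrack(labels=merged, genetic_map=genetic_map),
        diploid_pairs=pairs,
        transition_counts=n_events,
    )


def pair_into_diploids(n_haploids: int, seed: int) -> np.ndarray:
    """Random perfect matching of haploid indices into diploids; deterministic under seed."""
    if n_haploids % 2 != 0:
        raise ValueError("haploid count must be even to pair into diploids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_haploids)
    return order.reshape(-1, 2)


def ancestry_autocorrelation(
    track: AncestryTrack,
    max_dist: float = 0.1,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Binned autocorrelation of the ancestry indicator vs map distance.

    Under the pulse model the correlation at distance ``d`` is exp(-lambda*d),
    so a regression of log correlation on distance recovers the pulse time.
    Returns a frame with bin centre ``d`` and correlation ``r``.
    """
    gmap = track.genetic_map
    cross = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    edges = np.linspace(0.0, max_dist, n_bins + 1)

    x = track.labels.astype(np.float64)
    xc = x - x.mean(axis=0, keepdims=True)
    sd = xc.std(axis=0)
    ok = sd > 0
    for _, idx in gmap.chromosome_indices():
        idx = idx[ok[idx]]
        if len(idx) < 2:
            continue
        pos = gmap.position_morgans[idx]
        z = xc[:, idx] / sd[None, idx]
        n = z.shape[0]
        corr = z.T @ z / n
        d = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(idx), k=1)
        dv, cv = d[iu], corr[iu]
        keep = dv <= max_dist
        b = np.minimum(np.digitize(dv[keep], edges) - 1, n_bins - 1)
        np.add.at(cross, b, cv[keep])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        r = cross / counts
    centres = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"d": centres, "r": r, "n_pairs": counts})


def fit_autocorrelation_rate(acorr: pd.DataFrame, min_r: float = 0.02) -> float:
    """Slope of -log(r) on d over bins with positive correlation above ``min_r``."""
    ok = (acorr["r"] > min_r) & (acorr["n_pairs"] > 0)
    d = acorr.loc[ok, "d"].to_numpy()
    logr = np.log(acorr.loc[ok, "r"].to_numpy())
    if len(d) < 3:
        raise ValueError("too few usable bins to fit a decay rate")
    slope = np.polyfit(d, logr, 1)[0]
    return float(-slope)
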