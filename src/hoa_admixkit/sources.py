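"""Synthetic source populations: drift trees, allele frequencies, haplotype panels.

Diverged source populations are generated by propagating allele frequencies down
a rooted tree under the Balding–Nichols model: a child population's frequency is
drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) given its parent's frequency ``p`` and
the per-edge drift coefficient ``F``, which has mean ``p`` and variance
``F p (1-p)``.  Loci are simulated independently (no background LD), so any LD
observed in downstream admixed cohorts is admixture LD by construction.

Haplotype panels are binomial draws from the leaf frequencies, aligned to a
multi-chromosome genetic map whose positions are in Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "DriftTree",
    "FrequencyTable",
    "HaplotypePanel",
    "simulate_drift_frequencies",
    "simulate_panel",
    "simulate_panels",
    "make_genetic_map",
    "allele_frequencies",
]

#: Default ancestral-frequency window.  Uniform(0.05, 0.95) avoids monomorphic
#: loci, matching common-SNP genotyping arrays.
ROOT_FREQ_LOW = 0.05
ROOT_FREQ_HIGH = 0.95

#: bp per Morgan used when synthesising physical positions (1 cM ~ 1 Mb).
BP_PER_MORGAN = 100_000_000


@dataclass(frozen=True)
class GeneticMap:
    """Per-locus chromosome assignment and genetic position in Morgans.

    Positions must be strictly increasing within each chromosome.  Physical
    positions (bp) are optional and synthesised at 1 cM/Mb when absent.
    """

    locus_id: np.ndarray
    chromosome: np.ndarray
    position_morgans: np.ndarray
    position_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "locus_id", np.asarray(self.locus_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=np.int64))
        object.__setattr__(
            self, "position_morgans", np.asarray(self.position_morgans, dtype=float)
        )
        if len(self.locus_id) != len(self.chromosome) or len(self.locus_id) != len(
            self.position_morgans
        ):
            raise ValueError("locus_id, chromosome and position arrays must align")
        if np.any(self.position_morgans < 0):
            raise ValueError("genetic positions must be non-negative")
        for _, idx in self.chromosome_indices():
            pos = self.position_morgans[idx]
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")
        if self.position_bp is None:
            object.__setattr__(
                self,
                "position_bp",
                np.rint(self.position_morgans * BP_PER_MORGAN).astype(np.int64),
            )
        else:
            object.__setattr__(
                self, "position_bp", np.asarray(self.position_bp, dtype=np.int64)
            )

    @property
    def n_loci(self) -> int:
        return len(self.locus_id)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome labels in order of first appearance."""
        _, first = np.unique(self.chromosome, return_index=True)
        return self.chromosome[np.sort(first)]

    def chromosome_indices(self) -> Iterator[tuple[int, np.ndarray]]:
        """Yield ``(chromosome, locus index array)`` pairs in map order."""
        for chrom in self.chromosomes:
            yield int(chrom), np.flatnonzero(self.chromosome == chrom)

    def chromosome_starts(self) -> np.ndarray:
        """Boolean mask marking the first locus of each chromosome."""
        start = np.zeros(self.n_loci, dtype=bool)
        start[0] = True
        start[1:] = self.chromosome[1:] != self.chromosome[:-1]
        return start

    def inter_locus_distances(self) -> np.ndarray:
        """Map distance (Morgans) from the previous locus; 0 at chromosome starts."""
        d = np.zeros(self.n_loci)
        d[1:] = np.diff(self.position_morgans)
        d[self.chromosome_starts()] = 0.0
        return d

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        indices = np.asarray(indices)
        return GeneticMap(
            locus_id=self.locus_id[indices],
            chromosome=self.chromosome[indices],
            position_morgans=self.position_morgans[indices],
            position_bp=self.position_bp[indices],
        )


@dataclass
class DriftTree:
    """Rooted population tree with a Balding–Nichols drift coefficient per edge.

    ``f`` is the drift on the edge above this node (ignored at the root).
    Leaves carry population labels; internal nodes may be anonymous.
    """

    name: str
    f: float = 0.0
    children: list["DriftTree"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.f < 1.0):
            raise ValueError(f"drift coefficient must lie in [0, 1), got {self.f}")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["DriftTree"]:
        if self.is_leaf:
            return [self]
        out: list[DriftTree] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    @classmethod
    def from_dict(cls, spec: Mapping) -> "DriftTree":
        """Build from a nested mapping: ``{"name": ..., "f": ..., "children": [...]}``."""
        children = [cls.from_dict(c) for c in spec.get("children", [])]
        return cls(name=str(spec.get("name", "")), f=float(spec.get("f", 0.0)), children=children)

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "f": self.f}
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def star(cls, names: Sequence[str], f: float | Sequence[float]) -> "DriftTree":
        """Star tree: every leaf hangs directly off the root with drift ``f``."""
        fs = np.broadcast_to(np.asarray(f, dtype=float), (len(names),))
        return cls(name="root", children=[cls(name=n, f=fi) for n, fi in zip(names, fs)])


@dataclass
class FrequencyTable:
    """Per-population, per-locus allele frequencies with sample sizes.

    ``n_chromosomes`` is the number of sampled chromosomes behind each
    population's frequencies; ``0`` marks exact (parametric) frequencies.
    """

    populations: list[str]
    freq: np.ndarray  # (n_pops, n_loci)
    n_chromosomes: np.ndarray  # (n_pops,)
    locus_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_chromosomes = np.asarray(self.n_chromosomes, dtype=np.int64)
        if self.freq.ndim != 2 or self.freq.shape[0] != len(self.populations):
            raise ValueError("freq must be (n_pops, n_loci)")
        if np.any(self.freq < 0) or np.any(self.freq > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.freq.shape[1]

    def __getitem__(self, population: str) -> np.ndarray:
        return self.freq[self.populations.index(population)]

    def n_for(self, population: str) -> int:
        return int(self.n_chromosomes[self.populations.index(population)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: population, locus, freq, n."""
        loci = (
            self.locus_id
            if self.locus_id is not None
            else np.array([f"L{i}" for i in range(self.n_loci)], dtype=object)
        )
        rows = []
        for i, pop in enumerate(self.populations):
            rows.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "locus": loci,
                        "freq": self.freq[i],
                        "n": int(self.n_chromosomes[i]),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FrequencyTable":
        pops = list(dict.fromkeys(frame["population"]))
        wide = frame.pivot(index="population", columns="locus", values="freq").loc[pops]
        # preserve original locus order
        loci = list(dict.fromkeys(frame["locus"]))
        wide = wide[loci]
        n = frame.groupby("population")["n"].first().loc[pops].to_numpy()
        return cls(
            populations=pops,
            freq=wide.to_numpy(),
            n_chromosomes=n,
            locus_id=np.asarray(loci, dtype=object),
        )


@dataclass
class HaplotypePanel:
    """Phased 0/1 alleles for one population: rows = haploid genomes, cols = loci."""

    population: str
    haplotypes: np.ndarray  # (n_haplotypes, n_loci) in {0, 1}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("panel entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def _draw_balding_nichols(
    rng: np.random.Generator, parent: np.ndarray, f: float
) -> np.ndarray:
    """One step of Balding–Nichols drift; F = 0 is an exact copy."""
    if f == 0.0:
        return parent.copy()
    scale = (1.0 - f) / f
    # guard exact 0/1 parents: Beta parameters of 0 are undefined; a fixed
    # parent stays fixed under pure drift
    child = np.empty_like(parent)
    fixed = (parent <= 0.0) | (parent >= 1.0)
    child[fixed] = parent[fixed]
    free = ~fixed
    if np.any(free):
        child[free] = rng.beta(parent[free] * scale, (1.0 - parent[free]) * scale)
    return child


def simulate_drift_frequencies(
    tree: DriftTree,
    n_loci: int,
    seed: int,
    root_low: float = ROOT_FREQ_LOW,
    root_high: float = ROOT_FREQ_HIGH,
) -> FrequencyTable:
    """Propagate ancestral frequencies down ``tree`` and return leaf frequencies.

    The ancestral frequency at each locus is Uniform(``root_low``, ``root_high``);
    each edge applies one Balding–Nichols drift step with its own ``F``.
    Sample sizes are recorded as 0 (exact frequencies).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(root_low, root_high, size=n_loci)

    leaf_freqs: dict[str, np.ndarray] = {}

    def descend(node: DriftTree, freq: np.ndarray) -> None:
        if node.is_leaf:
            if node.name in leaf_freqs:
                raise ValueError(f"duplicate leaf name {node.name!r}")
            leaf_freqs[node.name] = freq
            return
        for child in node.children:
            descend(child, _draw_balding_nichols(rng, freq, child.f))

    descend(tree, ancestral)
    pops = tree.leaf_names()
    return FrequencyTable(
        populations=pops,
        freq=np.vstack([leaf_freqs[p] for p in pops]),
        n_chromosomes=np.zeros(len(pops), dtype=np.int64),
    )


def simulate_panel(
    freqs: FrequencyTable,
    n_haplotypes: int,
    genetic_map: GeneticMap,
    seed: int,
    population: str | None = None,
) -> HaplotypePanel:
    """Draw a phased panel for one population by independent Bernoulli sampling.

    Loci are independent: reference panels carry no background LD, so admixture
    alone creates LD downstream.
    """
    if n_haplotypes < 1:
        raise ValueError("n_haplotypes must be >= 1")
    if population is None:
        if len(freqs.populations) != 1:
            raise ValueError("population must be named when the table has several")
        population = freqs.populations[0]
    p = freqs[population]
    if len(p) != genetic_map.n_loci:
        raise ValueError(
            f"frequency table has {len(p)} loci but map has {genetic_map.n_loci}"
        )
    rng = np.random.default_rng(seed)
    hap = (rng.random((n_haplotypes, len(p))) < p[None, :]).astype(np.int8)
    return HaplotypePanel(population=population, haplotypes=hap)


def simulate_panels(
    freqs: FrequencyTable,
    n_haplotypes: int | Mapping[str, int],
    genetic_map: GeneticMap,
    seed: int,
) -> dict[str, HaplotypePanel]:
    """Panels for every population in ``freqs``; seeds derived deterministically."""
    seeds = np.random.SeedSequence(seed).spawn(len(freqs.populations))
    out = {}
    for pop, sub in zip(freqs.populations, seeds):
        n = n_haplotypes[pop] if isinstance(n_haplotypes, Mapping) else n_haplotypes
        out[pop] = simulate_panel(
            freqs, n, genetic_map, seed=sub.generate_state(1)[0] % (2**31), population=pop
        )
    return out


def make_genetic_map(
    n_chromosomes: int,
    length_morgans: float,
    n_loci: int,
    spacing: str = "uniform",
    seed: int | None = None,
) -> GeneticMap:
    """Multi-chromosome map with ``n_loci`` split as evenly as possible.

    ``length_morgans`` is the length of each chromosome.  ``spacing`` is
    ``"uniform"`` (equal gaps spanning [0, length]) or ``"random"`` (sorted
    uniform draws).  Per-chromosome locus counts differ by at most one.
    """
    if length_morgans <= 0:
        raise ValueError("length_morgans must be positive")
    if n_loci < 2:
        raise ValueError("n_loci must be >= 2")
    if spacing not in ("uniform", "random"):
        raise ValueError("spacing must be 'uniform' or 'random'")
    rng = np.random.default_rng(seed)
    counts = np.full(n_chromosomes, n_loci // n_chromosomes, dtype=int)
    counts[: n_loci % n_chromosomes] += 1

    chroms, positions, ids = [], [], []
    for c, count in enumerate(counts, start=1):
        if spacing == "uniform":
            pos = np.linspace(0.0, length_morgans, count)
        else:
            pos = np.sort(rng.uniform(0.0, length_morgans, size=count))
            # enforce strict monotonicity in the (measure-zero) event of ties
            while np.any(np.diff(pos) <= 0):
                pos = np.sort(rng.uniform(0.0, length_morgans, size=count))
        chroms.append(np.full(count, c))
        positions.append(pos)
        ids.extend(f"chr{c}_snp{i}" for i in range(count))
    return GeneticMap(
        locus_id=np.asarray(ids, dtype=object),
        chromosome=np.concatenate(chroms),
        position_morgans=np.concatenate(positions),
    )


def allele_frequencies(panels: Sequence[HaplotypePanel]) -> FrequencyTable:
    """Sample allele-frequency estimates (with chromosome counts) from panels."""
    pops = [p.population for p in panels]
    if len(set(pops)) != len(pops):
        raise ValueError("panels must have distinct population labels")
    return FrequencyTable(
        populations=pops,
        freq=np.vstack([p.frequencies() for p in panels]),
        n_chromosomes=np.array([p.n_haplotypes for p in panels]),
    )
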