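# hoa-admixkit

A desk-scale toolkit for admixture analysis of SNP panels, built around the
computational chain used to dissect layered admixture histories in
Horn-of-Africa and Middle-East/North-Africa populations: simulate diverged
sources and episodic (pulse) admixture with known truth, test for admixture
with f-statistics, date it from weighted admixture-LD decay, partition
admixed genomes by ancestry into fixed-depth composite panels, and analyse
population structure within each ancestry with gene identity, Mantel tests,
AMOVA and hierarchical tree models.

It is written for population geneticists who want the whole pipeline as
inspectable, testable Python — every estimator exercised end-to-end against
generative models with known parameters — rather than as a chain of external
binaries.

## The statistics at its core

* **f3 admixture test** — `f3(C; A, B) = E[(c−a)(c−b)] − ĉ(1−ĉ)/(n−1)`;
  significantly negative values (block-jackknife Z < −4) demonstrate
  admixture in C. Admixture-proportion bounds follow from the two f4-ratio
  orientations with an outgroup.
* **D statistic** — `D = Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz)` for the unrooted
  tree ((W,X),(Y,Z)); positive Z > 4 indicates gene flow between X and Z.
* **f4-ratio** — `α̂ = f4(A,O; X,C) / f4(A,O; B,C)`, the admixture proportion
  of X from the B side.
* **Weighted admixture LD** — the covariance of SNP-pair LD weighted by
  reference allele-frequency differences decays as `A·e^(−n·d)` with genetic
  distance `d` (Morgans); the rate `n` is the admixture date in generations
  (× 30 years/generation). Dual-pulse fits `A·e^(−n·d) + A₂·e^(−n₂·d)` are
  compared by a nested F-test plus a jackknife-consistency requirement.
* **Two-episode pulse simulator** — ancestry transition events are laid down
  with probability `1 − e^(−λg)` per inter-locus gap and segment ancestries
  drawn with probability α; a second pulse layers on top of the first,
  letting you measure how recent admixture masks ancient admixture in
  single-pulse dating.
* **Population structure** — gene identity `J` (probability two random
  alleles match), `FST = (J_W − J_B)/(1 − J_B)`, three-level AMOVA with
  `Φ_GT` and population-label permutation, Mantel tests with optional
  waypoint-routed great-circle distances, and Long–Kittles-style
  hierarchical tree models with chi-square goodness-of-fit Λ and nested
  improvement K. Divergence times from `t = −2·Ne·ln(1−FST)` generations
  (Ne = 5,000, 30 y/gen by default).

See `docs/methods.md` for derivations, defaults and limitations.

## Worked example

Simulate two sources at FST ≈ 0.15, admix them 50 generations ago (20%
introgression, 20 diploids, 30,000 SNPs on 10 × 1-Morgan chromosomes), test
and date:

```python
import numpy as np
from hoa_admixkit import (
    DriftTree, HaplotypePanel, make_genetic_map, simulate_drift_frequencies,
    simulate_panels, simulate_pulse, pair_into_diploids, BlockPartition,
    PopulationFreqs, f3, compute_weighted_ld, fit_single,
)

gmap = make_genetic_map(n_chromosomes=10, length_morgans=1.0, n_loci=30_000, seed=0)
tree = DriftTree.star(["AFR", "EUR"], f=0.15)
freqs = simulate_drift_frequencies(tree, n_loci=30_000, seed=1)
panels = simulate_panels(freqs, n_haplotypes=280, genetic_map=gmap, seed=2)

cohort = simulate_pulse(
    HaplotypePanel("EUR", panels["EUR"].haplotypes[:40]),
    HaplotypePanel("AFR", panels["AFR"].haplotypes[:40]),
    gmap, lambda_gens=50.0, alpha=0.2, n_haploids=40, seed=3,
)
genotypes = cohort.panel.haplotypes[pair_into_diploids(40, seed=4)].sum(axis=1)

blocks = BlockPartition.cm_windows(gmap, 5.0)
target = PopulationFreqs("ADMIXED", cohort.panel.frequencies(), 40)
ref_eur = PopulationFreqs("EUR", panels["EUR"].haplotypes[40:240].mean(axis=0), 200)
ref_afr = PopulationFreqs("AFR", panels["AFR"].haplotypes[80:280].mean(axis=0), 200)
print(f3(target, ref_eur, ref_afr, blocks))

curve = compute_weighted_ld(genotypes, gmap, ref_eur.p, ref_afr.p)
fit = fit_single(curve)
print(f"admixture date: {fit.rate:.1f} +/- {fit.rate_se:.1f} generations "
      f"(~{fit.years:.0f} years at 30 y/gen)")
```

Output:

```
f3(ADMIXED, EUR, AFR) = -0.021734 ± 0.000484 (Z = -44.90)
admixture date: 49.0 +/- 2.8 generations (~1469 years at 30 y/gen)
```

The strongly negative f3 (Z = −44.9, far past the −4 threshold) confirms the
cohort is admixed between populations related to the two references, and the
weighted-LD decay rate recovers the simulated 50-generation pulse within one
jackknife standard error; × 30 years/generation gives the date in years.

A command-line interface wraps the same functionality
(`hoa-admixkit simulate-sources | fstats | ld-date | identity | divtime |
run`); `hoa-admixkit run --config cfg.yaml` executes the whole synthetic
rehearsal (simulate → test → date → partition → structure) with per-stage
resumable outputs.

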