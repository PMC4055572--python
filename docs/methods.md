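# Methods

This note documents the models, estimators and numerical choices behind
`hoa-admixkit`. The package rehearses, on synthetic data with known truth, a
complete admixture analysis of the kind applied to Horn-of-Africa (HOA) and
Middle-East/North-Africa SNP panels: formal admixture tests, weighted-LD
admixture dating with single- vs dual-pulse model choice, ancestry
partitioning into composite panels, and hierarchical population-structure
inference.

## Source-population model

Source populations are generated by propagating allele frequencies down a
rooted tree under the Balding–Nichols model. Given a parent frequency `p` and
an edge drift coefficient `F ∈ [0, 1)`, the child frequency is drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, which has mean `p` and variance `F·p(1−p)`;
`F = 0` is an exact copy. Ancestral frequencies are Uniform(0.05, 0.95),
emulating a common-SNP genotyping array with no monomorphic sites.

Haplotype panels are independent Bernoulli draws from the leaf frequencies.
Loci are deliberately simulated without background LD: every downstream LD
signal is then admixture LD by construction, and a zero affine baseline in
the decay fit is exact (see below). Under this model the Hudson-type FST
between two leaves equals the average of the two per-branch drift
coefficients (verified against a Monte-Carlo oracle), so a two-source system
with `F = 0.15` per branch reproduces the ~0.15 FST typical of a
west-African/European reference pair — the default divergence used in tests.

Genetic maps place loci on `C` chromosomes of `L` Morgans each (default
1 Morgan ≈ 100 cM ≈ 100 Mb), uniformly or at sorted uniform random positions.

## Two-episode pulse admixture

A pulse `λ` generations ago is simulated per haploid output genome by:

1. drawing one template chromosome from each source pool (uniformly, with
   replacement);
2. placing ancestry transition events between consecutive loci with
   probability `1 − exp(−λ·g)`, `g` the inter-locus distance in Morgans
   (the transition process restarts at each chromosome);
3. drawing each inter-event segment's ancestry independently — the
   introgressing side with probability `α` — including a fresh draw at each
   chromosome start, which makes the marginal introgressed proportion exactly
   `α` at every locus;
4. copying alleles from the chosen template.

Two-episode scenarios run the old pulse (`λ0`, `α0`) into an intermediate
pool of 40 haploids, then use that pool as the non-introgressing template
side of the recent pulse (`λ1`, `α1`), drawing the recent pulse's donors from
a disjoint haplotype set. Final haploids are paired randomly into 20 diploids
(the cohort size the analysis emulates) and both episodes' truth tracks are
merged. Closed forms used as oracles: final introgressed fraction
`α1 + (1−α1)·α0`; transition counts ≈ Poisson(λ·L·C) in the dense-map limit;
ancestry autocorrelation `exp(−λ·d)` at map distance `d`.

The exact ancestry covariance of the two-episode output decomposes into three
exponentials with rates `λ1`, `λ0` and `λ0+λ1` and amplitudes
`α1(1−α1)(1−α0)²`, `(1−α1)²α0(1−α0)` and `α1(1−α1)α0(1−α0)`. This
decomposition is the package's deterministic oracle for what a single-pulse
fit should recover from a two-pulse history (the "masking" analysis).

## f-statistics

All f-statistics are ratios of locus sums with weighted block-jackknife
standard errors (Busing delete-m_j form; weights proportional to per-block
locus counts). Blocks are one-per-chromosome by default, or fixed 5-cM
windows; the 5-cM choice (~200 blocks at study scale) gives noticeably
better-calibrated Z-scores (null sd(Z) ≈ 1.0 vs ≈ 1.16 at 10 blocks) and is
used in the calibration tests.

* `f3(target; A, B)` = mean of `(c−a)(c−b) − c(1−c)/(n_c−1)`, optionally
  normalised by the target's corrected heterozygosity. Only the target gets
  the finite-sample correction (it is the source of the downward bias the
  test exploits); references enter as point estimates. Z < −4 is the
  conventional admixture call after strict Bonferroni control.
* `D(W, X; Y, Z)` = `Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz)`. Sign convention:
  positive D means shared drift between X and Z (equivalently W and Y), so
  with the layout ((African reference, test), (Papuan, non-African
  reference)) positive Z marks non-African gene flow into the test
  population. Z > 4 is the conventional call.
* `f4_ratio(O, A; target, proxy, other)` =
  `f4(A,O; target,other) / f4(A,O; proxy,other)`, the proportion of target
  ancestry from the proxy side; exact in expectation when A is a sister of
  the proxy clade. The outgroup may be a monomorphic pseudo-population
  (chimpanzee-style). Ratios with a denominator |Z| < 3 are flagged
  unreliable. The jackknife is taken on the ratio itself.
* Admixture-proportion bounds from the f3 test: the two f4-ratio
  orientations that use each reference as both proxy and sister,
  `α_min = f4(O,B; T,A)/f4(O,B; B,A)` and `α_max = 1 − f4(O,A; T,B)/f4(O,A; A,B)`.
  Each reference's private drift shrinks its ratio toward zero, making the
  first a lower and the second an upper bound on the B-side proportion. The
  exact published algebra is cited rather than restated in the source
  material, so this construction is validated by its containment property on
  simulations, not against a printed formula.

## Weighted-LD dating

The weighted LD statistic pairs SNPs `(i, j)` within a chromosome at map
distance `d ∈ (d_min, d_max]`, computes the diploid genotype covariance
(alder-style; a per-bin covariance/weight correlation is available as the
rolloff-style mode) and multiplies by the weight
`(p_A,i − p_B,i)(p_A,j − p_B,j)` from two reference populations. Binned by
distance, the curve decays as `A·exp(−n·d)` where `n` is the admixture time
in generations; years are `30·n` throughout.

Defaults: bin width 0.1 cM, `d_min` = 0.5 cM (excludes residual short-range
structure), `d_max` = 30 cM, bins with fewer than 10 pairs masked. Genotype
covariance is used so unphased input works. Cross-chromosome pairs are never
used.

Fitting profiles the decay rate: amplitudes (and the optional affine
constant) are solved by weighted linear least squares at each candidate rate
(weights ∝ √pair-count, matching the 1/count sampling variance of a bin),
with a multistart grid {5, 20, 80, 320, 1280} generations refined by bounded
scalar minimisation in log-rate; dual fits scan rate pairs and polish with
Nelder–Mead. Ties break to the lowest RSS, then the lowest rate. The affine
constant is **off by default**: the synthetic references carry no background
LD, so the generative truth is `c = 0`, and estimating `c` confounds slow
decays (at `λ = 10`, `exp(−λ·d_max) ≈ 0.05`, and the extra parameter inflates
the fitted rate by ~7% while shrinking the jackknife SE). It can be enabled
for data with a long-range LD floor.

Standard errors come from leave-one-chromosome-out refits on the curve's
per-chromosome accumulators. A fit whose delete-one rates deviate from the
full-data rate by more than 50% is flagged inconsistent — the package's
operational reading of an "inconsistent decay rates" failure, which the
source analyses report without defining.

Single- vs dual-pulse choice uses a nested F-test on residual sums of squares
(2 extra parameters) at α = 0.05, **and** requires the dual fit's jackknife
rates to be consistent; both must pass before "dual better" is declared.

The episodic sweep reports, per grid cell, weighted arithmetic, geometric
and harmonic means of `(λ0, λ1)` with weights equal to each episode's
contribution to final ancestry, `w0 = (1−α1)·α0` and `w1 = α1`. By the
three-exponential oracle above, the single-pulse estimate falls below the
weighted arithmetic mean whenever the pulses are separated (`λ0 ≥ 2·λ1`); in
the near-degenerate grid corner (`λ0 = 50, λ1 = 30`) the deterministic best
single fit lies within one generation of that mean, so no masking claim is
made there (the estimate still lands inside `[0.5·λ1, λ0]`).

## Ancestry partitioning

The built-in painter is a deliberately simple stand-in for HMM-based
chromosome painting: non-overlapping windows of 50 phased loci are scored by
product-Bernoulli log-likelihood under each donor's allele frequencies, with
a uniform prior. Donor frequencies of exactly 0/1 are honoured; windows
impossible under both donors fall back to a uniform posterior with a warning
(callers working from finite donor panels should clip frequencies to
`[1/2n, 1−1/2n]` first, as the pipeline does). Externally painted segment
posteriors can be imported from a per-haploid TSV instead.

Windows at ≥ 0.8 posterior confidence are assigned; raising the threshold
can only shrink the assigned set (monotonicity is tested). Composite panels
sample exactly k = 12 assigned allele observations per locus per ancestry
per population, without replacement, per-locus independently — composite
rows therefore preserve allele frequencies but have no haplotype structure,
and nothing downstream reads them as haplotypes. Loci with insufficient
depth are dropped and the retained set is intersected across all
population × ancestry cells, mirroring the fixed-depth "12 + 12 chromosome"
panel construction with complete-case site intersection.

## Population structure

**Gene identity.** `J` is the probability two random alleles are identical
by state: between populations `J_xy = mean(xy + (1−x)(1−y))`; within, the
unbiased `(n·J̃ − 1)/(n − 1)` correction (needs n ≥ 2 chromosomes).
Contiguous locus blocks retain per-block values for the jackknife.
`FST = (J̄_W − J̄_B)/(1 − J̄_B)`.

**Tree models.** Expected heterozygosity `H = 1 − J` decays multiplicatively
along edges: a node's H is `H_root · Π r_e` over its root path
(`r_e = 1 − F_e`); between-population expectations take the product to the
pair's MRCA. Internal edges at the same depth share one retention parameter
(so each added hierarchy level costs one degree of freedom, matching df = 1
nested comparisons); each leaf edge has its own. The parameter vector is fit
by generalised least squares: the residual vector of all `P + P(P−1)/2`
statistics is whitened by its block-jackknife covariance (eigenvalue-floored)
and minimised with bounded least squares. The minimised quadratic form is the
goodness-of-fit Λ, asymptotically chi-square with
`df = #statistics − #parameters`; the improvement statistic for nested
topologies is `K = Λ_restricted − Λ_full`, chi-square with df equal to the
parameter-count difference, and `Λ_restricted = Λ_full + K` holds exactly
because both fits share one whitening matrix. Two numerical points matter
for the chi-square calibration: (i) retention parameters are bounded above
by 2, not 1, so a true "no extra drift" level (`r = 1`) is interior and the
null K is not boundary-distorted; (ii) the jackknife covariance needs many
blocks relative to the statistic count (500 blocks for 21 statistics in the
calibration tests — with independent simulated loci small blocks are valid),
otherwise covariance noise inflates Λ and K by ~(B−1)/(B−m). The exact
likelihood of the cited hierarchical-tree method is not restated in the
source material; this quadratic-form formulation is the package's own,
chosen to deliver the promised chi-square behaviour of Λ and K.

**AMOVA.** Three levels (within populations / among populations within
groups / among groups) on haploid 0/1 allele copies with squared-Euclidean
(IBS mismatch) distance, standard unequal-size coefficients, and
`Φ_GT = σ²_among-groups / σ²_total`. The permutation unit is the population
(shuffled among groups), the exchangeable unit for the among-group
hypothesis; p-values are add-one corrected. Because whole populations are
permuted, the attainable p-value resolution is set by the number of distinct
partitions: 12 populations in 3 groups of 4 give 5,775 distinct groupings,
enough for p ≤ 0.001 claims and for a ~5% null rejection rate; small designs
(6 populations in 2 groups: 10 distinct groupings) cannot reject at 5% at
all, which is a property of the test, not a defect.

**Mantel tests.** Pearson correlation over off-diagonal entries with joint
row/column permutation. The tail is taken in the direction of the observed
sign and doubled, keeping null p-values uniform. Geographic distances are
haversine great circles (R = 6371 km); an optional waypoint routes
cross-partition pairs through a fixed point (e.g. an Egypt waypoint between
Arabia and northeast Africa), and waypoint distances always dominate direct
ones by the triangle inequality.

**Divergence times.** Under pure drift with known, constant `Ne`,
`FST = 1 − exp(−t/2Ne)`, so `t = −2·Ne·ln(1−FST)` generations, converted at
30 years/generation; defaults `Ne = 5,000`, giving ≈ 31.6 ky at FST = 0.1.
These are minimum times: post-divergence gene flow depresses FST. Wright's
island-model equilibrium `FST = 1/(1+4Nm)` gives `Nm = (1/FST − 1)/4`.

**Q-matrix summaries.** Per-population coefficients of variation of ancestry
components (sd/mean across individuals, ddof = 1), reported only for
components whose population mean exceeds 5%; CV declines with time since
admixture ended as segment sampling variance averages out, which is tested
at 5 vs 100 generations. Super-population totals sum mapped components per
individual.

## What the synthetic data do and do not emulate

The generator reproduces the features the estimators rely on: realistic
source divergence (FST ≈ 0.15), array-like common-SNP frequency spectra,
dense multi-chromosome maps, pulse-admixture LD with exact exponential decay
and known truth tracks, and the fixed-depth composite construction. It does
not emulate background LD, phasing or genotyping error, missing data,
ascertainment bias, sex chromosomes, or continuous migration. Passing tests
therefore demonstrate correctness of the estimators under their own model
assumptions and the qualitative robustness properties (masking, SNP-density
insensitivity) — not robustness to the real-data artefacts listed above.

## Problem sizes

Dating analyses run at 20 diploids, 10 chromosomes × 1 Morgan, 30,000 SNPs
(≈ the scale at which the published verification datasets operate after
down-thinning), with 40-haplotype template pools and 200-chromosome
reference panels. Calibration batteries use 1,000–2,000 loci with
50-chromosome panels and 200 replicates, which keeps every null-distribution
check well-resolved while the whole suite completes in minutes on one CPU.
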