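"""Package-wide default constants.

Every tunable that has a conventional printed value in the analysis this
package reproduces lives here, so nothing is hard-coded at call sites.
"""

#: Years per generation used to convert generation-scale estimates to years.
GENERATION_YEARS = 30.0

#: Default effective population size for FST-based minimum divergence times.
DEFAULT_NE = 5_000.0

#: |Z| significance thresholds after strict Bonferroni control.
Z_THRESHOLD_F3_D = 4.0
Z_THRESHOLD_WEIGHTED_LD = 3.2

#: Posterior confidence at/above which a painted window is assigned an ancestry.
PAINT_CONFIDENCE = 0.8

#: Composite-panel depth: alleles sampled per locus per ancestry per population.
COMPOSITE_K = 12

#: Ancestry components are summarised (CV) only when their population mean
#: proportion exceeds this threshold.
CV_COMPONENT_THRESHOLD = 0.05

#: Default permutation count for Mantel and AMOVA tests.
N_PERMUTATIONS = 10_000

#: Weighted-LD curve defaults (Morgans).
LD_BIN_WIDTH = 0.001
LD_D_MIN = 0.005
LD_D_MAX = 0.30

#: Minimum SNP pairs per distance bin before the bin is masked.
LD_MIN_PAIRS_PER_BIN = 10

#: Multistart grid of decay rates (generations) for exponential fitting.
LD_RATE_GRID = (5.0, 20.0, 80.0, 320.0, 1280.0)

#: Painting window size (loci) for the built-in simplified painter.
PAINT_WINDOW_LOCI = 50
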