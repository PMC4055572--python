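"""f-statistics: degenerate closed forms, simulation power, jackknife calibration."""

import numpy as np
import pytest

from hoa_admixkit import (
    BlockPartition,
    DriftTree,
    HaplotypePanel,
    PopulationFreqs,
    d_stat,
    f3,
    f3_bounds,
    f4,
    f4_ratio,
    make_genetic_map,
    simulate_drift_frequencies,
    simulate_panels,
    simulate_pulse,
)


def _freqs(name, p, n=0):
    return PopulationFreqs(name, np.asarray(p, dtype=float), n)


@pytest.fixture(scope="module")
def admix_quintet():
    """Outgroup-rooted tree for D/f4-ratio: ((REFA, PROXY), OTHER) + admixed target.

    Target = 30% PROXY-side source, 70% OTHER-side source.
    """
    gmap = make_genetic_map(4, 1.0, 8_000, seed=41)
    tree = DriftTree.from_dict(
        {"name": "root", "children": [
            {"name": "OTHER", "f": 0.15},
            {"name": "ab", "f": 0.075, "children": [
                {"name": "REFA", "f": 0.075},
                {"name": "PROXY", "f": 0.075}]},
        ]}
    )
    freqs = simulate_drift_frequencies(tree, gmap.n_loci, seed=42)
    panels = simulate_panels(freqs, 240, gmap, seed=43)
    srcC = HaplotypePanel("OTHER", panels["OTHER"].haplotypes[:40])
    srcB = HaplotypePanel("PROXY", panels["PROXY"].haplotypes[:40])
    cohort = simulate_pulse(srcC, srcB, gmap, 30.0, 0.3, 40, seed=44)
    pf = {
        "OTHER": PopulationFreqs("OTHER", panels["OTHER"].haplotypes[40:].mean(axis=0), 200),
        "PROXY": PopulationFreqs("PROXY", panels["PROXY"].haplotypes[40:].mean(axis=0), 200),
        "REFA": PopulationFreqs.from_panel(panels["REFA"]),
        "TGT": PopulationFreqs("TGT", cohort.panel.frequencies(), 40),
        "OUT": PopulationFreqs.monomorphic("OUT", gmap.n_loci),
    }
    return {"map": gmap, "blocks": BlockPartition.cm_windows(gmap, 5.0), "pf": pf}


class TestF3:
    def test_identical_populations_give_null_f3(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 5_000)
        blocks = BlockPartition.n_equal_blocks(5_000, 25)
        res = f3(_freqs("c", p), _freqs("a", p), _freqs("b", p), blocks)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_admixed_target_strongly_negative(self, two_source_setup):
        s = two_source_setup
        cohort = simulate_pulse(
            s["templates"]["A"], s["templates"]["B"], s["map"], 30.0, 0.5, 40, seed=51
        )
        blocks = BlockPartition.cm_windows(s["map"], 5.0)
        res = f3(
            PopulationFreqs("T", cohort.panel.frequencies(), 40),
            PopulationFreqs("A", s["ref_freq"]["A"], 200),
            PopulationFreqs("B", s["ref_freq"]["B"], 200),
            blocks,
        )
        assert res.z < -4

    def test_unadmixed_target_non_negative_within_2se(self, two_source_setup):
        s = two_source_setup
        blocks = BlockPartition.cm_windows(s["map"], 5.0)
        target = HaplotypePanel("T", s["panels"]["A"].haplotypes[:40])
        res = f3(
            PopulationFreqs.from_panel(target),
            PopulationFreqs("A", s["ref_freq"]["A"], 200),
            PopulationFreqs("B", s["ref_freq"]["B"], 200),
            blocks,
        )
        assert res.value > -2 * res.se

    def test_monomorphic_everywhere_reported(self):
        blocks = BlockPartition.n_equal_blocks(100, 5)
        z = np.zeros(100)
        with pytest.raises(ValueError):
            f3(_freqs("c", z), _freqs("a", z), _freqs("b", z), blocks)


class TestDStat:
    def test_equal_y_z_gives_exact_zero(self):
        rng = np.random.default_rng(1)
        w, x, y = (rng.uniform(0.2, 0.8, 2_000) for _ in range(3))
        blocks = BlockPartition.n_equal_blocks(2_000, 10)
        res = d_stat(_freqs("w", w), _freqs("x", x), _freqs("y", y), _freqs("z", y.copy()), blocks)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_z_side_introgression_detected(self, admix_quintet):
        # documented convention: D > 0 when x shares drift with z
        pf, blocks = admix_quintet["pf"], admix_quintet["blocks"]
        res = d_stat(pf["OTHER"], pf["TGT"], pf["REFA"], pf["PROXY"], blocks)
        assert res.z > 4

    def test_distinct_populations_required(self, admix_quintet):
        pf, blocks = admix_quintet["pf"], admix_quintet["blocks"]
        with pytest.raises(ValueError):
            d_stat(pf["TGT"], pf["TGT"], pf["REFA"], pf["PROXY"], blocks)


class TestF4:
    def test_additivity_machine_precision(self):
        rng = np.random.default_rng(2)
        a, b, c, d, e = (rng.uniform(0.1, 0.9, 3_000) for _ in range(5))
        blocks = BlockPartition.n_equal_blocks(3_000, 12)
        lhs = f4(_freqs("a", a), _freqs("b", b), _freqs("c", c), _freqs("d", d), blocks).value
        rhs = (
            f4(_freqs("a", a), _freqs("b", b), _freqs("c", c), _freqs("e", e), blocks).value
            + f4(_freqs("a", a), _freqs("b", b), _freqs("e", e), _freqs("d", d), blocks).value
        )
        assert lhs == pytest.approx(rhs, abs=1e-14)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(3)
        a, b, c, d = (rng.uniform(0.1, 0.9, 2_000) for _ in range(4))
        blocks = BlockPartition.n_equal_blocks(2_000, 10)
        flip = rng.random(2_000) < 0.5
        def rl(p):
            q = p.copy()
            q[flip] = 1 - q[flip]
            return q
        plain = f4(_freqs("a", a), _freqs("b", b), _freqs("c", c), _freqs("d", d), blocks)
        flipped = f4(_freqs("a", rl(a)), _freqs("b", rl(b)), _freqs("c", rl(c)), _freqs("d", rl(d)), blocks)
        assert plain.value == pytest.approx(flipped.value, abs=1e-14)


class TestF4Ratio:
    def test_target_equal_proxy_gives_one(self, admix_quintet):
        pf, blocks = admix_quintet["pf"], admix_quintet["blocks"]
        res = f4_ratio(pf["OUT"], pf["REFA"], pf["PROXY"], pf["PROXY"], pf["OTHER"], blocks)
        assert res.value == pytest.approx(1.0, abs=1e-12)

    def test_target_equal_other_gives_zero(self, admix_quintet):
        pf, blocks = admix_quintet["pf"], admix_quintet["blocks"]
        res = f4_ratio(pf["OUT"], pf["REFA"], pf["OTHER"], pf["PROXY"], pf["OTHER"], blocks)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_recovers_simulated_proportion(self, admix_quintet):
        pf, blocks = admix_quintet["pf"], admix_quintet["blocks"]
        res = f4_ratio(pf["OUT"], pf["REFA"], pf["TGT"], pf["PROXY"], pf["OTHER"], blocks)
        assert abs(res.value - 0.3) <= 0.05
        assert abs(res.value - 0.3) <= 2 * res.se
        assert not res.unreliable

    def test_weak_denominator_flagged(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 2_000)
        noise = lambda: np.clip(p + rng.normal(0, 0.01, p.size), 0, 1)
        blocks = BlockPartition.n_equal_blocks(2_000, 10)
        res = f4_ratio(
            _freqs("o", noise()), _freqs("a", noise()), _freqs("t", noise()),
            _freqs("p", noise()), _freqs("q", noise()), blocks,
        )
        assert res.unreliable


class TestBounds:
    def test_symmetric_mixture_contained(self, two_source_setup):
        s = two_source_setup
        cohort = simulate_pulse(
            s["templates"]["A"], s["templates"]["B"], s["map"], 30.0, 0.5, 40, seed=61
        )
        blocks = BlockPartition.cm_windows(s["map"], 5.0)
        bounds = f3_bounds(
            PopulationFreqs("T", cohort.panel.frequencies(), 40),
            PopulationFreqs("A", s["ref_freq"]["A"], 200),
            PopulationFreqs("B", s["ref_freq"]["B"], 200),
            PopulationFreqs.monomorphic("OUT", s["map"].n_loci),
            blocks,
        )
        assert bounds.alpha_min <= 0.5 <= bounds.alpha_max

    def test_bounds_ordered_across_random_scenarios(self, two_source_setup):
        s = two_source_setup
        blocks = BlockPartition.cm_windows(s["map"], 5.0)
        out = PopulationFreqs.monomorphic("OUT", s["map"].n_loci)
        rng = np.random.default_rng(62)
        for rep in range(20):
            alpha = rng.uniform(0.1, 0.9)
            cohort = simulate_pulse(
                s["templates"]["A"], s["templates"]["B"], s["map"],
                float(rng.uniform(5, 100)), alpha, 40, seed=1000 + rep,
            )
            b = f3_bounds(
                PopulationFreqs("T", cohort.panel.frequencies(), 40),
                PopulationFreqs("A", s["ref_freq"]["A"], 200),
                PopulationFreqs("B", s["ref_freq"]["B"], 200),
                out, blocks,
            )
            assert b.alpha_min <= b.alpha_max


class TestJackknife:
    def test_se_calibrated_against_replicate_spread(self):
        """Jackknife SE within 20% of the empirical sd over 100 replicates."""
        gmap = make_genetic_map(4, 1.0, 4_000, seed=71)
        tree = DriftTree.star(["A", "B", "C"], 0.1)
        blocks = BlockPartition.cm_windows(gmap, 5.0)
        vals, ses = [], []
        for rep in range(100):
            freqs = simulate_drift_frequencies(tree, 4_000, seed=3_000 + rep)
            panels = simulate_panels(freqs, 50, gmap, seed=4_000 + rep)
            res = f3(
                PopulationFreqs.from_panel(panels["C"]),
                PopulationFreqs.from_panel(panels["A"]),
                PopulationFreqs.from_panel(panels["B"]),
                blocks,
            )
            vals.append(res.value)
            ses.append(res.se)
        ratio = np.mean(ses) / np.std(vals, ddof=1)
        assert 0.8 < ratio < 1.2
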