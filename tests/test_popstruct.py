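"""Gene identity, Mantel, AMOVA, tree models, divergence times, Q summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hoa_admixkit import (
    DivergenceParams,
    DriftTree,
    HaplotypePanel,
    IdentityMatrix,
    QMatrix,
    amova_phi_gt,
    ancestry_cv,
    compare_trees,
    divergence_time_from_fst,
    fit_tree_model,
    fst_from_identity,
    gene_identity_matrix,
    geographic_distance,
    make_genetic_map,
    mantel_test,
    simulate_drift_frequencies,
    simulate_panels,
    sum_superpopulation,
    wright_equilibrium_fst,
    wright_equilibrium_nm,
)

# Frozen from an independent Monte-Carlo oracle (2M loci): identity-based FST
# between two Balding-Nichols leaves with F = 0.05 each is 0.050.
IDENTITY_FST_STAR_F005 = 0.050


class TestGeneIdentity:
    def test_monomorphic_identical_populations(self):
        p = HaplotypePanel("P", np.ones((4, 100), dtype=np.int8))
        q = HaplotypePanel("Q", np.ones((4, 100), dtype=np.int8))
        j = gene_identity_matrix([p, q], n_blocks=5)
        np.testing.assert_allclose(j.j, 1.0)

    def test_half_frequency_between_identity(self):
        # x = y = 0.5 at every locus -> between-J = 0.5 exactly
        hap = np.tile(np.array([[0], [1], [0], [1]], dtype=np.int8), (1, 100))
        p = HaplotypePanel("P", hap)
        q = HaplotypePanel("Q", hap[::-1].copy())
        j = gene_identity_matrix([p, q], n_blocks=5)
        assert j.j[0, 1] == pytest.approx(0.5)

    def test_drift_tree_identity_within_jackknife_error(self):
        gmap = make_genetic_map(1, 1.0, 50_000)
        tree = DriftTree.star(["P", "Q"], 0.05)
        freqs = simulate_drift_frequencies(tree, 50_000, seed=2)
        panels = simulate_panels(freqs, 100, gmap, seed=3)
        j = gene_identity_matrix(list(panels.values()), n_blocks=100)
        fst = fst_from_identity(j)
        assert abs(fst - IDENTITY_FST_STAR_F005) < 0.01

    def test_within_requires_two_chromosomes(self):
        p = HaplotypePanel("P", np.ones((1, 50), dtype=np.int8))
        with pytest.raises(ValueError):
            gene_identity_matrix([p])

    def test_within_at_least_between_under_drift(self, quartet_setup):
        panels = list(quartet_setup["panels"].values())
        j = gene_identity_matrix(panels, n_blocks=50)
        for i in range(4):
            for k in range(4):
                if i != k:
                    assert j.j[i, i] > j.j[i, k]


class TestFstFromIdentity:
    def test_identical_populations_zero(self):
        mat = np.full((3, 3), 0.7)
        assert fst_from_identity(mat) == pytest.approx(0.0)

    def test_relabeling_invariance(self, quartet_setup):
        j = gene_identity_matrix(list(quartet_setup["panels"].values()), n_blocks=20)
        perm = ["Z", "W", "Y", "X"]
        assert fst_from_identity(j) == pytest.approx(
            fst_from_identity(j, populations=perm)
        )


class TestMantel:
    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(4)
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        res = mantel_test(m, 3.0 * m + 1.0, n_perm=499, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_sign_flips_under_negation(self):
        rng = np.random.default_rng(5)
        m1 = rng.random((7, 7)); m1 = (m1 + m1.T) / 2; np.fill_diagonal(m1, 0)
        m2 = rng.random((7, 7)); m2 = (m2 + m2.T) / 2; np.fill_diagonal(m2, 0)
        r_pos = mantel_test(m1, m2, n_perm=99, seed=2).r
        r_neg = mantel_test(m1, -m2, n_perm=99, seed=2).r
        assert r_neg == pytest.approx(-r_pos)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(100):
            m1 = rng.random((8, 8)); m1 = (m1 + m1.T) / 2; np.fill_diagonal(m1, 0)
            m2 = rng.random((8, 8)); m2 = (m2 + m2.T) / 2; np.fill_diagonal(m2, 0)
            ps.append(mantel_test(m1, m2, n_perm=199, seed=int(rng.integers(2**31))).p_value)
        # one-sided p under the null is uniform up to permutation granularity
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_matrix_undefined(self):
        m = np.zeros((5, 5))
        res = mantel_test(m, m, n_perm=9, seed=0)
        assert np.isnan(res.r)


class TestGeography:
    def test_identical_points_zero(self):
        pts = pd.DataFrame({"population": ["a", "b"], "lat": [10.0, 10.0], "lon": [20.0, 20.0]})
        d = geographic_distance(pts)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_points_half_circumference(self):
        pts = pd.DataFrame({"population": ["a", "b"], "lat": [0.0, 0.0], "lon": [0.0, 180.0]})
        d = geographic_distance(pts)
        assert d.iloc[0, 1] == pytest.approx(np.pi * 6371.0088, rel=1e-4)

    def test_waypoint_at_least_direct(self):
        rng = np.random.default_rng(7)
        pts = pd.DataFrame(
            {
                "population": [f"p{i}" for i in range(6)],
                "lat": rng.uniform(-60, 60, 6),
                "lon": rng.uniform(-150, 150, 6),
            }
        )
        direct = geographic_distance(pts)
        routed = geographic_distance(
            pts, waypoint=(30.0, 31.0), waypoint_side=["p0", "p1", "p2"]
        )
        assert np.all(routed.to_numpy() >= direct.to_numpy() - 1e-9)

    def test_invalid_coordinates_rejected(self):
        pts = pd.DataFrame({"population": ["a"], "lat": [200.0], "lon": [0.0]})
        with pytest.raises(ValueError):
            geographic_distance(pts)


class TestAmova:
    def test_seed_reproducibility(self, quartet_setup):
        panels = quartet_setup["panels"]
        groups = {"W": "g1", "X": "g1", "Y": "g2", "Z": "g2"}
        r1 = amova_phi_gt(panels, groups, n_perm=99, seed=5)
        r2 = amova_phi_gt(panels, groups, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.phi_gt == pytest.approx(r2.phi_gt)

    def test_group_drift_detected(self, quartet_setup):
        # the quartet's generative tree has real (wx)(yz) group structure
        panels = quartet_setup["panels"]
        groups = {"W": "g1", "X": "g1", "Y": "g2", "Z": "g2"}
        res = amova_phi_gt(panels, groups, n_perm=199, seed=6)
        assert res.phi_gt > 0

    def test_single_group_rejected(self, quartet_setup):
        groups = dict.fromkeys(["W", "X", "Y", "Z"], "g1")
        with pytest.raises(ValueError):
            amova_phi_gt(quartet_setup["panels"], groups, n_perm=9, seed=0)


def _star_identity(h_root, leaf_r, n_blocks=60, jitter=1e-6, seed=0):
    """IdentityMatrix exactly at a star model's expectations (tiny block jitter)."""
    P = len(leaf_r)
    rng = np.random.default_rng(seed)
    J = np.empty((P, P))
    for i in range(P):
        for k in range(P):
            J[i, k] = 1 - h_root * leaf_r[i] if i == k else 1 - h_root
    block_j = J[None] + rng.normal(0, jitter, (n_blocks, P, P))
    block_j = (block_j + block_j.transpose(0, 2, 1)) / 2
    return IdentityMatrix(
        populations=[f"P{i}" for i in range(P)],
        j=J,
        block_j=block_j,
        block_loci=np.full(n_blocks, 10.0),
    )


class TestTreeModels:
    star_topo = {"name": "root", "children": [{"name": f"P{i}"} for i in range(5)]}

    def test_exact_model_data_gives_zero_lambda(self):
        j = _star_identity(0.5, [0.9, 0.8, 0.95, 0.85, 0.92])
        fit = fit_tree_model(j, self.star_topo)
        assert fit.lambda_stat == pytest.approx(0.0, abs=1e-2)
        assert fit.df == 15 - 6

    def test_recovers_generative_parameters(self):
        gmap = make_genetic_map(4, 1.0, 4_000, seed=8)
        pops = [f"P{i}" for i in range(6)]
        gen = DriftTree.from_dict(
            {"name": "root", "children": [
                {"name": "g1", "f": 0.03, "children": [{"name": p, "f": 0.05} for p in pops[:3]]},
                {"name": "g2", "f": 0.03, "children": [{"name": p, "f": 0.05} for p in pops[3:]]},
            ]}
        )
        topo = {"name": "root", "children": [
            {"name": "g1", "children": [{"name": p} for p in pops[:3]]},
            {"name": "g2", "children": [{"name": p} for p in pops[3:]]},
        ]}
        freqs = simulate_drift_frequencies(gen, 4_000, seed=9)
        panels = simulate_panels(freqs, 60, gmap, seed=10)
        j = gene_identity_matrix(list(panels.values()), n_blocks=500)
        fit = fit_tree_model(j, topo)
        assert abs(fit.level_f[0] - 0.03) / 0.03 < 0.25
        np.testing.assert_allclose(fit.leaf_f, 0.05, rtol=0.25)
        # model FST close to the generative expectation (~0.067)
        expected_fst = fst_from_identity(fit.expected_identity())
        assert fit.model_fst() == pytest.approx(expected_fst)
        assert abs(fit.model_fst() - 0.067) / 0.067 < 0.2

    def test_lambda_additivity_with_k(self):
        gmap = make_genetic_map(4, 1.0, 2_000, seed=11)
        pops = [f"P{i}" for i in range(6)]
        tree = DriftTree.star(pops, 0.05)
        freqs = simulate_drift_frequencies(tree, 2_000, seed=12)
        panels = simulate_panels(freqs, 50, gmap, seed=13)
        j = gene_identity_matrix(list(panels.values()), n_blocks=400)
        star = {"name": "root", "children": [{"name": p} for p in pops]}
        struct = {"name": "root", "children": [
            {"name": "g1", "children": [{"name": p} for p in pops[:3]]},
            {"name": "g2", "children": [{"name": p} for p in pops[3:]]},
        ]}
        f_star = fit_tree_model(j, star)
        f_struct = fit_tree_model(j, struct)
        cmp_res = compare_trees(f_star, f_struct)
        assert cmp_res.df == 1
        assert f_star.lambda_stat == pytest.approx(
            f_struct.lambda_stat + cmp_res.k_stat, abs=1e-9
        )

    def test_identical_models_give_zero_k(self):
        j = _star_identity(0.5, [0.9, 0.8, 0.95, 0.85, 0.92], seed=3)
        f1 = fit_tree_model(j, self.star_topo)
        f2 = fit_tree_model(j, self.star_topo)
        res = compare_trees(f1, f2)
        assert res.k_stat == pytest.approx(0.0, abs=1e-9)

    def test_different_data_rejected(self):
        j1 = _star_identity(0.5, [0.9, 0.8, 0.95, 0.85, 0.92], seed=4)
        j2 = _star_identity(0.5, [0.9, 0.8, 0.95, 0.85, 0.92], seed=5)
        with pytest.raises(ValueError):
            compare_trees(fit_tree_model(j1, self.star_topo), fit_tree_model(j2, self.star_topo))

    def test_overparameterised_topology_rejected(self):
        j = _star_identity(0.5, [0.9, 0.8], seed=6)
        topo = {"name": "root", "children": [{"name": "P0"}, {"name": "P1"}]}
        with pytest.raises(ValueError):
            fit_tree_model(j, topo)


class TestDivergenceTime:
    def test_zero_fst_zero_time(self):
        assert divergence_time_from_fst(0.0) == 0.0

    def test_closed_form_value(self):
        # independent closed-form evaluation: -2*5000*ln(0.9)*30 = 31608.15...
        expected = -2.0 * 5_000 * np.log(0.9) * 30.0
        assert divergence_time_from_fst(0.1) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(31_608.15, abs=0.5)

    @given(fst=st.floats(1e-6, 0.01))
    @settings(max_examples=30, deadline=None)
    def test_small_fst_linear_limit(self, fst):
        t = divergence_time_from_fst(fst)
        linear = 2.0 * 5_000 * fst * 30.0
        assert abs(t - linear) / linear < 0.01

    @given(a=st.floats(0.0, 0.98), b=st.floats(0.0, 0.98))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert divergence_time_from_fst(lo) < divergence_time_from_fst(hi)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            divergence_time_from_fst(1.0)


class TestWright:
    def test_fst_point_two_gives_nm_one(self):
        assert wright_equilibrium_nm(0.2) == pytest.approx(1.0)

    def test_high_fst_low_migration(self):
        assert wright_equilibrium_nm(0.999) < 3e-4

    @given(fst=st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, fst):
        assert wright_equilibrium_fst(wright_equilibrium_nm(fst)) == pytest.approx(
            fst, rel=1e-12
        )


class TestQMatrix:
    def _q(self):
        pops = np.repeat(["P", "Q"], 5)
        rng = np.random.default_rng(20)
        q = rng.dirichlet([3, 2, 0.2], size=10)
        return QMatrix(population=pops, proportions=q, components=["c1", "c2", "c3"])

    def test_identical_rows_zero_cv(self):
        q = QMatrix(
            population=np.array(["P"] * 4),
            proportions=np.tile([0.6, 0.4], (4, 1)),
            components=["a", "b"],
        )
        table = ancestry_cv(q)
        assert np.allclose(table["cv"], 0.0)

    def test_low_mean_component_excluded(self):
        q = QMatrix(
            population=np.array(["P"] * 4),
            proportions=np.tile([0.96, 0.04], (4, 1)),
            components=["big", "small"],
        )
        table = ancestry_cv(q, threshold=0.05)
        assert set(table["component"]) == {"big"}

    def test_cv_declines_with_time_since_pulse(self, two_source_setup):
        from hoa_admixkit import pair_into_diploids, simulate_pulse

        s = two_source_setup
        means = {}
        for lam in (5.0, 100.0):
            cvs = []
            for rep in range(5):
                c = simulate_pulse(
                    s["templates"]["A"], s["templates"]["B"], s["map"],
                    lam, 0.3, 40, seed=7_000 + 100 * int(lam) + rep,
                )
                frac = c.track.mean_b_fraction()[pair_into_diploids(40, seed=rep)].mean(axis=1)
                cvs.append(frac.std(ddof=1) / frac.mean())
            means[lam] = np.mean(cvs)
        assert means[100.0] < means[5.0]

    def test_superpopulation_sums(self):
        q = self._q()
        out = sum_superpopulation(q, {"c1": "african", "c2": "nonafrican", "c3": "nonafrican"})
        np.testing.assert_allclose(out["african"] + out["nonafrican"], 1.0)
        out2 = sum_superpopulation(q, {"c1": "g", "c2": "g", "c3": "g"})
        np.testing.assert_allclose(out2["g"], 1.0)

    def test_unmapped_component_rejected(self):
        with pytest.raises(KeyError):
            sum_superpopulation(self._q(), {"c1": "g"})

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            QMatrix(
                population=np.array(["P", "P"]),
                proportions=np.array([[0.5, 0.4], [0.5, 0.5]]),
                components=["a", "b"],
            )
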