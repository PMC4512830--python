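import numpy as np
import pandas as pd
import pytest

from crosstalk_mir import (PathwayCollection, build_regulon, delta_index,
                           delta_table, ksg_mi, mi_matrix, mra_pair,
                           permutation_null)
from conftest import hypergeom_sf_bruteforce


class TestKSGMI:
    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        y = 0.7 * x + 0.7 * rng.standard_normal(400)
        assert ksg_mi(x, y, k=3, seed=0) == pytest.approx(
            ksg_mi(y, x, k=3, seed=0), abs=0.02)

    def test_independent_near_zero(self):
        vals = []
        for s in range(5):
            rng = np.random.default_rng(50 + s)
            vals.append(ksg_mi(rng.standard_normal(800),
                               rng.standard_normal(800), k=3, seed=s))
        assert abs(np.mean(vals)) < 0.05

    def test_correlated_gaussian_near_closed_form(self):
        # true MI of a bivariate normal: -0.5 ln(1 - rho^2)
        rho = 0.8
        vals = []
        for s in range(5):
            rng = np.random.default_rng(60 + s)
            x = rng.standard_normal(1000)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(1000)
            vals.append(ksg_mi(x, y, k=3, seed=s))
        assert np.mean(vals) == pytest.approx(-0.5 * np.log(1 - rho ** 2),
                                              abs=0.08)

    def test_monotone_transform_invariance(self):
        # MI depends only on the copula: rank-transforming both marginals
        # should leave the estimate unchanged up to estimator noise
        rng = np.random.default_rng(3)
        x = rng.standard_normal(600)
        y = 0.9 * x + 0.44 * rng.standard_normal(600)
        a = ksg_mi(x, y, k=3, seed=0)
        rank = lambda v: np.argsort(np.argsort(v)).astype(float)
        b = ksg_mi(rank(x), rank(y), k=3, seed=0)
        assert a == pytest.approx(b, abs=0.1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ksg_mi([1.0, 2.0], [3.0, 4.0], k=3)

    def test_constant_vector_zero(self):
        assert ksg_mi(np.ones(50), np.arange(50.0), k=3) == 0.0

    def test_block_path_matches_pairwise_path(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((3, 120)))
        Y = pd.DataFrame(rng.standard_normal((4, 120)))
        block = mi_matrix(X, Y, k=3, log_transform=False, seed=0)
        for i in range(3):
            for j in range(4):
                pairwise = ksg_mi(X.to_numpy()[i], Y.to_numpy()[j], k=3, seed=1)
                assert block.iloc[i, j] == pytest.approx(pairwise, abs=0.05)


class TestBuildRegulon:
    def test_top_k_zero_gives_empty_regulon(self):
        mi = pd.DataFrame([[0.5, 0.1]], index=["m1"], columns=["g1", "g2"])
        regs = build_regulon(mi, rule="top_k", top_k=0)
        assert regs["m1"].targets == frozenset()

    def test_top_k_picks_highest_mi(self):
        mi = pd.DataFrame([[0.5, 0.1, 0.9]], index=["m1"],
                          columns=["g1", "g2", "g3"])
        regs = build_regulon(mi, rule="top_k", top_k=2)
        assert regs["m1"].targets == {"g1", "g3"}

    def test_permutation_rule_near_empty_on_independent_data(self):
        rng = np.random.default_rng(5)
        mir = pd.DataFrame(rng.poisson(40, (4, 80)).astype(float),
                           index=[f"m{i}" for i in range(4)])
        genes = pd.DataFrame(rng.poisson(40, (25, 80)).astype(float),
                             index=[f"g{i}" for i in range(25)])
        mi = mi_matrix(mir, genes, seed=0)
        null = permutation_null(mir, genes, n_permutations=5, seed=1)
        regs = build_regulon(mi, null=null)
        total = sum(len(r.targets) for r in regs.values())
        assert total <= 5  # ~alpha * n_mirnas * n_genes false calls

    def test_planted_regulons_recovered(self):
        from crosstalk_mir import SimulationConfig, generate_study

        # dependence-only study: no DE shifts, pure copula coupling
        cfg = SimulationConfig(n_tumor=50, n_normal=50, n_genes=200,
                               n_mirnas=15, n_pathways=4, n_de_genes=0,
                               planted_logfc=0.0, crosstalk_shift=0.0,
                               n_crosstalk_pairs=2, regulon_size=10,
                               regulon_strength=0.85, seed=13)
        st = generate_study(cfg)
        genes = sorted({g for a, b in st.truth.crosstalk_pairs
                        for g in st.pathways.sets[a] | st.pathways.sets[b]})
        mi = mi_matrix(st.mirna, st.mrna.loc[genes], seed=0)
        null = permutation_null(st.mirna, st.mrna.loc[genes],
                                n_permutations=5, seed=1)
        regs = build_regulon(mi, null=null)
        for mirna, truth_targets in st.truth.regulons.items():
            got = regs[mirna].targets
            inter = len(got & truth_targets)
            assert inter / max(len(got), 1) > 0.8
            assert inter / len(truth_targets) > 0.8


class TestMRAPair:
    def _setup(self):
        uni = frozenset(f"g{i}" for i in range(30))
        coll = PathwayCollection(
            sets={"A": frozenset(f"g{i}" for i in range(5)),
                  "B": frozenset(f"g{i}" for i in range(5, 10))},
            universe=uni)
        return uni, coll

    def test_maximal_enrichment(self):
        uni, coll = self._setup()
        from crosstalk_mir import Regulon

        targets = coll.sets["A"] | coll.sets["B"]
        regs = {"m1": Regulon("m1", frozenset(targets),
                              {g: 1.0 for g in targets}, "top_k")}
        out = mra_pair(regs, ("A", "B"), coll, de_mirnas={"m1"})
        row = out.iloc[0]
        assert row["p_a"] == pytest.approx(
            hypergeom_sf_bruteforce(5, 30, 5, 10), rel=1e-9)
        assert bool(row["is_mr"])

    def test_zero_targets_in_both_pathways(self):
        uni, coll = self._setup()
        from crosstalk_mir import Regulon

        targets = frozenset(f"g{i}" for i in range(10, 14))
        regs = {"m1": Regulon("m1", targets, {g: 1.0 for g in targets},
                              "top_k")}
        out = mra_pair(regs, ("A", "B"), coll, de_mirnas={"m1"})
        row = out.iloc[0]
        assert row["p_a"] == pytest.approx(1.0)
        assert row["p_b"] == pytest.approx(1.0)
        assert not bool(row["is_mr"])

    def test_non_de_mirna_never_master_regulator(self):
        uni, coll = self._setup()
        from crosstalk_mir import Regulon

        targets = coll.sets["A"] | coll.sets["B"]
        regs = {"m1": Regulon("m1", frozenset(targets),
                              {g: 1.0 for g in targets}, "top_k")}
        out = mra_pair(regs, ("A", "B"), coll, de_mirnas=set())
        assert not out["is_mr"].any()

    def test_empty_regulons_empty_result(self):
        uni, coll = self._setup()
        out = mra_pair({}, ("A", "B"), coll, de_mirnas=set())
        assert len(out) == 0


class TestDeltaIndex:
    @pytest.mark.parametrize("logfc, ex_bc, ex_ns, printed", [
        (1.134, 48.07, 19.65, 32.24),
        (1.432, 23.47, 8.02, 22.14),
        (2.608, 4.75, 0.78, 10.36),
        (2.312, 3.99, 0.701, 7.61),
    ])
    def test_published_worked_examples(self, logfc, ex_bc, ex_ns, printed):
        # two-decimal input rounding: 0.5% relative tolerance
        assert delta_index(ex_bc, ex_ns, logfc) == pytest.approx(
            printed, rel=5e-3)

    def test_equal_expression_gives_zero(self):
        assert delta_index(7.0, 7.0, 1.5) == 0.0

    def test_sign_agrees_with_change_direction(self):
        assert delta_index(10.0, 2.0, 1.2) > 0
        assert delta_index(2.0, 10.0, -1.2) > 0
        assert delta_index(10.0, 2.0, -1.2) < 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta_index(np.inf, 0.0, 1.0)

    def test_delta_table_from_dea_results(self):
        res = pd.DataFrame({
            "logFC": [2.0, -1.5],
            "mean_tumor": [40.0, 5.0],
            "mean_normal": [10.0, 25.0],
        }, index=["m1", "m2"])
        out = delta_table(res)
        assert out.loc[out["mirna"] == "m1", "delta"].iloc[0] == pytest.approx(60.0)
        assert out.loc[out["mirna"] == "m2", "delta"].iloc[0] == pytest.approx(30.0)
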