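"""Drug-target network, RWR, perturbation GSEA and Drug Score."""

import numpy as np
import pandas as pd
import pytest

from emtmet.drugs import (
    build_network,
    drug_score,
    gsea_preranked,
    perturbation_mps_test,
    prioritize_drugs,
    rank_perturbation,
    rwr,
    score_gsea,
)
from emtmet.model import ScoreModel
from emtmet.simulate import SimConfig, gen_drug_world


def _edges(pairs, cols=("drug_id", "gene_id")):
    return pd.DataFrame(list(pairs), columns=list(cols))


def _empty_dt():
    return pd.DataFrame(columns=["drug_id", "gene_id"])


@pytest.fixture(scope="module")
def drug_world():
    cfg = SimConfig(seed=41)
    sig = {f"G{i:04d}": ("up" if i < 15 else "down") for i in range(25)}
    return sig, gen_drug_world(cfg, sig)


class TestBuildNetwork:
    def test_two_node_transition_matrix(self):
        net = build_network(_edges([("d1", "g1")]),
                            _edges([], cols=("gene_a", "gene_b")), ["g1"])
        assert net.nodes == ["d1", "g1"]
        np.testing.assert_array_equal(net.A, [[0.0, 1.0], [1.0, 0.0]])

    def test_duplicate_edges_collapse(self):
        net = build_network(_edges([("d1", "g1"), ("d1", "g1")]),
                            _edges([("g1", "g2"), ("g2", "g1")],
                                   cols=("gene_a", "gene_b")), ["g1"])
        # g1 has two neighbors -> its column splits 1/2 each
        i = {n: k for k, n in enumerate(net.nodes)}
        assert net.A[i["d1"], i["g1"]] == 0.5
        assert net.A[i["g2"], i["g1"]] == 0.5

    def test_columns_sum_to_one(self, drug_world):
        _, world = drug_world
        net = build_network(world.drug_target_edges, world.ppi_edges,
                            world.truth.signature_up)
        np.testing.assert_allclose(net.A.sum(axis=0), 1.0, atol=1e-12)

    def test_self_loops_dropped(self):
        net = build_network(_edges([("d1", "g1")]),
                            _edges([("g1", "g1"), ("g1", "g2")],
                                   cols=("gene_a", "gene_b")), ["g1"])
        i = {n: k for k, n in enumerate(net.nodes)}
        assert net.A[i["g1"], i["g1"]] == 0.0

    def test_missing_seeds_warn_or_error(self):
        dt = _edges([("d1", "g1")])
        ppi = _edges([("g1", "g2")], cols=("gene_a", "gene_b"))
        with pytest.warns(UserWarning, match="seed"):
            net = build_network(dt, ppi, ["g1", "absent"])
        assert net.seeds == ["g1"]
        with pytest.raises(ValueError, match="seed"):
            build_network(dt, ppi, ["absent"])

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError, match="edges"):
            build_network(_empty_dt(),
                          pd.DataFrame(columns=["gene_a", "gene_b"]), ["g1"])

    def test_drug_nodes_typed(self, drug_world):
        _, world = drug_world
        net = build_network(world.drug_target_edges, world.ppi_edges,
                            world.truth.signature_up)
        assert set(net.drug_nodes) == set(world.drug_target_edges["drug_id"])
        assert (net.node_type[net.drug_nodes] == "drug").all()


class TestRwr:
    def test_alpha_zero_returns_seed_vector(self):
        net = build_network(_edges([("d1", "g1"), ("d1", "g2")]),
                            _edges([("g1", "g2")], cols=("gene_a", "gene_b")),
                            ["g1", "g2"])
        p = rwr(net, alpha=0.0)
        assert p["g1"] == pytest.approx(0.5)
        assert p["g2"] == pytest.approx(0.5)
        assert p["d1"] == pytest.approx(0.0)

    def test_two_node_closed_form(self):
        # P* = (1-a) (I - a A)^-1 P0 with A = [[0,1],[1,0]], P0 = (0,1):
        # P*_gene = (1-a)/(1-a^2) = 1/(1+a), P*_drug = a/(1+a)
        net = build_network(_edges([("d1", "g1")]),
                            _edges([], cols=("gene_a", "gene_b")), ["g1"])
        a = 0.7
        p = rwr(net, alpha=a)
        assert p["g1"] == pytest.approx(1 / (1 + a), abs=1e-8)
        assert p["d1"] == pytest.approx(a / (1 + a), abs=1e-8)

    def test_matches_linear_solve(self, rng):
        # random connected network vs direct (I - a A)^-1 solve
        for trial in range(5):
            n_g = int(rng.integers(8, 20))
            genes = [f"g{i}" for i in range(n_g)]
            ppi = [(genes[int(rng.integers(0, i))], genes[i])
                   for i in range(1, n_g)]
            dt = [(f"d{j}", genes[int(rng.integers(0, n_g))])
                  for j in range(4)]
            seeds = [genes[0], genes[-1]]
            net = build_network(_edges(dt), _edges(ppi, cols=("a", "b")),
                                seeds)
            p = rwr(net, alpha=0.7, tol=1e-12)
            p0 = np.array([1.0 if n in seeds else 0.0 for n in net.nodes])
            p0 /= p0.sum()
            direct = np.linalg.solve(np.eye(len(net.nodes)) - 0.7 * net.A,
                                     0.3 * p0)
            np.testing.assert_allclose(p.to_numpy(), direct, atol=1e-8)

    def test_mass_conserved(self, drug_world):
        _, world = drug_world
        net = build_network(world.drug_target_edges, world.ppi_edges,
                            world.truth.signature_up)
        p = rwr(net)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (p.to_numpy() >= 0).all()

    def test_invalid_alpha_rejected(self):
        net = build_network(_edges([("d1", "g1")]),
                            _edges([], cols=("gene_a", "gene_b")), ["g1"])
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                rwr(net, alpha=bad)

    def test_seed_neighbors_outrank_distant_nodes(self):
        # chain d_near - s - g1 - g2 - d_far: drug adjacent to the seed
        # receives more stationary mass than the distant one
        ppi = _edges([("s", "g1"), ("g1", "g2")], cols=("a", "b"))
        dt = _edges([("d_near", "s"), ("d_far", "g2")])
        net = build_network(dt, ppi, ["s"])
        p = rwr(net)
        assert p["d_near"] > p["d_far"]


class TestRankPerturbation:
    def test_welch_t_textbook_oracle(self):
        from scipy import stats

        a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        b = pd.DataFrame([[4.0, 4.5, 6.5]], index=["g"])
        ranked = rank_perturbation(a, b)
        expected = stats.ttest_ind([1.0, 2.0, 3.0], [4.0, 4.5, 6.5],
                                   equal_var=False).statistic
        assert ranked["g"] == pytest.approx(expected)
        assert expected < 0

    def test_single_replicate_mean_difference(self):
        a = pd.DataFrame({"t": [5.0, 1.0]}, index=["g1", "g2"])
        b = pd.DataFrame({"c": [2.0, 2.0]}, index=["g1", "g2"])
        ranked = rank_perturbation(a, b)
        assert ranked["g1"] == pytest.approx(3.0)
        assert ranked["g2"] == pytest.approx(-1.0)
        assert list(ranked.index) == ["g1", "g2"]

    def test_planted_down_genes_rank_bottom(self, drug_world):
        sig, world = drug_world
        drug = world.truth.planted_drugs[0]
        arms = world.profiles[drug]
        ranked = rank_perturbation(arms["treated"], arms["control"])
        bottom = set(ranked.index[-len(world.truth.signature_up):])
        overlap = len(bottom & set(world.truth.signature_up))
        assert overlap >= 0.8 * len(world.truth.signature_up)

    def test_descending_order(self, drug_world):
        _, world = drug_world
        arms = world.profiles["D010"]
        ranked = rank_perturbation(arms["treated"], arms["control"])
        assert (np.diff(ranked.to_numpy()) <= 0).all()

    def test_empty_arm_rejected(self):
        a = pd.DataFrame({"t": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            rank_perturbation(a, a.iloc[:, :0])


class TestGsea:
    def test_top_enriched_set_extreme_p(self, rng):
        stat = pd.Series(np.sort(rng.normal(0, 1, 200))[::-1],
                         index=[f"g{i}" for i in range(200)])
        es, nes, p = gsea_preranked(stat, [f"g{i}" for i in range(10)],
                                    n_perm=200, seed=0)
        assert es > 0 and nes > 0
        assert p <= 1.0 / (200 + 1) + 1e-12

    def test_bottom_set_negative_es(self, rng):
        stat = pd.Series(np.sort(rng.normal(0, 1, 200))[::-1],
                         index=[f"g{i}" for i in range(200)])
        es, nes, p = gsea_preranked(stat, [f"g{i}" for i in range(190, 200)],
                                    n_perm=200, seed=0)
        assert es < 0 and nes < 0
        assert p <= 1.0 / (200 + 1) + 1e-12

    def test_reversing_ranking_flips_sign(self, rng):
        vals = rng.normal(0, 1, 100)
        idx = [f"g{i}" for i in range(100)]
        fwd = pd.Series(np.sort(vals)[::-1], index=idx)
        rev = (-fwd).sort_values(ascending=False)
        set_ = idx[:8]
        es_f, _, _ = gsea_preranked(fwd, set_, n_perm=50, seed=0)
        es_r, _, _ = gsea_preranked(rev, set_, n_perm=50, seed=0)
        assert np.sign(es_f) == -np.sign(es_r)

    def test_null_p_uniformity(self, rng):
        # random sets on a random ranking: p should be ~Uniform(0,1)
        from scipy import stats

        stat = pd.Series(np.sort(rng.normal(0, 1, 150))[::-1],
                         index=[f"g{i}" for i in range(150)])
        pvals = []
        for b in range(200):
            genes = rng.choice(150, size=10, replace=False)
            _, _, p = gsea_preranked(stat, [f"g{i}" for i in genes],
                                     n_perm=100, seed=b)
            pvals.append(p)
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_tiny_overlap_rejected(self, rng):
        stat = pd.Series(rng.normal(0, 1, 50),
                         index=[f"g{i}" for i in range(50)])
        with pytest.raises(ValueError, match="< 3"):
            gsea_preranked(stat, ["g0", "g1"], n_perm=10)

    def test_deterministic_given_seed(self, rng):
        stat = pd.Series(np.sort(rng.normal(0, 1, 100))[::-1],
                         index=[f"g{i}" for i in range(100)])
        r1 = gsea_preranked(stat, [f"g{i}" for i in range(5)], n_perm=100,
                            seed=7)
        r2 = gsea_preranked(stat, [f"g{i}" for i in range(5)], n_perm=100,
                            seed=7)
        assert r1 == r2


class TestScores:
    def test_score_gsea_endpoints(self):
        nes = pd.Series({"a": -2.0, "b": 0.0, "c": 2.0})
        s = score_gsea(nes)
        assert s["a"] == 1.0 and s["c"] == 0.0 and s["b"] == 0.5

    def test_score_gsea_single_drug_rejected(self):
        with pytest.raises(ValueError):
            score_gsea(pd.Series({"a": 1.0}))

    def test_drug_score_weighted_sum(self):
        r = pd.Series({"a": 1.0, "b": 0.0})
        g = pd.Series({"a": 0.0, "b": 1.0})
        s = drug_score(r, g)
        assert s["a"] == pytest.approx(0.6)
        assert s["b"] == pytest.approx(0.4)
        assert list(s.index) == ["a", "b"]  # sorted descending

    def test_drug_score_intersection_only(self):
        r = pd.Series({"a": 1.0, "b": 0.5})
        g = pd.Series({"b": 1.0, "c": 0.2})
        s = drug_score(r, g)
        assert set(s.index) == {"b"}

    def test_nonunit_weights_warn(self):
        r = pd.Series({"a": 1.0, "b": 0.0})
        with pytest.warns(UserWarning, match="sum to 1"):
            drug_score(r, r, l1=0.6, l2=0.6)


class TestPrioritize:
    def test_planted_drugs_recovered(self, drug_world):
        sig, world = drug_world
        net = build_network(world.drug_target_edges, world.ppi_edges,
                            world.truth.signature_up
                            + world.truth.signature_down)
        table = prioritize_drugs(net, world.profiles,
                                 world.truth.signature_up, n_perm=200,
                                 seed=0)
        top = table.index[: max(1, len(table) // 5)]
        for d in world.truth.planted_drugs:
            assert d in top
            assert table.loc[d, "effect"] == "inhibits"

    def test_scores_in_unit_interval(self, drug_world):
        sig, world = drug_world
        net = build_network(world.drug_target_edges, world.ppi_edges,
                            world.truth.signature_up)
        table = prioritize_drugs(net, world.profiles,
                                 world.truth.signature_up, n_perm=100,
                                 seed=1)
        for col in ("score_rwr", "score_gsea", "drug_score"):
            assert table[col].between(0, 1).all()
        assert (np.diff(table["drug_score"].to_numpy()) <= 1e-12).all()


class TestPerturbationMpsTest:
    def _model(self, genes, coef):
        return ScoreModel(genes=list(genes), coef=np.asarray(coef, float),
                          intercept=0.0)

    def test_planted_drug_lowers_mps(self, drug_world):
        sig, world = drug_world
        up = world.truth.signature_up
        model = self._model(up, np.ones(len(up)))
        drug = world.truth.planted_drugs[0]
        arms = world.profiles[drug]
        delta, p = perturbation_mps_test(model, arms["treated"],
                                         arms["control"])
        assert delta < 0
        # 3 vs 3 replicates: best attainable two-sided rank-sum p = 0.1
        assert p <= 0.1 + 1e-12

    def test_decoy_drug_null(self, drug_world):
        sig, world = drug_world
        up = world.truth.signature_up
        model = self._model(up, np.ones(len(up)))
        arms = world.profiles["D030"]
        delta, p = perturbation_mps_test(model, arms["treated"],
                                         arms["control"])
        assert p > 0.05

    def test_wilcoxon_matches_scipy_oracle(self):
        from scipy import stats

        model = self._model(["g"], [1.0])
        treated = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                               columns=["t0", "t1", "t2"])
        control = pd.DataFrame([[4.0, 5.0, 6.0]], index=["g"],
                               columns=["c0", "c1", "c2"])
        delta, p = perturbation_mps_test(model, treated, control)
        assert delta == pytest.approx(-3.0)
        expected = stats.mannwhitneyu([1.0, 2.0, 3.0], [4.0, 5.0, 6.0],
                                      alternative="two-sided").pvalue
        assert p == pytest.approx(expected)

    def test_disjoint_genes_rejected(self):
        model = self._model(["gX"], [1.0])
        prof = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="overlap"):
            perturbation_mps_test(model, prof, prof)
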