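import numpy as np
import pandas as pd
import pytest

from diogene.data_model import EdgeList, GoldStandard
from diogene.network import (
    assemble_grn,
    edge_count_for_density,
    out_degree_ranking,
    precision_recall,
    prior_network_baseline,
)


class TestEdgeCount:
    @pytest.mark.parametrize(
        "density,R,T,expected",
        [
            (0.005, 201, 1426, 1432),  # published density/edge totals
            (0.0, 201, 1426, 0),
            (1.0, 3, 4, 9),  # complete oriented network R(T-1)
        ],
    )
    def test_examples(self, density, R, T, expected):
        assert edge_count_for_density(density, R, T) == expected

    def test_monotone_in_density(self):
        counts = [edge_count_for_density(d, 20, 30) for d in np.linspace(0, 1, 50)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            edge_count_for_density(1.5, 10, 10)
        with pytest.raises(ValueError):
            edge_count_for_density(0.5, 0, 10)


class TestAssembleGrn:
    def _importances(self):
        return {
            "t1": pd.Series({"r1": 0.9, "r2": 0.1, "r3": 0.0}),
            "t2": pd.Series({"r1": 0.5, "r2": 0.5, "r3": 0.2}),
        }

    def test_single_strongest_edge(self):
        # density chosen so E = 1
        grn = assemble_grn(self._importances(), 1 / 3, n_regulators=3, n_targets=2)
        assert grn.pairs() == {("r1", "t1")}

    def test_edge_count_obeys_density_formula(self):
        rng = np.random.default_rng(3)
        imps = {
            f"t{j}": pd.Series(rng.random(10), index=[f"r{i}" for i in range(10)])
            for j in range(8)
        }
        for d in (0.1, 0.3, 0.7):
            grn = assemble_grn(imps, d)
            assert len(grn) == edge_count_for_density(d, 10, 8)

    def test_zero_importance_pairs_never_selected_and_warns(self):
        imps = {"t1": pd.Series({"r1": 0.4, "r2": 0.0})}
        with pytest.warns(UserWarning, match="nonzero"):
            grn = assemble_grn(imps, 1.0, n_regulators=2, n_targets=2)
        assert grn.pairs() == {("r1", "t1")}

    def test_tie_break_lexicographic_and_stable(self):
        imps = {
            "t2": pd.Series({"r2": 0.5, "r1": 0.5}),
            "t1": pd.Series({"r2": 0.5}),
        }
        # E_total = R(T-1) = 2, so density 1.0 keeps both tied edges
        a = assemble_grn(imps, 1.0, n_regulators=2, n_targets=2)
        b = assemble_grn(imps, 1.0, n_regulators=2, n_targets=2)
        assert list(zip(a.edges["regulator"], a.edges["target"])) == [
            ("r1", "t2"),
            ("r2", "t1"),
        ]
        pd.testing.assert_frame_equal(a.edges, b.edges)


class TestPrecisionRecall:
    def test_perfect_agreement(self):
        grn = EdgeList(
            edges=pd.DataFrame(
                {"regulator": ["a"], "target": ["x"], "importance": [1.0]}
            )
        )
        gold = GoldStandard(edges={("a", "x")})
        res = precision_recall(grn, gold)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_worked_example(self):
        grn = EdgeList(
            edges=pd.DataFrame(
                {
                    "regulator": ["a", "a", "b"],
                    "target": ["x", "y", "x"],
                    "importance": [3.0, 2.0, 1.0],
                }
            )
        )
        gold = GoldStandard(edges={("a", "x"), ("b", "z")}, studied_regulators={"a", "b"})
        res = precision_recall(grn, gold, input_genes=["a", "b", "x", "y", "z"])
        assert res.precision == pytest.approx(1 / 3)
        assert res.recall == pytest.approx(1 / 2)

    def test_disjoint_sets(self):
        grn = EdgeList(
            edges=pd.DataFrame(
                {"regulator": ["a"], "target": ["y"], "importance": [1.0]}
            )
        )
        gold = GoldStandard(edges={("a", "x")})
        res = precision_recall(grn, gold)
        assert res.precision == 0.0 and res.recall == 0.0

    def test_undefined_metrics_flagged_not_zero(self):
        grn = EdgeList(
            edges=pd.DataFrame(
                {"regulator": ["c"], "target": ["x"], "importance": [1.0]}
            )
        )
        gold = GoldStandard(edges={("a", "x")}, studied_regulators={"a"})
        res = precision_recall(grn, gold, input_genes=["c", "x"])
        assert not res.precision_defined and np.isnan(res.precision)
        assert not res.recall_defined and np.isnan(res.recall)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        regs = [f"r{i}" for i in range(6)]
        tgts = [f"t{i}" for i in range(6)]
        for _ in range(1000):
            pairs = [(r, t) for r in regs for t in tgts]
            k = int(rng.integers(1, 12))
            grn_pairs = {pairs[i] for i in rng.choice(len(pairs), k, replace=False)}
            g = int(rng.integers(1, 12))
            gold_pairs = {pairs[i] for i in rng.choice(len(pairs), g, replace=False)}
            studied = {r for r in regs if rng.random() < 0.6} | {
                r for r, _ in gold_pairs
            }
            input_genes = [x for x in regs + tgts if rng.random() < 0.8]
            grn = EdgeList(
                edges=pd.DataFrame(
                    [(r, t, 1.0) for r, t in sorted(grn_pairs)],
                    columns=["regulator", "target", "importance"],
                )
            )
            gold = GoldStandard(edges=gold_pairs, studied_regulators=studied)
            res = precision_recall(grn, gold, input_genes)
            # brute-force oracle by explicit loops
            E = [(r, t) for r, t in grn_pairs if r in studied]
            G = [
                (r, t)
                for r, t in gold_pairs
                if r in input_genes and t in input_genes
            ]
            tp = [e for e in E if e in G]
            if E:
                assert res.precision == pytest.approx(len(tp) / len(E))
            else:
                assert np.isnan(res.precision)
            if G:
                assert res.recall == pytest.approx(len(tp) / len(G))
            else:
                assert np.isnan(res.recall)


class TestHubsAndBaseline:
    def test_star_network_ranking(self):
        grn = EdgeList(
            edges=pd.DataFrame(
                {
                    "regulator": ["hub"] * 4 + ["r2"],
                    "target": ["t1", "t2", "t3", "t4", "t1"],
                    "importance": [5.0, 4.0, 3.0, 2.0, 1.0],
                }
            )
        )
        ranking = out_degree_ranking(grn, top_k=25)
        assert ranking.iloc[0]["regulator"] == "hub"
        assert ranking.iloc[0]["out_degree"] == 4
        assert ranking["out_degree"].sum() == len(grn)

    def test_empty_grn(self):
        grn = EdgeList(
            edges=pd.DataFrame(columns=["regulator", "target", "importance"])
        )
        assert len(out_degree_ranking(grn)) == 0

    def test_top_k_truncation_and_tie_order(self):
        grn = EdgeList(
            edges=pd.DataFrame(
                {
                    "regulator": ["b", "a", "c"],
                    "target": ["t1", "t2", "t3"],
                    "importance": [1.0, 1.0, 1.0],
                }
            )
        )
        ranking = out_degree_ranking(grn, top_k=2)
        assert list(ranking["regulator"]) == ["a", "b"]

    def test_prior_baseline_counts_and_evaluates(self, toy_prior):
        baseline = prior_network_baseline(toy_prior)
        assert len(baseline) == int((toy_prior.pi.to_numpy() == 1.0).sum())
        gold = GoldStandard(edges={("g1", "g4")}, studied_regulators={"g1", "g3"})
        res = precision_recall(baseline, gold)
        assert res.precision == pytest.approx(1 / 2)  # (g1,g4) and (g3,g5) evaluable

    def test_all_zero_prior_gives_empty_network(self):
        from diogene.data_model import PriorMatrix

        prior = PriorMatrix(pi=pd.DataFrame(0.0, index=["r"], columns=["t"]))
        assert len(prior_network_baseline(prior)) == 0
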