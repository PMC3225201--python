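import numpy as np
import pandas as pd
import pytest

from midfuse.datamodel import PeptideProteinMap
from midfuse.fusion import FusionConfig, fit_fusion
from midfuse.interpret import (
    ImportanceTable, global_weights, group_importance, aggregate_peptides,
    correlation_matrix, build_network, extract_subnetwork, export_dot,
)


@pytest.fixture(scope="module")
def fitted(request):
    from midfuse.synthetic import simulate_study
    from conftest import small_sim_config
    study, truth = simulate_study(small_sim_config(seed=3))
    model = fit_fusion(study, FusionConfig(test_fraction=0.0,
                                           n_pls={"prot": 4, "met": 4},
                                           top_k={"prot": 30}))
    return study, truth, model


class TestGlobalWeights:
    def test_dimensions(self, fitted):
        study, _, model = fitted
        gw = global_weights(model, "prot")
        assert gw.shape == (30, model.r_global)
        gw2 = global_weights(model, "met")
        assert gw2.shape == (len(model.block_fits[1].kept_variable_ids), model.r_global)

    def test_equals_explicit_matrix_product(self, fitted):
        _, _, model = fitted
        fit = model.block_fits[0]
        cols = [i for i, b in enumerate(model.score_column_blocks) if b == "prot"]
        expected = np.zeros((fit.ecva.W.shape[0], model.r_global))
        for v in range(fit.ecva.W.shape[0]):
            for r in range(model.r_global):
                expected[v, r] = sum(
                    fit.ecva.W[v, a] * model.pca.loadings[cols[a], r]
                    / model.score_sds[cols[a]]
                    for a in range(fit.ecva.n_directions))
        np.testing.assert_allclose(global_weights(model, "prot").to_numpy(),
                                   expected, atol=1e-12)

    def test_identity_second_layer_returns_block_directions(self, fitted):
        """With identity loadings and unit score scale the global weights
        reduce to the block's canonical directions."""
        _, _, model = fitted
        import copy
        m = copy.copy(model)
        m.pca = copy.copy(model.pca)
        q = model.pca.loadings.shape[0]
        m.pca.loadings = np.eye(q)[:, :model.r_global]
        m.score_sds = np.ones(q)
        gw = global_weights(m, "prot").to_numpy()
        W = m.block_fits[0].ecva.W
        np.testing.assert_allclose(gw[:, :W.shape[1]], W, atol=1e-12)

    def test_unknown_block_rejected(self, fitted):
        _, _, model = fitted
        with pytest.raises(KeyError):
            global_weights(model, "nope")


class TestGroupImportance:
    def test_normalization_peaks_at_one(self, fitted):
        _, _, model = fitted
        table = group_importance(model, 3)
        assert table.frame["importance"].abs().max() == pytest.approx(1.0)
        assert (table.frame["importance"].abs() <= 1.0 + 1e-12).all()
        assert np.isclose(table.frame["importance"].abs(), 1.0).sum() == 1

    def test_rows_cover_all_retained_variables(self, fitted):
        _, _, model = fitted
        table = group_importance(model, 3)
        expected = sum(len(f.kept_variable_ids) for f in model.block_fits)
        assert len(table.frame) == expected

    def test_unknown_class_rejected(self, fitted):
        _, _, model = fitted
        with pytest.raises(ValueError, match="not in model classes"):
            group_importance(model, 9)

    def test_planted_disease_variables_rank_high_with_correct_sign(self, fitted):
        study, truth, model = fitted
        table = group_importance(model, 3)
        planted = {vid: truth.disease_sign(bid, vid, 3)
                   for bid in truth.discriminant
                   for vid in truth.discriminant[bid]}
        retained = set(table.frame["variable_id"])
        usable = {v: s for v, s in planted.items() if v in retained}
        top = table.important_set(2 * len(planted))
        recovered = set(usable) & top
        assert len(recovered) / len(usable) >= 0.6
        sub = table.frame[table.frame["variable_id"].isin(recovered)]
        agree = np.mean([row.sign == usable[row.variable_id]
                         for row in sub.itertuples()])
        assert agree >= 0.8


class TestAggregatePeptides:
    def _table(self, pairs):
        frame = pd.DataFrame([
            {"variable_id": v, "block_id": "prot", "raw_importance": imp,
             "importance": imp, "sign": int(np.sign(imp)) or 1, "mean_shift_sign": 0}
            for v, imp in pairs])
        return ImportanceTable(3, frame)

    def test_three_same_sign_averaged(self):
        table = self._table([("a", 0.5), ("b", 0.7), ("c", 0.6)])
        pmap = PeptideProteinMap({"a": "P1", "b": "P1", "c": "P1"})
        out = aggregate_peptides(table, pmap, min_peptides=3)
        assert out.loc[0, "importance"] == pytest.approx(0.6)

    def test_two_peptides_omitted(self):
        table = self._table([("a", 0.5), ("b", -0.7)])
        pmap = PeptideProteinMap({"a": "P1", "b": "P1"})
        assert aggregate_peptides(table, pmap, min_peptides=3).empty

    def test_majority_sign_average_excludes_dissenter(self):
        table = self._table([("a", 0.5), ("b", 0.6), ("c", 0.7), ("d", -0.9)])
        pmap = PeptideProteinMap({v: "P1" for v in "abcd"})
        out = aggregate_peptides(table, pmap, min_peptides=3)
        assert out.loc[0, "importance"] == pytest.approx(0.6)
        assert out.loc[0, "n_agreeing"] == 3

    def test_negative_majority(self):
        table = self._table([("a", -0.5), ("b", -0.6), ("c", -0.7), ("d", 0.9)])
        pmap = PeptideProteinMap({v: "P1" for v in "abcd"})
        out = aggregate_peptides(table, pmap, min_peptides=3)
        assert out.loc[0, "importance"] == pytest.approx(-0.6)

    def test_unmapped_peptides_ignored(self):
        table = self._table([("a", 0.5), ("b", 0.6), ("c", 0.7), ("z", 1.0)])
        pmap = PeptideProteinMap({v: "P1" for v in "abc"})
        out = aggregate_peptides(table, pmap, min_peptides=3)
        assert len(out) == 1 and out.loc[0, "n_peptides"] == 3


class TestCorrelationMatrix:
    def test_perfect_linear_and_anticorrelation(self, tiny_blocks, tiny_labels):
        from midfuse.datamodel import OmicsBlock, align_blocks
        x = np.array([1.0, 2.0, 4.0, 7.0])
        vals = np.column_stack([x, 2 * x + 1, -x])
        block = OmicsBlock("b", ["s1", "s2", "s3", "s4"], ["x", "y", "z"], vals)
        study = align_blocks([block], {s: 1 if s != "s4" else 2 for s in block.sample_ids})
        # class 1 has 3 samples
        R = correlation_matrix(study, 1)
        assert R.loc["x", "y"] == pytest.approx(1.0)
        assert R.loc["x", "z"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_matches_two_pass_formula(self, rng):
        from midfuse.datamodel import OmicsBlock, align_blocks
        X = rng.standard_normal((15, 20))
        ids = [f"s{i}" for i in range(15)]
        block = OmicsBlock("b", ids, [f"v{j}" for j in range(20)], X)
        study = align_blocks([block], {s: 1 for i, s in enumerate(ids[:-1])} | {ids[-1]: 2})
        R = correlation_matrix(study, 1).to_numpy()
        Xc = X[:-1]
        expected = np.corrcoef(Xc, rowvar=False)
        np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_constant_variable_flagged_zero(self):
        from midfuse.datamodel import OmicsBlock, align_blocks
        vals = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [9.0, 1.0]])
        block = OmicsBlock("b", ["s1", "s2", "s3", "s4"], ["x", "const"], vals)
        study = align_blocks([block], {"s1": 1, "s2": 1, "s3": 1, "s4": 2})
        R = correlation_matrix(study, 1)
        assert R.loc["x", "const"] == 0.0

    def test_cross_block_uses_common_samples(self, rng):
        import warnings as _w
        from midfuse.datamodel import OmicsBlock, align_blocks
        ids = [f"s{i}" for i in range(9)]
        xa = rng.standard_normal(9)
        a = OmicsBlock("a", ids, ["va"], xa[:, None])
        b = OmicsBlock("b", ids[:6], ["vb"], (2 * xa[:6] + 0.01 * rng.standard_normal(6))[:, None])
        labels = {s: 1 for s in ids[:-1]} | {ids[-1]: 2}
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # class 2 absent from block b
            study = align_blocks([a, b], labels)
        R = correlation_matrix(study, 1)
        manual = np.corrcoef(xa[:6], b.values[:, 0])[0, 1]
        assert R.loc["va", "vb"] == pytest.approx(manual, abs=1e-12)


class TestNetwork:
    def _matrices(self):
        ids = ["a", "b", "c"]
        R1 = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        R1.loc["a", "b"] = R1.loc["b", "a"] = 0.8     # exactly at threshold
        R1.loc["a", "c"] = R1.loc["c", "a"] = 0.95
        R2 = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        R2.loc["b", "c"] = R2.loc["c", "b"] = -0.85
        return {1: R1, 2: R2}

    def test_threshold_is_strict(self):
        net = build_network(self._matrices(), threshold=0.8)
        pairs = {(a, b, c) for a, b, c, _ in net.edges}
        assert ("a", "b", 1) not in pairs          # r = 0.8 exactly: no edge
        assert ("a", "c", 1) in pairs
        assert ("b", "c", 2) in pairs              # |-0.85| > 0.8

    def test_edge_set_matches_brute_force(self, rng):
        ids = [f"v{j}" for j in range(10)]
        mats = {}
        for cls in (1, 2):
            M = rng.uniform(-1, 1, (10, 10))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            mats[cls] = pd.DataFrame(M, index=ids, columns=ids)
        net = build_network(mats, threshold=0.8)
        expected = sum(1 for cls in (1, 2) for i in range(10) for j in range(i + 1, 10)
                       if abs(mats[cls].iloc[i, j]) > 0.8)
        assert len(net.edges) == expected

    def test_subnetwork_chain_two_layers(self):
        ids = list("abcd")
        R = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        for u, v in [("a", "b"), ("b", "c"), ("c", "d")]:
            R.loc[u, v] = R.loc[v, u] = 0.9
        net = build_network({1: R}, 0.8)
        sub = extract_subnetwork(net, ["a"], layers=2)
        assert set(sub.nodes) == {"a", "b", "c"}

    def test_subnetwork_isolated_seed(self):
        ids = ["a", "b"]
        R = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        net = build_network({1: R}, 0.8)
        sub = extract_subnetwork(net, ["a"], layers=2)
        assert set(sub.nodes) == {"a"} and sub.edges == []

    def test_subnetwork_saturates_at_component(self):
        ids = list("abcd")
        R = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        for u, v in [("a", "b"), ("b", "c"), ("c", "d")]:
            R.loc[u, v] = R.loc[v, u] = 0.9
        net = build_network({1: R}, 0.8)
        sub = extract_subnetwork(net, ["a"], layers=10)
        assert set(sub.nodes) == set(ids)

    def test_subnetwork_monotone_in_layers(self):
        ids = list("abcde")
        R = pd.DataFrame(np.eye(5), index=ids, columns=ids)
        for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]:
            R.loc[u, v] = R.loc[v, u] = 0.9
        net = build_network({1: R}, 0.8)
        prev: set = set()
        for layers in (1, 2, 3, 4):
            nodes = set(extract_subnetwork(net, ["a"], layers).nodes)
            assert prev <= nodes
            prev = nodes

    def test_unknown_seed_rejected(self):
        ids = ["a"]
        net = build_network({1: pd.DataFrame([[1.0]], index=ids, columns=ids)}, 0.8)
        with pytest.raises(KeyError, match="unknown seed"):
            extract_subnetwork(net, ["zzz"])


class TestExportDot:
    def test_empty_network_valid_header(self):
        from midfuse.interpret import CorrelationNetwork
        dot = export_dot(CorrelationNetwork({}, []))
        assert dot.startswith("graph correlation_network {")
        assert dot.rstrip().endswith("}")

    def test_disease_edge_is_dotted_and_reference_solid(self):
        ids = ["a", "b", "c"]
        R1 = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        R1.loc["a", "b"] = R1.loc["b", "a"] = 0.9
        R3 = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        R3.loc["a", "c"] = R3.loc["c", "a"] = 0.9
        net = build_network({1: R1, 3: R3}, 0.8, important={"a"})
        dot = export_dot(net, reference_class=1)
        assert dot.count("style=dotted") == 1
        assert dot.count("style=solid") == 1
        assert '"a" [shape=box];' in dot
        assert '"b" [shape=ellipse];' in dot

    def test_parse_back_counts(self):
        ids = [f"v{j}" for j in range(6)]
        R = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        for i in range(5):
            R.iloc[i, i + 1] = R.iloc[i + 1, i] = 0.9
        net = build_network({2: R}, 0.8)
        dot = export_dot(net)
        node_lines = [l for l in dot.splitlines() if "[shape=" in l]
        edge_lines = [l for l in dot.splitlines() if " -- " in l]
        assert len(node_lines) == len(net.nodes)
        assert len(edge_lines) == len(net.edges)

    def test_byte_deterministic(self):
        ids = list("xyz")
        R = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        R.loc["x", "y"] = R.loc["y", "x"] = 0.9
        net = build_network({1: R}, 0.8)
        assert export_dot(net) == export_dot(build_network({1: R.copy()}, 0.8))
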