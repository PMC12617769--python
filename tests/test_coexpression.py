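"""Signed adjacency, TOM, module detection/merging and trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from trinet import coexpression as cx
from trinet.datatypes import OmicsMatrix


def _expr(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return OmicsMatrix(
        pd.DataFrame(arr, index=[f"{prefix}{i:04d}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        "protein_log_abundance",
    )


def planted_modules(rng, n_modules=3, size=150, background=300, n_samples=40, cor=0.8):
    rows, labels = [], []
    for m in range(n_modules):
        factor = rng.normal(0, 1, n_samples)
        for _ in range(size):
            rows.append(np.sqrt(cor) * factor + np.sqrt(1 - cor) * rng.normal(0, 1, n_samples))
            labels.append(m + 1)
    for _ in range(background):
        rows.append(rng.normal(0, 1, n_samples))
        labels.append(0)
    return _expr(rows), np.array(labels)


class TestAdjacency:
    def test_endpoints_of_signed_map(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        expr = _expr([base, base * 2 + 1, -base])
        a = cx.signed_adjacency(expr, cx.CoexpressionParams(beta=15)).to_numpy()
        assert a[0, 1] == pytest.approx(1.0)  # cor +1
        assert a[0, 2] == pytest.approx(0.0, abs=1e-15)  # cor -1

    def test_zero_correlation_value(self):
        expr = _expr([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        a = cx.signed_adjacency(expr, cx.CoexpressionParams(beta=15)).to_numpy()
        assert a[0, 1] == pytest.approx(0.5**15)

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.normal(0, 1, (30, 12)))
        a = cx.signed_adjacency(expr, cx.CoexpressionParams()).to_numpy()
        assert np.allclose(a, a.T)
        assert (a >= 0).all() and (a <= 1).all()
        assert np.allclose(np.diag(a), 1.0)

    def test_zero_variance_feature_rejected(self):
        expr = _expr([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError):
            cx.signed_adjacency(expr, cx.CoexpressionParams())


class TestTOM:
    def test_two_gene_network_collapses_to_adjacency(self):
        a = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=["a", "b"], columns=["a", "b"])
        tom = cx.tom_similarity(a)
        assert tom.iloc[0, 1] == pytest.approx(0.3)

    def test_complete_module_saturates(self):
        a = pd.DataFrame(np.ones((5, 5)))
        assert np.allclose(cx.tom_similarity(a).to_numpy(), 1.0)

    def test_matches_elementwise_formula_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            raw = rng.uniform(0, 1, (5, 5))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 1.0)
            adf = pd.DataFrame(a)
            tom = cx.tom_similarity(adf).to_numpy()
            k = a.sum(axis=1) - 1
            for i in range(5):
                for j in range(5):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    shared = sum(a[i, u] * a[u, j] for u in range(5) if u not in (i, j))
                    expect = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                    assert tom[i, j] == pytest.approx(expect, abs=1e-12)

    def test_dissimilarity_axioms(self):
        rng = np.random.default_rng(6)
        expr = _expr(rng.normal(0, 1, (40, 15)))
        tom = cx.tom_similarity(cx.signed_adjacency(expr, cx.CoexpressionParams())).to_numpy()
        d = 1 - tom
        assert (d >= -1e-12).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            cx.tom_similarity(pd.DataFrame([[1.0, 0.2], [0.4, 1.0]]))


class TestModules:
    def test_planted_modules_recovered(self):
        rng = np.random.default_rng(7)
        expr, truth = planted_modules(rng)
        modules = cx.run_wgcna(expr, cx.CoexpressionParams())
        mask = truth != 0
        ari = adjusted_rand_score(truth[mask], modules.labels.to_numpy()[mask])
        assert ari >= 0.9
        assert len(modules.module_ids) == 3

    def test_too_few_genes_all_unassigned(self):
        rng = np.random.default_rng(8)
        expr = _expr(rng.normal(0, 1, (50, 10)))
        with pytest.warns(UserWarning):
            labels = cx.detect_modules(pd.DataFrame(np.ones((50, 50)) - np.eye(50),
                                                    index=expr.features, columns=expr.features),
                                       cx.CoexpressionParams(min_module_size=100))
        assert (labels == 0).all()

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        expr, _ = planted_modules(rng, n_modules=2, size=60, background=60, n_samples=20)
        a = cx.run_wgcna(expr, cx.CoexpressionParams(min_module_size=30))
        b = cx.run_wgcna(expr, cx.CoexpressionParams(min_module_size=30))
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestEigengenes:
    def test_identical_profiles_give_perfect_membership(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = _expr([profile, profile * 2, profile + 1])
        labels = pd.Series(1, index=expr.features)
        e = cx.eigengenes(expr, labels)
        r = np.corrcoef(e.loc[1], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign convention: positively oriented to members

    def test_latent_factor_recovered(self):
        rng = np.random.default_rng(10)
        factor = rng.normal(0, 1, 30)
        rows = [np.sqrt(0.8) * factor + np.sqrt(0.2) * rng.normal(0, 1, 30) for _ in range(80)]
        expr = _expr(rows)
        labels = pd.Series(1, index=expr.features)
        e = cx.eigengenes(expr, labels).loc[1]
        assert abs(np.corrcoef(e, factor)[0, 1]) >= 0.9

    def test_unit_norm(self):
        rng = np.random.default_rng(11)
        expr = _expr(rng.normal(0, 1, (20, 10)))
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.features)
        e = cx.eigengenes(expr, labels)
        np.testing.assert_allclose(np.linalg.norm(e.to_numpy(), axis=1), 1.0, rtol=1e-12)


class TestMerging:
    def test_same_factor_modules_merge(self):
        rng = np.random.default_rng(12)
        factor = rng.normal(0, 1, 30)
        rows = [np.sqrt(0.8) * factor + np.sqrt(0.2) * rng.normal(0, 1, 30) for _ in range(120)]
        expr = _expr(rows)
        labels = pd.Series([1] * 60 + [2] * 60, index=expr.features)
        eig = cx.eigengenes(expr, labels)
        merged = cx.merge_modules(expr, labels, eig, merge_cut=0.16)
        assert len(merged.module_ids) == 1

    def test_distinct_factors_do_not_merge(self):
        rng = np.random.default_rng(13)
        f1, f2 = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        rows = [np.sqrt(0.9) * f + np.sqrt(0.1) * rng.normal(0, 1, 30)
                for f in (f1,) * 60 + (f2,) * 60]
        expr = _expr(rows)
        labels = pd.Series([1] * 60 + [2] * 60, index=expr.features)
        eig = cx.eigengenes(expr, labels)
        assert abs(np.corrcoef(eig.loc[1], eig.loc[2])[0, 1]) < 0.84
        merged = cx.merge_modules(expr, labels, eig, merge_cut=0.16)
        assert len(merged.module_ids) == 2

    def test_gene_reassigned_to_highest_membership(self):
        rng = np.random.default_rng(14)
        f1, f2 = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        rows = [0.95 * f1 + 0.05 * rng.normal(0, 1, 40) for _ in range(30)]
        rows += [0.95 * f2 + 0.05 * rng.normal(0, 1, 40) for _ in range(30)]
        expr = _expr(rows)
        # mislabel one strong module-1 gene as module 2
        labels = pd.Series([1] * 30 + [2] * 30, index=expr.features)
        labels.iloc[0] = 2
        merged = cx.merge_modules(expr, labels, cx.eigengenes(expr, labels), merge_cut=0.16)
        assert merged.labels.iloc[0] == merged.labels.iloc[1]


class TestModuleTrait:
    def test_eigengene_equal_to_trait_flagged_positive(self):
        rng = np.random.default_rng(15)
        expr = _expr(rng.normal(0, 1, (10, 12)))
        labels = pd.Series(1, index=expr.features)
        e = cx.eigengenes(expr, labels)
        modules = cx.NetworkModules(labels=labels, eigengenes=e, kme=cx._kme(expr, e))
        traits = pd.DataFrame({"t": e.loc[1].to_numpy()}, index=e.columns)
        out = cx.module_trait(modules, traits)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["flag"] == "positive"

    def test_matches_pearson_oracle_on_toy(self):
        rng = np.random.default_rng(16)
        expr = _expr(rng.normal(0, 1, (8, 10)))
        labels = pd.Series(1, index=expr.features)
        e = cx.eigengenes(expr, labels)
        modules = cx.NetworkModules(labels=labels, eigengenes=e, kme=cx._kme(expr, e))
        t = rng.normal(0, 1, 10)
        out = cx.module_trait(modules, pd.DataFrame({"t": t}, index=e.columns))
        r_exp, p_exp = stats.pearsonr(e.loc[1].to_numpy(), t)
        assert out.iloc[0]["r"] == pytest.approx(r_exp)
        assert out.iloc[0]["p"] == pytest.approx(p_exp)

    def test_boundary_r_exactly_cut_not_flagged(self):
        assert cx.flag_module_trait(0.6, 0.001) == "none"
        assert cx.flag_module_trait(0.61, 0.001) == "positive"
        assert cx.flag_module_trait(-0.6, 0.001) == "none"
        assert cx.flag_module_trait(-0.7, 0.2) == "none"

    def test_constant_trait_reported_missing(self):
        rng = np.random.default_rng(17)
        expr = _expr(rng.normal(0, 1, (6, 8)))
        labels = pd.Series(1, index=expr.features)
        e = cx.eigengenes(expr, labels)
        modules = cx.NetworkModules(labels=labels, eigengenes=e, kme=cx._kme(expr, e))
        out = cx.module_trait(modules, pd.DataFrame({"t": np.ones(8)}, index=e.columns))
        assert np.isnan(out.iloc[0]["r"])
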