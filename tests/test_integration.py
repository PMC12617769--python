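"""Correlation cascade: selection thresholds, pair correlation, protein
overlay, export round-trips and cascade monotonicity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trinet import diffexpr as de
from trinet import integration as intg
from trinet.datatypes import OmicsMatrix, TIME_POINTS


def _de_table(rows):
    return pd.DataFrame(rows).set_index("feature")


class TestSelect:
    def test_boundary_lfc_one_excluded(self):
        t = _de_table([
            {"feature": "m1", "log2FC": 0.9, "padj": 0.01},
            {"feature": "m2", "log2FC": 1.0, "padj": 0.01},
            {"feature": "m3", "log2FC": 1.1, "padj": 0.01},
            {"feature": "m4", "log2FC": -1.5, "padj": 0.01},
            {"feature": "m5", "log2FC": 3.0, "padj": 0.06},
        ])
        up, down = intg.select_de_mirnas(t)
        assert up == ["m3"]
        assert down == ["m4"]

    def test_union_over_time_points(self):
        t1 = _de_table([{"feature": "m1", "log2FC": 2.0, "padj": 0.01}])
        t2 = _de_table([{"feature": "m2", "log2FC": -2.0, "padj": 0.01}])
        up, down = intg.select_de_mirnas([t1, t2])
        assert up == ["m1"] and down == ["m2"]

    def test_empty(self):
        up, down = intg.select_de_mirnas(pd.DataFrame(columns=["log2FC", "padj"]))
        assert up == [] and down == []


class TestCorrelatePairs:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        mi = pd.DataFrame([x], index=["m1"], columns=[f"s{i}" for i in range(6)])
        mr = pd.DataFrame([-x], index=["g1"], columns=[f"s{i}" for i in range(6)])
        pairs = intg.correlate_pairs(mi, mr, {"m1": ["g1"]})
        assert pairs.iloc[0]["r_mm"] == pytest.approx(-1.0)

    def test_matches_pearsonr_oracle_on_toy(self):
        rng = np.random.default_rng(0)
        mi = pd.DataFrame(rng.normal(0, 1, (2, 8)), index=["m1", "m2"],
                          columns=[f"s{i}" for i in range(8)])
        mr = pd.DataFrame(rng.normal(0, 1, (3, 8)), index=["g1", "g2", "g3"],
                          columns=[f"s{i}" for i in range(8)])
        pairs = intg.correlate_pairs(mi, mr, {"m1": ["g1", "g2"], "m2": ["g3"]})
        for row in pairs.itertuples(index=False):
            r_exp, p_exp = stats.pearsonr(mi.loc[row.mirna], mr.loc[row.mrna])
            assert row.r_mm == pytest.approx(r_exp, abs=1e-12)
            assert row.p_mm == pytest.approx(p_exp, rel=1e-9)

    def test_missing_target_skipped(self):
        x = np.arange(6.0)
        mi = pd.DataFrame([x], index=["m1"], columns=[f"s{i}" for i in range(6)])
        mr = pd.DataFrame([x], index=["g1"], columns=[f"s{i}" for i in range(6)])
        pairs = intg.correlate_pairs(mi, mr, {"m1": ["g1", "ghost"]})
        assert len(pairs) == 1

    def test_too_few_shared_samples_rejected(self):
        mi = pd.DataFrame([[1.0, 2.0]], index=["m1"], columns=["s0", "s1"])
        mr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s0", "s1"])
        with pytest.raises(ValueError):
            intg.correlate_pairs(mi, mr, {"m1": ["g1"]})


class TestFilterPairs:
    @pytest.fixture
    def pairs(self):
        return pd.DataFrame(
            {
                "mirna": ["m"] * 3,
                "mrna": ["a", "b", "c"],
                "r_mm": [-0.9, -0.85, -0.95],
                "p_mm": [0.001] * 3,
                "padj_mm": [0.01, 0.01, 0.2],
                "n_samples": [40] * 3,
            }
        )

    def test_boundary_semantics(self, pairs):
        kept = intg.filter_pairs(pairs)
        # r = -0.85 exactly is rejected (strict <), padj 0.2 is rejected
        assert list(kept["mrna"]) == ["a"]

    def test_monotone_in_thresholds(self, pairs):
        loose = set(intg.filter_pairs(pairs, r_cut=-0.8, padj_cut=0.1)["mrna"])
        tight = set(intg.filter_pairs(pairs, r_cut=-0.92, padj_cut=0.02)["mrna"])
        assert tight <= loose


class TestOverlay:
    def _inputs(self):
        groups = [("sham", tp) for tp in TIME_POINTS] + [("sci", tp) for tp in TIME_POINTS]
        rows = []
        for cond, tp in groups:
            for i in range(2):
                rows.append({"sample_id": f"{cond}_{tp}_{i+1}", "condition": cond, "time_point": tp})
        design = pd.DataFrame(rows)
        rng = np.random.default_rng(1)
        n = len(design)
        sci = (design["condition"] == "sci").to_numpy().astype(float)
        mi = pd.DataFrame([2.0 * sci + rng.normal(0, 0.1, n)], index=["m1"],
                          columns=design["sample_id"].tolist())
        prot_down = -1.5 * sci + rng.normal(0, 0.1, n)
        prot_up = 1.5 * sci + rng.normal(0, 0.1, n)
        protein = OmicsMatrix(
            pd.DataFrame([prot_down, prot_up], index=["g1", "g2"],
                         columns=design["sample_id"].tolist()),
            "protein_log_abundance",
        )
        pairs = pd.DataFrame(
            {"mirna": ["m1", "m1"], "mrna": ["g1", "g2"], "r_mm": [-0.95, -0.9],
             "p_mm": [1e-6] * 2, "padj_mm": [1e-4] * 2, "n_samples": [n] * 2}
        )
        return design, mi, protein, pairs

    def test_negative_protein_correlation_required(self):
        design, mi, protein, pairs = self._inputs()
        net = intg.overlay_protein(pairs, protein, mi, mirna_design=design,
                                   protein_design=design, mirna_directions={"m1": "up"})
        # g1 protein anti-correlates -> kept; g2 protein rises with the miRNA -> dropped
        assert list(net.triplets["mrna"]) == ["g1"]
        assert net.triplets.iloc[0]["r_mp"] < 0

    def test_zero_boundary_is_strict(self):
        design, mi, protein, pairs = self._inputs()
        net = intg.overlay_protein(pairs, protein, mi, mirna_design=design,
                                   protein_design=design, r_mp_cut=0.0)
        kept = intg.overlay_protein(pairs, protein, mi, mirna_design=design,
                                    protein_design=design, r_mp_cut=-0.99)
        # tightening the cut can only shrink the triplet set
        assert set(kept.triplets["mrna"]) <= set(net.triplets["mrna"])

    def test_missing_protein_blocks_promotion(self):
        design, mi, protein, pairs = self._inputs()
        gone = OmicsMatrix(protein.data.drop(index=["g1"]), "protein_log_abundance")
        net = intg.overlay_protein(pairs, gone, mi, mirna_design=design, protein_design=design)
        assert "g1" not in set(net.triplets["mrna"])

    def test_sample_matched_mode(self):
        design, mi, protein, pairs = self._inputs()
        net = intg.overlay_protein(pairs, protein, mi, matching="sample-matched")
        assert list(net.triplets["mrna"]) == ["g1"]


class TestExport:
    def _net(self):
        t = pd.DataFrame(
            [
                {"mirna": "m1", "mrna": "g1", "protein": "g1", "r_mm": -0.9, "padj_mm": 0.01,
                 "r_mp": -0.5, "direction_mirna": "up", "direction_target": "down", "bridge": False},
                {"mirna": "m2", "mrna": "g2", "protein": "g2", "r_mm": -0.88, "padj_mm": 0.02,
                 "r_mp": -0.1, "direction_mirna": "down", "direction_target": "up", "bridge": True},
            ]
        )
        return intg.Interactome(triplets=t)

    def test_round_trip(self, tmp_path):
        net = self._net()
        intg.export_interactome(net, tmp_path)
        back = intg.read_interactome(tmp_path)
        a = set(map(tuple, net.triplets[["mirna", "mrna", "protein"]].to_numpy()))
        b = set(map(tuple, back.triplets[["mirna", "mrna", "protein"]].to_numpy()))
        assert a == b

    def test_graph_structure(self):
        g = self._net().graph
        assert g.number_of_nodes() == 6  # 2 mirnas + 2 mrnas + 2 proteins
        types = {d["node_type"] for _, d in g.nodes(data=True)}
        assert types == {"mirna", "mrna", "protein"}
        for _, _, d in g.edges(data=True):
            assert d["edge_type"] in ("mirna-mrna", "mrna-protein")

    def test_empty_interactome_exports_valid_files(self, tmp_path):
        net = intg.Interactome(triplets=pd.DataFrame(columns=list(intg.TRIPLET_COLUMNS)))
        intg.export_interactome(net, tmp_path)
        back = intg.read_interactome(tmp_path)
        assert len(back.triplets) == 0


class TestCascadeRecovery:
    def test_planted_triplets_recovered_and_shuffle_collapses(self, small_dataset):
        d = small_dataset
        norm_mr = de.size_factors(d.mrna)
        norm_mi = de.size_factors(d.mirna)
        filt_mi = de.filter_low_expression(norm_mi, 5.0)
        de_mi = [de.nb_wald_test(filt_mi, d.design, ("sci", "sham", tp)) for tp in TIME_POINTS]
        up, down = intg.select_de_mirnas(de_mi)
        dirs = {m: "up" for m in up} | {m: "down" for m in down}
        ids = list(d.design[d.design["condition"].isin(["sham", "sci"])]["sample_id"])
        mi_expr = intg.log10_normalized(d.mirna.subset_samples(ids), norm_mi.size_factors)
        mr_expr = intg.log10_normalized(d.mrna.subset_samples(ids), norm_mr.size_factors)
        pairs = intg.correlate_pairs(mi_expr, mr_expr, d.truth.target_map, sorted(dirs))
        surv = intg.filter_pairs(pairs)
        net = intg.overlay_protein(surv, d.protein, mi_expr, mirna_design=d.design,
                                   protein_design=d.protein_design, mirna_directions=dirs)
        pred = set(zip(net.triplets["mirna"], net.triplets["mrna"]))
        true = {(mi, mr) for mi, mr, _ in d.truth.true_triplets}
        hits = len(pred & true)
        assert hits / len(true) >= 0.7
        assert hits / max(len(pred), 1) >= 0.7
        # every triplet reachable through the target map
        for mi, mr in pred:
            assert mr in d.truth.target_map[mi]
        # breaking the sample correspondence destroys the pairs
        rng = np.random.default_rng(3)
        shuffled = mr_expr.copy()
        shuffled.columns = list(rng.permutation(mr_expr.columns))
        shuffled = shuffled[mr_expr.columns]
        null_pairs = intg.correlate_pairs(mi_expr, shuffled, d.truth.target_map, sorted(dirs))
        assert len(intg.filter_pairs(null_pairs)) <= 1
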