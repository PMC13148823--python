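"""Detection sets, differential abundance, complex summaries, integration."""

import numpy as np
import pandas as pd
import pytest

from mitoflux import omics, syndata
from mitoflux.annotation import builtin_fixture_annotation
from mitoflux.normalize import compute_mef
from mitoflux.omics import (
    AbundanceMatrix,
    complex_summaries,
    detect_features,
    differential_abundance,
    integrate_layers,
    summed_mito_abundance,
)

from conftest import make_config


def matrix_from(values: dict, groups: dict, layer="protein"):
    vals = pd.DataFrame(values)
    vals.index.name = "feature_id"
    return AbundanceMatrix(values=vals, groups=pd.Series(groups), layer=layer)


class TestDetection:
    def test_partition_definitions(self):
        m = matrix_from(
            {
                "b1": [1.0, 1.0, np.nan],
                "b2": [1.0, 1.0, np.nan],
                "t1": [1.0, np.nan, 1.0],
                "t2": [1.0, np.nan, 1.0],
            },
            {"b1": "benign", "b2": "benign", "t1": "tumor", "t2": "tumor"},
        )
        m.values.index = ["shared", "benign_only", "tumor_only"]
        ds = detect_features(m, min_samples=2)
        assert ds.shared == {"shared"}
        assert ds.group1_only == {"benign_only"}
        assert ds.group2_only == {"tumor_only"}
        assert ds.all_detected == {"shared", "benign_only", "tumor_only"}

    def test_min_samples_exceeding_group_size_rejected(self):
        m = matrix_from({"b1": [1.0], "t1": [1.0]}, {"b1": "benign", "t1": "tumor"})
        with pytest.raises(ValueError, match="exceeds"):
            detect_features(m, min_samples=2)


class TestDifferentialAbundance:
    def test_identical_groups_give_zero_log2fc(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(10, 1, 50)
        m = matrix_from(
            {"b1": col, "b2": col * 1.0, "t1": col, "t2": col},
            {"b1": "benign", "b2": "benign", "t1": "tumor", "t2": "tumor"},
        )
        de = differential_abundance(m, pseudocount=0.0)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)

    def test_noiseless_twofold_shift_gives_log2fc_one(self):
        col = np.array([100.0, 200.0, 400.0])
        m = matrix_from(
            {"b1": col, "b2": col, "t1": 2 * col, "t2": 2 * col},
            {"b1": "benign", "b2": "benign", "t1": "tumor", "t2": "tumor"},
        )
        de = differential_abundance(m, pseudocount=0.0)
        np.testing.assert_allclose(de["log2fc"], 1.0, atol=1e-12)
        # noiseless -> zero variance in both groups: flagged, p = 1, not NaN
        assert de["zero_variance"].all()
        np.testing.assert_allclose(de["p"], 1.0)

    def test_effect_sign_recovered_for_mito_features(self):
        cfg = make_config(sigma=0.25, n_omics=6)
        cfg.groups["tumor"].content_scale = 1.0
        cfg.groups["tumor"].mito_log2fc = -1.0
        sim = syndata.simulate_proteome(cfg, 5)
        de = differential_abundance(sim.abundance).set_index("feature_id")
        mito = sim.truth.loc[sim.truth["is_mito"], "feature_id"]
        signs = de.loc[mito, "log2fc"] < 0
        assert signs.mean() >= 0.95

    def test_fdr_controlled_under_global_null(self):
        """Mean fraction of padj < 0.1 calls under the null stays <= 0.1."""
        rng = np.random.default_rng(99)
        n_feat, n, reps = 1000, 6, 200
        fractions = []
        groups = {f"b{i}": "benign" for i in range(n)} | {
            f"t{i}": "tumor" for i in range(n)
        }
        for _ in range(reps):
            vals = rng.lognormal(10.0, 0.5, size=(n_feat, 2 * n))
            m = matrix_from(
                {s: vals[:, j] for j, s in enumerate(groups)}, groups
            )
            de = differential_abundance(m, pseudocount=0.0)
            fractions.append((de["padj"] < 0.1).mean())
        assert np.mean(fractions) <= 0.1


class TestSummedAbundance:
    def test_no_mito_features_gives_zero(self):
        ann = pd.DataFrame(
            {"feature_id": ["A"], "gene_symbol": ["A"], "is_mito": [False],
             "complex": ["none"], "pathway_tags": [""]}
        )
        m = matrix_from({"b1": [5.0], "t1": [7.0]}, {"b1": "benign", "t1": "tumor"})
        m.values.index = ["A"]
        per_sample, per_group = summed_mito_abundance(m, ann)
        assert (per_sample == 0).all()

    def test_hand_summed_toy_table_and_mef_consistency(self):
        ann = pd.DataFrame(
            {
                "feature_id": ["A", "B", "C"],
                "gene_symbol": ["A", "B", "C"],
                "is_mito": [True, True, False],
                "complex": ["CI", "none", "none"],
                "pathway_tags": ["", "", ""],
            }
        )
        m = matrix_from({"b1": [30.0, 20.0, 50.0], "t1": [10.0, 10.0, 80.0]},
                        {"b1": "benign", "t1": "tumor"})
        m.values.index = ["A", "B", "C"]
        per_sample, per_group = summed_mito_abundance(m, ann)
        assert per_sample["b1"] == pytest.approx(50.0)
        assert per_sample["t1"] == pytest.approx(20.0)
        # equals the MEF numerator exactly
        mef, mef_per_sample = compute_mef(m, ann)
        totals = m.values.sum(axis=0)
        np.testing.assert_allclose(per_sample / totals, mef_per_sample)


class TestComplexSummaries:
    ann = pd.DataFrame(
        {
            "feature_id": ["a1", "a2", "b1", "m1", "x1", "x2"],
            "gene_symbol": ["a1", "a2", "b1", "m1", "x1", "x2"],
            "is_mito": [True, True, True, True, False, False],
            "complex": ["CI", "CI", "CII", "none", "none", "none"],
            "pathway_tags": [""] * 6,
        }
    )

    def make(self, col):
        m = matrix_from({"s1": col, "s2": col}, {"s1": "benign", "s2": "benign"})
        m.values.index = self.ann["feature_id"].tolist()
        return m

    def test_hand_computed_toy_ratios(self):
        # mito total = 10+20+30+40 = 100; grand total = 160
        m = self.make([10.0, 20.0, 30.0, 40.0, 50.0, 10.0])
        by_mito = complex_summaries(m, self.ann, denominator="mito")
        ci = by_mito[(by_mito["complex"] == "CI") & (by_mito.sample_id == "s1")]
        cii = by_mito[(by_mito["complex"] == "CII") & (by_mito.sample_id == "s1")]
        assert ci["relative_abundance"].iloc[0] == pytest.approx(30.0 / 100.0)
        assert cii["relative_abundance"].iloc[0] == pytest.approx(30.0 / 100.0)

    def test_single_complex_holding_all_mito_abundance(self):
        m = self.make([60.0, 40.0, 0.0, 0.0, 25.0, 25.0])
        out = complex_summaries(m, self.ann, denominator="mito")
        ci = out[(out["complex"] == "CI") & (out.sample_id == "s1")]
        assert ci["relative_abundance"].iloc[0] == pytest.approx(1.0)

    def test_denominators_differ_by_mef_exactly(self):
        m = self.make([10.0, 20.0, 30.0, 40.0, 50.0, 10.0])
        by_mito = complex_summaries(m, self.ann, "mito").set_index(
            ["complex", "sample_id"])
        by_total = complex_summaries(m, self.ann, "total").set_index(
            ["complex", "sample_id"])
        mef, _ = compute_mef(m, self.ann)
        ratio = by_total["relative_abundance"] / by_mito["relative_abundance"]
        populated = ratio.loc[["CI", "CII"]]  # empty complexes give 0/0
        np.testing.assert_allclose(populated, mef["benign"])


class TestIntegration:
    @staticmethod
    def de(rows):
        return pd.DataFrame(rows, columns=["feature_id", "gene_symbol",
                                           "log2fc", "p", "padj"])

    def test_copied_log2fc_gives_perfect_correlation(self):
        ann = builtin_fixture_annotation(0, 0)
        genes = ann["gene_symbol"][:10]
        rng = np.random.default_rng(1)
        fc = rng.normal(size=10)
        rna = self.de([(g, g, f, 0.5, 0.5) for g, f in zip(genes, fc)])
        prot = self.de([(g, g.upper(), f, 0.5, 0.5) for g, f in zip(genes, fc)])
        res = integrate_layers(rna, prot, ann)
        assert res.pearson_r == pytest.approx(1.0)
        assert len(res.pairs) == 10  # case-insensitive matching

    def test_toy_overlap_enumeration(self):
        ann = builtin_fixture_annotation(0, 0)
        genes = list(ann["gene_symbol"][:5])
        # two jointly significant down/down, one up/up, rest mixed/ns
        rna = self.de([
            (genes[0], genes[0], -1.0, 0.01, 0.05),
            (genes[1], genes[1], -2.0, 0.01, 0.05),
            (genes[2], genes[2], 1.0, 0.01, 0.05),
            (genes[3], genes[3], -1.0, 0.5, 0.9),
            (genes[4], genes[4], -1.0, 0.01, 0.05),
        ])
        prot = self.de([
            (genes[0], genes[0], -0.5, 0.01, 0.05),
            (genes[1], genes[1], -1.5, 0.01, 0.05),
            (genes[2], genes[2], 2.0, 0.01, 0.05),
            (genes[3], genes[3], -1.0, 0.01, 0.05),
            (genes[4], genes[4], 1.0, 0.01, 0.05),
        ])
        res = integrate_layers(rna, prot, ann)
        assert res.down_down == {genes[0], genes[1]}
        assert res.up_up == {genes[2]}

    def test_independent_noise_correlation_near_permutation_null(self):
        ann = builtin_fixture_annotation(40, 200)
        genes = ann["gene_symbol"]
        rng = np.random.default_rng(7)
        x = rng.normal(size=len(genes))
        y = rng.normal(size=len(genes))
        rna = self.de([(g, g, f, 0.5, 0.9) for g, f in zip(genes, x)])
        prot = self.de([(g, g, f, 0.5, 0.9) for g, f in zip(genes, y)])
        res = integrate_layers(rna, prot, ann)
        # permutation null for |r|
        perm = np.array([
            np.corrcoef(x, rng.permutation(y))[0, 1] for _ in range(500)
        ])
        assert abs(res.pearson_r) < np.quantile(np.abs(perm), 0.99) + 0.05

    def test_empty_intersection_rejected(self):
        ann = builtin_fixture_annotation(0, 0)
        rna = self.de([("g1", "geneA", 1.0, 0.5, 0.5)])
        prot = self.de([("g2", "geneB", 1.0, 0.5, 0.5)])
        with pytest.raises(ValueError, match="no overlapping"):
            integrate_layers(rna, prot, ann)

    def test_duplicate_symbols_collapsed_by_abundance(self):
        ann = builtin_fixture_annotation(0, 0)
        g = ann["gene_symbol"].iloc[0]
        g2 = ann["gene_symbol"].iloc[1]
        rna = self.de([(g, g, 1.0, 0.5, 0.5), (g2, g2, 0.0, 0.5, 0.5)])
        prot = pd.DataFrame(
            {
                "feature_id": ["p1", "p2", "p3"],
                "gene_symbol": [g, g.upper(), g2],
                "log2fc": [5.0, -5.0, 0.0],
                "p": [0.5] * 3,
                "padj": [0.5] * 3,
                "base_mean": [100.0, 10.0, 1.0],
            }
        )
        res = integrate_layers(rna, prot, ann)
        row = res.pairs.set_index(res.pairs["gene_symbol"].str.casefold())
        assert row.loc[g.casefold(), "protein_log2fc"] == pytest.approx(5.0)
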