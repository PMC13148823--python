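"""MEF computation, Bradford factors, scheme algebra and H2O2 calibration."""

import numpy as np
import pandas as pd
import pytest

from mitoflux import normalize, syndata
from mitoflux.normalize import (
    NormalizationFactors,
    apply_normalization,
    calibrate_h2o2,
    compute_mef,
    protein_factor,
)
from mitoflux.omics import AbundanceMatrix

from conftest import ols_slope_oracle


def tiny_matrix(values, annotation_rows):
    features = [r["feature_id"] for r in annotation_rows]
    vals = pd.DataFrame({"s1": values}, index=pd.Index(features, name="feature_id"))
    ann = pd.DataFrame(annotation_rows)
    ann["pathway_tags"] = ""
    matrix = AbundanceMatrix(values=vals, groups=pd.Series({"s1": "benign"}))
    return matrix, ann


class TestMEF:
    def test_all_mito_gives_one(self):
        m, ann = tiny_matrix([10.0, 20.0], [
            {"feature_id": "A", "gene_symbol": "A", "is_mito": True, "complex": "none"},
            {"feature_id": "B", "gene_symbol": "B", "is_mito": True, "complex": "none"},
        ])
        mef, per_sample = compute_mef(m, ann)
        assert mef["benign"] == pytest.approx(1.0)

    def test_no_mito_gives_zero(self):
        m, ann = tiny_matrix([10.0, 20.0], [
            {"feature_id": "A", "gene_symbol": "A", "is_mito": False, "complex": "none"},
            {"feature_id": "B", "gene_symbol": "B", "is_mito": False, "complex": "none"},
        ])
        mef, _ = compute_mef(m, ann)
        assert mef["benign"] == pytest.approx(0.0)

    def test_hand_summed_toy_table(self):
        # mito A:30 over total 100 -> 0.30
        m, ann = tiny_matrix([30.0, 50.0, 20.0], [
            {"feature_id": "A", "gene_symbol": "A", "is_mito": True, "complex": "none"},
            {"feature_id": "B", "gene_symbol": "B", "is_mito": False, "complex": "none"},
            {"feature_id": "C", "gene_symbol": "C", "is_mito": False, "complex": "none"},
        ])
        mef, per_sample = compute_mef(m, ann)
        assert mef["benign"] == pytest.approx(0.30)
        assert per_sample["s1"] == pytest.approx(0.30)

    def test_adding_mito_abundance_strictly_increases_mef(self):
        rows = [
            {"feature_id": "A", "gene_symbol": "A", "is_mito": True, "complex": "none"},
            {"feature_id": "B", "gene_symbol": "B", "is_mito": False, "complex": "none"},
        ]
        m1, ann = tiny_matrix([30.0, 70.0], rows)
        m2, _ = tiny_matrix([40.0, 70.0], rows)
        assert compute_mef(m2, ann)[0]["benign"] > compute_mef(m1, ann)[0]["benign"]

    def test_zero_total_abundance_rejected(self):
        m, ann = tiny_matrix([0.0, 0.0], [
            {"feature_id": "A", "gene_symbol": "A", "is_mito": True, "complex": "none"},
            {"feature_id": "B", "gene_symbol": "B", "is_mito": False, "complex": "none"},
        ])
        with pytest.raises(ValueError, match="zero total"):
            compute_mef(m, ann)


class TestProteinFactor:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["sample_id", "group", "wet_mg", "protein_ug"])

    def test_single_sample_arithmetic(self):
        pf = protein_factor(self.table([("s1", "benign", 10.0, 800.0)]))
        assert pf["benign"] == pytest.approx(80.0)

    def test_group_average(self):
        pf = protein_factor(self.table([
            ("s1", "tumor", 10.0, 800.0), ("s2", "tumor", 10.0, 1200.0)
        ]))
        assert pf["tumor"] == pytest.approx(100.0)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError, match="wet_mg"):
            protein_factor(self.table([("s1", "benign", 0.0, 10.0)]))
        with pytest.raises(ValueError, match="protein_ug"):
            protein_factor(self.table([("s1", "benign", 10.0, -1.0)]))


def flux_table():
    return pd.DataFrame(
        [
            {"sample_id": "b1", "group": "benign", "state": "PMDGS", "jo2": 10.0},
            {"sample_id": "b2", "group": "benign", "state": "PMDGS", "jo2": 12.0},
            {"sample_id": "t1", "group": "tumor", "state": "PMDGS", "jo2": 70.0},
        ]
    )


class TestApplyNormalization:
    factors = NormalizationFactors(
        protein_ug_per_mg={"benign": 40.0, "tumor": 100.0},
        mef={"benign": 0.15, "tumor": 0.10},
    )

    def test_mef_of_one_equals_total_protein_scheme(self):
        fac = NormalizationFactors(
            protein_ug_per_mg={"benign": 40.0, "tumor": 100.0},
            mef={"benign": 1.0, "tumor": 1.0},
        )
        tp = apply_normalization(flux_table(), "total_protein", fac)
        me = apply_normalization(flux_table(), "mef", fac)
        np.testing.assert_allclose(tp["jo2"], me["jo2"])

    def test_halving_mef_doubles_normalized_flux(self):
        half = NormalizationFactors(
            protein_ug_per_mg=dict(self.factors.protein_ug_per_mg),
            mef={g: v / 2 for g, v in self.factors.mef.items()},
        )
        base = apply_normalization(flux_table(), "mef", self.factors)
        doubled = apply_normalization(flux_table(), "mef", half)
        np.testing.assert_allclose(doubled["jo2"], 2 * base["jo2"])

    def test_scheme_algebra_exact(self):
        tp = apply_normalization(flux_table(), "total_protein", self.factors)
        me = apply_normalization(flux_table(), "mef", self.factors)
        mef_col = flux_table()["group"].map(self.factors.mef)
        np.testing.assert_allclose(me["jo2"], tp["jo2"] / mef_col)

    def test_within_group_ranking_invariant(self):
        ww = apply_normalization(flux_table(), "wet_weight")
        me = apply_normalization(flux_table(), "mef", self.factors)
        b_ww = ww[ww.group == "benign"].sort_values("jo2")["sample_id"].tolist()
        b_me = me[me.group == "benign"].sort_values("jo2")["sample_id"].tolist()
        assert b_ww == b_me

    def test_missing_group_factor_rejected(self):
        fac = NormalizationFactors(protein_ug_per_mg={"benign": 40.0}, mef={})
        with pytest.raises(ValueError, match="missing protein factor"):
            apply_normalization(flux_table(), "total_protein", fac)

    def test_zero_mef_rejected(self):
        fac = NormalizationFactors(
            protein_ug_per_mg={"benign": 40.0, "tumor": 100.0},
            mef={"benign": 0.0, "tumor": 0.1},
        )
        with pytest.raises(ValueError, match="MEF of zero"):
            apply_normalization(flux_table(), "mef", fac)


class TestCentralContrast:
    def test_content_halving_doubles_wet_weight_but_not_mef_flux(self, preset_config):
        """Halved mito content with equal intrinsic flux: wet-weight fluxes
        differ ~2-fold while MEF-normalized fluxes agree."""
        from mitoflux.respiro import build_state_table

        ww_ratios, mef_ratios = [], []
        for seed in range(8):
            cfg = syndata.central_contrast_config(preset_config, 0.5)
            for g in cfg.groups.values():
                g.n_samples = 6
            traces = syndata.simulate_respirometry(cfg, "CI_CII", seed)
            bio, _ = build_state_table(traces)
            sim = syndata.simulate_proteome(cfg, seed)
            mef, _ = compute_mef(sim.abundance, sim.annotation)
            pf = syndata.bradford_from_proteome(sim.abundance, "benign", 40.0)
            fac = NormalizationFactors(protein_ug_per_mg=pf, mef=mef)
            ww = bio[bio.state == "PMDGS"].groupby("group")["jo2"].mean()
            me = apply_normalization(bio, "mef", fac)
            mm = me[me.state == "PMDGS"].groupby("group")["jo2"].mean()
            ww_ratios.append(ww["benign"] / ww["tumor"])
            mef_ratios.append(mm["benign"] / mm["tumor"])
        assert np.mean(ww_ratios) == pytest.approx(2.0, rel=0.1)
        assert abs(np.mean(mef_ratios) - 1.0) < 0.05


class TestH2O2Calibration:
    standards = pd.DataFrame({"conc_uM": [0.0, 1.0], "fluorescence_au": [0.0, 100.0]})

    @staticmethod
    def fluor(rate_au_per_s, amount=5.0, n=60):
        t = np.arange(n, dtype=float)
        return pd.DataFrame(
            {
                "sample_id": "s1", "group": "benign", "time_s": t,
                "fluorescence_au": rate_au_per_s * t, "amount_mg": amount,
            }
        )

    def test_linear_closed_form(self):
        # 10 AU/s over 100 AU/µM -> 0.1 µM/s; x 1 ml x 1000 / 5 mg -> 20
        out = calibrate_h2o2(self.fluor(10.0), self.standards, volume_ml=1.0)
        assert out["jo2"].iloc[0] == pytest.approx(20.0)
        assert out["analyte"].iloc[0] == "H2O2"

    def test_zero_drift_gives_zero_rate(self):
        out = calibrate_h2o2(self.fluor(0.0), self.standards)
        assert out["jo2"].iloc[0] == pytest.approx(0.0)

    def test_matches_regression_oracle_with_noise(self):
        rng = np.random.default_rng(2)
        fl = self.fluor(10.0)
        fl["fluorescence_au"] += rng.normal(0, 2.0, len(fl))
        out = calibrate_h2o2(fl, self.standards, volume_ml=1.0)
        au_slope = ols_slope_oracle(fl["time_s"], fl["fluorescence_au"])
        expected = au_slope / 100.0 * 1.0 * 1000.0 / 5.0
        assert out["jo2"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_singular_calibration_rejected(self):
        bad = pd.DataFrame({"conc_uM": [1.0, 1.0], "fluorescence_au": [50.0, 50.0]})
        with pytest.raises(ValueError, match="2 distinct"):
            calibrate_h2o2(self.fluor(1.0), bad)

    def test_normalization_schemes_apply_to_emission_rates(self):
        out = calibrate_h2o2(self.fluor(10.0), self.standards, volume_ml=1.0)
        fac = NormalizationFactors(protein_ug_per_mg={"benign": 40.0},
                                   mef={"benign": 0.2})
        norm = apply_normalization(out, "mef", fac)
        assert norm["jo2"].iloc[0] == pytest.approx(20.0 / 40.0 / 0.2)
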