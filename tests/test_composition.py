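"""Cell-type proportions, outlier flags, protected bootstrap regression."""

import numpy as np
import pandas as pd
import pytest

import vasc_protnet as vp
from tests.conftest import partial_correlation_given_diagnosis
from vasc_protnet.simulate import StudyConfig


class TestProportionEstimation:
    def test_pure_sample_argmax(self):
        bench, sets, truth = vp.generate_deconvolution_benchmark(
            mixtures=[{"endothelial": 1.0}], seed=0)
        props = vp.estimate_cell_proportions(bench, sets)
        assert props.loc[truth.index[-1]].idxmax() == "endothelial"

    def test_fifty_fifty_mixture_within_tolerance(self):
        mix = [{"endothelial": 0.5, "neuron": 0.5}] * 5
        bench, sets, truth = vp.generate_deconvolution_benchmark(mixtures=mix, seed=1)
        avg, score, nnls_est = vp.estimate_cell_proportions(bench, sets, return_components=True)
        rows = truth.index[-5:]
        for est in (score, nnls_est, avg):
            assert abs(est.loc[rows, "endothelial"].mean() - 0.5) < 0.10
            assert abs(est.loc[rows, "neuron"].mean() - 0.5) < 0.10

    def test_identical_samples_identical_rows(self):
        bench, sets, _ = vp.generate_deconvolution_benchmark(n_cohort=20, seed=2)
        dup = bench.data.copy()
        dup["clone"] = dup[dup.columns[0]]
        props = vp.estimate_cell_proportions(vp.AbundanceMatrix(dup, scale="log2"), sets)
        pd.testing.assert_series_equal(
            props.loc["clone"], props.loc[dup.columns[0]], check_names=False)

    def test_rows_sum_to_one(self, proportions):
        np.testing.assert_allclose(proportions.sum(axis=1), 1.0, atol=1e-6)

    def test_sparse_signature_dropped(self):
        bench, sets, _ = vp.generate_deconvolution_benchmark(n_cohort=20, seed=2)
        sets = dict(sets)
        sets["neuron"] = sets["neuron"][:2]  # below the 3-marker minimum
        props = vp.estimate_cell_proportions(bench, sets)
        assert "neuron" not in props.columns


class TestOutlierDetection:
    def test_planted_outliers_exactly_recovered(self, study, outlier_flags):
        flagged = set(outlier_flags.index[outlier_flags])
        truth = set(study.truth.outlier_flags.index[study.truth.outlier_flags])
        assert flagged == truth and len(flagged) == 5

    def test_identical_samples_none_flagged(self):
        props = pd.DataFrame({"endothelial": [0.4] * 10, "neuron": [0.1] * 10},
                             index=[f"s{i}" for i in range(10)])
        flags = vp.detect_endothelial_outliers(props)
        assert not flags.any()

    def test_extreme_sample_flagged(self):
        rng = np.random.default_rng(0)
        props = pd.DataFrame({
            "endothelial": np.append(rng.normal(0.45, 0.03, 60), 0.0),
            "neuron": np.append(rng.normal(0.05, 0.02, 60), 0.9),
        }, index=[f"s{i}" for i in range(61)])
        flags = vp.detect_endothelial_outliers(props)
        assert flags.iloc[-1] and flags.iloc[:-1].sum() == 0

    def test_missing_column_is_error(self):
        with pytest.raises(ValueError, match="neuron"):
            vp.detect_endothelial_outliers(pd.DataFrame({"endothelial": [0.5]}))


def _noiseless_config(**effects):
    base = dict(n_proteins=300, module_sizes=(40,), noise_sd=0.0, batch_sd=0.0,
                loading_range=(0.0, 0.0), missing_fraction=0.0,
                ad_effects={}, psp_effects={}, age_effects={}, sex_effects={},
                pmi_effects={}, n_outliers=0, n_vascular_enriched=0,
                celltype_module_map={}, strong_ad_effect=0.0, strong_psp_effect=0.0)
    base.update(effects)
    return StudyConfig(**base)


def _raw_bio_log2(data):
    bio = data.meta.loc[~data.meta.is_gis, "sample_id"]
    return vp.AbundanceMatrix(np.log2(data.abundance.data[bio]), scale="log2")


class TestBootstrapRegression:
    def test_noiseless_coefficients_recovered_exactly(self):
        cfg = _noiseless_config(age_effects={"M1": 0.05})
        data = vp.generate_study(cfg, seed=4)
        raw = _raw_bio_log2(data)
        spec = vp.RegressionSpec(n_boot=50, seed=1)
        out, coefs = vp.bootstrap_regress(raw, data.meta, data.traits,
                                          data.truth.proportions, spec,
                                          return_coefficients=True)
        members = data.truth.module_labels.index[data.truth.module_labels == "M1"]
        np.testing.assert_allclose(coefs.loc[members, "age"], 0.05, atol=1e-6)
        # with exact coefficients the corrected profiles collapse to the
        # per-protein constant mu_i: no age (or any other) dependence remains
        assert out.data.loc[members].std(axis=1).max() < 1e-9

    def test_zero_effects_noiseless_passthrough(self):
        # marker-block proteins genuinely depend on cell proportions (that is
        # what the neuron covariate removes), so the zero-effect passthrough
        # claim applies to the non-marker proteome
        data = vp.generate_study(_noiseless_config(), seed=4)
        raw = _raw_bio_log2(data)
        out = vp.bootstrap_regress(raw, data.meta, data.traits,
                                   data.truth.proportions,
                                   vp.RegressionSpec(n_boot=50, seed=1))
        markers = {m for ms in data.markers.values() for m in ms}
        rows = [p for p in raw.protein_ids if p not in markers]
        diff = np.abs(out.data.loc[rows].to_numpy() - raw.data.loc[rows].to_numpy())
        assert np.nanmax(diff) < 1e-9

    def test_zero_effects_default_noise_bounded(self):
        # with no planted effects the subtraction is pure estimation noise;
        # per cell it is of order sigma * sqrt(k/n) ~ 0.15 (k = 9 covariate
        # columns, n = 67, sigma = 0.4), so the mean perturbation is ~0.1 and
        # extreme cells a few times that — never anywhere near the planted
        # effect sizes
        cfg = StudyConfig(n_proteins=400, module_sizes=(40, 30),
                          ad_effects={}, psp_effects={}, age_effects={},
                          sex_effects={}, pmi_effects={}, n_outliers=0,
                          strong_ad_effect=0.0, strong_psp_effect=0.0,
                          celltype_module_map={})
        data = vp.generate_study(cfg, seed=8)
        corr = vp.tampor(vp.filter_missingness(data.abundance), data.meta).corrected
        props = vp.estimate_cell_proportions(corr, data.markers)
        out = vp.bootstrap_regress(corr, data.meta, data.traits, props,
                                   vp.RegressionSpec(n_boot=300, seed=2))
        markers = {m for ms in data.markers.values() for m in ms}
        rows = [p for p in corr.protein_ids if p not in markers]
        diff = np.abs(out.data.loc[rows].to_numpy() - corr.data.loc[rows].to_numpy())
        assert np.nanmean(diff) < 0.2
        assert np.nanmax(diff) < 2.0

    def test_protected_ad_effect_recovered(self, study):
        raw = vp.filter_missingness(_raw_bio_log2(study))
        keep = [s for s in raw.sample_ids if not study.truth.outlier_flags[s]]
        trimmed = vp.AbundanceMatrix(raw.data[keep], scale="log2")
        out = vp.bootstrap_regress(trimmed, study.meta, study.traits,
                                   study.truth.proportions,
                                   vp.RegressionSpec(n_boot=300, seed=3))
        truth = study.truth
        members = [p for p in out.protein_ids
                   if truth.module_labels[p] == "M1" and truth.ad_effect_per_protein[p] == 1.0]
        d = study.meta.set_index("sample_id").loc[keep, "diagnosis"]
        diff = (out.data[d.index[d == "AD"]].mean(axis=1)
                - out.data[d.index[d == "control"]].mean(axis=1)).loc[members].mean()
        assert abs(diff - 1.0) < 0.10

    def test_age_effect_removed(self, study, regressed):
        truth = study.truth
        members = [p for p in regressed.protein_ids if truth.module_labels[p] == "M3"]
        meta = study.meta.set_index("sample_id").loc[regressed.sample_ids]
        traits = study.traits.set_index("sample_id").loc[regressed.sample_ids]
        age = meta["age"].to_numpy(float)
        is_ad = traits["is_ad"].to_numpy(float)
        is_psp = traits["is_psp"].to_numpy(float)
        pcs = [partial_correlation_given_diagnosis(
            regressed.data.loc[p].to_numpy(), age, is_ad, is_psp) for p in members]
        assert np.nanmean(np.abs(pcs)) < 0.05

    def test_grand_mean_preserved_fully_observed(self):
        cfg = _noiseless_config(noise_sd=0.3, age_effects={"M1": 0.05})
        data = vp.generate_study(cfg, seed=9)
        raw = _raw_bio_log2(data)
        out = vp.bootstrap_regress(raw, data.meta, data.traits,
                                   data.truth.proportions,
                                   vp.RegressionSpec(n_boot=100, seed=2))
        np.testing.assert_allclose(out.data.mean(axis=1), raw.data.mean(axis=1), atol=1e-9)

    def test_overlapping_protected_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            vp.RegressionSpec(covariates=("age", "is_ad"), protected=("is_ad",))


class TestVarianceExplained:
    def test_protein_equal_to_age(self):
        rng = np.random.default_rng(0)
        age = rng.normal(75, 8, 40)
        design = pd.DataFrame({"age": age, "noise_trait": rng.normal(size=40)},
                              index=[f"s{j}" for j in range(40)])
        data = pd.DataFrame([age], index=["p_age"], columns=design.index)
        out = vp.variance_explained(vp.AbundanceMatrix(data, scale="log2"), design)
        assert out.at["p_age", "age"] > 99.0

    def test_pure_noise_protein(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame({"age": rng.normal(75, 8, 60)},
                              index=[f"s{j}" for j in range(60)])
        data = pd.DataFrame(rng.normal(size=(1, 60)), index=["p"], columns=design.index)
        out = vp.variance_explained(vp.AbundanceMatrix(data, scale="log2"), design)
        assert out.at["p", "age"] < 10.0
        assert out.at["p", "residual"] > 85.0

    def test_batch_variance_before_vs_after_tampor(self, study, filtered, corrected):
        meta = study.meta.set_index("sample_id")
        bio = [s for s in filtered.sample_ids if not meta.loc[s, "is_gis"]]
        design = pd.DataFrame({"batch": meta.loc[bio, "batch"].astype(str)}, index=bio)
        sub = filtered.protein_ids[:200]
        before = vp.variance_explained(
            vp.AbundanceMatrix(np.log2(filtered.data.loc[sub, bio]), scale="log2"), design)
        after = vp.variance_explained(
            vp.AbundanceMatrix(corrected.data.loc[sub], scale="log2"),
            design.loc[corrected.sample_ids])
        assert before["batch"].mean() > 20.0
        assert after["batch"].mean() < 1.0
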