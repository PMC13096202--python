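"""Synthetic cohort generator: correlation geometry, determinism, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunocorr import (
    SimConfig,
    build_target_correlation,
    generate_cohort,
    inject_clinical_association,
    partial_correlate,
    project_to_correlation,
)


def _null_config(**kw):
    base = dict(
        hub_panel_corr_hc={"C4A": 0.0, "C4B": 0.0, "C1QA": 0.0},
        hub_panel_corr_fep={"C4A": 0.0, "C4B": 0.0, "C1QA": 0.0},
        hub_hub_corr_hc={}, hub_hub_corr_fep={},
        panel_base_corr=0.0, corr_jitter=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestTargetCorrelation:
    def test_all_zero_targets_give_identity(self):
        cfg = _null_config(n_panel=6)
        c = build_target_correlation(cfg, "HC")
        assert np.array_equal(c, np.eye(9))

    def test_psd_input_unchanged(self):
        cfg = _null_config(
            n_panel=4,
            hub_panel_corr_hc={"C4A": 0.1, "C4B": 0.1, "C1QA": 0.1},
            panel_base_corr=0.2,
            hub_hub_corr_hc={("C4A", "C4B"): 0.1},
        )
        c = build_target_correlation(cfg, "HC")
        # raw matrix is already PSD here: projection must be a no-op
        raw = np.eye(7)
        raw[3:, 3:] = np.where(np.eye(4, dtype=bool), 1.0, 0.2)
        for i, r in enumerate([0.1, 0.1, 0.1]):
            raw[i, 3:] = raw[3:, i] = r
        raw[0, 1] = raw[1, 0] = 0.1
        assert np.linalg.eigvalsh(raw)[0] > 0
        assert np.max(np.abs(c - raw)) < 1e-12

    def test_infeasible_targets_projected_down(self):
        cfg = SimConfig(
            n_panel=48, hub_names=("C4A", "C4B", "C1QA"),
            hub_panel_corr_hc={"C4A": 0.9, "C4B": 0.0, "C1QA": 0.0},
            hub_panel_corr_fep={"C4A": 0.9, "C4B": 0.0, "C1QA": 0.0},
            hub_hub_corr_hc={}, hub_hub_corr_fep={},
            panel_base_corr=0.0, corr_jitter=0.0,
        )
        c = build_target_correlation(cfg, "HC")
        # +0.9 to 48 mutually uncorrelated proteins is not a valid correlation
        # structure; eigen-decomposition oracle confirms shrinkage
        assert c[0, 3:].max() < 0.9
        assert np.linalg.eigvalsh(c)[0] >= -1e-10

    def test_projection_idempotent(self, rng):
        a = rng.uniform(-1, 1, (12, 12))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        once = project_to_correlation(a)
        twice = project_to_correlation(once)
        assert np.max(np.abs(once - twice)) < 1e-10

    def test_per_protein_target_vectors(self):
        targets = tuple([0.4] * 3 + [-0.4] * 3)
        cfg = _null_config(
            n_panel=6,
            hub_panel_corr_fep={"C4A": targets, "C4B": 0.0, "C1QA": 0.0},
        )
        c = build_target_correlation(cfg, "FEP")
        assert np.allclose(c[0, 3:6], 0.4, atol=1e-9)
        assert np.allclose(c[0, 6:9], -0.4, atol=1e-9)


class TestGenerateCohort:
    def test_bit_identical_under_seed(self):
        cfg = SimConfig(n_hc=20, n_fep=20, n_panel=6, seed=1)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.csf.values, b.csf.values)
        pd.testing.assert_frame_equal(a.plasma.values, b.plasma.values)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)

    def test_recovers_target_correlation_at_large_n(self):
        cfg = _null_config(
            n_hc=200, n_fep=200, n_panel=10, missing_rate=0.0, noise_sd=0.0,
            hub_panel_corr_hc={"C4A": 0.5, "C4B": 0.0, "C1QA": 0.0},
            hub_panel_corr_fep={"C4A": 0.5, "C4B": 0.0, "C1QA": 0.0},
            covariate_effects={}, seed=5,
        )
        target = build_target_correlation(cfg, "HC")[0, 3:].mean()
        coh = generate_cohort(cfg)
        hc = coh.csf.values.loc[coh.csf.group == "HC"]
        rs = [stats.spearmanr(hc["C4A"], hc[p]).statistic for p in cfg.panel_names]
        assert abs(np.mean(rs) - target) < 0.07

    def test_missing_fraction_calibrated(self):
        cfg = SimConfig(n_hc=200, n_fep=200, n_panel=48, missing_rate=0.2, seed=9)
        coh = generate_cohort(cfg)
        frac = coh.csf.values.isna().to_numpy().mean()
        assert abs(frac - 0.2) < 0.02

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_hc=3).validate()
        with pytest.raises(ValueError):
            SimConfig(missing_rate=1.0).validate()
        with pytest.raises(ValueError):
            SimConfig(hub_panel_corr_hc={"C4A": 1.5, "C4B": 0, "C1QA": 0}).validate()

    def test_medication_zero_in_controls(self, default_cohort):
        covs = default_cohort.covariates
        assert (covs.loc[covs.group == "HC", "medication"] == 0).all()
        assert covs.loc[covs.group == "FEP", "medication"].sum() > 0
        assert (covs.age > 0).all() and (covs.bmi > 0).all()

    def test_clinical_scores_in_panss_ranges(self, default_cohort):
        clin = default_cohort.clinical
        assert set(clin.index) == set(
            default_cohort.covariates.index[default_cohort.covariates.group == "FEP"]
        )
        assert clin.panss_positive.between(7, 49).all()
        assert clin.panss_negative.between(7, 49).all()
        assert clin.panss_general.between(16, 112).all()

    def test_cross_compartment_coupling_weak(self, default_cohort):
        cfg = default_cohort.config
        rs = []
        for p in cfg.panel_names[:10]:
            pair = pd.concat(
                [default_cohort.csf.values[p], default_cohort.plasma.values[p]], axis=1
            ).dropna()
            rs.append(stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic)
        assert abs(np.mean(rs) - cfg.cross_compartment_corr) < 0.15

    def test_confounding_inflates_marginal_over_partial(self):
        cfg = _null_config(
            n_hc=500, n_fep=4, n_panel=4, missing_rate=0.0, noise_sd=0.0,
            covariate_effects={"age": 0.6, "bmi": 0.6}, seed=13,
        )
        coh = generate_cohort(cfg)
        hc = coh.csf.group == "HC"
        x = coh.csf.values.loc[hc, "C4A"]
        y = coh.csf.values.loc[hc, "INF01"]
        covs = coh.covariates.loc[hc, ["age", "bmi"]]
        marginal = partial_correlate(x, y, None).r
        partial = partial_correlate(x, y, covs).r
        assert marginal > partial

    def test_olink_subset_masks_panel_only(self):
        cfg = SimConfig(n_hc=40, n_fep=50, n_panel=6, missing_rate=0.0,
                        olink_n_hc=15, olink_n_fep=25, seed=3)
        coh = generate_cohort(cfg)
        hc = coh.csf.group == "HC"
        panel_complete = coh.csf.values.loc[hc, cfg.panel_names].dropna(how="any")
        assert len(panel_complete) == 15
        # hub proteins stay measured in everyone
        assert coh.csf.values.loc[hc, list(cfg.hub_names)].notna().all().all()


class TestInjectClinical:
    def test_marginals_preserved_and_target_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        idx = pd.Index([f"S{i}" for i in range(n)])
        scores = pd.DataFrame({"panss_general": rng.integers(16, 113, n)}, index=idx)
        axis = pd.Series(rng.standard_normal(n), index=idx)
        out = inject_clinical_association(scores, axis, 0.9, seed=2)
        assert sorted(out.panss_general) == sorted(scores.panss_general)
        r = stats.spearmanr(out.panss_general, axis).statistic
        assert 0.8 <= r <= 0.97

    def test_zero_target_uncorrelated(self):
        rng = np.random.default_rng(8)
        n = 67
        idx = pd.Index([f"S{i}" for i in range(n)])
        scores = pd.DataFrame({"panss_positive": rng.integers(7, 50, n)}, index=idx)
        axis = pd.Series(rng.standard_normal(n), index=idx)
        out = inject_clinical_association(scores, axis, 0.0, seed=3)
        assert abs(stats.spearmanr(out.panss_positive, axis).statistic) < 0.25

    def test_length_mismatch_raises(self):
        scores = pd.DataFrame({"panss_positive": [10, 20]}, index=["a", "b"])
        axis = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            inject_clinical_association(scores, axis, 0.5)
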