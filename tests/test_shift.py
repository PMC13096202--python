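"""Permutation profile-shift tests: statistics, determinism, exchangeability."""

import dataclasses

import numpy as np
import pytest

from immunocorr import (
    SimConfig,
    directional_and_absolute,
    generate_cohort,
    hub_profile,
    observed_statistic,
    permutation_shift_test,
)

COVS = ["age", "sex", "bmi", "medication"]


def _profiles(cohort, hub, panel):
    covs = cohort.covariates[COVS]
    return tuple(
        hub_profile(cohort.csf.values, covs, hub, panel,
                    group_labels=cohort.csf.group, group=g)
        for g in ("FEP", "HC")
    )


class TestObservedStatistic:
    def test_identical_profiles_are_zero(self, clean_cohort):
        pf, _ = _profiles(clean_cohort, "C4A", ["INF01", "INF02"])
        assert observed_statistic(pf, pf, "directional") == 0.0
        assert observed_statistic(pf, pf, "absolute") == 0.0

    def test_constant_shift(self, clean_cohort):
        pf, ph = _profiles(clean_cohort, "C4A", [f"INF{i:02d}" for i in range(1, 11)])
        shifted = dataclasses.replace(
            pf,
            results=[dataclasses.replace(r, r=h.r + 0.3)
                     for r, h in zip(pf.results, ph.results)],
        )
        assert observed_statistic(shifted, ph, "directional") == pytest.approx(0.3)
        assert observed_statistic(shifted, ph, "absolute") == pytest.approx(0.3)

    def test_cancellation_vs_magnitude(self, clean_cohort):
        pf, ph = _profiles(clean_cohort, "C4A", ["INF01", "INF02"])
        deltas = [0.4, -0.4]
        shifted = dataclasses.replace(
            pf,
            results=[dataclasses.replace(r, r=h.r + d)
                     for r, h, d in zip(pf.results, ph.results, deltas)],
        )
        assert observed_statistic(shifted, ph, "directional") == pytest.approx(0.0, abs=1e-12)
        assert observed_statistic(shifted, ph, "absolute") == pytest.approx(0.4)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimConfig(n_hc=40, n_fep=40, n_panel=8, missing_rate=0.0,
                    noise_sd=0.0, corr_jitter=0.0, seed=21)
    return generate_cohort(cfg)


class TestPermutationShiftTest:
    def test_n_perm_floor(self, small_cohort):
        with pytest.raises(ValueError):
            permutation_shift_test(
                small_cohort.csf.values, small_cohort.covariates[COVS],
                small_cohort.csf.group, "C4A", ["INF01"], n_perm=50,
            )

    def test_deterministic_under_seed(self, small_cohort):
        kwargs = dict(
            proteins=small_cohort.csf.values,
            covariates=small_cohort.covariates[COVS],
            group_labels=small_cohort.csf.group,
            hub="C4A", panel=[f"INF{i:02d}" for i in range(1, 9)],
            n_perm=200, seed=9,
        )
        a = permutation_shift_test(**kwargs)
        b = permutation_shift_test(**kwargs)
        assert a == b

    def test_observed_matches_profile_statistic(self, small_cohort):
        panel = [f"INF{i:02d}" for i in range(1, 9)]
        res = permutation_shift_test(
            small_cohort.csf.values, small_cohort.covariates[COVS],
            small_cohort.csf.group, "C4B", panel, n_perm=100, seed=1,
        )
        pf, ph = _profiles(small_cohort, "C4B", panel)
        assert res.observed_raw == pytest.approx(
            observed_statistic(pf, ph, "directional"), abs=1e-12
        )

    def test_label_swap_antisymmetry(self, small_cohort):
        panel = [f"INF{i:02d}" for i in range(1, 9)]
        args = (small_cohort.csf.values, small_cohort.covariates[COVS],
                small_cohort.csf.group, "C4A", panel)
        fwd = permutation_shift_test(*args, n_perm=100, seed=2)
        rev = permutation_shift_test(*args, n_perm=100, seed=2,
                                     fep_label="HC", hc_label="FEP")
        assert rev.observed_raw == pytest.approx(-fwd.observed_raw, abs=1e-12)
        res_abs = permutation_shift_test(*args, mode="absolute", n_perm=100, seed=2)
        rev_abs = permutation_shift_test(*args, mode="absolute", n_perm=100, seed=2,
                                         fep_label="HC", hc_label="FEP")
        assert rev_abs.observed_raw == pytest.approx(res_abs.observed_raw, abs=1e-12)

    def test_add_one_p_never_zero(self, small_cohort):
        res = permutation_shift_test(
            small_cohort.csf.values, small_cohort.covariates[COVS],
            small_cohort.csf.group, "C4A", [f"INF{i:02d}" for i in range(1, 9)],
            n_perm=100, seed=3,
        )
        assert 0.0 < res.p_emp <= 1.0
        assert res.p_emp >= 1.0 / 101

    def test_both_modes_share_permutation_stream(self, small_cohort):
        panel = [f"INF{i:02d}" for i in range(1, 9)]
        res_d, res_a = directional_and_absolute(
            small_cohort.csf.values, small_cohort.covariates[COVS],
            small_cohort.csf.group, "C4A", panel, n_perm=150, seed=4,
        )
        single_d = permutation_shift_test(
            small_cohort.csf.values, small_cohort.covariates[COVS],
            small_cohort.csf.group, "C4A", panel, mode="directional",
            n_perm=150, seed=4,
        )
        assert res_d == single_d
        assert res_d.mode == "directional" and res_a.mode == "absolute"

    def test_missing_tolerant_path_agrees_with_fast_path(self):
        cfg = SimConfig(n_hc=50, n_fep=50, n_panel=5, missing_rate=0.0,
                        noise_sd=0.0, seed=33)
        coh = generate_cohort(cfg)
        panel = cfg.panel_names
        covs = coh.covariates[COVS]
        fast = permutation_shift_test(
            coh.csf.values, covs, coh.csf.group, "C4A", panel,
            n_perm=100, seed=5,
        )
        # poke one NaN into a protein column to force the masked path, then
        # compare observed statistics on the shared complete part
        vals = coh.csf.values.copy()
        vals.iloc[0, vals.columns.get_loc("INF05")] = np.nan
        slow = permutation_shift_test(
            vals, covs, coh.csf.group, "C4A", panel, n_perm=100, seed=5,
        )
        # same machinery, nearly identical statistic (one subject x one protein)
        assert slow.observed_raw == pytest.approx(fast.observed_raw, abs=0.03)

    def test_null_cohort_p_is_unsuspicious(self):
        # same latent structure in both groups: a single run should rarely
        # reach small p; check it lands strictly inside the unit interval and
        # the z-score stays moderate
        cfg = SimConfig(
            n_hc=50, n_fep=50, n_panel=8, missing_rate=0.0, noise_sd=0.0,
            corr_jitter=0.0, seed=55,
            hub_panel_corr_hc={"C4A": 0.2, "C4B": 0.2, "C1QA": 0.2},
            hub_panel_corr_fep={"C4A": 0.2, "C4B": 0.2, "C1QA": 0.2},
            hub_hub_corr_hc={}, hub_hub_corr_fep={},
        )
        coh = generate_cohort(cfg)
        res = permutation_shift_test(
            coh.csf.values, coh.covariates[COVS], coh.csf.group, "C4A",
            cfg.panel_names, n_perm=300, seed=6,
        )
        assert res.p_emp > 0.01
        assert abs(res.z) < 4
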