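import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lipidstats import diff_abundance as da
from lipidstats import quantmatrix as qm
from lipidstats import synthetic_data as sd
from lipidstats.diff_abundance import ContrastSpec
from tests.conftest import make_matrix

TWO_ARM = ContrastSpec("a_vs_b", "a", "b")


class TestInclusionRule:
    def test_all_zero_condition_excludes(self):
        assert da.include_species([0, 0, 0, 0], [0.1, 0.2, 0, 0]) is False

    def test_one_positive_value_in_each_suffices(self):
        assert da.include_species([0, 0, 0.3], [0.1, 0, 0]) is True

    def test_all_positive_included(self):
        assert da.include_species([1, 2], [3, 4]) is True

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            da.include_species([], [1.0])


class TestFitContrast:
    def test_worked_two_arm_example(self):
        res = da.fit_contrast({"a": [2, 3, 4], "b": [1, 2, 3]}, TWO_ARM)
        assert res.estimate == pytest.approx(1.0)
        assert res.t == pytest.approx(1.0 / np.sqrt(1 * (1 / 3 + 1 / 3)), rel=1e-10)
        assert res.t == pytest.approx(1.2247, abs=1e-4)
        assert res.p == pytest.approx(0.288, abs=1e-3)

    def test_reduces_to_classical_pooled_t(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.lognormal(0, 0.5, size=rng.integers(3, 9))
            b = rng.lognormal(0.3, 0.5, size=rng.integers(3, 9))
            res = da.fit_contrast({"a": a, "b": b}, TWO_ARM)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert res.t == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_pooled_variance_uses_all_arms(self):
        groups = {"a": [2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0], "c": [10.0, 10.5, 11.0]}
        res = da.fit_contrast(groups, TWO_ARM)
        ss = 2.0 + 2.0 + 0.5
        s2 = ss / (9 - 3)
        assert res.t == pytest.approx(1.0 / np.sqrt(s2 * (2 / 3)), rel=1e-12)

    def test_identical_arms_zero_effect(self):
        res = da.fit_contrast({"a": [1.0, 2.0], "b": [1.0, 2.0]}, TWO_ARM)
        assert res.estimate == 0.0 and res.log2fc == 0.0

    def test_doubled_mean_gives_unit_log2fc(self):
        res = da.fit_contrast({"a": [2.0, 6.0], "b": [1.0, 3.0]}, TWO_ARM)
        assert res.log2fc == pytest.approx(1.0)

    def test_zero_mean_log2fc_flagged_missing(self):
        res = da.fit_contrast({"a": [0.0, 1.0], "b": [0.0, 2.0]}, TWO_ARM)
        assert res.included and not np.isnan(res.p)
        # a zero *mean* cannot happen with non-negative data unless all
        # values are zero, which the inclusion rule already excludes
        res = da.fit_contrast({"a": [1.0, 1.0], "b": [1.0, 0.0]}, TWO_ARM)
        assert not res.log2fc_undefined

    def test_degenerate_zero_variance(self):
        res = da.fit_contrast({"a": [1.0, 1.0], "b": [1.0, 1.0]}, TWO_ARM)
        assert res.degenerate and res.p == 1.0
        res = da.fit_contrast({"a": [2.0, 2.0], "b": [1.0, 1.0]}, TWO_ARM)
        assert res.degenerate and res.p == 0.0


class TestBhFdr:
    def test_hand_bh_oracle(self):
        np.testing.assert_allclose(da.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_and_single(self):
        np.testing.assert_allclose(da.bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(da.bh_fdr([0.7]), [0.7])

    def test_step_definition_oracle_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = rng.integers(1, 15)
            p = rng.random(m)
            got = da.bh_fdr(p)
            order = np.argsort(p, kind="stable")
            expect = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                idx = order[rank]
                running = min(running, p[idx] * m / (rank + 1))
                expect[idx] = running
            np.testing.assert_allclose(got, expect, atol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_permutation_invariance_and_monotonicity(self, p):
        q = da.bh_fdr(p)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = da.bh_fdr(np.asarray(p)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(p) - 1e-15).all()


class TestRunContrasts:
    def test_matches_scalar_fit_contrast(self, hippo_molpct):
        cols = hippo_molpct.amounts.columns[:40]
        table = da.run_contrasts(hippo_molpct)
        meta = hippo_molpct.meta_frame()
        by_arm_ids = meta.groupby("arm").groups
        for spec in da.DEFAULT_CONTRASTS[:2]:
            sub = table[table.contrast == spec.name].set_index("species")
            for name in cols:
                groups = {
                    arm: hippo_molpct.amounts.loc[ids, name].tolist()
                    for arm, ids in by_arm_ids.items()
                }
                ref = da.fit_contrast(groups, spec, species=name)
                row = sub.loc[name]
                assert bool(row.included) == ref.included
                if ref.included:
                    assert row.t == pytest.approx(ref.t, rel=1e-10)
                    assert row.p == pytest.approx(ref.p, rel=1e-10)
                    assert row.log2fc == pytest.approx(ref.log2fc, rel=1e-10, nan_ok=True)

    def test_excluded_species_keep_auditable_rows(self):
        vals = np.ones((4, 2))
        vals[:2, 0] = 0.0  # species 0 all-zero in CONTROL
        m = make_matrix(vals, ["PC 34:1", "PE 36:2"], ["CONTROL", "CONTROL", "CORT", "CORT"])
        m.unit = "molpct"
        out = da.run_contrasts(m, [ContrastSpec("CORT_vs_CONTROL", "CORT", "CONTROL")])
        row = out[out.species == "PC 34:1"].iloc[0]
        assert not row.included and np.isnan(row.p) and np.isnan(row.fdr)

    def test_power_detects_unit_log2fc_effects(self):
        # 30 spiked species of 200, n=8/arm, within-arm CV 20%
        cfg = sd.null_config(seed=9, n_species=200)
        res = sd.generate(cfg)
        m = res.matrices["plasma"]
        rng = np.random.default_rng(1)
        spiked = rng.choice(m.amounts.columns, size=30, replace=False)
        ids = [s.sample_id for s in m.samples if s.arm.label == "CORT_ZE180"]
        m.amounts.loc[ids, spiked] *= 2.0
        out = da.run_contrasts(qm.to_molpct(qm.apply_lod(m)))
        sub = out[(out.contrast == "ZE180+CORT_vs_CORT") & out.species.isin(spiked)]
        assert (sub.fdr < 0.05).mean() >= 0.80


class TestVolcanoQq:
    def test_volcano_columns_and_threshold(self, hippo_molpct):
        table = da.run_contrasts(hippo_molpct)
        v = da.volcano_table(table, "ESC+CORT_vs_CORT")
        assert set(v.columns) == {"species", "log2fc", "neglog10_p", "fdr", "significant"}
        assert (v.significant == (v.fdr < 0.05)).all()

    def test_neglog10_identity(self):
        table = pd.DataFrame(
            {
                "species": ["PC 34:1"],
                "contrast": ["c"],
                "included": [True],
                "log2fc": [0.5],
                "p": [0.05],
                "fdr": [0.049],
            }
        )
        v = da.volcano_table(table, "c")
        assert v.neglog10_p.iloc[0] == pytest.approx(1.30103, abs=1e-5)
        assert bool(v.significant.iloc[0]) is True

    def test_null_contrast_qq_near_diagonal(self):
        res = sd.generate(sd.null_config(seed=4, n_species=300))
        out = da.run_contrasts(qm.to_molpct(qm.apply_lod(res.matrices["plasma"])))
        q = da.qq_table(out, "CORT_vs_CONTROL")
        # uniform p-values: observed ~ expected except in the extreme tail
        resid = (q.observed_neglog10_p - q.expected_neglog10_p).abs()
        assert resid.median() < 0.1
        p = out[(out.contrast == "CORT_vs_CONTROL") & out.included].p
        assert (p < 0.05).mean() < 0.10  # tail calibrated to ~5%
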