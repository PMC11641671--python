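import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidstats import behavior as bv
from lipidstats import quantmatrix as qm


class TestSpearman:
    def test_perfect_antitone(self):
        rho, p = bv.spearman([1, 2, 3], [3, 2, 1])
        assert rho == -1.0
        assert p == pytest.approx(2 / 6)  # continuity floor 2/n!

    def test_hand_rank_oracle(self):
        rho, _ = bv.spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_ties_get_average_ranks(self):
        ranks = stats.rankdata([1, 1, 2])
        np.testing.assert_allclose(ranks, [1.5, 1.5, 3.0])
        rho, _ = bv.spearman([1, 1, 2], [1, 2, 3])
        r = np.corrcoef(stats.rankdata([1, 1, 2]), stats.rankdata([1, 2, 3]))[0, 1]
        assert rho == pytest.approx(r, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            bv.spearman([1, 1, 1], [1, 2, 3])

    def test_rank_pearson_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            n = rng.integers(3, 15)
            x = rng.integers(0, 6, size=n).astype(float)  # with ties
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            rho, _ = bv.spearman(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_t_approximation_p(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=10), rng.normal(size=10)
        rho, p = bv.spearman(x, y)
        t = rho * np.sqrt((10 - 2) / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 8), rel=1e-9)

    def test_exact_permutation_small_n(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        rho, p = bv.spearman(x, y, exact=True)
        assert rho == pytest.approx(0.6)
        # enumeration: 24 permutations; |rho| >= 0.6 for 10 of them
        count = 0
        from itertools import permutations

        for perm in permutations(range(4)):
            r = np.corrcoef(np.asarray(x)[list(perm)], y)[0, 1]
            count += abs(r) >= 0.6 - 1e-12
        assert p == pytest.approx(count / 24)
        with pytest.raises(ValueError):
            bv.spearman(np.arange(12), np.arange(12.0), exact=True)


class TestCorrelateLipids:
    def test_monotone_transform_invariance(self, hippo_molpct, default_sim):
        sub = hippo_molpct.subset_samples(hippo_molpct.sample_ids[:20])
        out1 = bv.correlate_lipids(sub, default_sim.behavior, subset="all-arms")
        transformed = sub.subset_samples(sub.sample_ids)
        transformed.amounts = np.log1p(transformed.amounts * 3.0)
        out2 = bv.correlate_lipids(transformed, default_sim.behavior, subset="all-arms")
        merged = out1.merge(out2, on="species", suffixes=("_raw", "_log"))
        np.testing.assert_allclose(merged.rho_raw, merged.rho_log, atol=1e-12)

    def test_effect_species_positive_rho_in_cotreated(self, hippo_molpct, default_sim):
        gt = default_sim.ground_truth
        species = gt[gt.effect == "hippocampus_lpe_unsat"].species.unique()
        out = bv.correlate_lipids(hippo_molpct, default_sim.behavior, subset="cort-and-cotreated")
        rhos = out[out.species.isin(species)].rho
        assert (rhos > 0).mean() >= 0.8

    def test_all_arms_attenuates_mean_rho(self, hippo_molpct, default_sim):
        gt = default_sim.ground_truth
        species = gt[gt.effect == "hippocampus_lpe_unsat"].species.unique()
        co = bv.correlate_lipids(hippo_molpct, default_sim.behavior, subset="cort-and-cotreated")
        al = bv.correlate_lipids(hippo_molpct, default_sim.behavior, subset="all-arms")
        co_mean = co[co.species.isin(species)].rho.mean()
        all_mean = al[al.species.isin(species)].rho.mean()
        assert co_mean > 0 and all_mean < co_mean

    def test_permuted_behavior_centers_rho_on_zero(self, hippo_molpct, default_sim):
        rng = np.random.default_rng(3)
        permuted = default_sim.behavior.copy()
        permuted["latency_first_immobility_s"] = rng.permutation(
            permuted["latency_first_immobility_s"].to_numpy()
        )
        out = bv.correlate_lipids(hippo_molpct, permuted, subset="all-arms")
        assert abs(out.rho.mean()) < 0.1

    def test_missing_behavior_animals_dropped(self, hippo_molpct, default_sim):
        trimmed = default_sim.behavior.iloc[:-4]
        out = bv.correlate_lipids(hippo_molpct, trimmed, subset="all-arms")
        assert (out.n == len(hippo_molpct.sample_ids) - 4).all()


class TestFstGroupStats:
    def test_identical_arms_p_one(self):
        behavior = pd.DataFrame(
            {
                "total_immobility_s": [100.0, 110, 120, 100, 110, 120],
                "latency_first_immobility_s": [50.0, 60, 70, 50, 60, 70],
            },
            index=pd.Index([f"a{i}" for i in range(6)], name="animal_id"),
        )
        arms = {f"a{i}": ("CORT" if i < 3 else "CONTROL") for i in range(6)}
        out = bv.fst_group_stats(behavior, arms, reference_arm="CORT")
        for gc in out.values():
            assert gc.anova_p == pytest.approx(1.0)

    def test_cort_vs_ze180_latency_shift_detected(self):
        # arm means 69 s vs 115 s, SD 20, n=15: reliably significant
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(20):
            lat = {
                "CORT": rng.normal(69.2, 20, 15),
                "CORT_ZE180": rng.normal(115.4, 20, 15),
            }
            behavior = pd.DataFrame(
                {
                    "total_immobility_s": np.concatenate(
                        [rng.normal(250, 20, 15), rng.normal(150, 20, 15)]
                    ),
                    "latency_first_immobility_s": np.concatenate(
                        [lat["CORT"], lat["CORT_ZE180"]]
                    ).clip(0, 600),
                },
                index=pd.Index([f"a{i}" for i in range(30)], name="animal_id"),
            )
            arms = {f"a{i}": ("CORT" if i < 15 else "CORT_ZE180") for i in range(30)}
            out = bv.fst_group_stats(behavior, arms)
            adj = out["latency_first_immobility_s"].comparisons.loc["CORT_ZE180", "adj_p"]
            hits += adj < 0.05
        assert hits >= 19


class TestSelectSubgroup:
    def test_alternating_trim_hand_example(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0}
        assert bv.select_subgroup(vals, 3) == ["b", "c", "d"]
        assert bv.select_subgroup(vals, 4) == ["a", "b", "c", "d"]

    def test_fifteen_to_eight(self):
        rng = np.random.default_rng(8)
        vals = {f"a{i:02d}": float(v) for i, v in enumerate(rng.normal(100, 20, 15))}
        kept = bv.select_subgroup(vals, 8)
        assert len(kept) == 8
        kept_var = np.var([vals[a] for a in kept])
        assert kept_var <= np.var(list(vals.values()))

    def test_identity_and_error_cases(self):
        vals = {"a": 1.0, "b": 2.0}
        assert bv.select_subgroup(vals, 2) == ["a", "b"]
        with pytest.raises(ValueError):
            bv.select_subgroup(vals, 3)

    def test_tie_break_by_input_order(self):
        vals = {"x": 2.0, "y": 2.0, "z": 1.0}
        # first max encountered ("x") is dropped first
        assert bv.select_subgroup(vals, 2) == ["y", "z"]


class TestBehaviorRecord:
    def test_range_validation(self):
        with pytest.raises(ValueError):
            bv.BehaviorRecord("a1", 700.0, 10.0)
        with pytest.raises(ValueError):
            bv.BehaviorRecord("a1", 100.0, -1.0)
        bv.BehaviorRecord("a1", 0.0, 600.0)
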