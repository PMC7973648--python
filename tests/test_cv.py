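"""Cross-validation design, predictor-set comparison and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

import hybridpred as hp
from hybridpred.containers import CrossPlan, CvResult


def toy_plan(n_pol=20, n_testers=2):
    return CrossPlan.factorial([f"P{i}" for i in range(n_pol)],
                               [f"MS{j + 1}" for j in range(n_testers)])


class TestSplit:
    def test_pollinators_never_span_both_sets(self, rng):
        plan = toy_plan(37)
        for _ in range(20):
            train, val, masked = hp.cv_split(plan, 0.25, rng)
            train_pol = {h.split("x")[0] for h in train}
            val_pol = {h.split("x")[0] for h in val}
            assert not (train_pol & val_pol)
            assert val_pol == set(masked)

    def test_full_scale_layout_arithmetic(self):
        plan = toy_plan(475, 2)
        train, val, masked = hp.cv_split(plan, 0.25, 0)
        assert len(masked) == math.ceil(0.25 * 475) == 119
        assert len(val) == 238
        assert len(train) == 950 - 238

    def test_boundary_fraction_single_training_pollinator(self):
        plan = toy_plan(10)
        train, val, _ = hp.cv_split(plan, 9 / 10, 0)
        assert len({h.split("x")[0] for h in train}) == 1

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ValueError):
            hp.cv_split(toy_plan(), frac, 0)


@pytest.fixture(scope="module")
def cv_setup():
    cfg = hp.SimulationConfig(n_pollinators=60, n_snp=300, n_transcript=60,
                              n_metabolite=30, h2=0.8, seed=17)
    ds = hp.simulate_dataset(cfg)
    A = hp.additive_kernel(ds.hybrid_genotypes)
    return ds, A


class TestRunCv:
    def test_paired_splits_identical_across_runs(self, cv_setup):
        ds, A = cv_setup
        sets = [hp.PredictorSet("G", [A])]
        r1 = hp.run_cv(ds.hybrid_means, sets, ds.plan, cycles=5, seed=9)
        r2 = hp.run_cv(ds.hybrid_means, sets, ds.plan, cycles=5, seed=9)
        assert r1.masked_pollinators == r2.masked_pollinators
        pd.testing.assert_frame_equal(r1.accuracies, r2.accuracies)

    def test_same_kernels_under_two_labels_identical_accuracies(self, cv_setup):
        ds, A = cv_setup
        sets = [hp.PredictorSet("G", [A]), hp.PredictorSet("G2", [A])]
        res = hp.run_cv(ds.hybrid_means, sets, ds.plan, cycles=5, seed=3)
        np.testing.assert_allclose(res.accuracies["G"], res.accuracies["G2"])

    def test_duplicate_labels_rejected(self, cv_setup):
        ds, A = cv_setup
        with pytest.raises(ValueError):
            hp.run_cv(ds.hybrid_means, [hp.PredictorSet("G", [A])] * 2,
                      ds.plan, cycles=2)

    def test_near_noiseless_additive_trait_high_accuracy(self):
        # accuracy is capped by the marker:observation ratio, so give the
        # noiseless check many hybrids over few causal markers
        cfg = hp.SimulationConfig(n_pollinators=200, n_snp=60, n_causal=60,
                                  n_transcript=10, n_metabolite=5,
                                  h2=1.0, var_frac_add=1.0, var_frac_dom=0.0,
                                  var_frac_epi=0.0, loc_genotype_sd=0.0, seed=23)
        ds = hp.simulate_dataset(cfg)
        A = hp.additive_kernel(ds.hybrid_genotypes)
        res = hp.run_cv(ds.hybrid_means, [hp.PredictorSet("G", [A])], ds.plan,
                        cycles=10, seed=1)
        assert res.mean_accuracy()["G"] > 0.9

    def test_pure_noise_trait_accuracy_near_zero(self, cv_setup, rng):
        ds, A = cv_setup
        noise = pd.Series(rng.normal(size=len(ds.plan)),
                          index=ds.hybrid_means.index)
        res = hp.run_cv(noise, [hp.PredictorSet("G", [A])], ds.plan,
                        cycles=30, seed=2)
        accs = res.accuracies["G"].dropna()
        assert abs(accs.mean()) < 3 * accs.std() / np.sqrt(len(accs)) + 0.05

    def test_missing_phenotypes_excluded_from_accuracy(self, cv_setup):
        ds, A = cv_setup
        y = ds.hybrid_means.copy()
        y.iloc[:10] = np.nan  # e.g. BLUEs unavailable for some hybrids
        res = hp.run_cv(y, [hp.PredictorSet("G", [A])], ds.plan, cycles=4, seed=5)
        assert res.accuracies["G"].notna().all()


class TestSubsampling:
    def test_full_subset_is_identity(self, cv_setup):
        ds, _ = cv_setup
        om = ds.hybrid_genotypes
        subs = hp.subsample_features(om, om.shape[1], 2, seed=1)
        pd.testing.assert_frame_equal(subs[0].data, om.data)

    def test_different_seeds_differ(self, cv_setup):
        ds, _ = cv_setup
        om = ds.hybrid_genotypes
        a = hp.subsample_features(om, 150, 1, seed=1)[0]
        b = hp.subsample_features(om, 150, 1, seed=2)[0]
        assert a.features != b.features

    def test_oversized_request_rejected(self, cv_setup):
        ds, _ = cv_setup
        with pytest.raises(ValueError):
            hp.subsample_features(ds.hybrid_genotypes, 10**6, 1)

    def test_subset_kernels_approach_full_kernel(self, cv_setup):
        ds, A = cv_setup
        om = ds.hybrid_genotypes
        sizes = [50, 120, 200, 280]
        med = []
        for m in sizes:
            dists = []
            for sub in hp.subsample_features(om, m, 5, seed=7):
                Ks = hp.additive_kernel(sub)
                dists.append(np.linalg.norm(Ks.matrix - A.matrix))
            med.append(np.median(dists))
        assert all(np.diff(med) < 0), f"not decreasing: {med}"


def fake_result(columns: dict, seed=0, model="gblup"):
    return CvResult(pd.DataFrame(columns), [[f"P{i}"] for i in
                                            range(len(next(iter(columns.values()))))],
                    seed, model)


class TestComparisons:
    def test_null_sets_usually_share_a_letter(self):
        rng = np.random.default_rng(1)
        shared = 0
        for _ in range(20):
            res = fake_result({"X": 0.5 + 0.05 * rng.normal(size=100),
                               "Y": 0.5 + 0.05 * rng.normal(size=100)})
            tab = hp.compare_predictor_sets(res)
            letters = dict(zip(tab["set"], tab["letters"]))
            if set(letters["X"]) & set(letters["Y"]):
                shared += 1
        assert shared >= 18  # alpha = 0.05 null rejection rate

    def test_separated_sets_get_distinct_letters(self):
        rng = np.random.default_rng(2)
        res = fake_result({"lo": 0.3 + 0.02 * rng.normal(size=200),
                           "hi": 0.4 + 0.02 * rng.normal(size=200)})
        tab = hp.compare_predictor_sets(res)
        letters = dict(zip(tab["set"], tab["letters"]))
        assert not (set(letters["lo"]) & set(letters["hi"]))

    def test_three_group_letter_display_consistent_with_tukey(self):
        rng = np.random.default_rng(3)
        res = fake_result({"a": 0.30 + 0.02 * rng.normal(size=150),
                           "b": 0.30 + 0.02 * rng.normal(size=150),
                           "c": 0.45 + 0.02 * rng.normal(size=150)})
        tab = hp.compare_predictor_sets(res)
        letters = dict(zip(tab["set"], tab["letters"]))
        assert set(letters["a"]) & set(letters["b"])
        assert not (set(letters["c"]) & set(letters["a"]))

    def test_single_set_no_test(self):
        res = fake_result({"G": np.linspace(0.2, 0.4, 10)})
        tab = hp.compare_predictor_sets(res)
        assert list(tab["letters"]) == ["a"]

    def test_degenerate_zero_variance_error(self):
        res = fake_result({"X": np.full(10, 0.5), "Y": np.full(10, 0.5)})
        with pytest.raises(ValueError):
            hp.compare_predictor_sets(res)

    def test_self_comparison_no_stars(self):
        res = fake_result({"G": np.linspace(0.2, 0.4, 50)})
        tab = hp.compare_models(res, res)
        assert (tab["p"] == 1.0).all()
        assert (tab["stars"] == "").all()

    def test_swapped_order_flips_sign_only(self):
        rng = np.random.default_rng(4)
        ra = fake_result({"G": 0.4 + 0.03 * rng.normal(size=80)}, model="gblup")
        rb = fake_result({"G": 0.45 + 0.03 * rng.normal(size=80)}, model="rkhs")
        ab = hp.compare_models(ra, rb)
        ba = hp.compare_models(rb, ra)
        assert ab["mean_diff"].iloc[0] == pytest.approx(-ba["mean_diff"].iloc[0])
        assert ab["p"].iloc[0] == pytest.approx(ba["p"].iloc[0])
        assert ab["stars"].iloc[0] == ba["stars"].iloc[0]

    def test_shifted_distributions_flagged_significant(self):
        rng = np.random.default_rng(5)
        ra = fake_result({"G": 0.40 + 0.03 * rng.normal(size=100)})
        rb = fake_result({"G": 0.46 + 0.03 * rng.normal(size=100)})
        tab = hp.compare_models(ra, rb)
        assert tab["stars"].iloc[0] != ""
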