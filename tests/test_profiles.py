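import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from hgparcel.fingerprints import Fingerprint, normalize_fingerprints
from hgparcel.gradients import TimeSeriesBundle
from hgparcel.profiles import (
    MorphometryMaps,
    SoftThresholdParams,
    compare_cohort_profiles,
    compare_subregions,
    fdr_bh,
    functional_connectivity_profile,
    inverse_soft_threshold,
    morphometry_profile,
    paired_ttest,
    soft_threshold,
    structural_connectivity_profile,
)
from hgparcel.synthetic import (
    band_base_profiles,
    make_phantom,
    simulate_fingerprints,
    simulate_morphometry,
)


def brute_force_bh(p_values, q):
    """BH step-up from the definition: largest i with p_(i) <= i*q/m."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_star = i
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    adjusted = np.empty(m)
    for i in range(1, m + 1):
        adjusted[order[i - 1]] = min(
            min(m * p[order[j - 1]] / j for j in range(i, m + 1)), 1.0
        )
    return adjusted, rejected


class TestSoftThreshold:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.015625)])
    def test_exact_values_beta6(self, r, expected):
        assert soft_threshold(r, 6.0) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            soft_threshold(1.1, 6.0)

    def test_bad_beta_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            soft_threshold(0.0, 0.0)

    def test_strictly_monotone_on_grid(self):
        grid = np.linspace(-1, 1, 10001)
        vals = soft_threshold(grid, 6.0)
        assert np.all(np.diff(vals) > 0)
        assert vals[0] == 0.0 and vals[-1] == 1.0

    @given(st.floats(-1.0, 1.0), st.floats(0.5, 12.0))
    @settings(max_examples=200)
    def test_bijection_roundtrip(self, r, beta):
        assert inverse_soft_threshold(soft_threshold(r, beta), beta) == pytest.approx(
            r, abs=1e-12
        )


def _bundle_from_arrays(seed, targets, target_names):
    """Wrap explicit seed/target series into a TimeSeriesBundle."""
    n_t = len(target_names)
    membership = np.array(list(target_names), dtype=object)
    return TimeSeriesBundle(
        seed, targets, membership, tuple(target_names), target_mean_series=targets
    )


class TestFunctionalConnectivityProfile:
    def test_identical_series_contribute_one(self, rng):
        t = rng.standard_normal(100)
        bundle = _bundle_from_arrays(t[None, :], t[None, :], ["roi"])
        prof = functional_connectivity_profile(bundle, ["HG1"])
        assert prof.loc["HG1", "roi"] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_near_half_to_the_beta(self):
        rng = np.random.default_rng(99)
        n_seed, T = 120, 1400
        seed = rng.standard_normal((n_seed, T))
        target = rng.standard_normal((1, T))
        bundle = _bundle_from_arrays(seed, target, ["roi"])
        prof = functional_connectivity_profile(bundle, ["HG1"] * n_seed)
        # Monte-Carlo tolerance: 3 SE of the mean soft-thresholded r
        zs = (seed - seed.mean(1, keepdims=True)) / seed.std(1, keepdims=True)
        zt = (target - target.mean(1, keepdims=True)) / target.std(1, keepdims=True)
        w = soft_threshold(np.clip(zs @ zt.T / T, -1, 1), 6.0)
        se = w.std(ddof=1) / np.sqrt(n_seed)
        assert abs(prof.loc["HG1", "roi"] - 0.015625) < 3 * se + 3e-4

    def test_zero_variance_series_excluded(self, rng):
        seed = np.vstack([rng.standard_normal(50), np.zeros(50)])
        target = rng.standard_normal((1, 50))
        bundle = _bundle_from_arrays(seed, target, ["roi"])
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = functional_connectivity_profile(bundle, ["HG1", "HG1"])
        assert np.isfinite(prof.loc["HG1", "roi"])

    def test_planted_axis_association_ordering(self, default_subject, default_run):
        # cohort-level: HG3's association-target FC exceeds HG1's and HG2's
        fc = default_run.fc_profiles.mean(axis=0)  # (3, 42), HG1/HG2/HG3
        from hgparcel.synthetic import ASSOCIATION_TARGETS, DEFAULT_TARGETS

        idx = [i for i, t in enumerate(DEFAULT_TARGETS) if t in ASSOCIATION_TARGETS]
        hg1, hg2, hg3 = fc[0, idx], fc[1, idx], fc[2, idx]
        assert np.all(hg3 > hg1)
        assert np.all(hg3 > hg2)

    def test_short_series_rejected(self, rng):
        bundle = _bundle_from_arrays(
            rng.standard_normal((2, 5)), rng.standard_normal((1, 5)), ["roi"]
        )
        with pytest.raises(ValueError, match="10 timepoints"):
            functional_connectivity_profile(bundle, ["HG1", "HG1"])


class TestStructuralConnectivityProfile:
    def test_two_unit_arithmetic(self):
        fp = Fingerprint(np.array([[0.9, 0.1], [0.7, 0.3]]), ("a", "b"), "row_proportion")
        prof = structural_connectivity_profile(fp, ["HG1", "HG1"])
        assert prof.loc["HG1"].tolist() == pytest.approx([0.8, 0.2])

    def test_noise_free_equals_base_profile(self, noise_free_config):
        ph = make_phantom(noise_free_config)
        fp = simulate_fingerprints(ph, noise_free_config)
        prof = structural_connectivity_profile(fp, ph.true_labels)
        base = band_base_profiles(noise_free_config.target_names)
        for band in ("HG1", "HG2", "HG3"):
            assert np.allclose(prof.loc[band].to_numpy(), base[band], atol=1e-12)

    def test_hg3_stg_is_maximal(self, default_subject):
        ph, fp, _ = default_subject
        prof = structural_connectivity_profile(fp, ph.true_labels)
        assert prof["STG"].idxmax() == "HG3"
        assert prof["IN"].idxmax() == "HG2"

    def test_empty_subregion_rejected(self):
        fp = Fingerprint(np.array([[1.0, 1.0]]), ("a", "b"))
        with pytest.raises(ValueError, match="raw or row_proportion"):
            structural_connectivity_profile(
                normalize_fingerprints(fp, "log1p"), ["HG1"]
            )


class TestMorphometryProfile:
    def test_piecewise_constant_map(self):
        maps = MorphometryMaps(np.array([1.0, 1.0, 2.0]), np.array([3.0, 3.0, 2.5]))
        prof = morphometry_profile(maps, ["HG1", "HG1", "HG2"])
        assert prof.loc["HG1", "myelin"] == 1.0
        assert prof.loc["HG2", "thickness"] == 2.5

    def test_single_unit_subregion(self):
        maps = MorphometryMaps(np.array([1.5, 2.5]), np.array([2.0, 3.0]))
        prof = morphometry_profile(maps, ["HG1", "HG2"])
        assert prof.loc["HG2", "myelin"] == 2.5

    def test_myelin_max_at_hg1(self, default_config, default_phantom):
        maps = simulate_morphometry(default_phantom, default_config)
        prof = morphometry_profile(maps, default_phantom.true_labels)
        assert prof["myelin"].idxmax() == "HG1"


class TestPairedTTest:
    def test_identical_inputs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = paired_ttest(x, x)
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        # differences [1, 2, 3]: t = 2 / (1 / sqrt(3)), df = 2
        t, p = paired_ttest(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert p == pytest.approx(2 * scipy_stats.t.sf(2 * np.sqrt(3), 2), abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            paired_ttest(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_degenerate_differences_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_ttest(np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]))

    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.standard_normal(n)
            y = x + rng.standard_normal(n)
            t, p = paired_ttest(x, y)
            ref = scipy_stats.ttest_rel(x, y)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestFdrBH:
    def test_boundary_case_all_rejected(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        adjusted, rejected = fdr_bh(p, q=0.05)
        assert rejected.all()
        assert np.all(adjusted <= 0.05)

    def test_none_rejected(self):
        _, rejected = fdr_bh([0.2, 0.5], q=0.05)
        assert not rejected.any()

    def test_empty_input(self):
        adjusted, rejected = fdr_bh([], q=0.05)
        assert adjusted.size == 0 and rejected.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 51))
            p = rng.uniform(0, 1, m)
            q = float(rng.uniform(0.01, 0.2))
            adj, rej = fdr_bh(p, q)
            adj_o, rej_o = brute_force_bh(p, q)
            assert np.allclose(adj, adj_o, atol=1e-12)
            assert np.array_equal(rej, rej_o)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        adj, rej = fdr_bh(p, 0.05)
        rej_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, adj_sm, atol=1e-12)
        assert np.array_equal(rej, rej_sm)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50),
        st.floats(0.01, 0.25),
    )
    @settings(max_examples=100)
    def test_property_oracle_equivalence(self, p, q):
        adj, rej = fdr_bh(p, q)
        adj_o, rej_o = brute_force_bh(p, q)
        assert np.allclose(adj, adj_o, atol=1e-12)
        assert np.array_equal(rej, rej_o)


class TestCompareSubregions:
    def test_null_pair_no_significant_rows(self, rng):
        # HG1 and HG2 generated identically -> their contrasts stay null
        n_subj, n_targ = 20, 42
        values = rng.standard_normal((n_subj, 2, n_targ))
        table = compare_subregions({"fc": (values, [f"t{i}" for i in range(n_targ)])})
        assert not table["significant"].any()

    def test_q_zero_nothing_significant(self, rng):
        values = rng.standard_normal((10, 3, 5)) + np.arange(3)[None, :, None]
        table = compare_subregions(
            {"fc": (values, list("abcde"))}, q=0.0
        )
        assert not table["significant"].any()

    def test_cohort_myelin_contrasts(self, default_run):
        stats = default_run.stats
        myl = stats[stats["family"] == "myelin"].set_index("pair")
        assert myl.loc["HG1>HG2", "significant"].item()
        assert myl.loc["HG1>HG3", "significant"].item()
        assert myl.loc["HG1>HG2", "t"].item() > 0
        assert myl.loc["HG1>HG3", "t"].item() > 0

    def test_cohort_fc_hg3_contrasts(self, default_run):
        stats = default_run.stats
        fc = stats[stats["family"] == "fc"]
        hg12 = fc[fc["pair"] == "HG1>HG2"]
        # planted generator treats HG1/HG2 FC identically only in that both
        # follow the axis; nearby bands may differ. HG3 contrasts must be
        # strongly significant for association targets.
        from hgparcel.synthetic import ASSOCIATION_TARGETS

        hg13 = fc[(fc["pair"] == "HG1>HG3") & fc["target"].isin(ASSOCIATION_TARGETS)]
        assert hg13["significant"].all()
        assert (hg13["t"] < 0).all()

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="3 subjects"):
            compare_subregions({"m": rng.standard_normal((2, 3))})

    def test_family_wise_correction_is_independent(self, rng):
        strong = rng.standard_normal((15, 2)) + np.array([0.0, 5.0])
        null = rng.standard_normal((15, 2, 30))
        table = compare_subregions(
            {"myelin": strong, "fc": (null, [f"t{i}" for i in range(30)])}
        )
        assert table[table["family"] == "myelin"]["significant"].all()
        # the strong myelin effect must not drag null fc rows to significance
        assert table[table["family"] == "fc"]["p_adjusted"].min() > 0.05


class TestCompareCohortProfiles:
    def test_pair_renaming(self, rng):
        myelin = rng.standard_normal((10, 3)) + np.array([2.0, 0.0, 0.0])
        table = compare_cohort_profiles(myelin=myelin)
        assert set(table["pair"]) == {"HG1>HG2", "HG1>HG3", "HG2>HG3"}
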