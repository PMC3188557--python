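"""Sides-model ANOVA, FA indices, genotype comparisons, screening tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wingfa import asymmetry as asym
from wingfa import procrustes as pro
from wingfa import simulate as sim


def brute_force_sides_ss(arr):
    """Independent SS oracle: explicit deviations from cell/marginal means."""
    n, two, m = arr.shape
    grand = arr.mean()
    ss = {"Individual": 0.0, "Side": 0.0, "Individual x Side": 0.0, "Error": 0.0}
    for i in range(n):
        ss["Individual"] += 2 * m * (arr[i].mean() - grand) ** 2
    for s in range(2):
        ss["Side"] += n * m * (arr[:, s].mean() - grand) ** 2
    for i in range(n):
        for s in range(2):
            dev = arr[i, s].mean() - arr[i].mean() - arr[:, s].mean() + grand
            ss["Individual x Side"] += m * dev**2
            for r in range(m):
                ss["Error"] += (arr[i, s, r] - arr[i, s].mean()) ** 2
    return ss


class TestSidesAnova:
    def test_constant_data_all_zero(self):
        anova = asym.sides_anova_univariate(np.full((4, 2, 2), 7.0))
        for e in anova.effects:
            assert e.ss == 0.0

    def test_matches_brute_force_decomposition(self, rng):
        arr = rng.standard_normal((2, 2, 2)) * 3 + 10
        anova = asym.sides_anova_univariate(arr)
        oracle = brute_force_sides_ss(arr)
        total = ((arr - arr.mean()) ** 2).sum()
        assert sum(oracle.values()) == pytest.approx(total, rel=1e-12)
        for name, ss in oracle.items():
            assert anova[name].ss == pytest.approx(ss, abs=1e-12)

    def test_degrees_of_freedom(self, rng):
        arr = rng.standard_normal((10, 2, 3))
        anova = asym.sides_anova_univariate(arr)
        assert anova["Individual"].df == 9
        assert anova["Side"].df == 1
        assert anova["Individual x Side"].df == 9
        assert anova["Error"].df == 2 * 10 * 2

    def test_variance_component_expectations(self):
        """E[MS_int] = M*s2_FA + s2_ME and E[MS_err] = s2_ME (sigma2_FA=4,
        sigma2_ME=1, M=2 -> 9 and 1)."""
        rng = np.random.default_rng(11)
        ms_int, ms_err = [], []
        params = sim.TraitParams(
            n_individuals=300, m_replicates=2, ind_sigma2=10.0,
            fa_sigma2=4.0, me_sigma2=1.0,
        )
        for _ in range(200):
            arr = sim.simulate_trait_values(params, rng)
            anova = asym.sides_anova_univariate(arr)
            ms_int.append(anova["Individual x Side"].ms)
            ms_err.append(anova["Error"].ms)
        assert np.mean(ms_int) == pytest.approx(9.0, rel=0.10)
        assert np.mean(ms_err) == pytest.approx(1.0, rel=0.10)

    def test_labelled_input_and_balance_error(self, rng):
        vals = rng.standard_normal(8)
        inds = ["a", "a", "a", "a", "b", "b", "b", "b"]
        sides = ["L", "L", "R", "R"] * 2
        reps = [1, 2, 1, 2] * 2
        anova = asym.sides_anova_univariate(vals, inds, sides, reps)
        assert anova.n_individuals == 2
        with pytest.raises(asym.BalanceError):
            asym.sides_anova_univariate(vals[:-1], inds[:-1], sides[:-1], reps[:-1])

    def test_single_replicate_lacks_error_stratum(self, rng):
        with pytest.warns(UserWarning, match="M=1"):
            anova = asym.sides_anova_univariate(rng.standard_normal((5, 2, 1)))
        assert not anova.has_error_stratum
        with pytest.raises(asym.InsufficientDataError):
            asym.fa10(anova)


class TestProcrustesAnova:
    def test_symmetric_noiseless_dataset_zero_asymmetry(self):
        from wingfa.io import LandmarkConfiguration, LandmarkDataset, SpecimenRecord

        rng = np.random.default_rng(1)
        records = []
        for i in range(6):
            left = rng.standard_normal((8, 2))
            right = pro.reflect(left)
            for rep in (1, 2):
                for side, coords in (("L", left), ("R", right)):
                    records.append(
                        SpecimenRecord(
                            f"i{i}", side, rep, "g", "F",
                            LandmarkConfiguration(coords),
                        )
                    )
        fit = pro.gpa(LandmarkDataset(records), reflect_side="L")
        anova = asym.procrustes_anova(fit)
        assert anova["Side"].ss < 1e-18
        assert anova["Individual x Side"].ss < 1e-18
        assert anova["Error"].ss < 1e-18

    def test_df_multiplied_by_shape_dimension(self):
        params = sim.default_study_params(
            seed=5, n_per_cell=48, genotypes=("control",)
        )
        ds, _ = sim.simulate_landmark_dataset(params)
        fit = pro.gpa(ds.subset(sex="F"))
        anova = asym.procrustes_anova(fit)
        assert anova["Individual"].df == 47 * 26
        assert anova["Side"].df == 26
        assert anova["Individual x Side"].df == 47 * 26
        assert anova["Error"].df == 2 * 48 * 1 * 26

    def test_equals_sum_of_per_coordinate_anovas(self, small_fit):
        fit, _ = small_fit
        anova = asym.procrustes_anova(fit)
        arr, _, m = asym.procrustes_sides_table(fit)
        for name in ("Individual", "Side", "Individual x Side", "Error"):
            total = sum(
                asym.sides_anova_univariate(arr[:, :, :, c])[name].ss
                for c in range(arr.shape[-1])
            )
            assert anova[name].ss == pytest.approx(total, rel=1e-9)


class TestFAIndices:
    def test_fa10_arithmetic(self):
        anova = asym.AsymmetryAnova(
            effects=[
                asym.Effect("Individual", 9, 1.0, 1.0),
                asym.Effect("Side", 1, 0.1, 0.1),
                asym.Effect("Individual x Side", 9, 9 * 3e-5, 3e-5),
                asym.Effect("Error", 20, 20e-5, 1e-5),
            ],
            kind="univariate", m_replicates=2, n_individuals=10,
        )
        est = asym.fa10(anova)
        assert est.value == pytest.approx(1e-5)
        anova.effects[3] = asym.Effect("Error", 20, 20 * 3e-5, 3e-5)
        assert asym.fa10(anova).value == pytest.approx(0.0)

    def test_fa10_negative_flagged_not_clipped(self):
        anova = asym.AsymmetryAnova(
            effects=[
                asym.Effect("Individual", 9, 1.0, 1.0),
                asym.Effect("Side", 1, 0.1, 0.1),
                asym.Effect("Individual x Side", 9, 9.0, 1.0),
                asym.Effect("Error", 20, 60.0, 3.0),
            ],
            kind="univariate", m_replicates=2, n_individuals=10,
        )
        est = asym.fa10(anova)
        assert est.value == pytest.approx(-1.0)
        assert est.negative

    def test_fa10_simulation_recovery(self):
        rng = np.random.default_rng(21)
        params = sim.TraitParams(
            n_individuals=300, m_replicates=2, fa_sigma2=5e-5, me_sigma2=1e-5,
            ind_sigma2=1e-3,
        )
        vals = [
            asym.fa10(asym.sides_anova_univariate(sim.simulate_trait_values(params, rng))).value
            for _ in range(300)
        ]
        assert np.mean(vals) == pytest.approx(5e-5, rel=0.05)

    def test_fa4_hand_examples(self):
        assert asym.fa4(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])).value == 0.0
        est = asym.fa4(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert est.value == pytest.approx(2.0)  # diffs {-1, 1}, var = 2
        with pytest.raises(asym.InsufficientDataError):
            asym.fa4(np.array([1.0]), np.array([0.0]))

    def test_fa4_expectation(self):
        """E[FA4] = 2*s2_FA + 2*s2_ME for single measurements."""
        rng = np.random.default_rng(31)
        params = sim.TraitParams(
            n_individuals=500, m_replicates=1, fa_sigma2=2.0, me_sigma2=0.5
        )
        vals = [
            asym.fa4(arr[:, 1, 0], arr[:, 0, 0]).value
            for arr in (sim.simulate_trait_values(params, rng) for _ in range(200))
        ]
        assert np.mean(vals) == pytest.approx(5.0, rel=0.10)

    def test_fa4_averages_replicates(self, rng):
        r = rng.standard_normal((10, 3))
        l = rng.standard_normal((10, 3))
        est = asym.fa4(r, l)
        assert est.value == pytest.approx(
            np.var(r.mean(axis=1) - l.mean(axis=1), ddof=1)
        )


class TestCompareFa:
    def test_identical_estimates(self):
        a = asym.FAEstimate(index="FA4", value=2.0, n=30, df=29)
        cmp_res = asym.compare_fa(a, a)
        assert cmp_res.fa_ratio == 1.0
        assert cmp_res.p_raw == pytest.approx(1.0)

    def test_ratio_coverage_matches_f_distribution(self):
        """Sampling spread of the FA4 fold-ratio follows ratio ~ true x F."""
        rng = np.random.default_rng(41)
        n, true_ratio, reps = 50, 37.0, 400
        hits = 0
        lo, hi = 25.0, 55.0
        for _ in range(reps):
            a = rng.normal(0, np.sqrt(true_ratio / 2), size=(n, 2))
            b = rng.normal(0, np.sqrt(1 / 2), size=(n, 2))
            fa_a = asym.fa4(a[:, 1], a[:, 0])
            fa_b = asym.fa4(b[:, 1], b[:, 0])
            ratio = asym.compare_fa(fa_a, fa_b).fa_ratio
            hits += lo <= ratio <= hi
        fdist = stats.f(n - 1, n - 1)
        expected = fdist.cdf(hi / true_ratio) - fdist.cdf(lo / true_ratio)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert hits / reps == pytest.approx(expected, abs=4 * se)

    def test_negative_fa10_excluded_with_warning(self):
        neg = asym.FAEstimate(index="FA10", value=-1e-6, n=10, df=9, negative=True,
                              ms_interaction=1.0, ms_error=3.0)
        pos = asym.FAEstimate(index="FA10", value=1e-5, n=10, df=9,
                              ms_interaction=3.0, ms_error=1.0)
        with pytest.warns(UserWarning, match="negative"):
            cmp_res = asym.compare_fa(pos, neg)
        assert np.isnan(cmp_res.fa_ratio)

    def test_zero_denominator_rejected(self):
        a = asym.FAEstimate(index="FA4", value=1.0, n=10, df=9)
        b = asym.FAEstimate(index="FA4", value=0.0, n=10, df=9)
        with pytest.raises(ZeroDivisionError):
            asym.compare_fa(a, b)


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(asym.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(asym.holm_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            asym.holm_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = asym.holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestAntisymmetryCheck:
    def test_normal_sample_rarely_flagged(self):
        rng = np.random.default_rng(51)
        flags = sum(
            asym.antisymmetry_check(rng.normal(size=500), seed=7).flagged
            for _ in range(200)
        )
        assert flags / 200 <= 0.05

    def test_strong_bimodality_flagged(self):
        rng = np.random.default_rng(61)
        flags = 0
        for _ in range(200):
            comp = rng.integers(0, 2, size=500)
            d = rng.normal(3 * (2 * comp - 1), 0.3)
            flags += asym.antisymmetry_check(d, seed=7).flagged
        assert flags / 200 >= 0.95

    def test_constant_diffs_degenerate(self):
        report = asym.antisymmetry_check(np.full(20, 1.5))
        assert report.degenerate and not report.flagged

    def test_small_sample_rejected(self):
        with pytest.raises(asym.InsufficientDataError):
            asym.antisymmetry_check(np.arange(5.0))


class TestFaAllometryCheck:
    def test_null_calibration(self):
        rng = np.random.default_rng(71)
        rejections = 0
        reps = 500
        for _ in range(reps):
            size = rng.normal(10, 1, size=40)
            a = np.abs(rng.normal(0, 1, size=40))
            report = asym.fa_allometry_check(a, size, np.repeat("g", 40))
            rejections += report.iloc[0]["p"] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)

    def test_size_dependent_fa_detected(self):
        rng = np.random.default_rng(81)
        detected = 0
        for _ in range(50):
            size = rng.uniform(5, 15, size=100)
            a = np.abs(rng.normal(0, 0.3 * size))
            report = asym.fa_allometry_check(a, size, np.repeat("g", 100))
            detected += (report.iloc[0]["p"] < 0.05) and (report.iloc[0]["slope"] > 0)
        assert detected / 50 >= 0.80

    def test_tiny_group_rejected(self):
        with pytest.raises(asym.InsufficientDataError):
            asym.fa_allometry_check([1.0, 2.0], [3.0, 4.0], ["g", "g"])


class TestGroupTests:
    def test_univariate_ss_match_brute_force(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        genotype = np.repeat(["a", "b"], 4)
        sex = np.tile(["F", "F", "M", "M"], 2)
        table = asym.group_tests(vals, genotype, sex).set_index("effect")
        # balanced 2x2: SS_genotype = n * (mean_a - mean_b)^2 / 2 ... brute force:
        grand = vals.mean()
        cell = vals.reshape(2, 2, 2).mean(axis=2)
        ss_geno = 4 * ((cell.mean(axis=1) - grand) ** 2).sum()
        ss_sex = 4 * ((cell.mean(axis=0) - grand) ** 2).sum()
        inter = cell - cell.mean(axis=1, keepdims=True) - cell.mean(axis=0, keepdims=True) + grand
        ss_int = 2 * (inter**2).sum()
        assert table.loc["genotype", "SS"] == pytest.approx(ss_geno, rel=1e-12)
        assert table.loc["sex", "SS"] == pytest.approx(ss_sex, rel=1e-12)
        assert table.loc["genotype x sex", "SS"] == pytest.approx(ss_int, abs=1e-9)

    def test_manova_null_calibration(self):
        rng = np.random.default_rng(91)
        reps, rejections = 400, 0
        for _ in range(reps):
            scores = rng.standard_normal((40, 3))
            genotype = np.repeat(["a", "b"], 20)
            sex = np.tile(["F", "M"], 20)
            table = asym.group_tests(scores, genotype, sex)
            rejections += table.set_index("effect").loc["genotype", "p"] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_pillai_monotone_in_shift(self, rng):
        scores = rng.standard_normal((60, 3))
        genotype = np.repeat(["a", "b"], 30)
        sex = np.tile(["F", "M"], 30)
        pillais = []
        for delta in (0.0, 1.0, 2.0):
            shifted = scores.copy()
            shifted[genotype == "b", 0] += delta
            table = asym.group_tests(shifted, genotype, sex).set_index("effect")
            pillais.append(table.loc["genotype", "Pillai"])
        assert pillais[0] < pillais[1] < pillais[2]

    def test_empty_cell_rejected(self, rng):
        with pytest.raises(ValueError, match="cell"):
            asym.group_tests(
                rng.standard_normal(6),
                ["a", "a", "a", "b", "b", "b"],
                ["F", "F", "F", "F", "F", "M"],
            )


class TestDAImmunity:
    def test_side_offset_changes_only_side_ss(self, rng):
        """The DA-correction contract: a constant side offset moves SS_Side
        but leaves interaction/error strata (hence FA10) untouched."""
        arr = rng.standard_normal((20, 2, 2))
        base = asym.sides_anova_univariate(arr)
        shifted = arr.copy()
        shifted[:, 1, :] += 3.7  # constant right-side offset
        with_da = asym.sides_anova_univariate(shifted)
        assert with_da["Side"].ss > base["Side"].ss
        for name in ("Individual", "Individual x Side", "Error"):
            assert with_da[name].ss == pytest.approx(base[name].ss, rel=1e-9)
        assert asym.fa10(with_da).value == pytest.approx(
            asym.fa10(base).value, rel=1e-9
        )
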