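"""Statistics: scoring, IQR fences, correlations, rank tests, mixed ANOVA,
Scheffe gating, and repeated-measures power."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from digiphen.errors import ValidationError
from digiphen.stats import (
    cohens_d_change,
    independent_t,
    iqr_filter,
    iqr_mask,
    mann_whitney_u,
    mixed_anova_2x3,
    pearson_corr,
    rm_anova_power,
    rm_power_sample_size,
    scheffe_pairwise,
    score_questionnaire,
    split_plot_ss,
)


class TestScoring:
    def test_dass_extremes(self):
        zeros = score_questionnaire(np.zeros(21), "dass")
        assert set(zeros.values()) == {0.0}
        maxed = score_questionnaire(np.full(21, 3), "dass")
        assert set(maxed.values()) == {21.0}

    def test_mauq_all_sevens(self):
        out = score_questionnaire(np.full(21, 7), "mauq")
        assert out["mauq"] == pytest.approx(7.0)

    def test_sum_instruments(self):
        assert score_questionnaire(np.full(22, 3), "self_efficacy") == {"self_efficacy": 66.0}
        assert score_questionnaire(np.full(30, 5), "time_management") == {
            "time_management": 150.0
        }

    @pytest.mark.parametrize(
        "responses, instrument",
        [
            (np.zeros(20), "dass"),  # wrong item count
            (np.full(21, 4), "dass"),  # out of range
            (np.zeros(22), "self_efficacy"),  # below range
        ],
    )
    def test_validation(self, responses, instrument):
        with pytest.raises(ValidationError):
            score_questionnaire(responses, instrument)


class TestIqr:
    def test_worked_example(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        # linear-interpolation quartiles: Q1=3.25, Q3=7.75, fences -3.5/14.5
        kept = iqr_filter(vals)
        assert kept.tolist() == list(range(1, 10))

    def test_all_equal_unchanged(self):
        vals = np.full(10, 5.0)
        assert iqr_filter(vals).tolist() == vals.tolist()

    def test_idempotent_on_example(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        once = iqr_filter(vals)
        assert iqr_filter(once).tolist() == once.tolist()

    def test_small_sample_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            kept = iqr_filter(np.array([1.0, 2.0, 900.0]))
        assert kept.tolist() == [1.0, 2.0, 900.0]

    def test_nan_masked_out(self):
        m = iqr_mask(np.array([1.0, np.nan, 2.0, 3.0, 4.0, 5.0]))
        assert not m[1]
        assert m.sum() == 5


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        res = pearson_corr([1, 2, 3], [6, 5, 4])
        assert res.r == pytest.approx(-1.0)

    def test_product_moment_example(self):
        res = pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)

    def test_zero_variance_sentinel(self):
        res = pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            pearson_corr([1.0, 2.0], [3.0, 4.0])


def _brute_u(a, b):
    u1 = sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )
    return min(u1, len(a) * len(b) - u1)


class TestGroupTests:
    def test_identical_samples_t_zero(self):
        t, df, p = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert df == 4

    @pytest.mark.parametrize(
        "a, b, expected_u",
        [([1, 2], [3, 4], 0.0), ([1, 3], [2, 4], 1.0)],
    )
    def test_u_examples(self, a, b, expected_u):
        u, _p = mann_whitney_u(a, b)
        assert u == expected_u == _brute_u(a, b)

    def test_u_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n1, n2 = rng.integers(2, 9, size=2)
            a = rng.integers(0, 6, size=n1).astype(float)  # ties likely
            b = rng.integers(0, 6, size=n2).astype(float)
            u, _ = mann_whitney_u(a, b)
            assert u == pytest.approx(_brute_u(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


def _toy_waves(values_by_subject):
    rows = []
    for (pid, group), vals in values_by_subject.items():
        for wave, v in zip(("baseline", "mid", "post"), vals):
            rows.append(
                {"participant_id": pid, "group": group, "wave": wave, "y": float(v)}
            )
    return pd.DataFrame(rows)


def _brute_force_ss(df):
    """Definitional sums of squares for the split-plot design."""
    y = df["y"].to_numpy()
    grand = y.mean()
    m = df["wave"].nunique()
    subj = {p: g["y"].mean() for p, g in df.groupby("participant_id")}
    grp = {p: g["group"].iloc[0] for p, g in df.groupby("participant_id")}
    gmean = {g: sub["y"].mean() for g, sub in df.groupby("group")}
    tmean = {t: sub["y"].mean() for t, sub in df.groupby("wave")}
    cmean = {k: sub["y"].mean() for k, sub in df.groupby(["group", "wave"])}
    n_by_group = df.groupby("group")["participant_id"].nunique()

    ss_total = sum((v - grand) ** 2 for v in y)
    ss_subject = m * sum((sm - grand) ** 2 for sm in subj.values())
    ss_group = m * sum(n_by_group[g] * (gm - grand) ** 2 for g, gm in gmean.items())
    ss_time = len(subj) * sum((tm - grand) ** 2 for tm in tmean.values())
    ss_cells = sum(
        n_by_group[g] * (cm - grand) ** 2 for (g, t), cm in cmean.items()
    )
    return {
        "ss_total": ss_total,
        "ss_group": ss_group,
        "ss_subj_within": ss_subject - ss_group,
        "ss_time": ss_time,
        "ss_interaction": ss_cells - ss_group - ss_time,
        "ss_error_within": ss_total - ss_subject - ss_time - (ss_cells - ss_group - ss_time),
    }


class TestMixedAnova:
    def test_ss_partition_matches_bruteforce_toy(self):
        waves = _toy_waves(
            {
                ("A1", "control"): (3, 4, 5),
                ("A2", "control"): (2, 4, 6),
                ("A3", "control"): (5, 5, 5),
                ("B1", "intervention"): (6, 4, 2),
                ("B2", "intervention"): (7, 5, 4),
                ("B3", "intervention"): (5, 3, 1),
            }
        )
        got = split_plot_ss(waves, dv="y")
        want = _brute_force_ss(waves)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, rel=1e-10, abs=1e-10), key

    def test_f_statistics_match_hand_computation(self):
        waves = _toy_waves(
            {
                ("A1", "control"): (3, 4, 5),
                ("A2", "control"): (2, 4, 6),
                ("A3", "control"): (5, 5, 5),
                ("B1", "intervention"): (6, 4, 2),
                ("B2", "intervention"): (7, 5, 4),
                ("B3", "intervention"): (5, 3, 1),
            }
        ).rename(columns={"y": "score"})
        res = mixed_anova_2x3(waves, "score")
        ss = _brute_force_ss(waves.rename(columns={"score": "y"}))
        n, g, m = 6, 2, 3
        f_group = (ss["ss_group"] / (g - 1)) / (ss["ss_subj_within"] / (n - g))
        f_time = (ss["ss_time"] / (m - 1)) / (ss["ss_error_within"] / ((n - g) * (m - 1)))
        f_inter = (ss["ss_interaction"] / ((g - 1) * (m - 1))) / (
            ss["ss_error_within"] / ((n - g) * (m - 1))
        )
        tab = res.table.set_index("effect")
        assert tab.loc["group", "F"] == pytest.approx(f_group, rel=1e-6)
        assert tab.loc["time", "F"] == pytest.approx(f_time, rel=1e-6)
        assert tab.loc["time x group", "F"] == pytest.approx(f_inter, rel=1e-6)

    def test_df_identity_for_36_participants(self):
        rng = np.random.default_rng(1)
        rows = {}
        for i in range(19):
            rows[(f"C{i}", "control")] = rng.normal(size=3)
        for i in range(17):
            rows[(f"I{i}", "intervention")] = rng.normal(size=3)
        waves = _toy_waves(rows).rename(columns={"y": "score"})
        tab = mixed_anova_2x3(waves, "score").table.set_index("effect")
        assert (tab.loc["time x group", "df1"], tab.loc["time x group", "df2"]) == (2, 68)
        assert (tab.loc["group", "df1"], tab.loc["group", "df2"]) == (1, 34)

    def test_constant_outcome_gives_zero_f(self):
        waves = _toy_waves(
            {
                ("A1", "control"): (4, 4, 4),
                ("A2", "control"): (4, 4, 4),
                ("B1", "intervention"): (4, 4, 4),
                ("B2", "intervention"): (4, 4, 4),
            }
        ).rename(columns={"y": "score"})
        tab = mixed_anova_2x3(waves, "score").table
        assert (tab["F"] == 0.0).all()
        assert (tab["p"] == 1.0).all()

    def test_missing_wave_listwise_deleted(self):
        waves = _toy_waves(
            {
                ("A1", "control"): (3, 4, 5),
                ("A2", "control"): (2, 4, 6),
                ("A3", "control"): (5, 5, 5),
                ("B1", "intervention"): (6, 4, 2),
                ("B2", "intervention"): (7, 5, 4),
            }
        ).rename(columns={"y": "score"})
        waves = pd.concat(
            [
                waves,
                pd.DataFrame(
                    [
                        {
                            "participant_id": "B3",
                            "group": "intervention",
                            "wave": "baseline",
                            "score": 9.0,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
        res = mixed_anova_2x3(waves, "score")
        assert res.excluded_participants == ("B3",)

    def test_ss_decomposition_on_random_data(self):
        rng = np.random.default_rng(2)
        rows = {}
        for i in range(8):
            rows[(f"C{i}", "control")] = rng.normal(size=3)
            rows[(f"I{i}", "intervention")] = rng.normal(size=3)
        waves = _toy_waves(rows)
        ss = split_plot_ss(waves, dv="y")
        between = ss["ss_group"] + ss["ss_subj_within"]
        within = ss["ss_time"] + ss["ss_interaction"] + ss["ss_error_within"]
        assert between + within == pytest.approx(ss["ss_total"], rel=1e-8)
        # within-subject SS computed definitionally
        subj_mean = waves.groupby("participant_id")["y"].transform("mean")
        assert within == pytest.approx(((waves["y"] - subj_mean) ** 2).sum(), rel=1e-8)


class TestScheffe:
    def test_never_significant_without_omnibus(self):
        rng = np.random.default_rng(3)
        checked = 0
        for trial in range(30):
            rows = {}
            for i in range(5):
                rows[(f"C{i}", "control")] = rng.normal(size=3)
                rows[(f"I{i}", "intervention")] = rng.normal(size=3)
            waves = _toy_waves(rows).rename(columns={"y": "score"})
            data = waves.rename(columns={"score": "y"})
            ss = split_plot_ss(data, dv="y")
            f_time = (ss["ss_time"] / ss["df_time"]) / (
                ss["ss_error_within"] / ss["df_error_within"]
            )
            p_omni = sps.f.sf(f_time, ss["df_time"], ss["df_error_within"])
            if p_omni < 0.05:
                continue
            means = data.groupby("wave")["y"].mean().to_dict()
            ns = data.groupby("wave")["y"].size().to_dict()
            ph = scheffe_pairwise(
                means, ns, ss["ss_error_within"] / ss["df_error_within"],
                ss["df_error_within"], k=3,
            )
            assert not ph["significant"].any(), trial
            checked += 1
        assert checked >= 15  # most null draws must actually be exercised

    def test_detects_large_contrast(self):
        ph = scheffe_pairwise(
            {"a": 0.0, "b": 5.0}, {"a": 20, "b": 20}, ms_error=1.0, df_error=38, k=2
        )
        assert ph["significant"].all()


class TestCohensD:
    def test_known_change_scores(self):
        # intervention changes: -4, -6 (mean -5); control: 0, -2 (mean -1)
        waves = _toy_waves(
            {
                ("C1", "control"): (10, 10, 10),
                ("C2", "control"): (10, 9, 8),
                ("I1", "intervention"): (10, 8, 6),
                ("I2", "intervention"): (10, 7, 4),
            }
        ).rename(columns={"y": "score"})
        d = cohens_d_change(waves, "score")
        # changes: I (-4, -6), C (0, -2); pooled sd = sqrt((2+2)/2) = sqrt(2)
        assert d == pytest.approx((-5 - (-1)) / np.sqrt(2))


class TestPower:
    def test_huge_effect_gives_minimal_n(self):
        assert rm_power_sample_size(100.0) == 2

    def test_monotone_in_effect_size(self):
        for f in (0.1, 0.2, 0.3, 0.4):
            assert rm_power_sample_size(2 * f) <= rm_power_sample_size(f)

    @pytest.mark.parametrize("effect", ["between", "within", "interaction"])
    def test_self_consistent_at_boundary(self, effect):
        f_es = 0.25
        n = rm_power_sample_size(f_es, effect=effect)
        assert rm_anova_power(n, f_es, effect=effect) >= 0.80
        if n > 2:
            assert rm_anova_power(n - 1, f_es, effect=effect) < 0.80

    def test_power_matches_numerical_integration(self):
        # independent route: integrate the noncentral-F density directly
        n, f_es = 12, 0.3
        power = rm_anova_power(n, f_es, effect="within")
        groups, measures, rho = 2, 3, 0.5
        n_total = n * groups
        df1, df2 = measures - 1, (n_total - groups) * (measures - 1)
        lam = f_es**2 * n_total * measures / (1 - rho)
        fcrit = sps.f.isf(0.05, df1, df2)
        integrated, _err = integrate.quad(
            lambda x: sps.ncf.pdf(x, df1, df2, lam), fcrit, np.inf
        )
        assert power == pytest.approx(integrated, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            rm_anova_power(10, 0.3, rho=1.5)
        with pytest.raises(ValidationError):
            rm_power_sample_size(0.0)
        with pytest.raises(ValidationError):
            rm_power_sample_size(1e-6, n_max=50)
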