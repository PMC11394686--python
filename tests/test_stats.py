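"""Statistics engine: analytic identities, split-plot oracle equivalence,
sphericity machinery, LSD post hoc, and the test-selection cascade."""

import numpy as np
import pandas as pd
import pytest
from helpers import random_balanced_design, splitplot_oracle
from hypothesis import given, settings
from hypothesis import strategies as st

import lfpbands as lb
from lfpbands.stats import mauchly_test, ordering_string, round3


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [
            (4.516, 1, 18, 0.201),
            (6.491, 4, 72, 0.265),
            (5.804, 1, 18, 0.244),
            (3.016, 4, 72, 0.144),
            (0.635, 4, 72, 0.034),
        ],
    )
    def test_reported_effect_sizes(self, F, df1, df2, expected):
        assert round3(lb.partial_eta_squared(F, df1, df2)) == expected

    def test_zero_F(self):
        assert lb.partial_eta_squared(0.0, 3, 50) == 0.0

    def test_negative_F_rejected(self):
        with pytest.raises(ValueError):
            lb.partial_eta_squared(-1.0, 1, 10)


class TestFPvalue:
    @pytest.mark.parametrize(
        "F,p3", [(4.516, 0.048), (4.191, 0.056), (3.999, 0.061), (4.425, 0.050), (5.804, 0.027)]
    )
    def test_between_subject_pvalues(self, F, p3):
        assert round3(lb.f_pvalue(F, 1, 18)) == p3

    def test_zero_F_gives_one(self):
        assert lb.f_pvalue(0.0, 2, 10) == 1.0


class TestMixedAnova:
    def test_toy_integer_dataset_matches_oracle(self):
        rows = []
        vals = {
            ("g1", 0): [1, 2, 3], ("g1", 1): [2, 3, 4], ("g1", 2): [5, 4, 6],
            ("g2", 0): [2, 4, 3], ("g2", 1): [6, 5, 7], ("g2", 2): [8, 9, 7],
        }
        for (g, j), xs in vals.items():
            for i, v in enumerate(xs):
                rows.append(dict(subject=f"{g}s{i}", group=g, region=f"r{j}", diff=float(v)))
        df = pd.DataFrame(rows)
        res = lb.mixed_anova(df)
        ref = splitplot_oracle(df)
        for name in ("group", "channel", "group*channel"):
            F, d1, d2, p = ref[name]
            e = res.effects[name]
            assert e.F == pytest.approx(F, abs=1e-9)
            assert (e.df1, e.df2) == (d1, d2)
            assert e.p_uncorrected == pytest.approx(p, abs=1e-9)

    def test_oracle_equivalence_random_designs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            df = random_balanced_design(rng)
            res = lb.mixed_anova(df)
            ref = splitplot_oracle(df)
            for name in ("group", "channel", "group*channel"):
                assert res.effects[name].F == pytest.approx(ref[name][0], abs=1e-8)

    def test_study_design_degrees_of_freedom(self, small_tables):
        _, diff_table, _ = small_tables
        res = lb.mixed_anova(diff_table[diff_table.band == "gamma"], band="gamma")
        g = res.effects["group"]
        c = res.effects["channel"]
        assert (g.df1, g.df2) == (1, 18)
        assert (c.df1, c.df2) == (4, 72)

    def test_effect_size_self_consistency(self, small_tables):
        _, diff_table, _ = small_tables
        res = lb.mixed_anova(diff_table[diff_table.band == "delta"], band="delta")
        for e in res.effects.values():
            assert e.partial_eta_sq == pytest.approx(
                lb.partial_eta_squared(e.F, e.df1, e.df2), abs=1e-9
            )

    def test_gg_correction_is_conservative_at_alpha(self):
        # pointwise p monotonicity fails for small F (shrinking both dfs can
        # lower the tail probability), but the correction is conservative
        # where it matters: it never turns a non-significant within-subject
        # effect significant at alpha = 0.05
        rng = np.random.default_rng(5)
        for _ in range(60):
            df = random_balanced_design(rng)
            res = lb.mixed_anova(df)
            for name in ("channel", "group*channel"):
                e = res.effects[name]
                assert not (e.p_reported < 0.05 and e.p_uncorrected >= 0.05)
                if e.p_uncorrected < 0.05:
                    assert e.p_reported >= e.p_uncorrected - 1e-12

    def test_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        df = random_balanced_design(rng, max_n=4, max_k=4)
        res = lb.mixed_anova(df)
        ref = pg.mixed_anova(
            df, dv="diff", within="region", between="group", subject="subject"
        ).set_index("Source")
        assert res.effects["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res.effects["channel"].F == pytest.approx(ref.loc["region", "F"], rel=1e-9)
        assert res.effects["group*channel"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_incomplete_design_rejected(self):
        df = random_balanced_design(np.random.default_rng(0))
        with pytest.raises(ValueError, match="design error"):
            lb.mixed_anova(df.iloc[1:])

    def test_unbalanced_groups_rejected(self):
        df = random_balanced_design(np.random.default_rng(0))
        subj = df["subject"].iloc[0]
        with pytest.raises(ValueError, match="design error"):
            lb.mixed_anova(df[df.subject != subj])


class TestSphericity:
    def test_k2_epsilon_is_one(self):
        assert lb.gg_epsilon(np.array([[2.0, 0.5], [0.5, 1.0]])) == 1.0

    def test_compound_symmetry_epsilon_one(self):
        k = 5
        S = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert lb.gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_lower_bound(self):
        v = np.array([2.0, -0.5, -0.5, -0.5, -0.5])  # already centred
        S = np.outer(v, v)
        assert lb.gg_epsilon(S) == pytest.approx(0.25, abs=1e-12)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            lb.gg_epsilon(np.array([[1.0, 0.2], [0.4, 1.0]]))

    def test_mauchly_matches_pingouin_on_centred_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        rows = []
        for g, n in (("sham", 6), ("lesion", 6)):
            for i in range(n):
                base = rng.normal(0, 1)
                for j in range(4):
                    rows.append(
                        dict(subject=f"{g}{i}", group=g, region=f"r{j}",
                             diff=base + 0.5 * j + rng.normal(0, 1))
                    )
        df = pd.DataFrame(rows)
        res = lb.mixed_anova(df)
        dfc = df.copy()
        dfc["diff"] -= dfc.groupby(["group", "region"])["diff"].transform("mean")
        sph = pg.sphericity(dfc, dv="diff", within="region", subject="subject")
        eps = pg.epsilon(dfc, dv="diff", within="region", subject="subject", correction="gg")
        assert res.mauchly_W == pytest.approx(sph.W, rel=1e-9)
        assert res.gg_epsilon == pytest.approx(eps, rel=1e-9)

    def test_mauchly_spherical_accepts(self):
        W, p = mauchly_test(np.eye(4) * 2.0, n_error=30)
        assert W == pytest.approx(1.0)
        assert p == pytest.approx(1.0)


class TestLsdPosthoc:
    @staticmethod
    def fit(shift_region=None, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("g1", "g2"):
            for i in range(5):
                for j in range(4):
                    v = rng.normal(0, 1)
                    if shift_region == j:
                        v += shift
                    rows.append(dict(subject=f"{g}s{i}", group=g, region=f"r{j}", diff=v))
        return lb.mixed_anova(pd.DataFrame(rows))

    def test_equal_means_no_significant_pairs_na(self):
        res = self.fit()
        assert res.lsd_strings["channel"] == "NA"

    def test_shifted_region_beats_all(self):
        res = self.fit(shift_region=3, shift=10.0)
        s = res.lsd_strings["channel"]
        assert s.startswith("r3 > ")
        assert set(s.split(" > ")[1].split("/")) == {"r0", "r1", "r2"}

    def test_matches_bruteforce_pooled_t(self):
        res = self.fit(shift_region=1, shift=1.0, seed=3)
        ctx = res._context
        from scipy import stats as sst

        for pc in res.lsd["channel"]:
            se = np.sqrt(2 * ctx["ms_err_within"] / ctx["n_subjects"])
            t = (ctx["chan_means"][pc.a] - ctx["chan_means"][pc.b]) / se
            p = 2 * sst.t.sf(abs(t), ctx["df_err_within"])
            assert pc.t == pytest.approx(t, abs=1e-9)
            assert pc.p == pytest.approx(p, abs=1e-9)

    def test_missing_effect_rejected(self):
        res = self.fit()
        with pytest.raises(ValueError):
            lb.lsd_posthoc(res, "bogus")

    def test_ordering_string_canonical_region_order(self):
        from lfpbands.stats import PairwiseComparison

        pairs = [
            PairwiseComparison("STN", "M1", 5.0, 1.0, 4.0, 0.001),
            PairwiseComparison("PPN", "M1", 5.0, 1.0, 4.0, 0.001),
            PairwiseComparison("SNc", "M1", 5.0, 1.0, 4.0, 0.001),
            PairwiseComparison("CPu", "M1", 3.0, 1.0, 1.0, 0.4),
        ]
        assert ordering_string(pairs, gate_p=0.01) == "PPN/SNc/STN > M1"

    def test_gate_marginal_still_rendered(self):
        from lfpbands.stats import PairwiseComparison

        pairs = [PairwiseComparison("lesion", "sham", 2.0, 1.0, 2.5, 0.02)]
        assert ordering_string(pairs, gate_p=0.056) == "lesion > sham"
        assert ordering_string(pairs, gate_p=0.2) == "NA"


class TestCascade:
    def test_identical_samples_t_path_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = lb.select_and_run_test(x, x.copy())
        assert res.test_used == "t"
        assert res.p == pytest.approx(1.0)
        assert res.significance_class == "ns"

    def test_mann_whitney_exact_enumeration(self):
        U, z, p = lb.mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)=2/20
        assert z < 0

    def test_heavy_tails_select_mann_whitney(self):
        rng = np.random.default_rng(0)
        picks = 0
        for _ in range(200):
            x = rng.standard_cauchy(20)
            y = rng.standard_cauchy(20)
            picks += lb.select_and_run_test(x, y).test_used == "mann_whitney"
        assert picks >= 180

    def test_log_transform_rescues_lognormal(self):
        rng = np.random.default_rng(3)
        used = []
        for _ in range(50):
            x = np.exp(rng.normal(0, 1.5, 15))
            y = np.exp(rng.normal(0.3, 1.5, 15))
            r = lb.select_and_run_test(x, y)
            used.append((r.test_used, r.transform_used))
        # the log scale should frequently rescue the t path
        assert sum(t == "t" and tr == "log" for t, tr in used) > 15

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lb.select_and_run_test(np.array([1.0, 2]), np.array([3.0, 4, 5]))

    def test_t_on_equal_triples(self):
        t, p = lb.independent_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert (t, p) == (0.0, 1.0)

    def test_mann_whitney_complete_separation_U_zero(self):
        U, _, _ = lb.mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert U == 0.0

    def test_levene_calibrated_under_equal_spread(self):
        rng = np.random.default_rng(1)
        rej = sum(
            lb.levene(rng.normal(0, 1, 30), rng.normal(5, 1, 30))[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.09

    def test_shapiro_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            lb.shapiro_wilk(np.ones(10))


class TestClassifySignificance:
    @pytest.mark.parametrize(
        "p,cls", [(0.049, "significant"), (0.05, "marginal"), (0.099, "marginal"), (0.1, "ns")]
    )
    def test_cut_points(self, p, cls):
        assert lb.classify_significance(p) == cls

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_total_on_unit_interval(self, p):
        assert lb.classify_significance(p) in {"significant", "marginal", "ns"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lb.classify_significance(1.5)
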