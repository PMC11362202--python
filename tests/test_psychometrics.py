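import numpy as np
import pandas as pd
import pytest

from predinf.psychometrics import (
    add_cp_segments,
    categorize,
    icc,
    reliability_vs_ncps,
    required_n_correlation,
    spearman_brown,
    split_cp_segments,
    split_half,
    split_half_scores,
)


def icc_oracle(m):
    """Brute-force variance-components ICC on an n x 2 matrix.

    Computes the two-way ANOVA sums of squares by explicit loops,
    independently of the package implementation.
    """
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (m[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc31 = (msr - mse) / (msr + (k - 1) * mse)
    return icc21, icc31


def _segment_dataset(n_participants=30, n_segments=24, seg_len=5, rel_sd=1.0,
                     noise_sd=1.0, seed=0):
    """Toy trial table: a trait-driven measure plus segment-level noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_participants + 1):
        trait = rng.normal(0, rel_sd)
        trial = 1
        for seg in range(n_segments):
            seg_val = trait + rng.normal(0, noise_sd)
            for j in range(seg_len):
                rows.append(
                    {
                        "participant_id": pid,
                        "session": 1,
                        "trial": trial,
                        "is_cp": int(j == 0 and seg > 0),
                        "measure": seg_val + rng.normal(0, 0.1),
                    }
                )
                trial += 1
    return pd.DataFrame(rows)


def _mean_measure(df):
    return df.groupby("participant_id")["measure"].mean()


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(0.0, 0.0), (0.5, 0.667), (1.0, 1.0)])
    def test_formula(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected, abs=5e-4)

    def test_strictly_increasing(self):
        grid = np.linspace(-0.99, 0.99, 199)
        vals = [spearman_brown(r) for r in grid]
        assert np.all(np.diff(vals) > 0)


class TestCategorize:
    @pytest.mark.parametrize(
        "value,kind,expected",
        [
            (0.797, "consistency", "good"),
            (0.640, "icc", "moderate"),
            (0.5, "icc", "moderate"),
            (0.5, "consistency", "moderate"),
            (0.7, "consistency", "moderate"),
            (0.75, "icc", "moderate"),
            (0.751, "icc", "good"),
            (0.49, "icc", "low"),
            (-0.2, "consistency", "low"),
        ],
    )
    def test_thresholds(self, value, kind, expected):
        assert categorize(value, kind) == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            categorize(0.5, "bogus")


class TestSplitSegments:
    def test_partition_is_exact(self):
        df = _segment_dataset(n_participants=5, n_segments=25, seed=1)
        a, b = split_cp_segments(df)
        na, nb = len(a), len(b)
        assert na + nb == len(df)
        merged = pd.concat([a, b]).sort_values(["participant_id", "trial"])
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True),
            df.sort_values(["participant_id", "trial"]).reset_index(drop=True),
        )

    @pytest.mark.parametrize("n_segments,want", [(24, (12, 12)), (25, (13, 12))])
    def test_half_counts(self, n_segments, want):
        df = _segment_dataset(n_participants=2, n_segments=n_segments, seed=2)
        a, b = split_cp_segments(df)
        # every segment has exactly 5 trials, so trial counts identify
        # segment counts per half
        counts_a = a.groupby("participant_id")["trial"].count() // 5
        counts_b = b.groupby("participant_id")["trial"].count() // 5
        assert (counts_a == want[0]).all()
        assert (counts_b == want[1]).all()

    def test_too_few_segments_refused(self):
        df = _segment_dataset(n_participants=2, n_segments=3, seed=3)
        with pytest.raises(ValueError, match="segments"):
            split_cp_segments(df)


class TestSplitHalf:
    def test_identical_halves_give_unit_reliability(self):
        df = _segment_dataset(n_participants=20, noise_sd=0.0, seed=4)
        df["measure"] = df.groupby("participant_id")["measure"].transform("mean")
        res = split_half(_mean_measure, df)
        assert res.r == pytest.approx(1.0)
        assert res.r_sb == pytest.approx(1.0)
        assert res.category == "good"

    def test_known_half_reliability_recovers_sb_value(self):
        """Half-measures drawn with correlation 0.6 yield mean corrected
        reliability 2*0.6/1.6 = 0.75 over Monte-Carlo repetitions."""
        rng = np.random.default_rng(5)
        n, reps, rho = 300, 200, 0.6
        vals = []
        for _ in range(reps):
            a = rng.standard_normal(n)
            b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            res = split_half_scores(
                pd.Series(a, index=np.arange(n)), pd.Series(b, index=np.arange(n))
            )
            vals.append(res.r_sb)
        assert np.mean(vals) == pytest.approx(0.75, abs=0.03)

    def test_odd_even_mode_partitions_trials(self):
        df = _segment_dataset(n_participants=5, seed=6)
        res = split_half(_mean_measure, df, mode="odd_even_trials")
        assert res.mode == "odd_even_trials"
        assert -1 <= res.r <= 1


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(10, dtype=float)
        res = icc(x, x.copy())
        assert res.icc21 == pytest.approx(1.0)
        assert res.variance_components["error"] == pytest.approx(0.0, abs=1e-10)
        assert res.category == "good"

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(300)
        res = icc(x, rng.permutation(x))
        assert abs(res.icc21) < 0.15

    def test_variance_ratio_construction(self):
        """Participant SD 1 and error SD 1/sqrt(2) imply a population ICC of
        1 / (1 + 0.5) = 2/3; n=300 recovers it within 0.06."""
        rng = np.random.default_rng(8)
        n = 300
        trait = rng.standard_normal(n)
        e = 1 / np.sqrt(2)
        res = icc(trait + e * rng.standard_normal(n), trait + e * rng.standard_normal(n))
        assert res.icc21 == pytest.approx(2 / 3, abs=0.06)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            m = rng.normal(0, 1, size=(20, 2))
            res = icc(m[:, 0], m[:, 1])
            o21, o31 = icc_oracle(m)
            assert res.icc21 == pytest.approx(o21, abs=1e-10)
            assert res.icc31 == pytest.approx(o31, abs=1e-10)

    def test_matches_pingouin(self):
        """Cross-check estimates and CIs against the reference ICC
        implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        n = 40
        x = rng.standard_normal(n)
        y = 0.7 * x + 0.4 * rng.standard_normal(n) + 0.3  # systematic shift
        res = icc(x, y)
        long = pd.DataFrame(
            {
                "subject": np.r_[np.arange(n), np.arange(n)],
                "session": np.r_[np.zeros(n), np.ones(n)],
                "score": np.r_[x, y],
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="session", ratings="score"
        ).set_index("Type")
        # ICC(A,1) is the absolute-agreement single-measure score (2,1);
        # ICC(C,1) the consistency score (3,1); CIs are rounded to 2 dp
        assert res.icc21 == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert res.icc31 == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert res.ci95_21[0] == pytest.approx(ref.loc["ICC(A,1)", "CI95"][0], abs=6e-3)
        assert res.ci95_21[1] == pytest.approx(ref.loc["ICC(A,1)", "CI95"][1], abs=6e-3)

    def test_session_shift_penalises_absolute_agreement(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100)
        y = x + 1.5  # pure systematic shift
        res = icc(x, y)
        assert res.icc31 > res.icc21
        assert res.icc31 == pytest.approx(1.0)

    def test_components_sum_to_hundred(self):
        rng = np.random.default_rng(12)
        res = icc(rng.standard_normal(50), rng.standard_normal(50))
        assert sum(res.variance_components.values()) == pytest.approx(100.0, abs=0.1)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            icc([1.0, 2.0], [1.0, 2.0])


class TestReliabilityVsNcps:
    def test_full_length_reproduces_unrestricted_estimate(self):
        df = _segment_dataset(n_participants=25, n_segments=24, seed=13)
        full = split_half(_mean_measure, df)
        curve = reliability_vs_ncps(
            df, lambda sub: split_half(_mean_measure, sub), cp_range=[23]
        )
        assert curve.loc[0, "estimate"] == pytest.approx(full.r_sb, abs=1e-12)

    def test_noiseless_measure_constant_at_one(self):
        df = _segment_dataset(n_participants=15, noise_sd=0.0, seed=14)
        df["measure"] = df.groupby("participant_id")["measure"].transform("mean")
        curve = reliability_vs_ncps(
            df, lambda sub: split_half(_mean_measure, sub), cp_range=[6, 12, 23]
        )
        assert np.allclose(curve["estimate"], 1.0)

    def test_reliability_grows_with_segments(self):
        """Averaged over repetitions, the corrected split-half reliability
        is increasing in the number of CP segments (Spearman trend > 0)."""
        from scipy import stats

        curves = []
        for rep in range(40):
            df = _segment_dataset(
                n_participants=30, noise_sd=1.5, seed=100 + rep
            )
            curve = reliability_vs_ncps(
                df, lambda sub: split_half(_mean_measure, sub),
                cp_range=range(6, 24, 4),
            )
            curves.append(curve["estimate"].to_numpy())
        mean_curve = np.mean(curves, axis=0)
        rho = stats.spearmanr(np.arange(mean_curve.size), mean_curve)[0]
        assert rho > 0

    def test_below_six_rejected(self):
        df = _segment_dataset(n_participants=5, seed=15)
        with pytest.raises(ValueError, match="six|unstable"):
            reliability_vs_ncps(df, _mean_measure, cp_range=[4])


class TestRequiredN:
    def test_power_software_value(self):
        """The noncentral-t routine reproduces the N = 190 used to plan
        correlation studies at rho = 0.272, alpha = 0.01, power 0.90."""
        assert required_n_correlation(0.272, 0.01, 0.90, "two", "nct") == 190

    def test_exact_bivariate_normal_value(self):
        """The exact r-density computation needs N = 194 for the same
        target (frozen from an independent Monte-Carlo check: the achieved
        power at N = 190 is 0.894)."""
        assert required_n_correlation(0.272, 0.01, 0.90, "two", "exact") == 194

    def test_huge_effect_needs_few_participants(self):
        assert required_n_correlation(0.99, 0.05, 0.80) <= 10

    @pytest.mark.parametrize("rho", [0.2, 0.3, 0.5])
    def test_fisher_close_to_exact(self, rho):
        exact = required_n_correlation(rho, 0.05, 0.80, method="exact")
        fisher = required_n_correlation(rho, 0.05, 0.80, method="fisher_z")
        assert abs(fisher - exact) <= 6

    def test_achieved_power_at_returned_n(self):
        """Monte-Carlo at the returned N: achieved power >= target - 0.01."""
        rho, alpha, target = 0.3, 0.05, 0.80
        n = required_n_correlation(rho, alpha, target, method="exact")
        rng = np.random.default_rng(16)
        reps = 50_000
        z1 = rng.standard_normal((reps, n))
        z2 = rng.standard_normal((reps, n))
        y = rho * z1 + np.sqrt(1 - rho**2) * z2
        z1c = z1 - z1.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (z1c * yc).sum(1) / np.sqrt((z1c**2).sum(1) * (yc**2).sum(1))
        from scipy import stats

        t_crit = stats.t.ppf(1 - alpha / 2, n - 2)
        r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
        assert (np.abs(r) > r_crit).mean() >= target - 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            required_n_correlation(1.0)
        with pytest.raises(ValueError, match="alpha|power"):
            required_n_correlation(0.3, alpha=0.0)
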