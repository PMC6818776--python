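"""Sample-level inference: tests, correlations, reliability, outliers."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from sklearn.metrics import cohen_kappa_score

import dyadseq as dq
from dyadseq.inference import _partial_from_pairwise, sequence_label

from conftest import make_series


def rank_average(x):
    """Hand-rolled average ranks (the oracle stays library-free)."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


class TestUpperTailedT:
    def test_hand_computed_statistic(self):
        t, p = dq.upper_tailed_t([0.1, 0.2, 0.3])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0371, abs=1e-3)

    def test_symmetric_tail(self):
        t, p = dq.upper_tailed_t([-1.0, 1.0])
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            dq.upper_tailed_t([0.2, 0.2, 0.2])

    def test_p_decreasing_in_mean(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 20)
        ps = [dq.upper_tailed_t(base + shift)[1] for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestPropPositive:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.1, -0.2, 0.3, None], 2 / 3), ([0.5, 0.1], 1.0), ([None, None], None)],
    )
    def test_share_of_defined(self, values, expected):
        got = dq.prop_positive(values)
        assert got == (pytest.approx(expected) if expected is not None else None)


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            # average-rank convention with a tie in x; frozen from the
            # Pearson-on-ranks oracle below
            ([1, 2, 2, 4], [1, 3, 2, 4], 0.9486832980505138),
        ],
    )
    def test_examples(self, x, y, expected):
        res = dq.spearman(x, y)
        assert res.rho == pytest.approx(expected)
        assert res.rho == pytest.approx(pearson_oracle(rank_average(x), rank_average(y)))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = dq.spearman(x, y).rho
        assert dq.spearman(np.exp(x), y).rho == pytest.approx(base)
        assert dq.spearman(x, y**3).rho == pytest.approx(base)

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            dq.spearman([1, 2], [1, 2])
        with pytest.raises(ValueError, match="rank variance"):
            dq.spearman([1, 1, 1], [1, 2, 3])

    def test_missing_pairs_dropped(self):
        res = dq.spearman([1, 2, 3, None], [1, 2, 3, 4])
        assert res.n == 3 and res.rho == pytest.approx(1.0)


class TestPartialSpearman:
    def test_first_order_formula_fixed_points(self):
        assert _partial_from_pairwise(0.5, 0.5, 0.5) == pytest.approx(1 / 3)
        # control uncorrelated with both: partial reduces to the raw r
        assert _partial_from_pairwise(0.42, 0.0, 0.0) == pytest.approx(0.42)
        with pytest.raises(ValueError, match="degenerate"):
            _partial_from_pairwise(0.5, 1.0, 0.3)

    def test_control_identical_to_y_degenerate(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(ValueError, match="degenerate"):
            dq.partial_spearman([1, 3, 2, 5, 4], y, y)

    def test_matches_pingouin_on_random_data(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(8, 30))
            df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "z"])
            ours = dq.partial_spearman(df.x, df.y, df.z)
            ref = pg.partial_corr(df, x="x", y="y", covar="z", method="spearman")
            assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert ours.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_near_constant_control_approximates_spearman(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        z = rng.normal(size=40)  # independent control
        plain = dq.spearman(x, y).rho
        part = dq.partial_spearman(x, y, z).rho
        assert abs(part - plain) < 0.2  # independent control barely moves rho


class TestZScore:
    def test_low_trust_child_magnitude(self):
        # direct formula on the published sample moments (mean 3.51, sd 0.32)
        rng = np.random.default_rng(1)
        ref = rng.normal(size=54)
        ref = (ref - ref.mean()) / ref.std(ddof=1) * 0.32 + 3.51
        assert dq.zscore_vs_sample(1.5, ref) == pytest.approx(-6.28, abs=0.01)

    def test_value_at_mean_is_zero(self):
        assert dq.zscore_vs_sample(2.0, [1.0, 2.0, 3.0]) == 0.0

    def test_constant_reference_error(self):
        with pytest.raises(ValueError, match="zero reference"):
            dq.zscore_vs_sample(1.0, [2.0, 2.0, 2.0])


class TestFlagOutliers:
    @staticmethod
    def _scores(trusts):
        return [dq.AttachmentScores(f"d{i}", t, 2.0, 2.0) for i, t in enumerate(trusts)]

    def test_single_gross_outlier_in_homogeneous_sample(self):
        scores = self._scores([3.5] * 54 + [1.5])
        retained, excluded = dq.flag_outliers(scores, "trust", threshold=3.0)
        assert [s.trust for s in excluded] == [1.5]
        assert len(retained) == 54

    def test_homogeneous_sample_keeps_everything(self):
        retained, excluded = dq.flag_outliers(self._scores([3.4, 3.5, 3.6, 3.5]), "trust")
        assert excluded == []

    def test_threshold_zero_excludes_all(self):
        _, excluded = dq.flag_outliers(self._scores([3.4, 3.5, 3.6]), "trust", threshold=0.0)
        assert len(excluded) == 3

    def test_reflagging_after_exclusion_finds_nothing(self):
        scores = self._scores([3.5] * 20 + [3.4] * 20 + [3.6] * 14 + [1.5])
        retained, excluded = dq.flag_outliers(scores, "trust", threshold=3.0)
        assert len(excluded) == 1
        _, again = dq.flag_outliers(retained, "trust", threshold=3.0)
        assert again == []

    def test_missing_score_retained(self):
        scores = self._scores([3.4, 3.5, 3.6]) + [dq.AttachmentScores("dx", None, 2.0, 2.0)]
        retained, excluded = dq.flag_outliers(scores, "trust")
        assert any(s.dyad_id == "dx" for s in retained)


class TestPooledKappa:
    @staticmethod
    def _series(flat, dyad="d1", k=2):
        arr = np.array(flat).reshape(-1, k)
        return [make_series({f"B{j}": arr[:, j].tolist() for j in range(k)}, dyad)]

    def test_identical_matrices_kappa_one(self):
        a = self._series([1, 0, 1, 1, 0, 0, 1, 0])
        res = dq.pooled_kappa(a, a)
        assert res.kappa == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        # 10 pooled decisions, 9 agreements, marginals .5 and .6:
        # p_o = .9, p_e = .5*.6 + .5*.4 = .5, kappa = .8
        a = self._series([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        b = self._series([1, 1, 1, 1, 1, 1, 0, 0, 0, 0])
        res = dq.pooled_kappa(a, b)
        assert res.p_observed == pytest.approx(0.9)
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.8)
        assert res.ci_low < 0.8 < res.ci_high

    def test_systematic_disagreement(self):
        a = self._series([1, 0] * 5)
        b = self._series([0, 1] * 5)
        res = dq.pooled_kappa(a, b)
        assert res.kappa == pytest.approx(-1.0)

    def test_matches_sklearn_on_random_codes(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            T = int(rng.integers(4, 30))
            a = rng.integers(0, 2, (T, 3))
            b = np.where(rng.random((T, 3)) < 0.8, a, 1 - a)
            sa = [dq.BehaviorSeries("d1", pd.DataFrame(a, columns=list("XYZ")))]
            sb = [dq.BehaviorSeries("d1", pd.DataFrame(b, columns=list("XYZ")))]
            if len(np.unique(np.concatenate([a.ravel(), b.ravel()]))) < 2:
                continue
            ours = dq.pooled_kappa(sa, sb).kappa
            ref = cohen_kappa_score(a.ravel(), b.ravel())
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_bootstrap_ci_brackets_kappa(self):
        rng = np.random.default_rng(10)
        a = rng.integers(0, 2, (60, 2))
        b = np.where(rng.random((60, 2)) < 0.9, a, 1 - a)
        sa = [dq.BehaviorSeries("d1", pd.DataFrame(a, columns=["P", "Q"]))]
        sb = [dq.BehaviorSeries("d1", pd.DataFrame(b, columns=["P", "Q"]))]
        res = dq.pooled_kappa(sa, sb, ci_method="bootstrap", n_boot=300, seed=0)
        assert res.ci_low <= res.kappa <= res.ci_high

    def test_shape_mismatch_rejected(self):
        a = self._series([1, 0, 1, 1])
        b = self._series([1, 0, 1, 1, 0, 0])
        with pytest.raises(ValueError, match="mismatch"):
            dq.pooled_kappa(a, b)


class TestCoderMeasureAgreement:
    def _profiles(self, rng, scale=1.0, jitter=0.0):
        out = []
        for d in range(4):
            mat = rng.integers(0, 2, (20, 3))
            if jitter:
                mat = np.where(rng.random(mat.shape) < jitter, 1 - mat, mat)
            s = dq.BehaviorSeries(f"d{d}", pd.DataFrame(mat, columns=list("XYZ")))
            out.append(dq.dyad_profile(s))
        return out

    def test_identical_profiles_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        profiles = self._profiles(rng)
        res = dq.coder_measure_agreement(profiles, profiles, "frequency")
        assert res.rho == pytest.approx(1.0)

    def test_linear_rescaling_keeps_pearson_one(self):
        rng = np.random.default_rng(4)
        profiles = self._profiles(rng)
        doubled = [
            dq.DyadProfile(p.dyad_id, {c: 2 * v for c, v in p.frequencies.items()},
                           p.sequences)
            for p in profiles
        ]
        res = dq.coder_measure_agreement(profiles, doubled, "frequency", method="pearson")
        assert res.rho == pytest.approx(1.0)

    def test_matches_direct_pearson_oracle(self):
        rng = np.random.default_rng(12)
        pa = self._profiles(rng)
        rng2 = np.random.default_rng(12)
        pb = self._profiles(rng2, jitter=0.15)
        res = dq.coder_measure_agreement(pa, pb, "frequency")
        xs = [p.frequencies[c] for p in pa for c in p.frequencies]
        ys = [p.frequencies[c] for p in pb for c in p.frequencies]
        assert res.rho == pytest.approx(pearson_oracle(xs, ys))


class TestSampleSummaries:
    def test_sequence_summary_identities(self, mcam_profiles):
        summaries = dq.summarize_sequences(mcam_profiles)
        assert len(summaries) == 49
        by_measure = {s.measure: s for s in summaries}
        for pair in mcam_profiles[0].sequences:
            s = by_measure[sequence_label(*pair)]
            stats = [p.sequences[pair] for p in mcam_profiles]
            defined = [x.jac_norm for x in stats if x.jac_norm is not None]
            assert s.n_defined == len(defined)
            assert s.n_dyads_showing == sum(x.occurs for x in stats)
            if defined:
                assert s.mean == pytest.approx(np.mean(defined))
                assert s.prop_positive == pytest.approx(np.mean(np.array(defined) > 0))
                assert s.min == pytest.approx(min(defined))
                assert s.max == pytest.approx(max(defined))

    def test_frequency_summary(self, mcam_profiles):
        summaries = dq.summarize_frequencies(mcam_profiles)
        assert [s.measure for s in summaries] == list(mcam_profiles[0].categories)
        for s in summaries:
            assert s.min <= s.mean <= s.max
            assert 0 <= s.n_dyads_showing <= len(mcam_profiles)

    def test_persistent_positive_sequences_detected(self, mcam_profiles):
        """Auto-loops of frequent coupled categories test strongly positive."""
        by_measure = {s.measure: s for s in dq.summarize_sequences(mcam_profiles)}
        loop = by_measure[sequence_label("CAlone", "CAlone")]
        assert loop.mean > 0.1 and loop.p_value < 0.001


class TestCorrelateWithScores:
    def test_table_layout_and_partials(self, mcam_profiles, mcam_sample):
        results = dq.correlate_with_scores(mcam_profiles, mcam_sample.scores)
        frame = dq.inference.correlations_to_frame(results)
        # trust is never partialled; avoidance and anxiety control for each other
        assert set(frame["covariate"]) == {"trust", "avoidance", "anxiety"}
        partials = frame[frame["controlled_for"] != ""]
        assert set(zip(partials["covariate"], partials["controlled_for"])) == {
            ("avoidance", "anxiety"), ("anxiety", "avoidance")}
        assert (frame["rho"].abs() <= 1.0).all()

    def test_generator_link_recovered_with_correct_sign(self, mcam_profiles, mcam_sample):
        """The built-in avoidance link on the M+ auto-loop shows up positive."""
        results = dq.correlate_with_scores(mcam_profiles, mcam_sample.scores)
        rho = [r.rho for r in results
               if r.measure == sequence_label("M+", "M+")
               and r.covariate == "avoidance" and r.controlled_for is None]
        assert rho and rho[0] > 0

    def test_too_few_dyads(self, mcam_profiles, mcam_sample):
        with pytest.raises(ValueError, match="at least 3"):
            dq.correlate_with_scores(mcam_profiles[:2], mcam_sample.scores[:2])


class TestCompareDyadProfile:
    def test_zero_z_for_average_dyad(self, mcam_profiles):
        table = dq.compare_dyad_profile(mcam_profiles[0], mcam_profiles[1:])
        freq_rows = table[table["kind"] == "frequency"].set_index("measure")
        for cat in mcam_profiles[0].categories:
            row = freq_rows.loc[cat]
            expected = dq.zscore_vs_sample(
                mcam_profiles[0].frequencies[cat],
                [p.frequencies[cat] for p in mcam_profiles[1:]])
            assert row["z"] == pytest.approx(expected)

    def test_undefined_measures_noted(self, mcam_profiles):
        table = dq.compare_dyad_profile(mcam_profiles[0], mcam_profiles[1:])
        undefined = table[table["note"] == "undefined for target dyad"]
        assert np.isnan(undefined["z"]).all()
        assert len(table) == 7 + 49
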