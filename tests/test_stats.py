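"""Statistics layer: Wilcoxon, paired t, ICC(C,k), normality, summary table.

The Wilcoxon oracle enumerates all 2^n sign assignments directly
(independent of the package's distribution recursion); ICC is cross-checked
against pingouin's two-way mixed consistency estimate for averaged raters.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stentbench.errors import (
    DegenerateSampleError,
    InvalidParameterError,
    PairingError,
)
from stentbench.stats import (
    icc_consistency_avg,
    interpret_icc,
    normality_check,
    paired_t,
    reliability_iccs,
    summarize,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(d: np.ndarray) -> float:
    """Two-tailed exact p by enumerating every sign assignment."""
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-12:
            count += 1
    return min(1.0, 2.0 * count / 2**n)


class TestWilcoxon:
    def test_identical_pairs_give_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.method == "degenerate"

    def test_all_positive_differences_exact_tail(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p_value == pytest.approx(2 / 32)
        assert res.method == "exact"

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_exact_p_equals_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for n in (5, 9, 13):
            d = rng.normal(size=n)
            ours = wilcoxon_signed_rank(d).p_value
            assert ours == pytest.approx(sps.wilcoxon(d, method="exact").pvalue)

    def test_ties_route_to_normal_approximation(self):
        d = np.array([1.0, 1.0, 2.0, 3.0, -1.0, 2.0])
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal"
        assert 0.0 <= res.p_value <= 1.0

    def test_large_sample_normal_path_near_scipy(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1.0, size=40)
        ours = wilcoxon_signed_rank(d).p_value
        ref = sps.wilcoxon(d, correction=True, method="approx").pvalue
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, 3.0])
        assert res.n == 3


class TestPairedT:
    def test_hand_arithmetic_oracle(self):
        res = paired_t([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-4)
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2

    def test_agrees_with_scipy_ttest_rel(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_zero_variance_differences_error(self):
        with pytest.raises(DegenerateSampleError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_too_few_pairs_error(self):
        with pytest.raises(InvalidParameterError):
            paired_t([1.0])


class TestICC:
    def test_perfect_agreement_is_one(self):
        m = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_consistency_avg(m).value == pytest.approx(1.0)

    def test_constant_shift_is_still_one(self):
        a = np.arange(10.0)
        m = np.column_stack([a, a + 2.0])
        assert icc_consistency_avg(m).value == pytest.approx(1.0)

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(3, 1, size=(15, 2))
        base = icc_consistency_avg(m).value
        scaled = icc_consistency_avg(2.5 * m + 7.0).value
        shifted = icc_consistency_avg(m + np.array([[0.0, 1.3]])).value
        assert scaled == pytest.approx(base)
        assert shifted == pytest.approx(base)  # per-rater bias lands in the rater term

    def test_independent_random_scores_near_zero(self):
        # Monte-Carlo: E[ICC] over replicate 200-item draws of independent scores
        rng = np.random.default_rng(4)
        vals = [
            icc_consistency_avg(rng.integers(1, 6, size=(200, 2)).astype(float)).value
            for _ in range(25)
        ]
        assert abs(float(np.mean(vals))) <= 0.1

    def test_matches_pingouin_icc_c_k(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        m = rng.normal(3, 1, size=(20, 2)) + rng.normal(0, 0.5, size=(20, 1))
        df = pd.DataFrame(
            {
                "item": np.repeat(np.arange(20), 2),
                "rater": np.tile([0, 1], 20),
                "score": m.ravel(),
            }
        )
        tab = pg.intraclass_corr(df, targets="item", raters="rater", ratings="score")
        ref = float(tab.loc[tab["Type"] == "ICC(C,k)", "ICC"].iloc[0])
        assert icc_consistency_avg(m).value == pytest.approx(ref, abs=1e-9)

    def test_no_between_item_variance_flagged_nan(self):
        m = np.full((6, 2), 3.0)
        res = icc_consistency_avg(m)
        assert res.undefined and np.isnan(res.value)

    def test_interpretation_bands(self):
        assert interpret_icc(0.3) == "poor"
        assert interpret_icc(0.6) == "moderate"
        assert interpret_icc(0.8) == "good"
        assert interpret_icc(0.95) == "excellent"


class TestNormality:
    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            normality_check(rng.exponential(size=50))[1] < 0.05 for _ in range(40)
        )
        assert rejections > 36  # > 90% of draws

    def test_constant_vector_errors(self):
        with pytest.raises(DegenerateSampleError):
            normality_check([1.0] * 10)

    def test_sample_size_bounds(self):
        with pytest.raises(InvalidParameterError):
            normality_check([1.0, 2.0])


class TestSummarize:
    @staticmethod
    def _measurements(delta=0.0):
        rows = []
        rng = np.random.default_rng(7)
        for metric in ("abs_error_mm", "blooming_pct"):
            for fov in (150, 50):
                for stent in ("a", "b", "c"):
                    for loc in range(3):
                        base = rng.normal(10, 1)
                        rows.append(
                            dict(metric=metric, fov=fov, system="si_pcct",
                                 stent=stent, location=loc, value=base)
                        )
                        rows.append(
                            dict(metric=metric, fov=fov, system="eidct",
                                 stent=stent, location=loc, value=base + delta)
                        )
        return pd.DataFrame(rows)

    def test_identical_systems_give_p_one(self):
        rep = summarize(self._measurements(0.0))
        assert (rep.quantitative["p_value"] == 1.0).all()
        assert not rep.quantitative["significant"].any()

    def test_schema_metric_fov_system(self):
        rep = summarize(self._measurements(1.0))
        counts = rep.quantitative.groupby(["metric", "fov"]).size()
        assert (counts == 2).all()
        assert len(rep.quantitative) == 2 * 2 * 2
        assert rep.quantitative["significant"].equals(rep.quantitative["p_value"] < 0.05)

    def test_unpaired_inputs_rejected(self):
        df = self._measurements(1.0)
        df = df.drop(df[(df.system == "eidct") & (df.stent == "a")].index[:1])
        with pytest.raises(PairingError):
            summarize(df)

    def test_ordinal_median_and_iqr_convention(self):
        scores = [4, 4, 4, 4, 5, 4, 4, 2]
        rows = []
        for system, vals in (("si_pcct", scores), ("eidct", scores)):
            for i, v in enumerate(vals):
                rows.append(
                    dict(metric="blooming", fov=150, system=system,
                         item=f"i{i % 4}", reader=1 + i // 4, session=1, score=v)
                )
        sdf = pd.DataFrame(rows)
        rep = summarize(self._measurements(1.0).query("fov == 150"), sdf)
        row = rep.qualitative.iloc[0]
        assert row["median"] == 4.0
        assert row["q1"] == 4.0 and row["q3"] == 4.0


def test_reliability_icc_pooling_modes():
    rng = np.random.default_rng(8)
    rows = []
    for metric in ("stent_appearance", "blooming"):
        for fov in (150, 50):
            for system in ("si_pcct", "eidct"):
                for item in ("a", "b"):
                    latent = rng.normal(3, 1)
                    for reader in (1, 2):
                        for session in (1, 2):
                            rows.append(
                                dict(metric=metric, fov=fov, system=system, item=item,
                                     reader=reader, session=session,
                                     score=int(np.clip(round(latent + rng.normal(0, .5)), 1, 5)))
                            )
    df = pd.DataFrame(rows)
    pooled = reliability_iccs(df, pooling="pooled")
    per_metric = reliability_iccs(df, pooling="per_metric")
    for d in (pooled, per_metric):
        assert -1.0 <= d["inter_reader"] <= 1.0
        assert -1.0 <= d["intra_reader"] <= 1.0
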