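"""Parallel-design GMR confidence interval and effect classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from permscreen.equivalence import (
    DegenerateVarianceError,
    EffectCall,
    EquivalenceConfig,
    RatioEstimate,
    call_counts,
    classify_all,
    classify_effect,
    hauschke_ci,
)
from permscreen.ratios import (
    GroupLogStats,
    GroupSummary,
    log_stats_from_replicates,
    log_stats_from_summary,
)
from permscreen.transport import InvalidInputError


def _stats(mean_log, sd_log, n=3, treatment="t", drug="d"):
    return GroupLogStats(drug, treatment, n, mean_log, sd_log)


class TestHauschkeCi:
    def test_identical_groups_symmetric_about_one(self):
        g = _stats(math.log(1e-6), 0.3)
        r = hauschke_ci(g, _stats(math.log(1e-6), 0.3, treatment="control"))
        assert r.gmr == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0, rel=1e-12)
        assert r.df == 4

    @pytest.mark.parametrize(
        "treated, expected",
        [
            # acyclovir control (0.19, SEM 0.05) vs Tween 80 and vs SLS,
            # log-scale stats reconstructed by lognormal moment matching
            ((0.11e-6, 0.01e-6), (0.6285, 0.3560, 1.1096)),
            ((0.52e-6, 0.01e-6), (3.0061, 1.7582, 5.1395)),
        ],
    )
    def test_reconstructed_reference_comparisons(self, treated, expected):
        control = log_stats_from_summary(
            GroupSummary("acv", "control", 3, 0.19e-6, 0.05e-6)
        )
        treated_stats = log_stats_from_summary(
            GroupSummary("acv", "excipient", 3, *treated)
        )
        r = hauschke_ci(treated_stats, control)
        gmr, lo, hi = expected
        assert r.gmr == pytest.approx(gmr, abs=2e-4)
        assert r.ci_low == pytest.approx(lo, abs=2e-4)
        assert r.ci_high == pytest.approx(hi, abs=2e-4)
        assert r.source == "reconstructed"

    def test_replicates_equal_their_log_stats(self):
        """The CI from raw replicates equals the CI from their sufficient
        statistics — they are the same inputs to the formula."""
        rng = np.random.default_rng(11)
        a = np.exp(rng.normal(-14, 0.4, size=5))
        b = np.exp(rng.normal(-14.5, 0.2, size=3))
        r = hauschke_ci(log_stats_from_replicates(a), log_stats_from_replicates(b))
        # independent recomputation straight from the definition
        la, lb = np.log(a), np.log(b)
        df = a.size + b.size - 2
        pooled = ((a.size - 1) * la.var(ddof=1) + (b.size - 1) * lb.var(ddof=1)) / df
        from scipy import stats as sps

        half = sps.t.ppf(0.95, df) * math.sqrt(pooled * (1 / a.size + 1 / b.size))
        diff = la.mean() - lb.mean()
        assert r.df == df
        assert r.gmr == pytest.approx(math.exp(diff), rel=1e-12)
        assert r.ci_low == pytest.approx(math.exp(diff - half), rel=1e-12)
        assert r.ci_high == pytest.approx(math.exp(diff + half), rel=1e-12)

    @given(
        m1=st.floats(-16, -10),
        m2=st.floats(-16, -10),
        s1=st.floats(0.05, 1.0),
        s2=st.floats(0.05, 1.0),
        n1=st.integers(2, 8),
        n2=st.integers(2, 8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_swap_symmetry(self, m1, m2, s1, s2, n1, n2):
        """Swapping treated and control inverts the ratio and reverses the CI."""
        a = _stats(m1, s1, n1)
        b = _stats(m2, s2, n2, treatment="control")
        fwd = hauschke_ci(a, b)
        rev = hauschke_ci(b, a)
        assert rev.gmr == pytest.approx(1 / fwd.gmr, rel=1e-9)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high, rel=1e-9)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low, rel=1e-9)

    def test_crossover_design_narrows_interval(self):
        a, b = _stats(-14.0, 0.3), _stats(-14.2, 0.3, treatment="control")
        parallel = hauschke_ci(a, b)
        crossover = hauschke_ci(a, b, EquivalenceConfig(design_constant=0.5))
        assert crossover.ci_low > parallel.ci_low
        assert crossover.ci_high < parallel.ci_high

    def test_degenerate_variance(self):
        a, b = _stats(-14.0, 0.0), _stats(-14.0, 0.0, treatment="control")
        with pytest.raises(DegenerateVarianceError):
            hauschke_ci(a, b)
        r = hauschke_ci(a, b, EquivalenceConfig(allow_degenerate=True))
        assert r.ci_low == r.gmr == r.ci_high == pytest.approx(1.0)


class TestClassifyEffect:
    @staticmethod
    def _estimate(lo, hi):
        return RatioEstimate(
            "d", "t", "PR", math.sqrt(lo * hi), lo, hi, 4, "replicates"
        )

    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (1.758, 5.140, "E"),
            (0.356, 1.110, "R"),
            (0.9, 1.2, "NE"),
            (0.7, 1.3, "NC"),
            # bounds exactly on a limit count as within
            (0.8, 1.25, "NE"),
            (0.8, 1.3, "E"),
            (0.7, 1.25, "R"),
        ],
    )
    def test_four_way_rules(self, lo, hi, expected):
        assert classify_effect(self._estimate(lo, hi)).call == expected

    @given(
        lo=st.floats(0.05, 5.0),
        width=st.floats(1.0, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_exactly_one_call_and_limit_monotonicity(self, lo, width):
        est = self._estimate(lo, lo * width)
        call = classify_effect(est).call
        assert call in {"NE", "R", "E", "NC"}
        widened = classify_effect(
            est, EquivalenceConfig(lower_limit=0.4, upper_limit=2.5)
        ).call
        if call == "NE":
            assert widened == "NE"

    def test_shrinking_alpha_never_rescues_nc(self):
        """A wider interval (smaller alpha) can only move calls toward NC."""
        a = _stats(-14.0, 0.5)
        b = _stats(-14.1, 0.5, treatment="control")
        call_90 = classify_effect(hauschke_ci(a, b, EquivalenceConfig(alpha=0.10)))
        call_99 = classify_effect(
            hauschke_ci(a, b, EquivalenceConfig(alpha=0.01)),
        )
        if call_90.call == "NC":
            assert call_99.call == "NC"


class TestClassifyAll:
    def test_acyclovir_column(self, summaries_by_drug):
        calls = classify_all(summaries_by_drug["acyclovir"])
        counts = call_counts(calls)
        assert (counts["E"], counts["R"], counts["NC"]) == (1, 8, 0)
        by_treatment = {c.basis.treatment_id: c.call for c in calls}
        assert by_treatment["SLS"] == "E"
        assert by_treatment["tween80"] == "R"

    def test_sulpiride_column(self, summaries_by_drug):
        counts = call_counts(classify_all(summaries_by_drug["sulpiride"]))
        assert (counts["E"], counts["R"], counts["NC"]) == (2, 4, 3)

    def test_wide_limits_dominate(self, summaries_by_drug):
        cfg = EquivalenceConfig(lower_limit=0.01, upper_limit=100.0)
        calls = classify_all(summaries_by_drug["acyclovir"], cfg)
        assert {c.call for c in calls} == {"NE"}

    def test_control_never_compared_to_itself(self, summaries_by_drug):
        calls = classify_all(summaries_by_drug["nadolol"])
        assert len(calls) == 9
        assert "control" not in {c.basis.treatment_id for c in calls}

    def test_missing_control_names_the_drug(self, summaries_by_drug):
        groups = [
            s for s in summaries_by_drug["acyclovir"] if s.treatment_id != "control"
        ]
        with pytest.raises(InvalidInputError, match="acyclovir"):
            classify_all(groups)
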