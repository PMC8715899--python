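"""Repeatability statistics against hand values and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcequant.repeatability import (
    PairedCohort,
    bland_altman,
    build_report,
    cov_mean_diff,
    percent_rc,
    relative_change,
    wcv,
)
from dcequant.synthetic import simulate_summary_cohort


# ---------------------------------------------------------------------------
# independent brute-force implementations (explicit loops, no shared code)

def _wcv_loop(b1, b2):
    total = 0.0
    for x1, x2 in zip(b1, b2):
        xbar = (x1 + x2) / 2.0
        total += ((x1 - x2) ** 2 / 2.0) / xbar**2
    return math.sqrt(total / len(b1))


def _cov_loop(b1, b2):
    total = 0.0
    for x1, x2 in zip(b1, b2):
        s = abs(x1 - x2) / math.sqrt(2.0)
        total += s / ((x1 + x2) / 2.0)
    return 100.0 * total / len(b1)


def _ba_loop(d):
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    sd = math.sqrt(var)
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


class TestRelativeChange:
    def test_identity_pair_is_zero(self):
        assert relative_change(1.0, 1.0) == 0.0

    def test_doubling(self):
        assert relative_change(1.0, 2.0) == pytest.approx(math.log(2), rel=1e-12)
        assert relative_change(1.0, 2.0) == pytest.approx(0.6931, abs=1e-4)

    def test_antisymmetry(self):
        assert relative_change(2.0, 1.0) == -relative_change(1.0, 2.0)

    def test_nonpositive_input_names_the_subject(self):
        with pytest.raises(ValueError, match="subject 7"):
            relative_change(0.0, 1.0, subject=7)


class TestBlandAltman:
    def test_hand_values(self):
        d = [0.6931, -0.6931]
        bias, (lb, ub) = bland_altman(d)
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert ub == pytest.approx(1.9213, abs=2e-4)  # 1.96 * SD(0.9803)
        assert lb == pytest.approx(-ub)

    def test_constant_differences_collapse_the_limits(self):
        bias, (lb, ub) = bland_altman([0.3, 0.3, 0.3])
        assert bias == lb == ub == pytest.approx(0.3)

    def test_permutation_invariance(self, rng):
        d = rng.normal(0, 1, 30)
        fwd_bias, fwd_loa = bland_altman(d)
        perm = d.copy()
        rng.shuffle(perm)
        rev_bias, rev_loa = bland_altman(perm)
        assert fwd_bias == pytest.approx(rev_bias, abs=1e-12)
        assert fwd_loa == pytest.approx(rev_loa, abs=1e-12)

    def test_single_observation_errors(self):
        with pytest.raises(ValueError):
            bland_altman([0.1])


class TestWCVAndFriends:
    def test_identical_pairs_give_zero(self):
        c = PairedCohort(b1=[1.0, 5.0], b2=[1.0, 5.0])
        assert wcv(c) == 0.0
        assert cov_mean_diff(c) == 0.0
        assert percent_rc(wcv(c)) == 0.0

    def test_single_pair_hand_values(self):
        c = PairedCohort(b1=[1.0], b2=[2.0])
        assert wcv(c) == pytest.approx(math.sqrt(0.5 / 2.25), rel=1e-12)
        assert wcv(c) == pytest.approx(0.4714, abs=1e-4)
        assert percent_rc(wcv(c)) == pytest.approx(130.7, abs=0.05)
        assert cov_mean_diff(c) == pytest.approx(47.1, abs=0.05)

    def test_two_pair_hand_values(self):
        c = PairedCohort(b1=[10.0, 1.0], b2=[10.0, 2.0])
        assert wcv(c) == pytest.approx(math.sqrt(0.111111), abs=1e-4)
        assert wcv(c) == pytest.approx(0.3333, abs=1e-4)
        assert percent_rc(wcv(c)) == pytest.approx(92.4, abs=0.05)
        assert cov_mean_diff(c) == pytest.approx(23.6, abs=0.05)

    def test_percent_rc_is_exact_multiple_of_wcv(self):
        assert percent_rc(0.4714) == pytest.approx(1.96 * math.sqrt(2) * 0.4714 * 100, rel=1e-15)

    def test_negative_wcv_rejected(self):
        with pytest.raises(ValueError):
            percent_rc(-0.1)


class TestOracleEquivalence:
    def test_brute_force_agreement_on_random_cohorts(self):
        """Vectorized statistics match explicit-loop oracles to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            b1 = np.exp(rng.normal(0, 0.8, n))
            b2 = np.exp(rng.normal(0, 0.8, n))
            c = PairedCohort(b1=b1, b2=b2)
            assert abs(wcv(c) - _wcv_loop(b1, b2)) < 1e-12
            assert abs(cov_mean_diff(c) - _cov_loop(b1, b2)) < 1e-12
            assert abs(percent_rc(wcv(c)) - 1.96 * math.sqrt(2) * 100 * _wcv_loop(b1, b2)) < 1e-9
            bias, (lb, ub) = bland_altman(c.d)
            obias, (olb, oub) = _ba_loop(list(c.d))
            assert abs(bias - obias) < 1e-12
            assert abs(lb - olb) < 1e-12 and abs(ub - oub) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 100.0, allow_nan=False),
                st.floats(0.01, 100.0, allow_nan=False),
            ),
            min_size=2,
            max_size=30,
        )
    )
    def test_baseline_swap_property(self, pairs):
        """Swapping baselines negates bias, mirrors LoA, preserves %RC/%CoV."""
        b1 = np.array([p[0] for p in pairs])
        b2 = np.array([p[1] for p in pairs])
        fwd = PairedCohort(b1=b1, b2=b2)
        rev = PairedCohort(b1=b2, b2=b1)
        bias_f, (lb_f, ub_f) = bland_altman(fwd.d)
        bias_r, (lb_r, ub_r) = bland_altman(rev.d)
        assert bias_f == pytest.approx(-bias_r, abs=1e-10)
        assert lb_f == pytest.approx(-ub_r, abs=1e-10)
        assert ub_f == pytest.approx(-lb_r, abs=1e-10)
        assert wcv(fwd) == pytest.approx(wcv(rev), rel=1e-12)
        assert cov_mean_diff(fwd) == pytest.approx(cov_mean_diff(rev), rel=1e-12)


class TestAnalyticRecovery:
    def test_percent_rc_approaches_analytic_limit(self):
        """Noise-free log-normal per-scan variation: %RC -> 277.19 * sigma."""
        sigma = 0.1
        b1, b2 = simulate_summary_cohort(200, sigma, seed=1)
        rc = percent_rc(wcv(PairedCohort(b1=b1, b2=b2)))
        assert rc == pytest.approx(277.19 * sigma, rel=0.10)

    def test_zero_variation_gives_zero_everywhere(self):
        b1, b2 = simulate_summary_cohort(50, 0.0, seed=3)
        c = PairedCohort(b1=b1, b2=b2, parameter="ktrans", model="etm", vif_method="auto")
        report = build_report([c])
        row = report.iloc[0]
        assert row["bias"] == 0.0 and row["pct_rc"] == 0.0 and row["pct_cov"] == 0.0


class TestBuildReport:
    def _cohorts(self):
        rng = np.random.default_rng(5)
        out = []
        for model in ("etm", "ltkm"):
            for vm in ("auto", "manual"):
                for param in ("vp", "ve", "ktrans"):
                    b1 = np.exp(rng.normal(0, 0.3, 10))
                    out.append(
                        PairedCohort(
                            b1=b1, b2=b1 * np.exp(rng.normal(0, 0.1, 10)),
                            parameter=param, model=model, vif_method=vm,
                        )
                    )
        return out

    def test_one_row_per_parameter_model_vif(self):
        report = build_report(self._cohorts())
        assert len(report) == 2 * 2 * 3
        assert set(report["model"]) == {"etm", "ltkm"}

    def test_qc_outliers_annotated_not_excluded(self):
        cohorts = self._cohorts()
        report = build_report(cohorts, qc_outliers={3: 0.25})
        assert (report["n"] == 10).all()  # nothing dropped
        assert (report["qc_outlier_subjects"] == "3").all()

    def test_nonpositive_subjects_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="dcequant.repeatability"):
            c = PairedCohort(b1=[1.0, -2.0, 3.0], b2=[1.1, 2.0, 2.9], parameter="vp")
        assert c.n == 2
        assert "dropping" in caplog.text

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_report([])
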