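"""Spearman correlation, Bonferroni control, mRS dichotomisation, logistic fits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from strokeqeeg import (
    PatientOutcomes,
    StatsConfig,
    bonferroni,
    dichotomize_mrs,
    logistic_univariate,
    run_association_study,
    spearman,
)
from strokeqeeg.stats import ConstantInputError


def brute_force_spearman(x, y):
    """Oracle: rho via scipy, exact two-sided p by enumerating every pairing."""
    rho = sps.spearmanr(x, y).statistic
    n = len(x)
    count = 0
    total = 0
    y = np.asarray(y)
    for perm in itertools.permutations(range(n)):
        r = sps.spearmanr(x, y[list(perm)]).statistic
        count += abs(r) >= abs(rho) - 1e-12
        total += 1
    return rho, count / total


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman(np.arange(5.0), np.exp(np.arange(5.0)))
        assert r.rho == pytest.approx(1.0)

    def test_perfect_antimonotone(self):
        r = spearman(np.array([1, 2, 3, 4, 5.0]), np.array([5, 4, 3, 2, 1.0]))
        assert r.rho == pytest.approx(-1.0)

    def test_exact_p_matches_brute_force_enumeration(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        y = np.array([2, 1, 4, 3, 6, 5.0])
        r = spearman(x, y)
        rho_oracle, p_oracle = brute_force_spearman(x, y)
        assert r.method == "exact-permutation"
        assert r.rho == pytest.approx(rho_oracle, abs=1e-12)
        assert r.p == pytest.approx(p_oracle, abs=1e-12)

    @pytest.mark.parametrize("n,with_ties", [(4, False), (5, True), (6, False)])
    def test_exact_p_matches_oracle_on_random_instances(self, n, with_ties, rng):
        for _ in range(5):
            if with_ties:
                x = rng.integers(0, 3, size=n).astype(float)
                y = rng.integers(0, 3, size=n).astype(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
            else:
                x, y = rng.normal(size=n), rng.normal(size=n)
            r = spearman(x, y)
            rho_o, p_o = brute_force_spearman(x, y)
            assert r.rho == pytest.approx(rho_o, abs=1e-12)
            assert r.p == pytest.approx(p_o, abs=1e-12)

    def test_large_n_matches_scipy_t_approximation(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.method == "t-approximation"
        assert r.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantInputError):
            spearman(np.ones(5), np.arange(5.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_antisymmetry_under_negation(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=12)
        assert spearman(x, -y).rho == pytest.approx(-spearman(x, y).rho, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariance_under_strictly_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=10), r.normal(size=10)
        base = spearman(x, y)
        warped = spearman(np.exp(2 * x), y**3 + 5 * y)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p == pytest.approx(base.p, abs=1e-12)


class TestBonferroni:
    def test_threshold_arithmetic(self):
        res = bonferroni([0.01, 0.001], m=6)
        assert res.threshold == pytest.approx(0.05 / 6)
        assert res.flags == (False, True)

    def test_m_one_reduces_to_uncorrected_rule(self):
        res = bonferroni([0.04, 0.06], m=1)
        assert res.flags == (True, False)

    def test_flags_monotone_in_family_size(self, rng):
        ps = rng.uniform(0, 0.1, size=10)
        for m_small, m_big in [(1, 3), (3, 6), (6, 20)]:
            small = bonferroni(ps, m=m_small).flags
            big = bonferroni(ps, m=m_big).flags
            # lowering m never turns a significant result non-significant
            assert all(s or not b for s, b in zip(small, big))

    def test_default_family_is_six_eeg_parameters(self):
        assert bonferroni([0.009]).threshold == pytest.approx(0.05 / 6)


class TestDichotomizeMrs:
    @pytest.mark.parametrize("mrs,expected", [(0, True), (2, True), (3, False), (5, False)])
    def test_default_convention(self, mrs, expected):
        assert dichotomize_mrs(mrs) is expected

    def test_literal_convention_leaves_mrs3_unassigned(self):
        assert dichotomize_mrs(3, mrs3_is_bad=False) is None
        assert dichotomize_mrs(4, mrs3_is_bad=False) is False

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_mrs(7)


class TestLogisticUnivariate:
    def test_constant_feature_rejected(self):
        with pytest.raises(ConstantInputError):
            logistic_univariate(np.full(10, 2.0), np.arange(10) < 5)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both outcome classes"):
            logistic_univariate(rng.uniform(1, 2, 10), np.ones(10, dtype=bool))

    def test_high_dar_with_bad_outcome_gives_or_below_one(self, rng):
        # bad outcome generated to accompany high DAR
        dar = rng.uniform(0.5, 8.0, size=60)
        p_good = 1 / (1 + np.exp(2.0 * (np.log(dar) - np.log(2.5))))
        good = rng.uniform(size=60) < p_good
        res = logistic_univariate(dar, good, feature_name="dar")
        assert res.converged
        assert res.or_ < 1.0
        assert res.ci_low <= res.or_ <= res.ci_high

    def test_complete_separation_flagged_not_converged(self):
        x = np.array([1.0, 1.1, 1.2, 3.0, 3.1, 3.2])
        good = np.array([True, True, True, False, False, False])
        res = logistic_univariate(x, good)
        assert res.separated and not res.converged

    def test_permuted_labels_ci_covers_one_usually(self, rng):
        dar = rng.uniform(0.5, 8.0, size=20)
        good = np.arange(20) < 11
        covered = 0
        for _ in range(100):
            perm = rng.permutation(good)
            res = logistic_univariate(dar, perm)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 90


def _cohort_tables(n=20, seed=0, constant_severity=None):
    import pandas as pd

    from strokeqeeg import generate_outcomes
    from strokeqeeg.io import outcomes_frame

    rng = np.random.default_rng(seed)
    severities = (
        np.full(n, constant_severity)
        if constant_severity is not None
        else np.linspace(0.05, 0.95, n)
    )
    feats, outs = {}, {}
    for i, s in enumerate(severities):
        pid = f"P{i:03d}"
        outs[pid] = generate_outcomes(s, noise_sd=0.5, volume_scale=116.0, seed=i)
        # features monotone in severity with small noise
        dar = 0.2 + 8.0 * s + rng.normal(0, 0.05)
        feats[pid] = {
            "rel_delta": 0.1 + 0.5 * s + rng.normal(0, 0.005),
            "rel_theta": 0.2 + rng.normal(0, 0.005),
            "rel_alpha": 0.6 - 0.5 * s + rng.normal(0, 0.005),
            "rel_beta": 0.1 + rng.normal(0, 0.005),
            "dar": dar,
            "dtabr": dar * 0.9,
        }
    features = pd.DataFrame(feats).T.rename_axis("id")
    return features, outcomes_frame(outs)


class TestRunAssociationStudy:
    def test_sign_and_significance_on_coupled_cohort(self):
        features, outcomes = _cohort_tables()
        report = run_association_study(features, outcomes)
        by_key = {
            (c.feature_name, c.outcome_name): c for c in report.correlations
        }
        dar = by_key[("dar", "nihss_7d")]
        alpha = by_key[("rel_alpha", "nihss_7d")]
        assert dar.rho > 0 and dar.significant
        assert alpha.rho < 0 and alpha.significant
        assert len(report.correlations) == 6 * 4
        assert len(report.logistic) == 6

    def test_constant_severity_cohort_is_degenerate(self):
        features, outcomes = _cohort_tables(constant_severity=0.0)
        with pytest.raises(ConstantInputError, match="degenerate"):
            run_association_study(features, outcomes)

    def test_minimal_cohort_produces_no_bonferroni_significance(self):
        features, outcomes = _cohort_tables(n=3)
        report = run_association_study(features, outcomes.assign(mrs_12m=[0, 3, 5]))
        # exact permutation p for n=3 is at least 1/6 ≈ 0.167 > 0.05/6
        assert all(not c.significant for c in report.correlations)
        assert all(c.p_raw >= 1 / 6 for c in report.correlations)

    def test_id_mismatch_listed(self):
        features, outcomes = _cohort_tables(n=5)
        with pytest.raises(ValueError, match="P004"):
            run_association_study(features.iloc[:-1], outcomes)


class TestPatientOutcomesValidation:
    def test_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            PatientOutcomes(50, 0, 0, 0, 0, 0.0)
        with pytest.raises(ValueError):
            PatientOutcomes(0, 0, 0, 0, 7, 0.0)

    def test_stats_config_defaults(self):
        cfg = StatsConfig()
        assert cfg.bonferroni_m == 6 and cfg.alpha == 0.05 and cfg.mrs3_is_bad
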