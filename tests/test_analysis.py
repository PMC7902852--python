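"""Tests for the release-statistics estimators against brute-force oracles."""

import itertools

import numpy as np
import pytest

from boutonsim.analysis import (ReleaseEventLog, bootstrap_se,
                                conditional_p11, cv_stats, estimate_pr,
                                facilitation_curve, fit_exponential_recovery,
                                ppr, summarize)


def log_from_patterns(patterns, onsets=(0.0, 0.040)):
    """Build a log from per-trial tuples of stimulus-success flags; a
    success places one event 5 ms after that stimulus onset."""
    times, paths = [], []
    for pat in patterns:
        t = [onsets[j] + 0.005 for j, hit in enumerate(pat) if hit]
        times.append(np.array(sorted(t)))
        paths.append(np.array(["synchronous"] * len(t), dtype=object))
    return ReleaseEventLog(times, paths, tuple(onsets), len(patterns))


def brute_force_pr(log, j):
    lo, hi = log.window(j)
    return sum(bool(np.any((t >= lo) & (t < hi)))
               for t in log.trial_times) / log.n_trials


def test_pr_exhaustive_two_stimulus_patterns():
    """Estimator equals direct counting on every pattern combination of a
    small two-stimulus log."""
    for combo in itertools.product([(0, 0), (0, 1), (1, 0), (1, 1)], repeat=4):
        log = log_from_patterns(list(combo))
        for j in (0, 1):
            pr, _ = estimate_pr(log, j, n_resamples=10)
            assert pr == brute_force_pr(log, j)


def test_pr_fraction_of_successful_trials():
    # 194 successes of 2000 trials -> 0.097, the documented convention
    patterns = [(1,)] * 194 + [(0,)] * 1806
    log = log_from_patterns(patterns, onsets=(0.0,))
    pr, se = estimate_pr(log, 0)
    assert pr == pytest.approx(194 / 2000)
    assert se == pytest.approx(np.sqrt(pr * (1 - pr) / 2000), rel=0.15)


def test_pr_extremes():
    assert estimate_pr(log_from_patterns([(0, 0)] * 5), 0)[0] == 0.0
    assert estimate_pr(log_from_patterns([(1, 1)] * 5), 0)[0] == 1.0


def test_pr_window_truncated_at_next_onset():
    """An event 15 ms after pulse 1 counts for pulse 1 only if the ISI is
    >= 15 ms; with a 10 ms ISI the window is truncated."""
    times = [np.array([0.015])]
    paths = [np.array(["synchronous"], dtype=object)]
    log_long = ReleaseEventLog(times, paths, (0.0, 0.040), 1)
    assert estimate_pr(log_long, 0, n_resamples=10)[0] == 1.0
    log_short = ReleaseEventLog(times, paths, (0.0, 0.010), 1)
    assert estimate_pr(log_short, 0, n_resamples=10)[0] == 0.0
    assert estimate_pr(log_short, 1, n_resamples=10)[0] == 1.0


def test_ppr_arithmetic():
    # Pr1 = 0.1, Pr2 = 0.25 -> 2.5
    pats = [(1, 1)] * 2 + [(0, 1)] * 3 + [(0, 0)] * 15
    val, _ = ppr(log_from_patterns(pats))
    assert val == pytest.approx(2.5)
    pats = [(1, 1)] * 3 + [(0, 0)] * 7
    assert ppr(log_from_patterns(pats))[0] == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        ppr(log_from_patterns([(0, 1)] * 5))


def test_facilitation_curve_properties():
    on = (0.0, 0.05, 0.10, 0.15)
    # constant Pr -> all ones; first entry always 1
    pats = [(1, 1, 1, 1), (0, 0, 0, 0)]
    np.testing.assert_allclose(
        facilitation_curve(log_from_patterns(pats, on)), 1.0)
    # doubling then RRP-limited decline: interior maximum, matches counting
    pats = [(1, 1, 0, 0)] * 2 + [(0, 1, 1, 0)] * 2 + [(0, 0, 0, 0)] * 6
    fac = facilitation_curve(log_from_patterns(pats, on))
    expected = np.array([0.2, 0.4, 0.2, 0.0]) / 0.2
    np.testing.assert_allclose(fac, expected)
    assert fac.argmax() == 1 and fac[0] == 1.0


def test_p11_direct_count():
    log = log_from_patterns([(1, 1), (1, 0), (0, 1), (0, 0)])
    p, _ = conditional_p11(log)
    assert p == pytest.approx(0.5)
    assert conditional_p11(log_from_patterns([(1, 1)] * 4))[0] == 1.0
    with pytest.raises(ZeroDivisionError):
        conditional_p11(log_from_patterns([(0, 1), (0, 0)]))


def test_p11_independent_pulses_converges_to_pr2():
    """If the two pulses are independent Bernoulli, P11 -> Pr2."""
    rng = np.random.default_rng(42)
    pats = list(zip(rng.random(40000) < 0.5, rng.random(40000) < 0.3))
    p, _ = conditional_p11(log_from_patterns(pats))
    assert p == pytest.approx(0.3, abs=0.01)


def test_cv_conventions():
    assert cv_stats([2.0, 2.0, 2.0]) == 0.0
    # population sd: {1, 3} -> sd 1, mean 2 -> 1/2
    assert cv_stats([1.0, 3.0]) == pytest.approx(0.5)
    with pytest.raises(ZeroDivisionError):
        cv_stats([0.0, 0.0])
    # Bernoulli(0.2) indicator: CV -> ((1 - p)/p)^1/2 = 2
    rng = np.random.default_rng(7)
    x = (rng.random(200000) < 0.2).astype(float)
    assert cv_stats(x) == pytest.approx(2.0, rel=0.02)


def test_bootstrap_se_binomial_closed_form():
    rng = np.random.default_rng(3)
    pats = [(1,) if rng.random() < 0.25 else (0,) for _ in range(400)]
    log = log_from_patterns(pats, onsets=(0.0,))
    se = bootstrap_se(lambda lg: lg.success_matrix()[:, 0].mean(), log,
                      n_resamples=1000, seed=5)
    p = log.success_matrix()[:, 0].mean()
    assert se == pytest.approx(np.sqrt(p * (1 - p) / 400), rel=0.15)
    # zero-variance log
    se0 = bootstrap_se(lambda lg: lg.success_matrix()[:, 0].mean(),
                       log_from_patterns([(1,)] * 20, onsets=(0.0,)))
    assert se0 == 0.0


def test_exponential_fit_recovers_constants():
    t = np.linspace(0, 12, 60)
    y = 7 * (1 - np.exp(-t / 2.94))
    fit = fit_exponential_recovery(t, y)
    assert fit.tau == pytest.approx(2.94, rel=1e-6)
    assert fit.amplitude == pytest.approx(7.0, rel=1e-6)
    with pytest.raises(ValueError):
        fit_exponential_recovery(t, np.full_like(t, 3.0))
    with pytest.raises(ValueError):
        fit_exponential_recovery([0, 1], [0, 1])


def test_exponential_fit_noisy_ci_covers_truth():
    rng = np.random.default_rng(11)
    t = np.linspace(0, 12, 120)
    y = 7 * (1 - np.exp(-t / 2.94)) + rng.normal(0, 0.2, t.size)
    fit = fit_exponential_recovery(t, y)
    assert abs(fit.tau - 2.94) < 1.96 * fit.tau_se + 1e-9


def test_summarize_bundle():
    pats = [(1, 1)] * 10 + [(1, 0)] * 10 + [(0, 1)] * 20 + [(0, 0)] * 60
    s = summarize(log_from_patterns(pats), n_resamples=200, seed=1)
    assert s.pr_per_stimulus[0] == pytest.approx(0.2)
    assert s.pr_per_stimulus[1] == pytest.approx(0.3)
    assert s.ppr == pytest.approx(1.5)
    assert s.p11 == pytest.approx(0.5)
    assert s.facilitation[0] == 1.0
    assert s.cv_pr2 == pytest.approx(np.sqrt(0.7 / 0.3), rel=1e-9)
    assert s.n_trials == 100


def test_log_validation():
    with pytest.raises(ValueError):
        ReleaseEventLog([np.array([0.02, 0.01])],
                        [np.array(["synchronous"], dtype=object)],
                        (0.0,), 1)
    with pytest.raises(ValueError):
        ReleaseEventLog([], [], (0.0,), 3)
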