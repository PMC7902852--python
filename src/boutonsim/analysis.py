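"""Release statistics and calibration fits from simulated ensembles.

A trial is a "success" for a given stimulus when at least one vesicle fuses
(any pathway) within 20 ms of that AP's onset; the window is truncated at
the next AP onset if the ISI is shorter than 20 ms.  Release probability is
the fraction of successful trials; the paired-pulse ratio is Pr2/Pr1,
facilitation the vector Pr_n/Pr_1 along a train, and P11 the probability of
a second-pulse success conditioned on a first-pulse success.  Standard
errors come from resampling trials with replacement (1000 resamples by
default, seeded).  The coefficient of variation uses the population
standard deviation (sd/mean with ddof=0), so the CV of a Bernoulli success
indicator reproduces the binomial form ((1 - Pr)/(n Pr))^1/2 with n = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

RELEASE_WINDOW = 0.020  # s


@dataclass
class ReleaseEventLog:
    """Per-trial fusion times/pathways together with the protocol onsets."""

    trial_times: List[np.ndarray]
    trial_pathways: List[np.ndarray]
    onsets: tuple
    n_trials: int

    def __post_init__(self):
        if self.n_trials != len(self.trial_times):
            raise ValueError("n_trials must match the number of trials")
        for t in self.trial_times:
            if np.any(np.diff(t) < 0):
                raise ValueError("event times must be sorted within a trial")

    @classmethod
    def from_trials(cls, trials) -> "ReleaseEventLog":
        """Build a log from engine TrialResult objects."""
        if not trials:
            raise ValueError("empty ensemble")
        onsets = tuple(trials[0].protocol.onsets)
        return cls(
            trial_times=[np.sort(tr.event_times) for tr in trials],
            trial_pathways=[tr.event_pathways for tr in trials],
            onsets=onsets,
            n_trials=len(trials),
        )

    def window(self, stimulus_index: int) -> tuple:
        if not (0 <= stimulus_index < len(self.onsets)):
            raise IndexError("stimulus does not exist in this protocol")
        start = self.onsets[stimulus_index]
        end = start + RELEASE_WINDOW
        if stimulus_index + 1 < len(self.onsets):
            end = min(end, self.onsets[stimulus_index + 1])
        return start, end

    def success_matrix(self) -> np.ndarray:
        """Boolean (n_trials, n_stimuli): any fusion in each stimulus window."""
        n_stim = len(self.onsets)
        out = np.zeros((self.n_trials, n_stim), dtype=bool)
        for j in range(n_stim):
            lo, hi = self.window(j)
            for i, t in enumerate(self.trial_times):
                out[i, j] = bool(np.any((t >= lo) & (t < hi)))
        return out

    def subset(self, idx: np.ndarray) -> "ReleaseEventLog":
        return ReleaseEventLog([self.trial_times[i] for i in idx],
                               [self.trial_pathways[i] for i in idx],
                               self.onsets, len(idx))


def _resample_indices(n: int, n_resamples: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(n_resamples, n))


def estimate_pr(log: ReleaseEventLog, stimulus_index: int = 0,
                n_resamples: int = 1000, seed: int = 0) -> tuple:
    """Release probability for one stimulus: successes/trials, bootstrap SE."""
    if log.n_trials == 0:
        raise ValueError("empty event log")
    succ = log.success_matrix()[:, stimulus_index].astype(float)
    pr = float(succ.mean())
    reps = succ[_resample_indices(log.n_trials, n_resamples, seed)].mean(axis=1)
    return pr, float(reps.std(ddof=0))


def ppr(log: ReleaseEventLog, n_resamples: int = 1000, seed: int = 0) -> tuple:
    """Paired-pulse ratio Pr2/Pr1 with bootstrap SE."""
    if len(log.onsets) < 2:
        raise ValueError("paired-pulse log requires at least two stimuli")
    s = log.success_matrix().astype(float)
    pr1, pr2 = s[:, 0].mean(), s[:, 1].mean()
    if pr1 == 0:
        raise ZeroDivisionError("Pr1 = 0: paired-pulse ratio undefined")
    idx = _resample_indices(log.n_trials, n_resamples, seed)
    r1 = s[idx, 0].mean(axis=1)
    r2 = s[idx, 1].mean(axis=1)
    ratios = np.divide(r2, r1, out=np.full(len(r1), np.nan), where=r1 > 0)
    return float(pr2 / pr1), float(np.nanstd(ratios, ddof=0))


def facilitation_curve(log: ReleaseEventLog) -> np.ndarray:
    """Pr_n / Pr_1 for every stimulus of a train (first entry 1 by definition)."""
    s = log.success_matrix().astype(float)
    pr = s.mean(axis=0)
    if pr[0] == 0:
        raise ZeroDivisionError("Pr1 = 0: facilitation undefined")
    return pr / pr[0]


def conditional_p11(log: ReleaseEventLog, n_resamples: int = 1000,
                    seed: int = 0) -> tuple:
    """P(success on pulse 2 | success on pulse 1), with bootstrap SE."""
    if len(log.onsets) < 2:
        raise ValueError("P11 requires a paired-pulse log")
    s = log.success_matrix()
    n1 = int(s[:, 0].sum())
    if n1 == 0:
        raise ZeroDivisionError("no first-pulse successes: P11 undefined")
    p11 = float((s[:, 0] & s[:, 1]).sum() / n1)
    idx = _resample_indices(log.n_trials, n_resamples, seed)
    b1 = s[idx, 0]
    b11 = s[idx, 0] & s[idx, 1]
    denom = b1.sum(axis=1).astype(float)
    reps = np.divide(b11.sum(axis=1), denom,
                     out=np.full(len(denom), np.nan), where=denom > 0)
    return p11, float(np.nanstd(reps, ddof=0))


def cv_stats(values: Sequence[float]) -> float:
    """Coefficient of variation: population standard deviation / mean."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("zero mean: CV undefined")
    return float(v.std(ddof=0) / m)


def bootstrap_se(statistic: Callable[[ReleaseEventLog], float],
                 log: ReleaseEventLog, n_resamples: int = 1000,
                 seed: int = 0) -> float:
    """SE of an arbitrary trial-level statistic under resampling with
    replacement (seeded, reproducible)."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    idx = _resample_indices(log.n_trials, n_resamples, seed)
    reps = np.array([statistic(log.subset(row)) for row in idx])
    return float(reps.std(ddof=0))


@dataclass
class ExponentialFit:
    amplitude: float
    tau: float
    baseline: float
    cov: np.ndarray
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def tau_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))


def fit_exponential_recovery(times: Sequence[float],
                             values: Sequence[float]) -> ExponentialFit:
    """Least-squares fit of y = A (1 - exp(-t/tau)) + y0.

    Used for the ER-refill and RRP-recovery calibrations.  Requires at least
    5 points; a constant series is rejected as a degenerate fit.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 5 or t.size != y.size:
        raise ValueError("need >= 5 (time, value) points")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.ptp(y) == 0:
        raise ValueError("constant series: degenerate exponential fit")

    def f(tt, A, tau, y0):
        return A * (1.0 - np.exp(-tt / tau)) + y0

    span = max(t[-1] - t[0], 1e-12)
    p0 = (y[-1] - y[0], span / 3.0, y[0])
    try:
        popt, pcov = curve_fit(f, t, y, p0=p0,
                               bounds=([-np.inf, 1e-12, -np.inf],
                                       [np.inf, np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as err:
        resid = y - f(t, *p0)
        raise RuntimeError(f"exponential fit did not converge ({err}); "
                           f"initial residual rms {np.sqrt(np.mean(resid**2)):.3g}")
    resid = y - f(t, *popt)
    return ExponentialFit(amplitude=float(popt[0]), tau=float(popt[1]),
                          baseline=float(popt[2]), cov=pcov, residuals=resid)


@dataclass
class EnsembleSummary:
    """Release statistics of one ensemble (paired pulse or train)."""

    pr_per_stimulus: np.ndarray
    pr_se: np.ndarray
    ppr: Optional[float] = None
    ppr_se: Optional[float] = None
    facilitation: Optional[np.ndarray] = None
    p11: Optional[float] = None
    p11_se: Optional[float] = None
    cv_pr2: Optional[float] = None
    n_trials: int = 0

    def __post_init__(self):
        if np.any((self.pr_per_stimulus < 0) | (self.pr_per_stimulus > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.facilitation is not None and len(self.facilitation) \
                and abs(self.facilitation[0] - 1.0) > 1e-12:
            raise ValueError("facilitation[0] must be 1 by definition")


def summarize(log: ReleaseEventLog, n_resamples: int = 1000,
              seed: int = 0) -> EnsembleSummary:
    """Full summary of an ensemble's release statistics."""
    n_stim = len(log.onsets)
    prs, ses = [], []
    for j in range(n_stim):
        p, se = estimate_pr(log, j, n_resamples, seed)
        prs.append(p)
        ses.append(se)
    prs = np.array(prs)
    out = EnsembleSummary(pr_per_stimulus=prs, pr_se=np.array(ses),
                          n_trials=log.n_trials)
    if n_stim >= 2 and prs[0] > 0:
        out.ppr, out.ppr_se = ppr(log, n_resamples, seed)
        out.facilitation = facilitation_curve(log)
        s = log.success_matrix()
        if s[:, 0].any():
            out.p11, out.p11_se = conditional_p11(log, n_resamples, seed)
        if prs[1] > 0:
            out.cv_pr2 = cv_stats(s[:, 1].astype(float))
    return out
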