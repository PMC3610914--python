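"""Paired pre/post comparisons and across-dose tests on trace summaries.

The experimental design is within-neuron: each neuron is recorded for a
pre-drug window, a wash-in interval that is excluded from analysis, and a
post-drug window.  Oscillation frequency is compared with the Wilcoxon
signed-rank test (exact null distribution at small n, zero differences
dropped) and amplitude with the paired t-test; dose ladders measured on the
same neurons are compared with the Friedman rank test.  All tests are
two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .detection import FluorescenceTrace, TraceSummary

__all__ = [
    "PhaseProtocol",
    "PairedMeasurements",
    "TestResult",
    "split_phases",
    "pair_summaries",
    "signed_rank_exact_p",
    "paired_frequency_test",
    "paired_amplitude_test",
    "friedman_across_doses",
    "condition_report",
]


@dataclass(frozen=True)
class PhaseProtocol:
    """Perfusion timing in seconds: pre window, wash-in (excluded), post window."""

    pre_duration: float = 120.0
    wash_duration: float = 60.0
    post_duration: float = 120.0

    def __post_init__(self) -> None:
        if min(self.pre_duration, self.wash_duration, self.post_duration) < 0:
            raise ValueError("phase durations must be >= 0")

    @property
    def total(self) -> float:
        return self.pre_duration + self.wash_duration + self.post_duration


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-neuron (pre, post) values of one metric.

    ``pairs`` is a list of (neuron_id, pre, post); a pair whose pre or post
    value is missing (None) is dropped before testing (pairwise deletion).
    Each neuron may appear at most once.
    """

    metric: str
    pairs: tuple

    def __post_init__(self) -> None:
        if self.metric not in ("frequency", "amplitude"):
            raise ValueError(f"unknown metric {self.metric!r}")
        ids = [p[0] for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("each neuron may appear at most once")

    def complete_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        pre = [p[1] for p in self.pairs if p[1] is not None and p[2] is not None]
        post = [p[2] for p in self.pairs if p[1] is not None and p[2] is not None]
        return np.asarray(pre, float), np.asarray(post, float)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_pairs: int
    warning: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def split_phases(
    trace: FluorescenceTrace, protocol: PhaseProtocol | None = None
) -> tuple[FluorescenceTrace, FluorescenceTrace]:
    """Cut one recording into its pre- and post-drug analysis windows.

    Pre covers [0, pre_duration); post covers [pre + wash, pre + wash +
    post_duration); the wash-in samples are discarded.  Times are relative
    to the trace's own ``t0``.
    """
    protocol = protocol or PhaseProtocol()
    if trace.duration + 1e-9 < protocol.total:
        raise ValueError(
            f"trace {trace.neuron_id!r} spans {trace.duration:g} s but the "
            f"protocol requires {protocol.total:g} s"
        )
    dt = trace.dt
    n_pre = int(round(protocol.pre_duration / dt))
    i_post = int(round((protocol.pre_duration + protocol.wash_duration) / dt))
    n_post = int(round(protocol.post_duration / dt))
    pre = FluorescenceTrace(
        neuron_id=trace.neuron_id, values=trace.values[:n_pre], t0=trace.t0, dt=dt
    )
    post = FluorescenceTrace(
        neuron_id=trace.neuron_id,
        values=trace.values[i_post : i_post + n_post],
        t0=trace.t0 + i_post * dt,
        dt=dt,
    )
    return pre, post


def signed_rank_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p conditional on the observed ranks.

    Returns (W+, p).  Ranks of |diff| use average ranks for ties; the null
    distribution of W+ is built by dynamic programming over all 2^n sign
    assignments of the observed (possibly tied) ranks, so the p-value is
    exact even in the presence of ties, where the tabulated no-tie
    distribution is only approximate.  Two-sided p = 2 * min(P(W+ <= w),
    P(W+ >= w)), capped at 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # doubled ranks are integers even with .5 average ranks
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r or None]
    w2 = int(round(2 * w_plus))
    n_total = float(2**n)
    p_le = counts[: w2 + 1].sum() / n_total
    p_ge = counts[w2:].sum() / n_total
    return w_plus, min(1.0, 2.0 * min(p_le, p_ge))


def paired_frequency_test(pairs: PairedMeasurements) -> TestResult:
    """Wilcoxon signed-rank test on per-neuron (post - pre) frequencies.

    Zero differences are dropped (Wilcoxon's original rule) and their
    count noted in the warning field.  For n <= 25 retained pairs the
    exact conditional null distribution is enumerated (see
    :func:`signed_rank_exact_p`); above that the normal approximation is
    used.  If every difference is zero the test is vacuous and p = 1 is
    returned with a warning flag instead of an exception.
    """
    if pairs.metric != "frequency":
        raise ValueError("paired_frequency_test expects the frequency metric")
    pre, post = pairs.complete_pairs()
    if len(pre) < 1:
        raise ValueError("no complete pairs to test")
    diffs = post - pre
    n_zero = int((diffs == 0).sum())
    nz = diffs[diffs != 0]
    warning = f"{n_zero} zero differences dropped" if n_zero else None
    if nz.size == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, len(pre), warning="all differences zero"
        )
    if nz.size <= 25:
        stat, p = signed_rank_exact_p(nz)
    else:
        res = sps.wilcoxon(nz, zero_method="wilcox", method="approx")
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult("wilcoxon_signed_rank", stat, p, len(pre), warning=warning)


def paired_amplitude_test(pairs: PairedMeasurements) -> TestResult:
    """Paired t-test on per-neuron (post - pre) amplitudes.

    Pairs with a missing amplitude on either side (zero-event traces) are
    excluded first; fewer than two complete pairs is an error.  A nonzero
    mean difference with exactly zero spread is degenerate for the t
    statistic and is reported as p = 0 with a warning flag.
    """
    if pairs.metric != "amplitude":
        raise ValueError("paired_amplitude_test expects the amplitude metric")
    pre, post = pairs.complete_pairs()
    n = len(pre)
    if n < 2:
        raise ValueError(
            f"paired t-test needs >= 2 complete pairs, got {n} "
            "(zero-event traces are excluded from amplitude comparisons)"
        )
    diffs = post - pre
    if np.std(diffs, ddof=1) == 0.0:
        if diffs[0] == 0.0:
            return TestResult("paired_t", 0.0, 1.0, n, warning="all differences zero")
        return TestResult(
            "paired_t",
            math.copysign(math.inf, diffs[0]),
            0.0,
            n,
            warning="zero-variance differences",
        )
    res = sps.ttest_rel(post, pre)
    return TestResult("paired_t", float(res.statistic), float(res.pvalue), n)


def friedman_across_doses(matrix) -> TestResult:
    """Friedman chi-square over >= 3 conditions measured on the same neurons.

    ``matrix`` is (n_neurons, n_conditions) with no missing cells (complete
    blocks); ranks are computed within each neuron with average ranks for
    ties.  A matrix whose rows are all completely tied carries no rank
    information; statistic 0 / p 1 is returned with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("need a complete (neurons x >=3 conditions) matrix")
    if not np.isfinite(m).all():
        raise ValueError("incomplete blocks: every neuron must be measured in every condition")
    if all(np.unique(row).size == 1 for row in m):
        return TestResult(
            "friedman", 0.0, 1.0, m.shape[0], warning="all conditions tied"
        )
    res = sps.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return TestResult("friedman", float(res.statistic), float(res.pvalue), m.shape[0])


def pair_summaries(
    pre: list[TraceSummary], post: list[TraceSummary], metric: str
) -> PairedMeasurements:
    """Match pre- and post-phase summaries by neuron id into paired data."""
    post_by_id = {s.neuron_id: s for s in post}
    pairs = []
    for s in pre:
        if s.neuron_id not in post_by_id:
            continue
        q = post_by_id[s.neuron_id]
        if metric == "frequency":
            pairs.append((s.neuron_id, s.frequency, q.frequency))
        else:
            pairs.append((s.neuron_id, s.amplitude, q.amplitude))
    return PairedMeasurements(metric=metric, pairs=tuple(pairs))


def condition_report(conditions: dict[str, tuple[list, list]]):
    """Per-condition table of mean +/- SD, n and paired-test results.

    ``conditions`` maps a condition name to (pre summaries, post
    summaries).  For each condition and metric the table reports the
    post-phase mean and SD across neurons (SD over a single neuron is NA),
    the n actually used (after excluding missing amplitudes), the paired
    p-value against the pre phase, and significance flags at 0.05 / 0.01.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for name, (pre, post) in conditions.items():
        if not pre or not post:
            raise ValueError(f"condition {name!r} has an empty phase")
        for metric in ("frequency", "amplitude"):
            pairs = pair_summaries(pre, post, metric)
            pre_v, post_v = pairs.complete_pairs()
            if metric == "frequency":
                test = paired_frequency_test(pairs) if len(pre_v) else None
            else:
                try:
                    test = paired_amplitude_test(pairs)
                except ValueError:
                    test = None
            for phase, vals in (("pre", pre_v), ("post", post_v)):
                n = len(vals)
                rows.append(
                    {
                        "condition": name,
                        "metric": metric,
                        "phase": phase,
                        "n": n,
                        "mean": float(np.mean(vals)) if n else math.nan,
                        "sd": float(np.std(vals, ddof=1)) if n > 1 else math.nan,
                        "p_vs_pre": (
                            test.p_value if (test is not None and phase == "post") else math.nan
                        ),
                        "sig_05": bool(
                            test is not None and phase == "post" and test.p_value < 0.05
                        ),
                        "sig_01": bool(
                            test is not None and phase == "post" and test.p_value < 0.01
                        ),
                    }
                )
    return pd.DataFrame(rows)
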