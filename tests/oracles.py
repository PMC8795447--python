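"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a pipeline quantity by a deliberately different route
(flat per-element loops, regex, exhaustive enumeration) so agreement is a
genuine cross-check rather than a re-run of the implementation.
"""
from __future__ import annotations

import math
import re


def reduction_oracle(time, donor, acceptor, mock_ratio_series_list, t_stim,
                     base_dur, stim_dur, vehicle_fold):
    """Scalar-loop recomputation of one well's net fold change."""
    n = len(time)
    ratio = [acceptor[i] / donor[i] for i in range(n)]
    corrected = []
    for i in range(n):
        if mock_ratio_series_list:
            mock_mean = sum(m[i] for m in mock_ratio_series_list) / len(
                mock_ratio_series_list
            )
        else:
            mock_mean = 0.0
        corrected.append(ratio[i] - mock_mean)
    base_vals = [
        corrected[i]
        for i in range(n)
        if t_stim - base_dur <= time[i] < t_stim
    ]
    stim_vals = [
        corrected[i]
        for i in range(n)
        if t_stim < time[i] <= t_stim + stim_dur
    ]
    baseline_mean = sum(base_vals) / len(base_vals)
    stimulated_mean = sum(stim_vals) / len(stim_vals)
    fold = stimulated_mean / baseline_mean
    return fold / vehicle_fold


_P_CLASS = "[STDE]"


def regex_motif_oracle(seq: str, pattern: str):
    """Overlap-counting motif scan via a regex lookahead."""
    rx = "".join(_P_CLASS if ch == "P" else "." for ch in pattern)
    return [m.start() for m in re.finditer(rf"(?=({rx}))", seq)]


def loop_motif_oracle(seq: str, pattern: str):
    """Character-by-character nested-loop motif scan."""
    hits = []
    for s in range(len(seq) - len(pattern) + 1):
        for k, slot in enumerate(pattern):
            if slot == "P" and seq[s + k] not in "STDE":
                break
        else:
            hits.append(s)
    return hits


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration with factorial arithmetic."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def point_prob(k):
        # hypergeometric point probability via log-factorials
        b_ = r1 - k
        c_ = c1 - k
        d_ = n - r1 - c_
        if min(b_, c_, d_) < 0:
            return 0.0
        lf = math.lgamma
        num = (
            lf(r1 + 1) + lf(n - r1 + 1) + lf(c1 + 1) + lf(n - c1 + 1)
        )
        den = (
            lf(n + 1) + lf(k + 1) + lf(b_ + 1) + lf(c_ + 1) + lf(d_ + 1)
        )
        return math.exp(num - den)

    p_obs = point_prob(a)
    total = 0.0
    for k in range(0, min(r1, c1) + 1):
        pk = point_prob(k)
        if pk <= p_obs * (1.0 + 1e-7):
            total += pk
    return min(1.0, total)


def canberra_loop_oracle(u, v):
    total = 0.0
    for ui, vi in zip(u, v):
        denom = abs(ui) + abs(vi)
        if denom > 0:
            total += abs(ui - vi) / denom
    return total


def anova_closed_form(groups):
    """Textbook one-way ANOVA from sums of squares."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    from scipy.stats import f

    return F, float(f.sf(F, dfb, dfw))


def piecewise_linear_auc(times, values, lo=0.0, hi=1800.0):
    """Closed-form integral of a piecewise-linear trace via antiderivatives."""
    total = 0.0
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        y0, y1 = values[i], values[i + 1]
        a = max(t0, lo)
        bnd = min(t1, hi)
        if bnd <= a:
            continue
        slope = (y1 - y0) / (t1 - t0)

        def F(t):
            return y0 * (t - t0) + 0.5 * slope * (t - t0) ** 2

        total += F(bnd) - F(a)
    return total
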