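"""Brute-force oracles: direct loop evaluation of the printed statistics.

Deliberately slow and scalar — these implementations share no code with the
package and serve as independent references on small datasets.
"""

import math


def nam_zelen_brute(time, event, x, Z, W):
    """Score pair by direct summation over distinct event times.

    Returns (S0, V0, S1, V1).  z_j(t) = I(W_j <= t) (never for Z_j = 0);
    risk R_j(t) = I(T_j >= t); tied events share risk-set shares and the
    variance carries the multiplicity factor (n - d) / (n - 1).
    """
    n = len(time)
    w = [W[j] if Z[j] == 1 else math.inf for j in range(n)]
    times = sorted({time[i] for i in range(n) if event[i] == 1})
    S0 = V0 = S1 = V1 = 0.0
    for t in times:
        riskers = [j for j in range(n) if time[j] >= t]
        post = [j for j in riskers if w[j] <= t]
        pre = [j for j in riskers if w[j] > t]
        ev_here = [i for i in range(n) if event[i] == 1 and time[i] == t]
        d1 = [i for i in ev_here if w[i] <= t]
        d0 = [i for i in ev_here if w[i] > t]
        if d1:
            N1 = len(post)
            p = sum(x[j] for j in post) / N1
            d = len(d1)
            S1 += sum(x[i] for i in d1) - p * d
            V1 += p * (1 - p) * d * ((N1 - d) / (N1 - 1) if N1 > 1 else 0.0)
        if d0:
            M0 = len(pre)
            pi = sum(x[j] for j in pre) / M0
            d = len(d0)
            S0 += sum(x[i] for i in d0) - pi * d
            V0 += pi * (1 - pi) * d * ((M0 - d) / (M0 - 1) if M0 > 1 else 0.0)
    return S0, V0, S1, V1


def logrank_brute(time, event, x):
    """(O - E, variance) for group A by direct per-event-time enumeration."""
    n = len(time)
    times = sorted({time[i] for i in range(n) if event[i] == 1})
    oe = v = 0.0
    for t in times:
        risk = [j for j in range(n) if time[j] >= t]
        nA = sum(x[j] for j in risk)
        nn = len(risk)
        ev_here = [i for i in range(n) if event[i] == 1 and time[i] == t]
        d = len(ev_here)
        dA = sum(x[i] for i in ev_here)
        oe += dA - d * nA / nn
        if nn > 1:
            v += d * (nA / nn) * (1 - nA / nn) * (nn - d) / (nn - 1)
    return oe, v


def stratified_logrank_brute(time, event, x, strata):
    """Stratified log-rank chi-square by per-stratum enumeration."""
    oe = v = 0.0
    for s in sorted(set(strata)):
        idx = [i for i in range(len(time)) if strata[i] == s]
        o, vv = logrank_brute(
            [time[i] for i in idx], [event[i] for i in idx], [x[i] for i in idx]
        )
        oe += o
        v += vv
    return oe * oe / v
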