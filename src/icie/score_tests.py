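"""Two-sample score statistics in the presence of an intermediate event.

The core statistics follow the counting-process score test of Nam and Zelen
for comparing two survival distributions when subjects may experience an
intermediate event (IE) at an exactly observed waiting time ``W``: under
stratum-specific proportional hazards ``Q_kA(t) = Q_kB(t)^{beta_k}``
(``k = 0`` pre-IE, ``k = 1`` post-IE), the score for ``beta_1`` is

    S1 = sum_i x_i z_i(t_i) dN_i - sum_i p_i dN_i,   p_i = n_i / N_i,

with ``z_j(t) = I(W_j <= t)`` (identically 0 for subjects without the IE),
risk indicator ``R_j(t) = I(T_j >= t)``, ``n_i`` and ``N_i`` the group-A and
total at-risk counts among currently post-IE subjects at the i-th event
time, and null variance ``V(S1) = sum_i p_i (1 - p_i) dN_i`` (with the
standard log-rank multiplicity correction ``(N_i - dN_i)/(N_i - 1)`` at
tied event times, to which imputed datasets are prone).  ``S0`` is the
analogue on the pre-IE stratum using ``1 - z`` and shares ``pi_i = m_i/M_i``.
Each event contributes to exactly one of the two scores according to the
subject's IE status at its own event time.  The composite null
``beta_0 = beta_1 = 0`` is referred to chi-square with 2 df,
``chi2 = S1^2/V(S1) + S0^2/V(S0)``; the hypothesis is separable, giving the
1-df component tests.

The standard log-rank and the IE-stratified log-rank comparators (computed
on exact/right-censored times) live here too, built on the same risk-set
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ScorePair",
    "ChiSquareSummary",
    "nam_zelen_score",
    "chi2_tests",
    "logrank",
    "stratified_logrank",
]


@dataclass
class ScorePair:
    """Score statistics and null variances from one (completed) dataset."""

    S0: float
    V0: float
    S1: float
    V1: float


@dataclass
class ChiSquareSummary:
    """Composite 2-df test and the separable 1-df component tests.

    Components with zero variance are dropped and the composite degrees of
    freedom reduced accordingly; the corresponding 1-df entries are NaN.
    """

    chi2_2df: float
    df: int
    p_2df: float
    chi1_beta0: float
    p_beta0: float
    chi1_beta1: float
    p_beta1: float


def _as_arrays(time, event, x, Z=None, W=None):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=int)
    if Z is None:
        Z = np.zeros_like(event)
    else:
        Z = np.asarray(Z, dtype=int)
    if W is None:
        W = np.full_like(time, np.nan)
    else:
        W = np.asarray(W, dtype=float)
    return time, event, x, Z, W


def _tie_factor(n_risk: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Hypergeometric multiplicity correction ``(n - d) / (n - 1)`` for ties.

    Equals 1 at untied event times (d = 1) and 0 when the risk set is a
    single subject; without it the null variance is overstated when many
    events share one time, as happens for imputed times drawn from a
    discrete estimate with few atoms.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (n_risk - d) / (n_risk - 1.0)
    return np.where(n_risk > 1, f, 0.0)


def nam_zelen_score(time, event, x, Z=None, W=None) -> ScorePair:
    """Nam–Zelen score pair on exact / right-censored data.

    Parameters
    ----------
    time, event
        Follow-up time and event indicator (1 = event) per subject.
    x
        Group indicator (1 = group A, 0 = group B).
    Z, W
        IE indicator and exactly observed IE time (ignored where ``Z = 0``);
        omitting them treats every subject as pre-IE throughout, in which
        case ``S0`` reduces to the numerator of the standard log-rank
        statistic and ``S1 = V1 = 0``.

    Notes
    -----
    Tied event times are aggregated with shared risk-set shares.  Event
    times whose stratum risk set is empty are skipped (cannot occur for the
    event's own stratum, since the subject itself is at risk).  A dataset
    without events yields the degenerate pair (0, 0, 0, 0) with a warning.
    """
    time, event, x, Z, W = _as_arrays(time, event, x, Z, W)
    # z_j(t) = I(W_j <= t); encode "never" as W = +inf
    w_eff = np.where(Z == 1, W, np.inf)
    if np.any(np.isnan(w_eff)):
        raise ValueError("W must be provided wherever Z = 1")

    ev = event == 1
    if not ev.any():
        warnings.warn("no events in dataset; score statistics are degenerate")
        return ScorePair(0.0, 0.0, 0.0, 0.0)
    te = time[ev]
    xe = x[ev]
    ze = w_eff[ev] <= te  # IE status of each event's subject at its own time

    u = np.unique(te)
    k = u.size
    at_risk = time[None, :] >= u[:, None]
    z_mat = w_eff[None, :] <= u[:, None]
    x_row = x[None, :] == 1

    N1 = (at_risk & z_mat).sum(axis=1).astype(float)
    n1 = (at_risk & z_mat & x_row).sum(axis=1).astype(float)
    M0 = (at_risk & ~z_mat).sum(axis=1).astype(float)
    m0 = (at_risk & ~z_mat & x_row).sum(axis=1).astype(float)

    idx = np.searchsorted(u, te)
    dN1 = np.bincount(idx[ze], minlength=k).astype(float)
    dN1A = np.bincount(idx[ze & (xe == 1)], minlength=k).astype(float)
    dN0 = np.bincount(idx[~ze], minlength=k).astype(float)
    dN0A = np.bincount(idx[~ze & (xe == 1)], minlength=k).astype(float)

    ok1 = N1 > 0
    p = np.divide(n1, N1, out=np.zeros(k), where=ok1)
    S1 = float((dN1A - p * dN1)[ok1].sum())
    V1 = float((p * (1.0 - p) * dN1 * _tie_factor(N1, dN1))[ok1].sum())

    ok0 = M0 > 0
    pi = np.divide(m0, M0, out=np.zeros(k), where=ok0)
    S0 = float((dN0A - pi * dN0)[ok0].sum())
    V0 = float((pi * (1.0 - pi) * dN0 * _tie_factor(M0, dN0))[ok0].sum())
    return ScorePair(S0, V0, S1, V1)


def chi2_tests(S0: float, V0: float, S1: float, V1: float) -> ChiSquareSummary:
    """Composite and separable chi-square tests from a score pair.

    Raises ``ValueError`` when both variances are zero (test undefined).
    """
    if V0 < 0 or V1 < 0:
        raise ValueError("variances must be nonnegative")
    comps = []
    if V0 > 0:
        comps.append(S0 * S0 / V0)
    else:
        warnings.warn("zero-variance beta0 component dropped; df reduced")
    if V1 > 0:
        comps.append(S1 * S1 / V1)
    else:
        warnings.warn("zero-variance beta1 component dropped; df reduced")
    if not comps:
        raise ValueError("both score variances are zero; test undefined")
    chi2 = float(sum(comps))
    df = len(comps)
    c0 = S0 * S0 / V0 if V0 > 0 else np.nan
    c1 = S1 * S1 / V1 if V1 > 0 else np.nan
    return ChiSquareSummary(
        chi2_2df=chi2,
        df=df,
        p_2df=float(stats.chi2.sf(chi2, df)),
        chi1_beta0=c0,
        p_beta0=float(stats.chi2.sf(c0, 1)) if V0 > 0 else np.nan,
        chi1_beta1=c1,
        p_beta1=float(stats.chi2.sf(c1, 1)) if V1 > 0 else np.nan,
    )


def _logrank_oe(time, event, x) -> tuple[float, float]:
    """Observed-minus-expected and hypergeometric variance for group A."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=int)
    ev = event == 1
    if not ev.any():
        return 0.0, 0.0
    u = np.unique(time[ev])
    at_risk = time[None, :] >= u[:, None]
    n = at_risk.sum(axis=1).astype(float)
    nA = (at_risk & (x[None, :] == 1)).sum(axis=1).astype(float)
    idx = np.searchsorted(u, time[ev])
    d = np.bincount(idx, minlength=u.size).astype(float)
    dA = np.bincount(idx[x[ev] == 1], minlength=u.size).astype(float)
    frac = nA / n
    oe = float((dA - d * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d * frac * (1.0 - frac) * (n - d) / (n - 1.0)
    v = float(np.where(n > 1, v_terms, 0.0).sum())
    return oe, v


def logrank(time, event, x) -> tuple[float, float]:
    """Standard two-sample log-rank test on exact/right-censored data.

    Returns ``(chi-square statistic, p-value)`` on 1 df.
    """
    x = np.asarray(x, dtype=int)
    if not (np.any(x == 1) and np.any(x == 0)):
        raise ValueError("both groups must be non-empty")
    if not np.any(np.asarray(event, dtype=int) == 1):
        raise ValueError("log-rank undefined without events")
    oe, v = _logrank_oe(time, event, x)
    if v <= 0:
        raise ValueError("log-rank variance is zero")
    chi2 = oe * oe / v
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def stratified_logrank(time, event, x, strata) -> tuple[float, float]:
    """Log-rank test stratified by IE occurrence (or any label).

    O−E contributions and variances are accumulated within each stratum and
    summed; strata without events contribute nothing.  Returns
    ``(chi-square statistic, p-value)`` on 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=int)
    strata = np.asarray(strata)
    if not (np.any(x == 1) and np.any(x == 0)):
        raise ValueError("both groups must be non-empty")
    oe_total = 0.0
    v_total = 0.0
    for s in np.unique(strata):
        mask = strata == s
        oe, v = _logrank_oe(time[mask], event[mask], x[mask])
        oe_total += oe
        v_total += v
    if v_total <= 0:
        raise ValueError("stratified log-rank variance is zero")
    chi2 = oe_total * oe_total / v_total
    return float(chi2), float(stats.chi2.sf(chi2, 1))
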