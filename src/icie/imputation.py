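"""Non-iterative multiple imputation for interval-censored IE data.

Each imputation converts the interval-censored cohort into two completed
datasets:

* a **pre-IE** dataset covering every subject — subjects with the IE are
  right-censored at their (exactly observed) IE time ``W``, censored no-IE
  subjects keep ``L`` as a censoring time, and no-IE events get an event
  time drawn from the stratum's candidate points inside their interval;
* a **post-IE** dataset covering IE subjects only — left-truncated at ``W``,
  censored subjects keep ``L``, and events get a drawn time inside their
  interval.

Two sampling weights are supported: *uniform* over the candidate points in
``(L, R]``, and *NPMLE-weighted*, drawing from the Turnbull estimate of the
stratum's survival distribution restricted and renormalized to ``(L, R]``.
Each completed pair is scored with the Nam–Zelen statistics and the M
replicates are pooled with the within/between variance combination, using
both the additive form ``V1 = within + (1 + 1/M) * between`` and the
subtractive form ``V2 = within - between``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .npmle import (
    CandidateSet,
    NPMLEEstimate,
    ZeroMassError,
    build_candidate_sets,
    turnbull_npmle,
)
from .score_tests import ChiSquareSummary, ScorePair, chi2_tests, nam_zelen_score

__all__ = [
    "ImputedDataset",
    "MITestResult",
    "impute_uniform",
    "impute_weighted",
    "score_imputed",
    "pool_rubin",
    "mi_test",
    "fit_stratum_npmle",
]


@dataclass
class ImputedDataset:
    """One completed dataset: a pre-IE (k=0) and a post-IE (k=1) view.

    ``t0`` holds columns ``time, event, x, Z, W`` for all subjects (IE
    subjects censored exactly at ``W``); ``t1`` holds ``time, event, x, W``
    for IE subjects only, with ``W`` both the truncation/entry time and the
    IE clock used by the score's z-process.
    """

    rep: int
    t0: pd.DataFrame
    t1: pd.DataFrame
    n_fallback: int = 0


def _draw_uniform_candidates(
    cand: CandidateSet, L: np.ndarray, R: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Uniform draws from ``{s_j : L_i < s_j <= R_i}``, vectorized.

    Subjects whose candidate subset is empty are imputed at ``R`` itself
    (a valid upper bound for the event time); the count is returned.
    """
    lo, hi = cand.subset_range(L, R)
    width = hi - lo
    empty = width <= 0
    # L == R is an exact observation: a deterministic singleton, not a fallback
    n_fb = int((empty & (L < R)).sum())
    if n_fb:
        warnings.warn(f"{n_fb} empty candidate subsets; imputing R directly")
    if empty.any():
        width = np.maximum(width, 1)
    j = lo + (rng.uniform(size=len(L)) * width).astype(int)
    j = np.minimum(j, len(cand.points) - 1)
    out = cand.points[j]
    if empty.any():
        out = np.where(empty, R, out)
    return out, n_fb


def _draw_npmle_candidates(
    est: NPMLEEstimate,
    cand: CandidateSet,
    L: np.ndarray,
    R: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Draws from the NPMLE conditional on ``(L_i, R_i]``, vectorized.

    The support intervals are disjoint and ordered, so the retained support
    for each subject is a contiguous run; sampling inverts the mass cumsum.
    Zero conditional mass falls back to a uniform draw over the subject's
    candidate points.
    """
    lo = np.searchsorted(est.support_right, L, side="right")
    hi = np.searchsorted(est.support_right, R, side="right")
    csum = np.concatenate(([0.0], np.cumsum(est.mass)))
    lo_c = csum[np.minimum(lo, len(est.mass))]
    hi_c = csum[np.minimum(np.maximum(hi, lo), len(est.mass))]
    total = hi_c - lo_c
    u = rng.uniform(size=len(L))
    zero = total <= 0.0
    target = lo_c + u * total
    j = np.searchsorted(np.cumsum(est.mass), target, side="left")
    # clamp into the subject's support run (guards exact-tie edge cases)
    j = np.clip(j, lo, np.maximum(hi - 1, lo))
    j = np.minimum(j, len(est.mass) - 1)
    out = est.support_right[j]
    n_fb = int(zero.sum())
    if n_fb:
        warnings.warn(
            f"{n_fb} subjects with zero NPMLE mass on (L, R]; uniform fallback"
        )
        fb, _ = _draw_uniform_candidates(
            cand, L[zero], R[zero], rng
        )
        out = out.copy()
        out[zero] = fb
    return out, n_fb


def _assemble(
    data: pd.DataFrame,
    rep: int,
    t0_draw,
    t1_draw,
    n_fallback: int,
) -> ImputedDataset:
    """Build the completed pre-/post-IE views from imputed event times."""
    Z = data["Z"].to_numpy()
    L = data["L"].to_numpy(dtype=float)
    W = data["W"].to_numpy(dtype=float)
    delta = data["delta"].to_numpy()
    x = (data["group"].to_numpy() == "A").astype(int)

    t0_time = np.where(Z == 1, W, np.where(delta == 1, t0_draw, L))
    t0_event = ((delta == 1) & (Z == 0)).astype(int)
    t0 = pd.DataFrame({"time": t0_time, "event": t0_event, "x": x, "Z": Z, "W": W})

    z1 = Z == 1
    t1_time = np.where(delta[z1] == 1, t1_draw[z1], L[z1])
    t1 = pd.DataFrame(
        {
            "time": t1_time,
            "event": delta[z1].astype(int),
            "x": x[z1],
            "W": W[z1],
        }
    )
    return ImputedDataset(rep=rep, t0=t0, t1=t1, n_fallback=n_fallback)


def impute_uniform(
    data: pd.DataFrame,
    cands: tuple[CandidateSet, CandidateSet],
    rng: np.random.Generator,
    rep: int = 1,
) -> ImputedDataset:
    """One uniform-weight imputation of the cohort.

    Event subjects are imputed uniformly over the stratum candidate points
    inside their censoring interval; censoring structure follows the module
    docstring.
    """
    c0, c1 = cands
    Z = data["Z"].to_numpy()
    L = data["L"].to_numpy(dtype=float)
    R = data["R"].to_numpy(dtype=float)
    delta = data["delta"].to_numpy()
    n = len(data)

    t0_draw = np.full(n, np.nan)
    t1_draw = np.full(n, np.nan)
    n_fb = 0
    m0 = (delta == 1) & (Z == 0)
    if m0.any():
        t0_draw[m0], fb = _draw_uniform_candidates(c0, L[m0], R[m0], rng)
        n_fb += fb
    m1 = (delta == 1) & (Z == 1)
    if m1.any():
        t1_draw[m1], fb = _draw_uniform_candidates(c1, L[m1], R[m1], rng)
        n_fb += fb
    return _assemble(data, rep, t0_draw, t1_draw, n_fb)


def impute_weighted(
    data: pd.DataFrame,
    est0: NPMLEEstimate | None,
    est1: NPMLEEstimate | None,
    rng: np.random.Generator,
    rep: int = 1,
    cands: tuple[CandidateSet, CandidateSet] | None = None,
) -> ImputedDataset:
    """One NPMLE-weighted imputation of the cohort.

    Identical censoring structure to :func:`impute_uniform`, but event times
    are drawn from the stratum NPMLE restricted to ``(L, R]``.  ``cands``
    supplies the uniform fallback sets (rebuilt from the data if omitted).
    """
    if cands is None:
        cands = build_candidate_sets(data)
    c0, c1 = cands
    Z = data["Z"].to_numpy()
    L = data["L"].to_numpy(dtype=float)
    R = data["R"].to_numpy(dtype=float)
    delta = data["delta"].to_numpy()
    n = len(data)

    t0_draw = np.full(n, np.nan)
    t1_draw = np.full(n, np.nan)
    n_fb = 0
    m0 = (delta == 1) & (Z == 0)
    if m0.any():
        if est0 is None:
            raise ValueError("est0 required: pre-IE events present")
        t0_draw[m0], fb = _draw_npmle_candidates(est0, c0, L[m0], R[m0], rng)
        n_fb += fb
    m1 = (delta == 1) & (Z == 1)
    if m1.any():
        if est1 is None:
            raise ValueError("est1 required: post-IE events present")
        t1_draw[m1], fb = _draw_npmle_candidates(est1, c1, L[m1], R[m1], rng)
        n_fb += fb
    return _assemble(data, rep, t0_draw, t1_draw, n_fb)


def fit_stratum_npmle(
    data: pd.DataFrame, tol: float = 1e-6, max_iter: int = 5000
) -> tuple[NPMLEEstimate | None, NPMLEEstimate | None]:
    """Fit the two stratum NPMLEs used as imputation weights.

    Pre-IE (k=0): all subjects, with IE subjects right-censored at ``W``.
    Post-IE (k=1): IE subjects only, intervals ``(L, R]`` left-truncated at
    ``W``.  A stratum with no subjects returns ``None``.
    """
    Z = data["Z"].to_numpy()
    L = data["L"].to_numpy(dtype=float)
    R = data["R"].to_numpy(dtype=float)
    W = data["W"].to_numpy(dtype=float)
    left0 = np.where(Z == 1, W, L)
    right0 = np.where(Z == 1, np.inf, R)
    est0 = turnbull_npmle(left0, right0, tol=tol, max_iter=max_iter)
    z1 = Z == 1
    est1 = None
    if z1.any():
        est1 = turnbull_npmle(L[z1], R[z1], trunc_left=W[z1], tol=tol, max_iter=max_iter)
    return est0, est1


def score_imputed(imp: ImputedDataset) -> ScorePair:
    """Nam–Zelen score pair from one completed dataset.

    ``S0, V0`` come from the pre-IE view (right-censored data; IE subjects
    leave the pre-IE risk set at ``W`` through the z-process) and ``S1, V1``
    from the post-IE view (left-truncated right-censored data; a subject
    enters the post-IE risk set at its own ``W``).
    """
    p0 = nam_zelen_score(
        imp.t0["time"], imp.t0["event"], imp.t0["x"], imp.t0["Z"], imp.t0["W"]
    )
    if len(imp.t1):
        p1 = nam_zelen_score(
            imp.t1["time"],
            imp.t1["event"],
            imp.t1["x"],
            np.ones(len(imp.t1), dtype=int),
            imp.t1["W"],
        )
    else:
        p1 = ScorePair(0.0, 0.0, 0.0, 0.0)
    return ScorePair(S0=p0.S0, V0=p0.V0, S1=p1.S1, V1=p1.V1)


@dataclass
class MITestResult:
    """Pooled multiple-imputation test result.

    ``V1_*`` are the additive combined variances (within + (1 + 1/M) *
    between), ``V2_*`` the subtractive ones (within − between).  When a
    subtractive variance is nonpositive the additive one is substituted for
    that component and the component index recorded in ``v2_guarded``.
    """

    S_bar_0: float
    S_bar_1: float
    within0: float
    within1: float
    between0: float
    between1: float
    V1_0: float
    V1_1: float
    V2_0: float
    V2_1: float
    chi2_add: float
    p_add: float
    chi2_sub: float
    p_sub: float
    df_add: int
    df_sub: int
    M: int
    v2_guarded: tuple[int, ...] = ()
    summary_add: ChiSquareSummary | None = None
    summary_sub: ChiSquareSummary | None = None
    n_fallback: int = 0

    def row(self) -> dict:
        """Flat single-row record for delimited output."""
        return {
            k: getattr(self, k)
            for k in (
                "S_bar_0",
                "S_bar_1",
                "V1_0",
                "V1_1",
                "V2_0",
                "V2_1",
                "chi2_add",
                "p_add",
                "chi2_sub",
                "p_sub",
                "M",
            )
        }


def pool_rubin(pairs: list[ScorePair]) -> MITestResult:
    """Pool M score pairs with the within/between variance combination.

    ``S_bar_k`` is the mean score; ``within_k`` the mean of the per-imputation
    null variances; ``between_k`` the sample variance of the scores across
    imputations (0 when ``M = 1``, with a warning).  The additive and
    subtractive combined variances obey the identity
    ``V1 - V2 = (2 + 1/M) * between``.
    """
    M = len(pairs)
    if M < 1:
        raise ValueError("need at least one imputation")
    if M == 1:
        warnings.warn("M = 1: between-imputation variance is zero")
    S = np.array([[p.S0, p.S1] for p in pairs])
    V = np.array([[p.V0, p.V1] for p in pairs])
    s_bar = S.mean(axis=0)
    within = V.mean(axis=0)
    between = S.var(axis=0, ddof=1) if M > 1 else np.zeros(2)
    v_add = within + (1.0 + 1.0 / M) * between
    v_sub = within - between

    guarded = []
    v_sub_eff = v_sub.copy()
    for k in range(2):
        if v_sub[k] <= 0.0 and v_add[k] > 0.0:
            v_sub_eff[k] = v_add[k]
            guarded.append(k)
            warnings.warn(
                f"subtractive variance nonpositive for component {k}; "
                "falling back to the additive form"
            )
        elif v_sub[k] < 0.0:
            v_sub_eff[k] = 0.0

    sum_add = chi2_tests(s_bar[0], v_add[0], s_bar[1], v_add[1])
    sum_sub = chi2_tests(s_bar[0], v_sub_eff[0], s_bar[1], v_sub_eff[1])
    return MITestResult(
        S_bar_0=float(s_bar[0]),
        S_bar_1=float(s_bar[1]),
        within0=float(within[0]),
        within1=float(within[1]),
        between0=float(between[0]),
        between1=float(between[1]),
        V1_0=float(v_add[0]),
        V1_1=float(v_add[1]),
        V2_0=float(v_sub[0]),
        V2_1=float(v_sub[1]),
        chi2_add=sum_add.chi2_2df,
        p_add=sum_add.p_2df,
        chi2_sub=sum_sub.chi2_2df,
        p_sub=sum_sub.p_2df,
        df_add=sum_add.df,
        df_sub=sum_sub.df,
        M=M,
        v2_guarded=tuple(guarded),
        summary_add=sum_add,
        summary_sub=sum_sub,
    )


def mi_test(
    data: pd.DataFrame,
    method: str = "uniform",
    M: int = 10,
    rng: np.random.Generator | int | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> MITestResult:
    """Full multiple-imputation two-sample test on an interval-censored cohort.

    Parameters
    ----------
    data
        Cohort table with columns ``group, L, R, delta, Z, W`` (the
        :mod:`icie.simulate` cohort layout; ``T_true`` is ignored).
    method
        ``"uniform"`` or ``"weighted"`` (NPMLE sampling weights).
    M
        Number of imputations (default 10).
    rng
        Seed or generator; per-imputation substreams are spawned from it so
        results do not depend on how many imputations precede a given one.
    """
    if method not in ("uniform", "weighted"):
        raise ValueError("method must be 'uniform' or 'weighted'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cands = build_candidate_sets(data)
    est0 = est1 = None
    if method == "weighted":
        est0, est1 = fit_stratum_npmle(data, tol=tol, max_iter=max_iter)
    streams = rng.spawn(M)
    pairs = []
    n_fb = 0
    for r in range(M):
        if method == "uniform":
            imp = impute_uniform(data, cands, streams[r], rep=r + 1)
        else:
            imp = impute_weighted(data, est0, est1, streams[r], rep=r + 1, cands=cands)
        n_fb += imp.n_fallback
        pairs.append(score_imputed(imp))
    result = pool_rubin(pairs)
    result.n_fallback = n_fb
    return result
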