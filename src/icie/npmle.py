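"""Turnbull NPMLE for interval-censored data with left truncation.

The nonparametric maximum likelihood estimator of a survival distribution
from interval-censored observations ``T in (L, R]``, optionally each paired
with a left-truncation set ``(W, inf)``, places all its mass on the innermost
(Turnbull) intervals — maximal intervals ``(l, r]`` whose endpoints come from
the observed (and truncation) endpoints and that contain no other endpoint.
The masses are the fixed point of the self-consistency / EM iteration; with
truncation the E-step additionally imputes the expected "ghost" subjects
falling outside each truncation region.

Two stratum-specific candidate-point sets drive the downstream imputation:
the pre-IE set collects interval endpoints of subjects without the
intermediate event plus the IE times of subjects with it (those act as
right-censoring times for the pre-IE course), while the post-IE set collects
endpoints and IE times of subjects with the event only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CandidateSet",
    "NPMLEEstimate",
    "ZeroMassError",
    "build_candidate_sets",
    "turnbull_intervals",
    "turnbull_npmle",
    "conditional_mass",
]


class ZeroMassError(ValueError):
    """The NPMLE assigns zero mass to the requested interval."""


@dataclass
class CandidateSet:
    """Ordered distinct mass-point candidates for one IE stratum.

    ``points`` always starts at 0 and ends at ``inf``; the interior points
    are the distinct data endpoints relevant to the stratum.
    """

    stratum: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size < 2 or pts[0] != 0.0 or not np.isinf(pts[-1]):
            raise ValueError("candidate points must start at 0 and end at inf")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("candidate points must be strictly increasing")
        self.points = pts

    @property
    def is_empty(self) -> bool:
        """True when the stratum contributed no data points (only {0, inf})."""
        return self.points.size == 2

    def subset_range(self, L, R) -> tuple[np.ndarray, np.ndarray]:
        """Index range [lo, hi) of candidate points in ``(L, R]`` (vectorized)."""
        lo = np.searchsorted(self.points, L, side="right")
        hi = np.searchsorted(self.points, R, side="right")
        return lo, hi

    def subset(self, L: float, R: float) -> np.ndarray:
        """Candidate points ``{s : L < s <= R}`` for one subject."""
        lo, hi = self.subset_range(L, R)
        return self.points[int(lo) : int(hi)]


def build_candidate_sets(data: pd.DataFrame) -> tuple[CandidateSet, CandidateSet]:
    """Assemble the pre-IE (k=0) and post-IE (k=1) candidate-point sets.

    Subjects without the IE contribute their interval endpoints ``L, R`` to
    the k=0 set; subjects with the IE contribute their IE time ``W`` to the
    k=0 set (as a right-censoring time for the pre-IE course) and ``L, R, W``
    to the k=1 set.  An empty k=1 set (no IE subjects) is legal and reduces
    to ``{0, inf}``.
    """
    if len(data) == 0:
        raise ValueError("cannot build candidate sets from empty data")
    Z = data["Z"].to_numpy()
    L = data["L"].to_numpy(dtype=float)
    R = data["R"].to_numpy(dtype=float)
    W = data["W"].to_numpy(dtype=float)
    z0 = Z == 0
    z1 = Z == 1
    pts0 = np.concatenate(([0.0], L[z0], R[z0], W[z1], [np.inf]))
    pts1 = np.concatenate(([0.0], L[z1], R[z1], W[z1], [np.inf]))
    pts0 = np.unique(pts0[~np.isnan(pts0)])
    pts1 = np.unique(pts1[~np.isnan(pts1)])
    return CandidateSet(0, pts0), CandidateSet(1, pts1)


@dataclass
class NPMLEEstimate:
    """NPMLE support intervals ``(left, right]`` with probability masses."""

    support_left: np.ndarray
    support_right: np.ndarray
    mass: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def survival(self, times) -> np.ndarray:
        """Right-continuous survival step function S(t) = P(T > t).

        Within a Turnbull interval the NPMLE is unidentified; this evaluates
        the version that drops each interval's mass at its right endpoint.
        """
        t = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.array([self.mass[self.support_right > v].sum() for v in t])
        return out if np.ndim(times) else float(out[0])


def turnbull_intervals(
    left: np.ndarray,
    right: np.ndarray,
    trunc_left: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Innermost (Turnbull) intervals from observation and truncation endpoints.

    An innermost interval ``(l, r]`` pairs a left endpoint with the next
    right endpoint in the pooled sorted order with no endpoint in between;
    truncation left endpoints participate as left endpoints (they may carry
    positive mass).  Right endpoints sort before left endpoints at ties so
    that abutting intervals such as ``(1,2], (2,3]`` yield both intervals
    rather than an empty one.
    """
    lefts = np.asarray(left, dtype=float)
    rights = np.asarray(right, dtype=float)
    if trunc_left is not None:
        lefts = np.concatenate([lefts, np.asarray(trunc_left, dtype=float)])
    vals = np.concatenate([rights, lefts])
    # type code: 0 = right endpoint, 1 = left endpoint; rights first at ties
    typ = np.concatenate([np.zeros(len(rights), int), np.ones(len(lefts), int)])
    order = np.lexsort((typ, vals))
    q_left, q_right = [], []
    cur_left = None
    for v, t in zip(vals[order], typ[order]):
        if t == 1:
            cur_left = v
        elif cur_left is not None:
            q_left.append(cur_left)
            q_right.append(v)
            cur_left = None
    return np.asarray(q_left), np.asarray(q_right)


def _exact_shift(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Open the left endpoint of exact observations (L == R) by a relative eps."""
    exact = left == right
    if np.any(exact):
        scale = np.maximum(np.abs(right), 1.0)
        left = np.where(exact, right - 1e-9 * scale, left)
    return left


def turnbull_npmle(
    left,
    right,
    trunc_left=None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> NPMLEEstimate:
    """Fit the NPMLE by the self-consistency EM iteration.

    Parameters
    ----------
    left, right
        Interval endpoints per subject, ``T in (L, R]``; ``R = inf`` encodes
        right censoring and ``L == R`` an exact observation (handled by
        opening the left endpoint infinitesimally).
    trunc_left
        Optional per-subject left-truncation times ``W`` (``T`` observed only
        if ``T > W``); NaN or ``-inf``/0 entries mean no truncation.
    tol
        Convergence tolerance on the max absolute mass change (also applied
        to the log-likelihood change).
    max_iter
        Iteration cap; exceeding it returns ``converged=False``.

    Notes
    -----
    With truncation the E-step adds the expected ghost counts outside each
    subject's truncation region, following Turnbull's original treatment.
    The log-likelihood ``sum_i log(alpha_i' p) - log(beta_i' p)`` is
    nondecreasing along the iteration.
    """
    L = np.asarray(left, dtype=float)
    R = np.asarray(right, dtype=float)
    n = L.size
    if n == 0:
        raise ValueError("cannot fit NPMLE to empty data")
    if np.any(R < L):
        raise ValueError("intervals must satisfy L <= R")
    L = _exact_shift(L, R)

    tr = None
    if trunc_left is not None:
        tr = np.asarray(trunc_left, dtype=float).copy()
        tr[np.isnan(tr)] = -np.inf
        if np.any(tr > L):
            raise ValueError("truncation set must contain its interval (W <= L)")

    ql, qr = turnbull_intervals(L, R, None if tr is None else tr[np.isfinite(tr)])
    m = ql.size
    if m == 0:
        raise ValueError("no innermost intervals — degenerate input")

    # membership: innermost interval j lies inside subject i's sets
    alpha = (ql[None, :] >= L[:, None]) & (qr[None, :] <= R[:, None])
    if not alpha.any(axis=1).all():
        raise ValueError("a subject's interval contains no innermost interval")
    beta = None
    if tr is not None and np.any(np.isfinite(tr)):
        beta = ql[None, :] >= tr[:, None]
        if not beta.any(axis=1).all():
            raise ValueError("a truncation region contains no innermost interval")
    alpha_f = alpha.astype(float)
    beta_f = beta.astype(float) if beta is not None else None

    p = np.full(m, 1.0 / m)
    loglik = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        a = alpha_f @ p  # P(L_i < T <= R_i)
        if beta_f is not None:
            b = beta_f @ p  # P(T in truncation region i)
            new_ll = float(np.sum(np.log(a)) - np.sum(np.log(b)))
            inv_b = 1.0 / b
            # observed E-step counts + ghost counts outside truncation regions
            weight = alpha_f.T @ (1.0 / a) + (inv_b.sum() - beta_f.T @ inv_b)
        else:
            new_ll = float(np.sum(np.log(a)))
            weight = alpha_f.T @ (1.0 / a)
        p_new = p * weight
        p_new /= p_new.sum()
        delta_mass = float(np.max(np.abs(p_new - p)))
        delta_ll = new_ll - loglik
        p, loglik = p_new, new_ll
        if delta_mass < tol or (np.isfinite(delta_ll) and abs(delta_ll) < tol):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Turnbull EM did not converge in {max_iter} iterations "
            f"(last mass change {delta_mass:.2e})",
            RuntimeWarning,
        )
    return NPMLEEstimate(ql, qr, p, loglik, it, converged)


def conditional_mass(
    est: NPMLEEstimate, interval: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """NPMLE mass restricted to ``(L, R]`` and renormalized.

    Returns ``(points, probs)`` where the points are the right endpoints of
    the retained support intervals — the discrete sampling distribution for
    imputation conditional on ``L < T <= R``.  Raises :class:`ZeroMassError`
    when the estimate puts no mass on the interval (callers fall back to a
    uniform draw over the subject's candidate points).
    """
    Lq, Rq = interval
    # membership via the representative atoms: support intervals never
    # straddle a subject endpoint (all endpoints enter the innermost-interval
    # computation), so this equals whole-interval containment in-pipeline
    inside = (est.support_right > Lq) & (est.support_right <= Rq)
    total = est.mass[inside].sum()
    if total <= 0.0:
        raise ZeroMassError(f"NPMLE mass on ({Lq}, {Rq}] is zero")
    return est.support_right[inside], est.mass[inside] / total
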