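"""Synthetic two-group cohorts with an intermediate clinical event (IE).

The generator follows a change-of-hazard model: each subject carries a latent
waiting time ``W ~ Exponential(mu_g)`` until the IE and a latent pre-IE event
time ``T0 ~ Exponential(lambda0_g)``.  If the IE arrives first (``W <= T0``,
indicator ``Z = 1``), the event time is redrawn from the post-IE exponential
with rate ``lambda1_g = 1/m1_g`` left-truncated at ``W`` (the subject has, by
construction, survived to ``W`` — the length-bias mechanism).  Censoring is an
independent Bernoulli flag with probability ``c_p``, and a periodic visit
process with missed visits converts the latent time into a censoring interval
``(L, R]`` with ``R = inf`` for right-censored subjects.

The IE probability per group is ``theta_g = mu_g / (mu_g + lambda0_g)``; the
scenario configuration is parameterized by ``theta_g`` and ``lambda0_g``, from
which ``mu_g = theta_g * lambda0_g / (1 - theta_g)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "generate_latent",
    "schedule_visits",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

GROUPS = ("A", "B")

#: columns of a cohort table, in canonical order
COHORT_COLUMNS = ["id", "group", "L", "R", "delta", "Z", "W", "T_true"]


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    Parameters
    ----------
    theta_A, theta_B
        Probability of experiencing the IE in each group, in [0, 1).
    lambda0_A, lambda0_B
        Pre-IE event hazard rates (1/time), strictly positive.
    m1_A, m1_B
        Post-IE mean times to failure (time units); the post-IE hazard is
        ``lambda1_g = 1 / m1_g``.
    c_p
        Censoring probability (independent Bernoulli).
    psi
        Inter-visit interval (time units).
    miss_prob_year1, miss_prob_later
        Per-visit miss probabilities before and after time 1.0.  The first
        visit is always attended.
    n_per_group
        Subjects per group.
    n_reps
        Replications when the scenario drives a simulation table.
    M
        Imputations per multiple-imputation test.
    seed
        Root RNG seed for the scenario.
    """

    theta_A: float = 0.5
    theta_B: float = 0.5
    lambda0_A: float = 1.0
    lambda0_B: float = 1.0
    m1_A: float = 2.0
    m1_B: float = 2.0
    c_p: float = 0.0
    psi: float = 0.5
    miss_prob_year1: float = 0.1
    miss_prob_later: float = 0.2
    n_per_group: int = 200
    n_reps: int = 1000
    M: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            th = self._field("theta", g)
            if not 0.0 <= th < 1.0:
                raise ValueError(f"theta_{g} must lie in [0, 1), got {th}")
            if self._field("lambda0", g) <= 0:
                raise ValueError(f"lambda0_{g} must be positive")
            if self._field("m1", g) <= 0:
                raise ValueError(f"m1_{g} must be positive")
        if not 0.0 <= self.c_p < 1.0:
            raise ValueError("c_p must lie in [0, 1)")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        for p in (self.miss_prob_year1, self.miss_prob_later):
            if not 0.0 <= p < 1.0:
                raise ValueError("miss probabilities must lie in [0, 1)")
        if self.n_per_group < 0 or self.n_reps < 0 or self.M < 1:
            raise ValueError("n_per_group, n_reps must be >= 0 and M >= 1")

    def _field(self, name: str, group: str) -> float:
        return getattr(self, f"{name}_{group}")

    def mu(self, group: str) -> float:
        """IE hazard ``mu_g = theta_g * lambda0_g / (1 - theta_g)``."""
        th = self._field("theta", group)
        return th * self._field("lambda0", group) / (1.0 - th)

    def lambda1(self, group: str) -> float:
        """Post-IE event hazard ``1 / m1_g``."""
        return 1.0 / self._field("m1", group)

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


def generate_latent(
    cfg: ScenarioConfig,
    group: str,
    rng: np.random.Generator,
    n: int | None = None,
) -> pd.DataFrame:
    """Draw latent times for one group.

    Returns a frame with columns ``T_true, W, Z, delta``.  ``W`` is NaN for
    subjects who never experience the IE (``Z = 0``).  Draw order within the
    stream is fixed: W, T0, truncated-T1 uniforms, delta.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if n is None:
        n = cfg.n_per_group
    mu = cfg.mu(group)
    lam0 = cfg._field("lambda0", group)
    lam1 = cfg.lambda1(group)

    W = rng.exponential(1.0 / mu, n) if mu > 0 else np.full(n, np.inf)
    T0 = rng.exponential(1.0 / lam0, n)
    Z = W <= T0
    # Left-truncated post-IE time via inversion: Q1(T1) ~ U(0, Q1(W)),
    # i.e. T1 = W - log(U)/lambda1 (memorylessness of the exponential).
    U = rng.uniform(size=n)
    T1 = W - np.log(U) / lam1
    T = np.where(Z, T1, T0)
    delta = (rng.uniform(size=n) >= cfg.c_p).astype(int)
    return pd.DataFrame(
        {
            "T_true": T,
            "W": np.where(Z, W, np.nan),
            "Z": Z.astype(int),
            "delta": delta,
        }
    )


def schedule_visits(
    T_true: float,
    W: float | None,
    Z: int,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Convert one latent event time into a visit-bracketed interval.

    The first visit is at ``E ~ U(0, psi)`` (``U(W, W + psi)`` when the IE
    occurred, since follow-up of the post-IE course starts at the observed
    IE) and is always attended; later visits at ``E + k*psi`` are each missed
    independently with probability ``miss_prob_year1`` before time 1.0 and
    ``miss_prob_later`` afterward.  Returns ``(L, R)`` where ``L`` is the
    largest attended visit below ``T_true`` (falling back to the follow-up
    origin — 0, or ``W`` when ``Z = 1``) and ``R`` the smallest attended
    visit at or above it.  Right censoring (``R = inf``) is applied by the
    caller from ``delta``.
    """
    origin = float(W) if Z else 0.0
    E = origin + rng.uniform(0.0, cfg.psi)
    L = origin
    k = 0
    while True:
        t_visit = E + k * cfg.psi
        if k == 0:
            attended = True
        else:
            miss = cfg.miss_prob_year1 if t_visit < 1.0 else cfg.miss_prob_later
            attended = rng.uniform() >= miss
        if attended:
            if t_visit < T_true:
                L = t_visit
            else:
                return L, t_visit
        k += 1


def _schedule_visits_vec(
    T: np.ndarray,
    W: np.ndarray,
    Z: np.ndarray,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized visit bracketing for a whole group.

    Iterates over the visit index, drawing one attendance uniform per subject
    per visit round, until every subject has an attended visit at/after its
    event time.  The visit count is uncapped; the loop terminates with
    probability one because miss probabilities are < 1.
    """
    n = len(T)
    origin = np.where(Z == 1, W, 0.0)
    E = origin + rng.uniform(0.0, cfg.psi, n)
    L = origin.copy()
    R = np.full(n, np.inf)
    done = np.zeros(n, dtype=bool)
    k = 0
    while not done.all():
        t_visit = E + k * cfg.psi
        if k == 0:
            attended = np.ones(n, dtype=bool)
        else:
            miss = np.where(t_visit < 1.0, cfg.miss_prob_year1, cfg.miss_prob_later)
            attended = rng.uniform(size=n) >= miss
        act = attended & ~done
        before = act & (t_visit < T)
        L[before] = t_visit[before]
        closing = act & (t_visit >= T)
        R[closing] = t_visit[closing]
        done |= closing
        k += 1
        if k > 100_000:  # unreachable in practice; guards an infinite loop
            raise RuntimeError("visit schedule failed to bracket all event times")
    return L, R


def generate_cohort(
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a full two-group cohort as a tidy table.

    Columns: ``id, group, L, R, delta, Z, W, T_true``.  ``R`` is ``inf`` for
    right-censored subjects (``delta = 0``) and ``W`` is NaN when ``Z = 0``.
    Stream order per group: latent draws, then visit-schedule draws; group A
    before group B.  With a fixed seed the cohort is reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frames = []
    offset = 0
    for g in GROUPS:
        lat = generate_latent(cfg, g, rng)
        T = lat["T_true"].to_numpy()
        W = lat["W"].to_numpy()
        Z = lat["Z"].to_numpy()
        delta = lat["delta"].to_numpy()
        L, R = _schedule_visits_vec(T, W, Z, cfg, rng)
        R = np.where(delta == 1, R, np.inf)
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(offset, offset + len(T)),
                    "group": g,
                    "L": L,
                    "R": R,
                    "delta": delta,
                    "Z": Z,
                    "W": W,
                    "T_true": T,
                }
            )
        )
        offset += len(T)
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort to delimited text (``inf`` for unbounded R, empty W)."""
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "T_true"]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    if "T_true" not in df.columns:
        df["T_true"] = np.nan
    return df[COHORT_COLUMNS]
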