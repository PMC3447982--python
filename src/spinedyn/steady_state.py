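"""Master-equation steady state of a synapse with M close appositions.

The synapse between one neuron pair consists of M close appositions, each
hosting a contact that is unrealized, inactive (thin spine) or active (large
spine).  The synapse state is the pair (n_active, n_inactive); the allowed
transitions are creation (unrealized -> inactive, rate gamma per unrealized
site), maturation (inactive -> active), shrinkage (active -> inactive) and
pruning (inactive -> unrealized), with per-contact rates evaluated at the
pre-transition active count and multiplied by the number of eligible
contacts.  The state probabilities evolve under a Master equation whose
generator is column-stochastic; for gamma > 0 and delta > 0 the chain is
irreducible, so by Perron-Frobenius there is a unique stationary
distribution, obtained here by a dense linear solve (with a null-space
fallback).  Stationary joints for each M are averaged over the empirical
close-apposition distribution a(M) to produce the observable marginals of
total, active and inactive contact numbers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping

import numpy as np
import scipy.linalg

from .rates import PlasticityParams, contact_rates

logger = logging.getLogger(__name__)

__all__ = [
    "StateSpace",
    "GeneratorMatrix",
    "StationaryResult",
    "enumerate_states",
    "build_generator",
    "stationary_distribution",
    "apposition_average",
    "independent_contact_limit",
    "solve_model",
]


@dataclass(frozen=True)
class StateSpace:
    """Ordered enumeration of synapse states (n_active, n_inactive) for M sites."""

    m: int
    states: tuple[tuple[int, int], ...]
    index: Mapping[tuple[int, int], int]

    def __len__(self) -> int:
        return len(self.states)


def enumerate_states(m: int) -> StateSpace:
    """All states with n_active + n_inactive <= m, lexicographic in (a, i).

    The state count is (m+1)(m+2)/2.
    """
    if m < 0:
        raise ValueError(f"number of close appositions must be >= 0, got {m}")
    states = tuple(
        (a, i) for a in range(m + 1) for i in range(m - a + 1)
    )
    index = {s: k for k, s in enumerate(states)}
    return StateSpace(m=m, states=states, index=index)


@dataclass(frozen=True)
class GeneratorMatrix:
    """Column-stochastic rate matrix Q over a StateSpace (Q[j, k] = rate k -> j)."""

    m: int
    space: StateSpace
    matrix: np.ndarray

    def __post_init__(self) -> None:
        col_sums = self.matrix.sum(axis=0)
        if np.max(np.abs(col_sums)) > 1e-9:
            raise ValueError("generator columns must sum to zero")


def build_generator(m: int, params: PlasticityParams) -> GeneratorMatrix:
    """Assemble the Master-equation generator for M close appositions.

    From state (a, i) with u = m - a - i unrealized sites:

    - creation   (a, i) -> (a, i+1) at gamma * u
    - maturation (a, i) -> (a+1, i-1) at i * r_mat(a)
    - shrinkage  (a, i) -> (a-1, i+1) at a * r_shr(a)
    - pruning    (a, i) -> (a, i-1) at i * r_prn(a)

    where the per-contact rates are evaluated at the pre-transition active
    count a.  The diagonal is set so that every column sums to zero.
    """
    space = enumerate_states(m)
    n = len(space)
    q = np.zeros((n, n))
    # per-contact rates only depend on a
    per_a = [contact_rates(a, params) for a in range(m + 1)]
    for k, (a, i) in enumerate(space.states):
        u = m - a - i
        r_mat, r_shr, r_prn = per_a[a]
        if u > 0 and params.gamma > 0:
            q[space.index[(a, i + 1)], k] += params.gamma * u
        if i > 0:
            if r_mat > 0:
                q[space.index[(a + 1, i - 1)], k] += i * r_mat
            if r_prn > 0:
                q[space.index[(a, i - 1)], k] += i * r_prn
        if a > 0 and r_shr > 0:
            q[space.index[(a - 1, i + 1)], k] += a * r_shr
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=0))
    return GeneratorMatrix(m=m, space=space, matrix=q)


def stationary_distribution(gen: GeneratorMatrix) -> np.ndarray:
    """Unique stationary distribution P solving Q P = 0, sum(P) = 1.

    Solved by replacing the normalization row in the dense linear system,
    with an SVD null-space fallback.  Entries are clipped at zero (tiny
    negatives from roundoff) and renormalized; the residual ||Q P||_inf is
    checked against 1e-10.  A reducible chain with gamma = 0 has the empty
    synapse as absorbing state; its point-mass solution is returned with a
    warning.
    """
    n = len(gen.space)
    q = gen.matrix
    empty = gen.space.index[(0, 0)]
    if np.allclose(q[:, empty], 0.0) and n > 1:
        # no creation: (0, 0) is absorbing
        warnings.warn(
            "generator is reducible (no creation from the empty synapse); "
            "returning the absorbing-state point mass",
            stacklevel=2,
        )
        p = np.zeros(n)
        p[empty] = 1.0
        return p

    a = q.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        with warnings.catch_warnings():
            # extreme rate ratios make the system ill-conditioned; the
            # residual check below decides whether the solution is usable
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            p = scipy.linalg.solve(a, b)
    except scipy.linalg.LinAlgError:
        p = None
    if p is not None and not np.all(np.isfinite(p)):
        p = None
    if p is None or np.max(np.abs(q @ p)) > 1e-10 or p.min() < -1e-9:
        ns = scipy.linalg.null_space(q)
        if ns.shape[1] == 0:
            raise RuntimeError("generator has no stationary solution")
        p = ns[:, 0]
        p = p / p.sum()
    if p.min() < -1e-9:
        raise RuntimeError("stationary solve produced significantly negative mass")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    residual = np.max(np.abs(q @ p))
    if residual > 1e-10:
        raise RuntimeError(f"stationary residual {residual:.3e} exceeds 1e-10")
    return p


def _joint_array(space: StateSpace, p: np.ndarray, size: int) -> np.ndarray:
    """Embed a state-indexed vector into a (size+1, size+1) array over (Na, Ni)."""
    joint = np.zeros((size + 1, size + 1))
    for k, (a, i) in enumerate(space.states):
        joint[a, i] = p[k]
    return joint


@dataclass(frozen=True)
class StationaryResult:
    """Apposition-averaged stationary law of the synapse.

    ``averaged[a, i]`` is the probability of a active and i inactive contacts;
    ``p_total``, ``p_active``, ``p_inactive`` are the marginal pmfs of
    N = Na + Ni, Na and Ni.  ``moments`` holds first moments and sd(N);
    ``corr_ai`` is the Pearson correlation of Na and Ni (nan if degenerate).
    """

    per_m: Mapping[int, np.ndarray]
    averaged: np.ndarray
    p_total: np.ndarray
    p_active: np.ndarray
    p_inactive: np.ndarray
    moments: Mapping[str, float]
    corr_ai: float
    apposition_dist: np.ndarray = field(default=None, repr=False)


def apposition_average(
    per_m: Mapping[int, np.ndarray], a_dist: Mapping[int, float] | np.ndarray
) -> StationaryResult:
    """Average per-M stationary joints over the close-apposition pmf a(M).

    ``per_m`` maps M to either a flat state-vector (in ``enumerate_states(M)``
    order) or an (M+1, M+1) joint array over (Na, Ni).  ``a_dist`` is the pmf
    of M as an array indexed by M or a mapping M -> probability; it must sum
    to one and its support must be covered by ``per_m``.
    """
    if isinstance(a_dist, Mapping):
        a_items = {int(m): float(w) for m, w in a_dist.items()}
    else:
        arr = np.asarray(a_dist, dtype=float)
        a_items = {m: float(w) for m, w in enumerate(arr)}
    total = sum(a_items.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"apposition distribution sums to {total}, expected 1")
    support = [m for m, w in a_items.items() if w > 0]
    missing = [m for m in support if m not in per_m]
    if missing:
        raise ValueError(f"per_m misses apposition counts {missing}")

    m_max = max(support)
    per_m_joints: dict[int, np.ndarray] = {}
    for m in support:
        pm = np.asarray(per_m[m], dtype=float)
        if pm.ndim == 1:
            pm = _joint_array(enumerate_states(m), pm, m)
        per_m_joints[m] = pm

    averaged = np.zeros((m_max + 1, m_max + 1))
    for m in support:
        pm = per_m_joints[m]
        averaged[: pm.shape[0], : pm.shape[1]] += a_items[m] * pm
    averaged /= averaged.sum()

    na = np.arange(m_max + 1)
    p_active = averaged.sum(axis=1)
    p_inactive = averaged.sum(axis=0)
    p_total = np.zeros(2 * m_max + 1)
    for a in range(m_max + 1):
        for i in range(m_max + 1):
            p_total[a + i] += averaged[a, i]
    # trim trailing zeros beyond m_max (Na + Ni <= M <= m_max always)
    p_total = p_total[: m_max + 1]

    mean_a = float(na @ p_active)
    mean_i = float(na @ p_inactive)
    ntot = np.arange(len(p_total))
    mean_n = float(ntot @ p_total)
    var_n = float(((ntot - mean_n) ** 2) @ p_total)
    moments = {
        "mean_active": mean_a,
        "mean_inactive": mean_i,
        "mean_total": mean_n,
        "sd_total": float(np.sqrt(var_n)),
    }

    # Pearson correlation of Na and Ni from the averaged joint
    e_ai = float(na @ averaged @ na)
    var_a = float((na**2) @ p_active) - mean_a**2
    var_i = float((na**2) @ p_inactive) - mean_i**2
    denom = np.sqrt(max(var_a, 0.0) * max(var_i, 0.0))
    corr = (e_ai - mean_a * mean_i) / denom if denom > 1e-15 else float("nan")

    return StationaryResult(
        per_m=per_m_joints,
        averaged=averaged,
        p_total=p_total,
        p_active=p_active,
        p_inactive=p_inactive,
        moments=moments,
        corr_ai=float(corr),
        apposition_dist=np.array(
            [a_items.get(m, 0.0) for m in range(m_max + 1)]
        ),
    )


def independent_contact_limit(m: int, params: PlasticityParams) -> np.ndarray:
    """Closed-form stationary joint for activity-independent rates (w = 0).

    With ``w = lambda_resp * u_epsp = 0`` the transition rates do not depend
    on the active count, so the M contacts evolve independently.  The
    per-contact three-state chain (unrealized -> inactive at gamma, inactive
    -> active at r_mat, inactive -> unrealized at r_prn, active -> inactive
    at r_shr) is a birth-death chain on a path, hence satisfies detailed
    balance; the joint over (Na, Ni) is the multinomial with M trials and
    the per-contact stationary probabilities as cell probabilities.

    Returns the flat state vector in ``enumerate_states(m)`` order.
    """
    if params.trace.w != 0:
        raise ValueError("independent-contact closed form requires w = 0")
    space = enumerate_states(m)
    if m == 0:
        return np.ones(1)
    r_mat, r_shr, r_prn = contact_rates(0, params)
    if params.gamma == 0:
        pi_u, pi_i, pi_a = 1.0, 0.0, 0.0
    else:
        if r_prn <= 0 or r_shr <= 0:
            raise ValueError("closed form requires positive pruning and shrinkage")
        # detailed balance on the path u - i - a
        pi_u = 1.0
        pi_i = params.gamma / r_prn
        pi_a = pi_i * r_mat / r_shr
        z = pi_u + pi_i + pi_a
        pi_u, pi_i, pi_a = pi_u / z, pi_i / z, pi_a / z
    p = np.zeros(len(space))
    for k, (a, i) in enumerate(space.states):
        u = m - a - i
        p[k] = (
            comb(m, a) * comb(m - a, i)
            * pi_a**a * pi_i**i * pi_u**u
        )
    return p


def solve_model(
    params: PlasticityParams, a_dist: Mapping[int, float] | np.ndarray
) -> StationaryResult:
    """Solve the stationary law for every M in the support of a(M) and average."""
    if isinstance(a_dist, Mapping):
        support = [int(m) for m, w in a_dist.items() if w > 0]
    else:
        support = [m for m, w in enumerate(np.asarray(a_dist)) if w > 0]
    per_m = {}
    for m in support:
        gen = build_generator(m, params)
        per_m[m] = stationary_distribution(gen)
    return apposition_average(per_m, a_dist)
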