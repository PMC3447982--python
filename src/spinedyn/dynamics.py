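"""Stochastic simulation, contact lifetimes and spine turnover.

``gillespie_run`` draws exact realizations of the synapse jump process and
serves as the simulation oracle for the Master-equation solver (long-run
occupancies must match the stationary law) and for event counting.

``contact_lifetimes`` evaluates the closed-form expected lifetime of a
contact — the time until it is pruned — under a mean-field freezing of the
other contacts: an inactive contact at active count n matures with rate m(n)
or is pruned with rate q(n); if it matures, it shrinks back with rate s(n+1)
and tries again.  Summing the geometric number of excursions gives

    L_inactive(n) = (1 + m(n) / s(n+1)) / q(n)
    L_active(n)   = 1 / s(n) + L_inactive(n - 1)

``turnover_ratio`` computes the expected spine turnover
(gained + lost) / (2 * observed) per observation window from stationary
event rates, and ``calibrate_timescale`` converts model time to days by
matching a physiological turnover target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .rates import PlasticityParams, contact_rates
from .steady_state import (
    StationaryResult,
    build_generator,
    enumerate_states,
    stationary_distribution,
)

__all__ = [
    "Trajectory",
    "LifetimeCurves",
    "TurnoverReport",
    "gillespie_run",
    "occupancy_from_trajectory",
    "contact_lifetimes",
    "turnover_ratio",
    "calibrate_timescale",
]


@dataclass(frozen=True)
class Trajectory:
    """Event record of one synapse realization.

    ``events`` is a time-ordered list of (time, kind, (n_active, n_inactive))
    with the state after the event; ``initial_state`` is the state at time 0.
    """

    events: tuple[tuple[float, str, tuple[int, int]], ...]
    m: int
    duration: float
    seed: int
    initial_state: tuple[int, int] = (0, 0)


def gillespie_run(
    m: int,
    params: PlasticityParams,
    duration: float,
    seed: int = 0,
    initial_state: tuple[int, int] = (0, 0),
) -> Trajectory:
    """Exact (next-reaction) simulation of the synapse Markov jump process."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    space = enumerate_states(m)
    if initial_state not in space.index:
        raise ValueError(f"initial state {initial_state} invalid for m={m}")

    # per-state event table: (rate, kind, target state)
    per_a = [contact_rates(a, params) for a in range(m + 1)]
    table: list[list[tuple[float, str, tuple[int, int]]]] = []
    for a, i in space.states:
        u = m - a - i
        r_mat, r_shr, r_prn = per_a[a]
        rows = []
        if u > 0 and params.gamma > 0:
            rows.append((params.gamma * u, "creation", (a, i + 1)))
        if i > 0:
            if r_mat > 0:
                rows.append((i * r_mat, "maturation", (a + 1, i - 1)))
            if r_prn > 0:
                rows.append((i * r_prn, "pruning", (a, i - 1)))
        if a > 0 and r_shr > 0:
            rows.append((a * r_shr, "shrinkage", (a - 1, i + 1)))
        table.append(rows)

    rng = np.random.default_rng(seed)
    t = 0.0
    state = initial_state
    events: list[tuple[float, str, tuple[int, int]]] = []
    while True:
        rows = table[space.index[state]]
        total = sum(r for r, _, _ in rows)
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        x = rng.uniform(0.0, total)
        acc = 0.0
        for rate, kind, target in rows:
            acc += rate
            if x < acc:
                state = target
                events.append((t, kind, target))
                break
    return Trajectory(
        events=tuple(events),
        m=m,
        duration=duration,
        seed=seed,
        initial_state=initial_state,
    )


def occupancy_from_trajectory(
    traj: Trajectory, burn_in: float = 0.0
) -> dict[tuple[int, int], float]:
    """Time-weighted occupancy of each state after ``burn_in``; sums to one."""
    if burn_in >= traj.duration:
        raise ValueError("burn-in must be shorter than the trajectory")
    occ: dict[tuple[int, int], float] = {}
    t_prev = 0.0
    state = traj.initial_state
    for t, _, after in list(traj.events) + [(traj.duration, "end", None)]:
        lo = max(t_prev, burn_in)
        if t > lo:
            occ[state] = occ.get(state, 0.0) + (t - lo)
        t_prev = t
        if after is not None:
            state = after
    total = sum(occ.values())
    return {s: w / total for s, w in occ.items()}


@dataclass(frozen=True)
class LifetimeCurves:
    """Expected contact lifetimes, per active count and equilibrium-averaged.

    Lifetimes are in model time units (1/gamma); ``math.inf`` flags a zero
    pruning rate.  The averaged values weight the per-n lifetimes by the
    equilibrium number of eligible contacts: i * P(a, i) for inactive
    contacts at n = a, a * P(a, i) for active ones.
    """

    inactive_by_na: Mapping[int, float]
    active_by_na: Mapping[int, float]
    averaged_inactive: float
    averaged_active: float


def _lifetime_inactive(n: int, params: PlasticityParams) -> float:
    r_mat, _, r_prn = contact_rates(n, params)
    _, r_shr_up, _ = contact_rates(n + 1, params)
    if r_prn <= 0:
        return math.inf
    if r_shr_up <= 0:
        return math.inf  # a matured contact can never return to be pruned
    return (1.0 + r_mat / r_shr_up) / r_prn


def _lifetime_active(n: int, params: PlasticityParams) -> float:
    _, r_shr, _ = contact_rates(n, params)
    if r_shr <= 0:
        return math.inf
    return 1.0 / r_shr + _lifetime_inactive(n - 1, params)


def contact_lifetimes(
    params: PlasticityParams,
    m: int,
    stationary: np.ndarray | None = None,
    weighting: str = "occupancy",
) -> LifetimeCurves:
    """Closed-form contact lifetimes for a synapse with M close appositions.

    ``stationary`` may supply a precomputed joint for M (flat state vector or
    (M+1, M+1) array); otherwise it is solved here.  ``weighting`` selects
    the averaging convention: "occupancy" (default) weights by the number of
    eligible contacts in each state, "state" weights by state probability
    alone over states containing at least one eligible contact.
    """
    if weighting not in ("occupancy", "state"):
        raise ValueError(f"unknown weighting {weighting!r}")
    space = enumerate_states(m)
    if stationary is None:
        stationary = stationary_distribution(build_generator(m, params))
    p = np.asarray(stationary, dtype=float)
    if p.ndim == 2:
        p = np.array([p[a, i] for a, i in space.states])

    inactive = {n: _lifetime_inactive(n, params) for n in range(m)}
    active = {n: _lifetime_active(n, params) for n in range(1, m + 1)}

    w_in = w_ac = 0.0
    s_in = s_ac = 0.0
    for k, (a, i) in enumerate(space.states):
        wi = i * p[k] if weighting == "occupancy" else (p[k] if i > 0 else 0.0)
        wa = a * p[k] if weighting == "occupancy" else (p[k] if a > 0 else 0.0)
        if wi > 0:
            s_in += wi * inactive[a]
            w_in += wi
        if wa > 0:
            s_ac += wa * active[a]
            w_ac += wa
    avg_in = s_in / w_in if w_in > 0 else math.nan
    avg_ac = s_ac / w_ac if w_ac > 0 else math.nan
    return LifetimeCurves(
        inactive_by_na=inactive,
        active_by_na=active,
        averaged_inactive=float(avg_in),
        averaged_active=float(avg_ac),
    )


@dataclass(frozen=True)
class TurnoverReport:
    """Expected spine gain/loss rates and turnover ratio per window."""

    gain_rate: float
    loss_rate: float
    n_spines: float
    ratio: float
    window: float


def turnover_ratio(
    params: PlasticityParams, stationary: StationaryResult, window: float = 1.0
) -> TurnoverReport:
    """Expected turnover ratio (gained + lost) / (2 * observed) per window.

    Gains are creation events (rate gamma per unrealized site), losses are
    pruning events (per-contact pruning rate times inactive count), both
    averaged over the stationary law and the apposition distribution.  At
    stationarity the two rates balance.
    """
    a_dist = stationary.apposition_dist
    gain = loss = 0.0
    for m, weight in enumerate(a_dist):
        if weight <= 0 or m not in stationary.per_m:
            continue
        joint = stationary.per_m[m]
        for a in range(m + 1):
            _, _, r_prn = contact_rates(a, params)
            for i in range(m - a + 1):
                pr = joint[a, i]
                if pr == 0:
                    continue
                gain += weight * pr * params.gamma * (m - a - i)
                loss += weight * pr * i * r_prn
    n_spines = stationary.moments["mean_total"]
    if n_spines <= 0:
        raise ValueError("turnover undefined for a synapse with no spines")
    ratio = (gain + loss) * window / (2.0 * n_spines)
    return TurnoverReport(
        gain_rate=float(gain),
        loss_rate=float(loss),
        n_spines=float(n_spines),
        ratio=float(ratio),
        window=float(window),
    )


def calibrate_timescale(
    report: TurnoverReport, target_ratio: float, target_window: float
) -> float:
    """Days per model time unit so the model matches a measured turnover.

    The model's turnover per unit model time is r = ratio / window; over a
    real window of ``target_window`` days and with omega days per model time
    unit the expected turnover is r * target_window / omega.  Equating it to
    ``target_ratio`` gives omega = r * target_window / target_ratio.
    """
    if target_ratio <= 0 or target_window <= 0:
        raise ValueError("turnover target and window must be positive")
    rate_per_unit = report.ratio / report.window
    if rate_per_unit <= 0:
        raise ValueError("model turnover rate must be positive to calibrate")
    return float(rate_per_unit * target_window / target_ratio)
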