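"""Synthetic inputs for the full analysis pipeline.

Three generators cover everything the pipeline consumes: a truncated,
discretized gamma-shaped close-apposition distribution a(M) matched to a
target mean and sd; forward-sampled contact-number datasets drawn from a
known model's stationary law (for parameter-recovery experiments); and
bimodal histogram templates with suppressed single-contact probability and a
secondary peak, the shape reported for intra-cortical paired recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .inference import ReferenceDataset
from .rates import PlasticityParams
from .steady_state import solve_model

__all__ = [
    "SynthSpec",
    "make_apposition_distribution",
    "sample_reference_dataset",
    "make_bimodal_target",
    "default_fixture_params",
]


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic reference dataset."""

    true_params: PlasticityParams
    apposition_mean: float = 5.0
    apposition_sd: float = 2.0
    m_max: int = 10
    n_pairs: int = 10_000
    observable: str = "total"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apposition_mean <= 0:
            raise ValueError("apposition_mean must be positive")
        if self.m_max < 1:
            raise ValueError("m_max must be at least 1")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        if self.observable not in ("total", "active"):
            raise ValueError(f"unknown observable {self.observable!r}")


def make_apposition_distribution(
    mean: float, sd: float, m_max: int, moment_tol: float = 0.05
) -> np.ndarray:
    """Discretized, truncated gamma pmf over M = 0..m_max with matched moments.

    The gamma shape is set by the target coefficient of variation; the scale
    is found by a one-dimensional root search so that the truncated,
    discretized pmf hits the target mean despite truncation bias.  Mean and
    sd of the result must match the targets within ``moment_tol`` (relative),
    otherwise the moment pair is infeasible on 0..m_max and a ValueError is
    raised.  ``sd`` close to zero degenerates to a point mass at round(mean).
    """
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    if mean >= m_max:
        raise ValueError(f"mean {mean} must be below m_max {m_max}")
    ms = np.arange(m_max + 1)
    if sd < 1e-9:
        pmf = np.zeros(m_max + 1)
        pmf[int(round(mean))] = 1.0
        return pmf

    def pmf_for(shape: float, scale: float) -> np.ndarray:
        edges = np.arange(m_max + 2) - 0.5
        cdf = gamma_dist.cdf(np.clip(edges, 0.0, None), a=shape, scale=scale)
        w = np.diff(cdf)
        total = w.sum()
        if total <= 0:  # all mass beyond the support cap
            raise ValueError("no probability mass on the truncated support")
        return w / total

    def mean_matched(shape: float) -> np.ndarray:
        # inner search: scale such that the truncated, discretized mean hits
        # the target despite truncation bias
        def mean_gap(scale: float) -> float:
            return float(ms @ pmf_for(shape, scale)) - mean

        scale0 = mean / shape
        return pmf_for(shape, brentq(mean_gap, scale0 / 20.0, scale0 * 20.0,
                                     xtol=1e-10))

    def sd_gap(width: float) -> float:
        # truncation narrows the distribution; widen the parent gamma until
        # the realized sd matches
        try:
            pmf = mean_matched((mean / (width * sd)) ** 2)
        except ValueError:
            # parent too wide to hit the mean on this support: overshoot
            return sd
        mu = float(ms @ pmf)
        return float(np.sqrt((ms - mu) ** 2 @ pmf)) - sd

    try:
        width = brentq(sd_gap, 0.3, 3.0, xtol=1e-8)
    except ValueError as exc:
        raise ValueError(
            f"cannot match mean {mean} with sd {sd} on support 0..{m_max}"
        ) from exc
    pmf = mean_matched((mean / (width * sd)) ** 2)
    got_mean = float(ms @ pmf)
    got_sd = float(np.sqrt((ms - got_mean) ** 2 @ pmf))
    if abs(got_mean - mean) > moment_tol * mean or abs(got_sd - sd) > moment_tol * sd:
        raise ValueError(
            f"moment targets infeasible on 0..{m_max}: "
            f"got mean {got_mean:.3f}, sd {got_sd:.3f}"
        )
    return pmf


def sample_reference_dataset(spec: SynthSpec) -> ReferenceDataset:
    """Forward-sample a contact-number dataset from a known model.

    For each neuron pair draw the apposition count M from a(M) and the state
    (Na, Ni) from the model's stationary joint at that M; record the number
    of contacts k (total or active).  Pairs with k >= 1 are "connected":
    their histogram becomes the counts and their fraction the connection
    probability.  Deterministic given ``spec.seed``.
    """
    a_dist = make_apposition_distribution(
        spec.apposition_mean, spec.apposition_sd, spec.m_max
    )
    stationary = solve_model(spec.true_params, a_dist)
    rng = np.random.default_rng(spec.seed)

    n_per_m = rng.multinomial(spec.n_pairs, a_dist)
    ks: list[np.ndarray] = []
    for m, n_m in enumerate(n_per_m):
        if n_m == 0:
            continue
        joint = stationary.per_m.get(m)
        if joint is None:  # a(M) assigns zero mass here
            continue
        flat = joint.ravel()
        states = rng.choice(len(flat), size=n_m, p=flat / flat.sum())
        a, i = np.unravel_index(states, joint.shape)
        ks.append(a if spec.observable == "active" else a + i)
    k = np.concatenate(ks) if ks else np.zeros(0, dtype=int)

    connected = k[k >= 1]
    p_conn = len(connected) / spec.n_pairs
    if p_conn == 0:
        raise ValueError("degenerate sample: no connected pairs")
    values, freqs = np.unique(connected, return_counts=True)
    counts = {int(v): int(f) for v, f in zip(values, freqs)}
    return ReferenceDataset(
        counts=counts,
        p_conn=p_conn,
        u_epsp=spec.true_params.trace.u_epsp,
        apposition_dist=a_dist,
        label=f"synthetic(seed={spec.seed})",
    )


def make_bimodal_target(
    peak_k: int,
    suppression: float = 0.01,
    k_max: int = 8,
    p_conn: float = 0.2,
    width: float = 1.0,
) -> np.ndarray:
    """Bimodal contact-number pmf with suppressed P(1) and a secondary peak.

    The shape template of the experimental histograms: most pairs are
    unconnected (P(0) = 1 - p_conn), single-contact pairs are almost absent
    (P(1) <= suppression * P(peak_k)) and connected pairs cluster in a bump
    around ``peak_k`` contacts.
    """
    if not 2 <= peak_k < k_max:
        raise ValueError("peak_k must satisfy 2 <= peak_k < k_max")
    if not 0.0 <= suppression < 1.0:
        raise ValueError("suppression must lie in [0, 1)")
    if not 0.0 < p_conn < 1.0:
        raise ValueError("p_conn must lie in (0, 1)")
    ks = np.arange(k_max + 1)
    bump = np.exp(-0.5 * ((ks - peak_k) / width) ** 2)
    bump[0] = 0.0
    bump[1] = suppression * bump[peak_k]
    bump = p_conn * bump / bump.sum()
    pmf = bump.copy()
    pmf[0] = 1.0 - p_conn
    return pmf


def default_fixture_params() -> PlasticityParams:
    """A cooperative parameter set with a bimodal stationary contact pmf.

    Maturation, shrinkage and pruning rates all fall off as active contacts
    accumulate (left-saturating laws), so lone contacts are short-lived while
    established multi-contact synapses stabilize each other: the stationary
    total-contact pmf is bimodal with suppressed P(1) and a secondary peak,
    the qualitative shape of the experimental histograms.
    """
    from .rates import RateLaw
    from .trace import TraceParams

    trace = TraceParams(
        tau=1000.0, nu=5.0, c=1.0,
        sigma_thin=1.0, sigma_large=1.0,
        p0=0.5, lambda_resp=0.01, u_epsp=1.0,
    )
    return PlasticityParams(
        maturation=RateLaw(-5.0, 150.0, "thin"),
        shrinkage=RateLaw(-50.0, -30.0, "large"),
        delta=0.05,
        gamma=1.0,
        trace=trace,
    )
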