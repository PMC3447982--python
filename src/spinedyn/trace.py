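"""Equilibrium statistics of the per-spine correlation trace.

Each synaptic contact maintains a leaky "correlation trace" that counts causal
(pre-before-post) minus anti-causal spike pairings of the connected neuron
pair.  Every postsynaptic spike (Poisson, rate ``nu``) bumps the trace by
``+c`` with the causal-pairing probability ``p`` and by ``-c`` otherwise; the
trace leaks with time constant ``tau`` and carries additive white noise of
amplitude ``sigma``.  The trace is an exponential-kernel shot noise plus an
Ornstein-Uhlenbeck noise term, so its stationary law is normal with moments
given by Campbell's theorem:

    mean     = tau * nu * c * (2 p - 1)
    variance = (tau / 2) * (nu * c**2 + sigma**2)

Only the mean depends on ``p`` (and hence on the number of active contacts);
the variance is a constant of the parameter set.  ``simulate_trace`` provides
a direct Euler-Maruyama simulation of the jump-diffusion used as an
independent oracle for these closed forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import lfilter

logger = logging.getLogger(__name__)

SpineClass = Literal["thin", "large"]


@dataclass(frozen=True)
class TraceParams:
    """Parameters of the correlation-trace process and causal pairing.

    Parameters
    ----------
    tau : float
        Leak time constant of the trace, in model time units.
    nu : float
        Postsynaptic Poisson firing rate (events per time unit).
    c : float
        Jump magnitude per causal/anti-causal event; a single value is used
        for both signs so the equilibrium variance is independent of ``p``.
    sigma_thin, sigma_large : float
        White-noise amplitude of the trace at thin resp. large spines
        (trace units per sqrt(time)).
    p0 : float
        Baseline probability of a causal pairing (chance level 0.5 for
        independently firing neurons).
    lambda_resp : float
        Response-probability slope per unit EPSP (1/mV): each active contact
        raises the causal-pairing probability by ``lambda_resp * u_epsp``.
    u_epsp : float
        Unitary EPSP amplitude per active contact (mV).
    """

    tau: float = 100.0
    nu: float = 5.0
    c: float = 1.0
    sigma_thin: float = 1.0
    sigma_large: float = 1.0
    p0: float = 0.5
    lambda_resp: float = 0.01
    u_epsp: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.nu < 0:
            raise ValueError(f"nu must be non-negative, got {self.nu}")
        if self.c < 0:
            raise ValueError(f"c must be non-negative, got {self.c}")
        if self.sigma_thin < 0 or self.sigma_large < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must lie in [0, 1], got {self.p0}")
        if self.lambda_resp < 0:
            raise ValueError("lambda_resp must be non-negative")
        if self.u_epsp < 0:
            raise ValueError("u_epsp must be non-negative")

    @property
    def w(self) -> float:
        """Causal-probability increment per active contact, lambda_resp * u_epsp."""
        return self.lambda_resp * self.u_epsp

    def sigma(self, spine_class: SpineClass) -> float:
        if spine_class == "thin":
            return self.sigma_thin
        if spine_class == "large":
            return self.sigma_large
        raise ValueError(f"unknown spine class {spine_class!r}")


@dataclass(frozen=True)
class TraceEquilibrium:
    """Stationary normal law of the correlation trace."""

    mean: float
    variance: float
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        object.__setattr__(self, "sd", float(np.sqrt(self.variance)))


def causal_probability(n_active: int, params: TraceParams) -> float:
    """Probability that a postsynaptic spike is causally paired.

    Each of the ``n_active`` active contacts raises the pairing probability
    linearly by ``lambda_resp * u_epsp`` above the baseline ``p0``.  Values
    outside [0, 1] are clipped (the linearization must saturate) with a
    logged warning.
    """
    if n_active < 0:
        raise ValueError(f"n_active must be non-negative, got {n_active}")
    p = params.p0 + n_active * params.w
    if p < 0.0 or p > 1.0:
        logger.warning(
            "causal probability %.4f outside [0, 1] at n_active=%d; clipping",
            p, n_active,
        )
        p = min(max(p, 0.0), 1.0)
    return float(p)


def trace_equilibrium(
    n_active: int, params: TraceParams, spine_class: SpineClass = "thin"
) -> TraceEquilibrium:
    """Stationary mean and variance of the trace at a given active count.

    The mean grows with the causal-pairing probability; the variance combines
    the shot-noise term ``nu * c**2`` with the class-specific white noise and
    is independent of ``p`` (and hence of ``n_active``).
    """
    p = causal_probability(n_active, params)
    mean = params.tau * params.nu * params.c * (2.0 * p - 1.0)
    sigma = params.sigma(spine_class)
    variance = 0.5 * params.tau * (params.nu * params.c**2 + sigma**2)
    return TraceEquilibrium(mean=float(mean), variance=float(variance))


@dataclass(frozen=True)
class TraceTrajectory:
    """Sampled correlation-trace trajectory with empirical moments.

    Standard errors are estimated by batch means so that comparison against
    the analytic equilibrium can use a ``3 * SE`` band.
    """

    times: np.ndarray
    values: np.ndarray
    empirical_mean: float
    empirical_variance: float
    se_mean: float
    se_variance: float


def simulate_trace(
    n_active: int,
    params: TraceParams,
    spine_class: SpineClass = "thin",
    duration: float = 1e4,
    step: float = 0.02,
    seed: int = 0,
    x0: float = 0.0,
    burn_in_fraction: float = 0.1,
) -> TraceTrajectory:
    """Euler-Maruyama simulation of the correlation-trace jump diffusion.

    Per step of width ``dt`` the trace decays by ``exp(-dt/tau)``, receives
    ``K ~ Poisson(nu*dt)`` pairing events of which ``Binomial(K, p)`` are
    causal (+c) and the rest anti-causal (-c), plus a Gaussian increment of
    variance ``sigma**2 * dt``.  Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    p = causal_probability(n_active, params)
    sigma = params.sigma(spine_class)
    rng = np.random.default_rng(seed)

    n_steps = int(np.ceil(duration / step))
    counts = rng.poisson(params.nu * step, size=n_steps)
    causal = rng.binomial(counts, p)
    increments = params.c * (2.0 * causal - counts).astype(float)
    if sigma > 0:
        increments += rng.normal(0.0, sigma * np.sqrt(step), size=n_steps)

    decay = np.exp(-step / params.tau)
    # x_n = decay * x_{n-1} + inc_n  -> linear IIR filter
    values = lfilter([1.0], [1.0, -decay], increments, zi=[decay * x0])[0]
    values = np.concatenate([[x0], values])
    times = step * np.arange(n_steps + 1)

    start = int(burn_in_fraction * n_steps)
    post = values[start:]
    emp_mean = float(np.mean(post))
    emp_var = float(np.var(post))

    # batch means over ~30 batches for autocorrelation-aware standard errors
    n_batches = 30
    usable = (len(post) // n_batches) * n_batches
    batches = post[:usable].reshape(n_batches, -1)
    bm = batches.mean(axis=1)
    bv = batches.var(axis=1)
    se_mean = float(bm.std(ddof=1) / np.sqrt(n_batches))
    se_var = float(bv.std(ddof=1) / np.sqrt(n_batches))

    return TraceTrajectory(
        times=times,
        values=values,
        empirical_mean=emp_mean,
        empirical_variance=emp_var,
        se_mean=se_mean,
        se_variance=se_var,
    )
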