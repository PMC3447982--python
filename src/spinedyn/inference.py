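"""Fitting the plasticity model to contact-number data, and model diagnostics.

The observable is the distribution of the number of synaptic contacts between
connected neuron pairs.  Reported histograms f_k (k >= 1 contacts) together
with the connection probability P_conn define a reference pmf with
P(0) = 1 - P_conn and P(k) = P_conn * f_k / sum(f).  The model's stationary
pmf of the total contact number is compared through residuals scaled by the
maximum of the reference pmf, and the sum of squared residuals E is minimized
by multi-start Levenberg-Marquardt over an 8-dimensional parameter subset
(tau, sigma_thin, sigma_large, A_mat, theta_mat, A_shr, theta_shr, delta),
with gamma = 1 fixed to set the unit of time.

Diagnostics: the Hebbian index d<Na>/dp0 (positive: causal pairings grow the
connection), the firing-rate-homeostasis derivative d<Na>/dnu evaluated after
re-expressing the baseline correlation via the threshold-shift identity
(shifting every threshold by 2 tau nu c (p0' - p0) leaves all rates and hence
the equilibrium unchanged), and the two-state detailed-balance inversion that
shows why a model without the inactive state cannot produce histograms with
suppressed P(1) and a secondary peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .rates import PlasticityParams, RateLaw
from .steady_state import StationaryResult, solve_model
from .trace import TraceParams

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceDataset",
    "FitResult",
    "TwoStateProfile",
    "reference_pmf",
    "model_error",
    "model_total_pmf",
    "fit_model",
    "hebbian_index",
    "shift_thresholds",
    "homeostasis_derivative",
    "two_state_ratio_profile",
]


@dataclass(frozen=True)
class ReferenceDataset:
    """Observed contact-number histogram of one intra-cortical projection.

    ``counts`` maps k >= 1 contacts to the observed frequency among connected
    pairs; ``p_conn`` is the probability that a pair is connected at all;
    ``u_epsp`` the unitary EPSP amplitude per active contact (mV);
    ``apposition_dist`` the pmf of the number of close appositions M.
    """

    counts: Mapping[int, float]
    p_conn: float
    u_epsp: float
    apposition_dist: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p_conn <= 1.0:
            raise ValueError(f"p_conn must lie in (0, 1], got {self.p_conn}")
        if any(k < 1 for k in self.counts):
            raise ValueError("contact counts are defined for k >= 1")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("frequencies must be non-negative")
        if sum(self.counts.values()) <= 0:
            raise ValueError("histogram must have positive total count")


def reference_pmf(dataset: ReferenceDataset) -> np.ndarray:
    """Reference pmf over k = 0..K: P(0) = 1 - P_conn, P(k) proportional to f_k."""
    k_max = max(dataset.counts)
    total = float(sum(dataset.counts.values()))
    pmf = np.zeros(k_max + 1)
    pmf[0] = 1.0 - dataset.p_conn
    for k, f in dataset.counts.items():
        pmf[k] = dataset.p_conn * f / total
    return pmf


def model_error(
    model_pmf: np.ndarray, ref_pmf: np.ndarray
) -> tuple[np.ndarray, float]:
    """Residuals and squared error between model and reference pmfs.

    Both pmfs are zero-padded to common support; residuals are
    (model - ref) / max(ref), and E is their sum of squares.  The scaling by
    the reference maximum makes E comparable across datasets.
    """
    ref_pmf = np.asarray(ref_pmf, dtype=float)
    model_pmf = np.asarray(model_pmf, dtype=float)
    scale = ref_pmf.max()
    if scale <= 0:
        raise ValueError("reference pmf must have positive mass")
    n = max(len(model_pmf), len(ref_pmf))
    model = np.zeros(n)
    model[: len(model_pmf)] = model_pmf
    ref = np.zeros(n)
    ref[: len(ref_pmf)] = ref_pmf
    residuals = (model - ref) / scale
    return residuals, float(residuals @ residuals)


def model_total_pmf(
    params: PlasticityParams,
    a_dist: np.ndarray,
    observable: str = "total",
) -> np.ndarray:
    """Stationary pmf of the fitted observable (total or active contact count)."""
    result = solve_model(params, a_dist)
    if observable == "total":
        return result.p_total
    if observable == "active":
        return result.p_active
    raise ValueError(f"unknown observable {observable!r}")


# fitted subset: log tau, log sigma_thin, log sigma_large,
#                A_mat, theta_mat, A_shr, theta_shr, log delta
_FIT_NAMES = (
    "tau", "sigma_thin", "sigma_large",
    "A_mat", "theta_mat", "A_shr", "theta_shr", "delta",
)


def _params_from_vector(
    x: np.ndarray, base_trace: TraceParams, gamma: float = 1.0
) -> PlasticityParams:
    x = np.clip(x, -1e8, 1e8)
    # clamp log-parameters so exp stays finite while LM explores
    tau = np.exp(np.clip(x[0], -30.0, 30.0))
    s_thin = np.exp(np.clip(x[1], -30.0, 30.0))
    s_large = np.exp(np.clip(x[2], -30.0, 30.0))
    a_mat, th_mat, a_shr, th_shr = x[3], x[4], x[5], x[6]
    delta = np.exp(np.clip(x[7], -30.0, 30.0))
    trace = replace(
        base_trace, tau=float(tau),
        sigma_thin=float(s_thin), sigma_large=float(s_large),
    )
    return PlasticityParams(
        maturation=RateLaw(float(a_mat), float(th_mat), "thin"),
        shrinkage=RateLaw(float(a_shr), float(th_shr), "large"),
        delta=float(delta),
        gamma=gamma,
        trace=trace,
    )


def _vector_from_params(params: PlasticityParams) -> np.ndarray:
    t = params.trace
    return np.array([
        np.log(t.tau), np.log(t.sigma_thin), np.log(t.sigma_large),
        params.maturation.amplitude, params.maturation.threshold,
        params.shrinkage.amplitude, params.shrinkage.threshold,
        np.log(max(params.delta, 1e-12)),
    ])


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    params: PlasticityParams
    error: float
    residuals: np.ndarray
    n_starts: int
    starts: tuple[dict, ...] = field(repr=False)
    hebbian_index: float = float("nan")
    converged: bool = True


def _default_start_grid() -> list[list[float]]:
    """Four candidate values per fitted dimension, as in a 4^d start design.

    Threshold entries are coefficients, scaled at assembly by the equilibrium
    trace-mean shift per active contact at the start's tau, so that threshold
    starts stay commensurate with the trace scale for every tau candidate.
    """
    taus = list(np.log([30.0, 100.0, 300.0, 1000.0]))
    sigmas = list(np.log([0.5, 1.0, 2.0, 4.0]))
    amps = [-30.0, -3.0, -0.3, 3.0]
    theta_coeffs = [-2.0, -0.5, 0.5, 2.0]
    deltas = list(np.log([1e-3, 1e-2, 1e-1, 1.0]))
    return [taus, sigmas, sigmas, amps, theta_coeffs, amps, theta_coeffs, deltas]


def fit_model(
    dataset: ReferenceDataset,
    n_starts: int = 32,
    seed: int = 0,
    observable: str = "total",
    base_trace: TraceParams | None = None,
    max_nfev: int = 200,
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Multi-start Levenberg-Marquardt fit of the plasticity model.

    Starts are drawn (deterministically given ``seed``) from the full
    factorial grid of four candidate values per fitted dimension; positive
    parameters are log-transformed so the unconstrained LM steps keep them
    positive.  Per-start optimizer failures are recorded, not fatal; the
    best-error start wins.  ``extra_starts`` allows data-driven or
    user-supplied initial vectors in addition to the sampled grid.
    """
    if base_trace is None:
        base_trace = TraceParams(u_epsp=dataset.u_epsp)
    else:
        base_trace = replace(base_trace, u_epsp=dataset.u_epsp)
    ref = reference_pmf(dataset)
    a_dist = np.asarray(dataset.apposition_dist, dtype=float)

    t = base_trace
    w_eff = t.w if t.w > 0 else 0.01 * t.u_epsp if t.u_epsp > 0 else 0.01
    grid = _default_start_grid()

    rng = np.random.default_rng(seed)
    n_grid = int(np.prod([len(g) for g in grid]))
    n_sample = max(0, n_starts - len(extra_starts))
    chosen = rng.choice(n_grid, size=min(n_sample, n_grid), replace=False)
    dims = [len(g) for g in grid]
    start_vectors = [np.asarray(x, dtype=float) for x in extra_starts]
    for flat in sorted(chosen):
        idx = np.unravel_index(flat, dims)
        x0 = np.array([grid[d][j] for d, j in enumerate(idx)])
        mu_scale = 2.0 * np.exp(x0[0]) * t.nu * t.c * w_eff  # at the start's tau
        x0[4] *= mu_scale
        x0[6] *= mu_scale
        start_vectors.append(x0)

    def residual_fn(x: np.ndarray) -> np.ndarray:
        try:
            params = _params_from_vector(x, base_trace)
            pmf = model_total_pmf(params, a_dist, observable)
        except (ValueError, RuntimeError):
            return np.full(len(ref), 1e3)
        if not np.all(np.isfinite(pmf)):
            return np.full(len(ref), 1e3)
        res, _ = model_error(pmf, ref)
        return res

    starts_log: list[dict] = []
    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    for x0 in start_vectors:
        e0 = float(np.sum(residual_fn(x0) ** 2))
        try:
            sol = least_squares(
                residual_fn, x0, method="lm", max_nfev=max_nfev, xtol=1e-10,
            )
            x_opt, ok = sol.x, bool(sol.success)
        except Exception as exc:  # optimizer failure on this start
            logger.warning("optimization start failed: %s", exc)
            starts_log.append({"x0": x0, "error": e0, "converged": False})
            continue
        res = residual_fn(x_opt)
        e_opt = float(res @ res)
        # LM is a descent method but guard against pathological evaluations
        if e_opt > e0:
            x_opt, e_opt, res = x0, e0, residual_fn(x0)
        starts_log.append({"x0": x0, "x_opt": x_opt, "error": e_opt, "converged": ok})
        if best is None or e_opt < best[0]:
            best = (e_opt, x_opt, res, ok)
    if best is None:
        raise RuntimeError("all optimization starts failed")

    e_best, x_best, res_best, ok = best
    params_best = _params_from_vector(x_best, base_trace)
    starts_ranked = tuple(sorted(starts_log, key=lambda d: d["error"]))
    hebb = hebbian_index(params_best, a_dist)
    return FitResult(
        params=params_best,
        error=e_best,
        residuals=res_best,
        n_starts=len(start_vectors),
        starts=starts_ranked,
        hebbian_index=hebb,
        converged=ok,
    )


def _mean_active(params: PlasticityParams, a_dist: np.ndarray) -> float:
    return solve_model(params, a_dist).moments["mean_active"]


def hebbian_index(
    params: PlasticityParams, a_dist: np.ndarray, h: float = 1e-3
) -> float:
    """Central finite difference d<Na>/dp0.

    Positive values mean more causal pairings grow the connection (Hebbian),
    negative values shrink it (anti-Hebbian).  The step shrinks if p0 +/- h
    would leave [0, 1].
    """
    p0 = params.trace.p0
    h = min(h, p0, 1.0 - p0) if 0.0 < p0 < 1.0 else h
    if h <= 0:
        raise ValueError("p0 at the boundary of [0, 1]; cannot differentiate")
    lo = replace(params, trace=replace(params.trace, p0=p0 - h))
    hi = replace(params, trace=replace(params.trace, p0=p0 + h))
    return (_mean_active(hi, a_dist) - _mean_active(lo, a_dist)) / (2.0 * h)


def classify_hebbian(index: float, tol: float = 1e-9) -> str:
    if index > tol:
        return "Hebbian"
    if index < -tol:
        return "anti-Hebbian"
    return "neutral"


def shift_thresholds(params: PlasticityParams, new_p0: float) -> PlasticityParams:
    """Re-express the baseline correlation without changing the model.

    Changing p0 shifts every equilibrium trace mean by
    ``2 tau nu c (new_p0 - p0)``; translating all thresholds by the same
    amount preserves every distance to threshold, hence all transition rates
    and the stationary distribution.  This makes p0 an effectively free
    parameter.
    """
    if not 0.0 <= new_p0 <= 1.0:
        raise ValueError(f"new_p0 must lie in [0, 1], got {new_p0}")
    t = params.trace
    shift = 2.0 * t.tau * t.nu * t.c * (new_p0 - t.p0)
    return replace(
        params,
        maturation=replace(params.maturation,
                           threshold=params.maturation.threshold + shift),
        shrinkage=replace(params.shrinkage,
                          threshold=params.shrinkage.threshold + shift),
        trace=replace(t, p0=new_p0),
    )


def homeostasis_derivative(
    params: PlasticityParams,
    a_dist: np.ndarray,
    p0_eff: float | None = None,
    rel_step: float = 1e-3,
) -> float:
    """Firing-rate-homeostasis derivative d<Na>/dnu.

    The model is first re-expressed at the effective baseline ``p0_eff`` via
    the threshold shift (leaving the base equilibrium untouched), then the
    postsynaptic rate nu is perturbed symmetrically; nu enters both the
    equilibrium trace mean and its variance.  Negative values mean a rate
    increase prunes synapses: firing-rate homeostasis.
    """
    if p0_eff is not None:
        params = shift_thresholds(params, p0_eff)
    nu = params.trace.nu
    if nu <= 0:
        raise ValueError("homeostasis derivative requires nu > 0")
    h = rel_step * nu
    lo = replace(params, trace=replace(params.trace, nu=nu - h))
    hi = replace(params, trace=replace(params.trace, nu=nu + h))
    return (_mean_active(hi, a_dist) - _mean_active(lo, a_dist)) / (2.0 * h)


@dataclass(frozen=True)
class TwoStateProfile:
    """Detailed-balance inversion of a two-state (no inactive state) model.

    ``ratios[n]`` is the creation/pruning rate ratio g(n)/q(n+1) implied by
    the target pmf; ``monotone`` is False when the sequence decreases then
    increases, the signature that no biophysically plausible monotone rate
    functions can generate the target.
    """

    ratios: np.ndarray
    monotone: bool


def two_state_ratio_profile(
    ref_pmf: np.ndarray, m: int, atol: float = 1e-12
) -> TwoStateProfile:
    """Implied rate ratios of a birth-death model without inactive contacts.

    For a chain on n = 0..m with creation rate g(n) per unrealized site and
    pruning rate q(n) per active contact, detailed balance gives
    P(n+1)/P(n) = g(n) (m - n) / (q(n+1) (n + 1)), so the pmf determines

        ratio(n) = P(n+1) (n+1) / (P(n) (m - n)).

    Near-zero P(1) with a secondary peak forces this sequence to plunge and
    then rise again, i.e. highly non-monotone rate functions.  Zero bins
    yield inf/0 entries rather than errors.
    """
    p = np.asarray(ref_pmf, dtype=float)
    if len(p) < m + 1:
        p = np.concatenate([p, np.zeros(m + 1 - len(p))])
    ratios = np.empty(m)
    for n in range(m):
        num = p[n + 1] * (n + 1)
        den = p[n] * (m - n)
        if den <= atol:
            ratios[n] = np.inf if num > atol else 0.0
        else:
            ratios[n] = num / den
    finite = ratios[np.isfinite(ratios)]
    diffs = np.diff(finite)
    tol = max(atol, 1e-9 * (np.max(np.abs(finite)) if len(finite) else 1.0))
    sign = np.where(np.abs(diffs) <= tol, 0, np.sign(diffs))
    decreasing_then_increasing = False
    if len(sign) >= 2:
        # any descent followed (anywhere later) by an ascent
        descent = np.where(sign < 0)[0]
        ascent = np.where(sign > 0)[0]
        decreasing_then_increasing = (
            len(descent) > 0 and len(ascent) > 0 and ascent.max() > descent.min()
        )
    monotone = not decreasing_then_increasing and (
        np.all(sign <= 0) or np.all(sign >= 0)
    )
    return TwoStateProfile(ratios=ratios, monotone=bool(monotone))
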