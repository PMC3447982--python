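"""Activity-dependent transition rates of synaptic contacts.

A structural transition (maturation, shrinkage, pruning) is triggered when the
correlation trace crosses a threshold theta.  Far from threshold the escape
rate of the trace follows the Arrhenius form ``exp(-(theta - mu)^2 / (2 sd^2))``
with ``mu`` and ``sd`` the equilibrium mean and standard deviation of the
trace; near and beyond threshold the cellular machinery saturates, so the rate
converges to a plateau ``|A|``.  The sign of the amplitude ``A`` selects on
which side of the threshold the plateau lies: ``A > 0`` gives a
right-saturating rate (non-decreasing in mu), ``A < 0`` a left-saturating one.

The three activity-dependent transitions share this rate law with separate
parameters; pruning re-uses the shrinkage amplitude and threshold but feels
the thin-spine noise, because pruning takes place in thin spines.  An
activity-independent intrinsic rate ``delta`` adds to each, and new thin
spines are created at unrealized close appositions with rate ``gamma``
(fixed at 1 to set the unit of time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .trace import SpineClass, TraceParams, trace_equilibrium

__all__ = ["RateLaw", "PlasticityParams", "plateau_arrhenius_rate", "contact_rates"]


@dataclass(frozen=True)
class RateLaw:
    """Saturating Arrhenius-style rate law.

    ``amplitude`` is the signed plateau rate (its sign selects the saturated
    side), ``threshold`` the trace level at which the plateau is reached, and
    ``spine_class`` selects which noise amplitude sets the equilibrium sd.
    """

    amplitude: float
    threshold: float
    spine_class: SpineClass = "thin"

    def __post_init__(self) -> None:
        # amplitude 0 denotes an inactive law (identically zero rate), used
        # for intrinsic-only models
        if self.spine_class not in ("thin", "large"):
            raise ValueError(f"unknown spine class {self.spine_class!r}")


def plateau_arrhenius_rate(mu: float, law: RateLaw, eq_sd: float) -> float:
    """Transition rate at trace mean ``mu``.

    On the saturated side (``sign(A) * (mu - theta) >= 0``) the rate equals
    the plateau ``|A|``; on the other side it follows the Gaussian Arrhenius
    flank ``|A| * exp(-(theta - mu)^2 / (2 eq_sd^2))``.  Continuous and once
    differentiable at ``mu = theta``; monotone in ``mu`` with the direction
    of ``sign(A)``.
    """
    if eq_sd <= 0:
        raise ValueError(f"eq_sd must be positive, got {eq_sd}")
    a = law.amplitude
    side = np.sign(a) * (mu - law.threshold)
    if side >= 0:
        return float(abs(a))
    z = (law.threshold - mu) / eq_sd
    return float(abs(a) * np.exp(-0.5 * z * z))


@dataclass(frozen=True)
class PlasticityParams:
    """Full parameter set of the structural plasticity model.

    ``maturation`` acts on thin spines, ``shrinkage`` on large ones; the
    pruning law is derived from shrinkage (same amplitude and threshold) but
    evaluated with the thin-spine noise, which enforces the sharing invariant
    by construction.  ``delta`` is the intrinsic (activity-independent) rate
    of maturation/shrinkage/pruning and ``gamma`` the creation rate per
    unrealized close apposition; gamma = 1 sets the unit of model time.
    """

    maturation: RateLaw
    shrinkage: RateLaw
    delta: float = 0.0
    gamma: float = 1.0
    trace: TraceParams = field(default_factory=TraceParams)

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        if self.maturation.spine_class != "thin":
            raise ValueError("maturation law must use the thin-spine noise")
        if self.shrinkage.spine_class != "large":
            raise ValueError("shrinkage law must use the large-spine noise")

    @property
    def pruning(self) -> RateLaw:
        """Pruning law: shrinkage amplitude/threshold with thin-spine noise."""
        return RateLaw(
            amplitude=self.shrinkage.amplitude,
            threshold=self.shrinkage.threshold,
            spine_class="thin",
        )


def contact_rates(
    n_active: int, params: PlasticityParams
) -> tuple[float, float, float]:
    """Per-contact (maturation, shrinkage, pruning) rates at a given active count.

    Each component evaluates the plateau-Arrhenius law at the equilibrium
    trace mean for ``n_active`` active contacts (inactive contacts contribute
    nothing to the pairing probability) with the class-specific equilibrium
    sd, plus the intrinsic rate ``delta``.
    """
    rates = []
    for law in (params.maturation, params.shrinkage, params.pruning):
        eq = trace_equilibrium(n_active, params.trace, law.spine_class)
        rates.append(plateau_arrhenius_rate(eq.mean, law, eq.sd) + params.delta)
    return rates[0], rates[1], rates[2]
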