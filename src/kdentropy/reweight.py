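"""Reweighting of accelerated-MD frames.

Accelerated MD adds a non-negative boost potential dV (kcal/mol) to each
frame; unbiased statistics are recovered by weighting frame i with
exp(beta * dV_i).  The raw exponential is numerically violent, so the weight
is truncated to a Maclaurin series — by default of 10th order:

    w_i = sum_{k=0}^{order} (beta * dV_i)^k / k!

Weights are returned unnormalised; binning normalises, so a constant boost
cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DataError

#: Boltzmann constant in kcal/(mol K) — matches Amber-family boost energies.
K_B_KCAL = 0.0019872041

#: Default Maclaurin truncation order.
DEFAULT_ORDER = 10


@dataclass(frozen=True)
class BoostSeries:
    """Per-frame boost potentials with the thermodynamic beta they imply."""

    delta_v: np.ndarray
    temperature: float = 300.0
    beta: Optional[float] = None
    order: int = DEFAULT_ORDER

    def __post_init__(self) -> None:
        dv = np.asarray(self.delta_v, dtype=float)
        if dv.ndim != 1 or dv.size == 0:
            raise DataError("delta_v must be a non-empty 1D array")
        if not np.all(np.isfinite(dv)):
            raise DataError("non-finite boost potential")
        if np.any(dv < 0):
            bad = int(np.flatnonzero(dv < 0)[0])
            raise DataError(f"negative boost potential at frame {bad}")
        object.__setattr__(self, "delta_v", dv)
        if self.temperature <= 0:
            raise DataError("temperature must be positive")
        expected_beta = 1.0 / (K_B_KCAL * self.temperature)
        if self.beta is None:
            object.__setattr__(self, "beta", expected_beta)
        elif not np.isclose(self.beta, expected_beta, rtol=1e-9):
            raise DataError(
                f"beta {self.beta} inconsistent with temperature {self.temperature} K "
                f"(expected {expected_beta:.10g} per kcal/mol)"
            )
        if self.order < 0:
            raise DataError("order must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.delta_v.size


def maclaurin_weights(boost: BoostSeries) -> np.ndarray:
    """Truncated-exponential frame weights, sum_{k<=order} (beta dV)^k / k!.

    Monotone in dV and >= 1 everywhere; order 0 gives uniform weights, which
    reproduce the unweighted analysis exactly.
    """
    x = boost.beta * boost.delta_v
    weights = np.ones_like(x)
    term = np.ones_like(x)
    for k in range(1, boost.order + 1):
        term = term * x / k
        weights = weights + term
    if not np.all(np.isfinite(weights)):
        raise DataError(
            "Maclaurin weights overflow; boost potentials are too large for "
            f"order {boost.order} — rescale dV or lower the order"
        )
    return weights
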