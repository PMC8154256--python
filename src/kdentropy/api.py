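"""High-level one-call pipelines for generic 1D data.

These wire the stages together — resolution, grid, binning, plug-in
bandwidth, spectral KDE, entropy — so a density or an entropy is one call:

    >>> from kdentropy import entropy_1d
    >>> result = entropy_1d(samples)
    >>> result.value   # J/(mol K)
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np

from .bandwidth import select_bandwidth
from .density import DensityEstimate, estimate_density
from .entropy import EntropyResult, IntegrationRule, integrate_entropy
from .gridding import (
    DEFAULT_PAD_FRACTION,
    ResolutionRule,
    Sample1D,
    bin_samples,
    choose_resolution,
    is_power_of_two,
    make_grid,
    next_power_of_two,
)

log = logging.getLogger(__name__)

Resolution = Union[int, str]


def _as_sample(
    values: Union[Sample1D, np.ndarray, Sequence[float]],
    weights: Optional[Sequence[float]],
    label: str,
) -> Sample1D:
    if isinstance(values, Sample1D):
        return values
    return Sample1D(np.asarray(values, dtype=float), weights=None if weights is None
                    else np.asarray(weights, dtype=float), label=label)


def resolve_resolution(
    resolution: Resolution, n_samples: int, data_kind: str = "generic",
    rule: ResolutionRule = "auto",
) -> int:
    """Turn a resolution request ('auto', a rule name, or an integer) into bins.

    Integers that are not powers of two are rounded up with a logged notice.
    """
    if isinstance(resolution, str):
        if resolution == "auto":
            return choose_resolution(n_samples, data_kind, rule)
        return choose_resolution(n_samples, data_kind, resolution)  # type: ignore[arg-type]
    r = int(resolution)
    if not is_power_of_two(r):
        rounded = next_power_of_two(r)
        log.info("resolution %d rounded up to the next power of two, %d", r, rounded)
        r = rounded
    return r


def density_1d(
    values: Union[Sample1D, np.ndarray, Sequence[float]],
    weights: Optional[Sequence[float]] = None,
    resolution: Resolution = "auto",
    rule: ResolutionRule = "auto",
    pad_fraction: float = DEFAULT_PAD_FRACTION,
    label: str = "",
) -> DensityEstimate:
    """Binned Gaussian KDE with plug-in bandwidth for generic 1D data."""
    sample = _as_sample(values, weights, label)
    r = resolve_resolution(resolution, sample.n, "generic", rule)
    grid = make_grid(sample, r, "generic", pad_fraction)
    binned = bin_samples(sample, grid)
    bandwidth = select_bandwidth(binned)
    log.info(
        "KDE: n=%d, resolution=%d, bandwidth=%.6g (data units), converged=%s",
        sample.n, r, bandwidth.sigma_data, bandwidth.converged,
    )
    return estimate_density(binned, bandwidth)


def entropy_1d(
    values: Union[Sample1D, np.ndarray, Sequence[float]],
    weights: Optional[Sequence[float]] = None,
    resolution: Resolution = "auto",
    rule: ResolutionRule = "auto",
    pad_fraction: float = DEFAULT_PAD_FRACTION,
    integration_rule: IntegrationRule = "simpson",
    label: str = "",
) -> EntropyResult:
    """Differential entropy, J/(mol K), of generic 1D data via the binned KDE."""
    density = density_1d(values, weights, resolution, rule, pad_fraction, label)
    return integrate_entropy(density, integration_rule, label=label)
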