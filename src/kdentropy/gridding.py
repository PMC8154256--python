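"""Resolution selection and binning of 1D samples onto a uniform grid.

Spectral (DCT-based) kernel density estimation operates on binned data, so the
first stage of every pipeline is: choose a resolution ``r`` (number of bins),
build a :class:`Grid`, and accumulate the (optionally weighted) samples into a
:class:`BinnedData` histogram.  Resolutions are powers of two, which keeps the
cosine transforms clean and matches the defaults used for dihedral data
(2048, 4096).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import DataError

log = logging.getLogger(__name__)

DataKind = Literal["generic", "dihedral"]
ResolutionRule = Literal["auto", "sturges", "rice", "sqrt", "fixed"]

#: Clamp range for automatically chosen resolutions.
RESOLUTION_MIN = 2**5
RESOLUTION_MAX = 2**13

#: Default per-side padding of the grid range for non-periodic data.
DEFAULT_PAD_FRACTION = 0.1


def wrap_degrees(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Wrap angles in degrees into [-180, 180).

    Trajectory tools occasionally emit exactly 180.0; wrapping (rather than
    rejecting) maps it to -180.0.  Idempotent.
    """
    values = np.asarray(values, dtype=float)
    return (values + 180.0) % 360.0 - 180.0


def is_power_of_two(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


def next_power_of_two(n: int) -> int:
    if n < 1:
        raise DataError(f"cannot round {n} up to a power of two")
    return 1 << (int(n) - 1).bit_length()


@dataclass(frozen=True)
class Sample1D:
    """Raw observations with optional per-observation weights.

    ``values`` are in arbitrary units (degrees for dihedrals).  Weights must be
    strictly positive; they are kept unnormalised — binning normalises.
    """

    values: np.ndarray
    weights: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise DataError("values must be a non-empty 1D array")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise DataError(f"non-finite value at index {bad}")
        object.__setattr__(self, "values", values)
        if self.weights is not None:
            weights = np.asarray(self.weights, dtype=float)
            if weights.shape != values.shape:
                raise DataError(
                    f"weights length {weights.size} != values length {values.size}"
                )
            if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
                raise DataError("weights must be finite and strictly positive")
            object.__setattr__(self, "weights", weights)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def total_weight(self) -> float:
        if self.weights is None:
            return float(self.n)
        return float(self.weights.sum())

    @property
    def n_effective(self) -> float:
        """Kish effective sample size (Σw)²/Σw²; equals n when unweighted."""
        if self.weights is None:
            return float(self.n)
        w = self.weights
        return float(w.sum() ** 2 / np.square(w).sum())


@dataclass(frozen=True)
class Grid:
    """Uniform evaluation lattice on [lower, upper)."""

    lower: float
    upper: float
    resolution: int

    def __post_init__(self) -> None:
        if not (self.upper > self.lower):
            raise DataError(f"grid upper ({self.upper}) must exceed lower ({self.lower})")
        if self.resolution < 1:
            raise DataError("resolution must be a positive integer")

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / self.resolution

    @property
    def span(self) -> float:
        return self.upper - self.lower

    @property
    def centers(self) -> np.ndarray:
        return self.lower + (np.arange(self.resolution) + 0.5) * self.spacing

    @property
    def edges(self) -> np.ndarray:
        return self.lower + np.arange(self.resolution + 1) * self.spacing


@dataclass(frozen=True)
class BinnedData:
    """Weighted histogram of a :class:`Sample1D` on a :class:`Grid`."""

    grid: Grid
    bin_mass: np.ndarray
    n_samples: int
    total_weight: float
    n_effective: float

    def __post_init__(self) -> None:
        mass = np.asarray(self.bin_mass, dtype=float)
        if mass.size != self.grid.resolution:
            raise DataError("bin_mass length must equal grid resolution")
        if np.any(mass < 0):
            raise DataError("bin masses must be non-negative")
        object.__setattr__(self, "bin_mass", mass)

    @property
    def frequencies(self) -> np.ndarray:
        """Bin masses normalised to sum to one."""
        return self.bin_mass / self.total_weight

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.bin_mass))


def _rule_bin_count(n_samples: int, rule: str) -> int:
    if rule == "sturges":
        return math.ceil(math.log2(n_samples)) + 1 if n_samples > 1 else 1
    if rule == "rice":
        return math.ceil(2.0 * n_samples ** (1.0 / 3.0))
    if rule == "sqrt":
        return math.ceil(math.sqrt(n_samples))
    raise DataError(f"unknown resolution rule {rule!r}")


# Dihedral auto schedule: 4096 for large data sets, halving each time the
# frame count drops by a factor of four, down to a floor of 512.
_DIHEDRAL_SCHEDULE = ((10_000, 4096), (2_500, 2048), (625, 1024), (0, 512))


def choose_resolution(
    n_samples: int,
    data_kind: DataKind = "generic",
    rule: ResolutionRule = "auto",
    fixed_value: Optional[int] = None,
) -> int:
    """Pick the number of bins for the spectral KDE.

    ``auto`` uses the Rice rule for generic data and a dedicated schedule for
    dihedrals (4096 for >= 10^4 frames).  The result is always a power of two
    clamped to [2^5, 2^13]; explicit rules are rounded up to the next power of
    two before clamping, so the choice is monotone in ``n_samples``.
    """
    if n_samples < 1:
        raise DataError("n_samples must be >= 1")
    if rule == "fixed":
        if fixed_value is None:
            raise DataError("rule='fixed' requires fixed_value")
        if not is_power_of_two(fixed_value):
            raise DataError(
                f"fixed resolution {fixed_value} is not a power of two; "
                f"use {next_power_of_two(fixed_value)} instead"
            )
        return int(fixed_value)
    if fixed_value is not None:
        raise DataError("fixed_value is only valid with rule='fixed'")

    if data_kind == "dihedral" and rule == "auto":
        for threshold, res in _DIHEDRAL_SCHEDULE:
            if n_samples >= threshold:
                return res

    effective_rule = "rice" if rule == "auto" else rule
    count = _rule_bin_count(n_samples, effective_rule)
    return int(np.clip(next_power_of_two(count), RESOLUTION_MIN, RESOLUTION_MAX))


def make_grid(
    samples: Sample1D,
    resolution: int,
    data_kind: DataKind = "generic",
    pad_fraction: float = DEFAULT_PAD_FRACTION,
) -> Grid:
    """Build the evaluation grid for a sample.

    Generic data get a range padded by ``pad_fraction`` of the data span per
    side (default 10%), which keeps the mass away from the reflective DCT
    boundaries.  Dihedral data always use exactly [-180, 180).
    """
    if not is_power_of_two(resolution):
        raise DataError(f"resolution {resolution} is not a power of two")
    if data_kind == "dihedral":
        return Grid(-180.0, 180.0, resolution)
    if pad_fraction < 0:
        raise DataError("pad_fraction must be non-negative")
    lo = float(samples.values.min())
    hi = float(samples.values.max())
    if hi == lo:
        raise DataError(
            f"all samples identical ({lo}); no density scale exists for a grid"
        )
    pad = pad_fraction * (hi - lo)
    return Grid(lo - pad, hi + pad, resolution)


def bin_samples(samples: Sample1D, grid: Grid) -> BinnedData:
    """Accumulate sample weights into the grid's bins.

    Bins are half-open [edge_k, edge_{k+1}) with the final bin closed; a value
    exactly on an interior edge goes to the right-hand bin.  Mass is conserved:
    ``sum(bin_mass) == total_weight``.
    """
    values = samples.values
    below = values < grid.lower
    above = values > grid.upper
    if below.any() or above.any():
        bad = int(np.flatnonzero(below | above)[0])
        raise DataError(
            f"sample {values[bad]} at index {bad} lies outside the grid "
            f"[{grid.lower}, {grid.upper}]"
        )
    mass, _ = np.histogram(values, bins=grid.edges, weights=samples.weights)
    return BinnedData(
        grid=grid,
        bin_mass=mass.astype(float),
        n_samples=samples.n,
        total_weight=samples.total_weight,
        n_effective=samples.n_effective,
    )
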