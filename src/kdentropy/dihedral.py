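"""Dihedral-angle entropies with full periodic handling.

Backbone torsions live on a circle: an angle of -179 deg and one of +179 deg
are two degrees apart.  A KDE with reflective boundaries would see a spurious
gap there, so the pipeline replicates every sample at x - 360 and x + 360,
smooths on the extended grid [-540, 540), and keeps only the central
[-180, 180) window, renormalised.  The bandwidth selection sees the original
frame count, not the tripled one, so replication does not shrink the kernel.

Entropies are integrated with the angle expressed in radians; the per-residue
phi/psi sum is the residuewise flexibility metric that gets mapped onto
structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .bandwidth import Bandwidth, select_bandwidth_periodic
from .density import DensityEstimate, estimate_density
from .entropy import EntropyResult, IntegrationRule, integrate_entropy
from .errors import DataError
from .gridding import Grid, Sample1D, bin_samples, wrap_degrees
from .api import resolve_resolution, Resolution

log = logging.getLogger(__name__)

DEG2RAD = np.pi / 180.0


@dataclass(frozen=True)
class DihedralSeries:
    """One dihedral's trajectory, wrapped to [-180, 180) degrees on creation."""

    angles: np.ndarray
    name: str
    residue_index: Optional[int] = None
    residue_name: Optional[str] = None

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise DataError(f"dihedral series {self.name!r} is empty")
        if not np.all(np.isfinite(angles)):
            raise DataError(f"non-finite angle in series {self.name!r}")
        object.__setattr__(self, "angles", wrap_degrees(angles))

    @property
    def n_frames(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class ResiduewiseEntropy:
    """Per-residue dihedral entropies; ``combined`` is their sum."""

    residue_index: int
    residue_name: str
    entropy_values: Dict[str, float]
    combined: float


def dihedral_entropy(
    series: Union[DihedralSeries, np.ndarray, Sequence[float]],
    weights: Optional[Sequence[float]] = None,
    resolution: Resolution = "auto",
    integration_rule: IntegrationRule = "midpoint",
) -> EntropyResult:
    """Entropy of one dihedral distribution, J/(mol K).

    ``resolution`` is the number of bins of the central window; 'auto' picks
    4096 for >= 10^4 frames and less for smaller series.  The returned result
    carries the periodic density on [-pi, pi) in radians.
    """
    if not isinstance(series, DihedralSeries):
        series = DihedralSeries(np.asarray(series, dtype=float), name="dihedral")
    angles = series.angles
    n = series.n_frames
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None and w.shape != angles.shape:
        raise DataError(
            f"weights length {w.size} does not match frame count {n}"
        )

    r = resolve_resolution(resolution, n, "dihedral")

    # Bandwidth from the one-period histogram through the periodic
    # (spectrum-based) selector: invariant under circular shifts, and it sees
    # the original frame count, not the replicated one.
    original = Sample1D(angles, w, label=series.name)
    one_period = bin_samples(original, Grid(-180.0, 180.0, r))
    bandwidth = select_bandwidth_periodic(one_period, n_used=original.n_effective)
    log.info(
        "dihedral %s: n=%d, resolution=%d, bandwidth=%.4g deg, converged=%s",
        series.name, n, r, bandwidth.sigma_data, bandwidth.converged,
    )

    # Triple replication: each frame also appears shifted by +-360 deg, so the
    # smoother sees the periodic continuation; its reflective boundaries at
    # +-540 deg are a full period away from the window that is kept.
    replicated = np.concatenate([angles - 360.0, angles, angles + 360.0])
    rep_weights = None if w is None else np.tile(w, 3)
    extended = Grid(-540.0, 540.0, 3 * r)
    binned = bin_samples(Sample1D(replicated, rep_weights, label=series.name), extended)
    bandwidth_ext = Bandwidth(
        t_unit=bandwidth.t_unit / 9.0,  # same t_data, span tripled
        t_data=bandwidth.t_data,
        converged=bandwidth.converged,
        residual=bandwidth.residual,
        n_used=bandwidth.n_used,
    )
    dens = estimate_density(binned, bandwidth_ext)

    # Central window [-180, 180) occupies the middle third of the bins.
    central = dens.pdf[r : 2 * r]
    central_grid_rad = Grid(-np.pi, np.pi, r)
    pdf_rad = central / DEG2RAD  # per-radian density, still unnormalised
    mass = pdf_rad.sum() * central_grid_rad.spacing
    if mass <= 0:
        raise DataError("no density mass in the central window")
    pdf_rad = pdf_rad / mass
    bw_rad = Bandwidth(
        t_unit=bandwidth.t_unit,
        t_data=bandwidth.t_data * DEG2RAD**2,
        converged=bandwidth.converged,
        residual=bandwidth.residual,
        n_used=bandwidth.n_used,
    )
    central_density = DensityEstimate(
        grid=central_grid_rad, pdf=pdf_rad, bandwidth=bw_rad,
        normalization_applied=True,
    )
    return integrate_entropy(central_density, integration_rule, label=series.name)


def residuewise_entropy(
    series_set: Iterable[DihedralSeries],
    weights: Optional[Sequence[float]] = None,
    resolution: Resolution = "auto",
) -> List[ResiduewiseEntropy]:
    """Group dihedral series by residue and sum their entropies.

    Every series must carry residue metadata; each entropy is computed
    independently (the computations share no state and could run
    concurrently).  Output is ordered by residue index.
    """
    groups: Dict[int, List[DihedralSeries]] = {}
    names: Dict[int, str] = {}
    for s in series_set:
        if s.residue_index is None:
            raise DataError(f"series {s.name!r} has no residue_index")
        groups.setdefault(s.residue_index, []).append(s)
        names.setdefault(s.residue_index, s.residue_name or "")

    results: List[ResiduewiseEntropy] = []
    for idx in sorted(groups):
        values: Dict[str, float] = {}
        for s in groups[idx]:
            if s.name in values:
                raise DataError(
                    f"duplicate dihedral name {s.name!r} in residue {idx}"
                )
            values[s.name] = dihedral_entropy(s, weights, resolution).value
        results.append(
            ResiduewiseEntropy(
                residue_index=idx,
                residue_name=names[idx],
                entropy_values=values,
                combined=float(sum(values.values())),
            )
        )
    return results
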