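"""Synthetic data generators.

Every estimator in the package can be exercised without touching a
trajectory: Gaussians and Gaussian mixtures for the generic KDE, von Mises
draws for the periodic pipeline, and a biased-sampling fixture that emulates
the accelerated-MD workflow end to end (angles drawn from a boosted
distribution plus the per-frame boost potentials needed to reweight them).

Reference entropies are computed from the *analytic* densities — closed form
where one exists, adaptive quadrature otherwise — never through the package's
own KDE, so accuracy tests have an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Literal, Optional

import numpy as np
from scipy import integrate as sintegrate
from scipy import stats

from .dihedral import DihedralSeries
from .entropy import GAS_CONSTANT, analytic_gaussian_entropy
from .errors import DataError
from .gridding import Sample1D, wrap_degrees
from .reweight import BoostSeries, K_B_KCAL

FixtureKind = Literal["gaussian", "mixture", "uniform", "von_mises", "boosted_dihedral"]

#: Quadrature tolerance for numerically integrated reference entropies.
_QUAD_TOL = 1e-10

_RAD2DEG = 180.0 / np.pi


@dataclass(frozen=True)
class FixtureSpec:
    kind: FixtureKind
    n: int
    params: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("n must be >= 1")


@dataclass(frozen=True)
class GeneratedSample:
    sample: Sample1D
    true_entropy: Optional[float]


@dataclass(frozen=True)
class BoostedDihedralFixture:
    series: DihedralSeries
    boost: BoostSeries
    true_density: Callable[[np.ndarray], np.ndarray]
    true_entropy: float


def _entropy_by_quadrature(pdf: Callable[[np.ndarray], np.ndarray],
                           lo: float, hi: float, points=None) -> float:
    """-R integral p ln p by adaptive quadrature on the analytic density."""

    def integrand(x):
        p = pdf(np.asarray(x))
        return np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)

    val, _ = sintegrate.quad(integrand, lo, hi, points=points,
                             epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=400)
    return GAS_CONSTANT * val


def _mixture_pdf(means, sigmas, weights):
    means = np.asarray(means, float)
    sigmas = np.asarray(sigmas, float)
    weights = np.asarray(weights, float)
    if not (means.size == sigmas.size == weights.size):
        raise DataError("mixture means, sigmas and weights must align")
    if np.any(sigmas <= 0):
        raise DataError("mixture sigmas must be positive")
    if not np.isclose(weights.sum(), 1.0, atol=1e-12):
        raise DataError("mixture weights must sum to 1")

    def pdf(x):
        x = np.asarray(x, float)
        return sum(w * stats.norm.pdf(x, m, s) for m, s, w in zip(means, sigmas, weights))

    return pdf, means, sigmas, weights


def _von_mises_pdf_rad(kappa: float, mu_rad: float):
    if kappa <= 0:
        raise DataError("kappa must be positive")

    def pdf(theta):
        return stats.vonmises.pdf(np.asarray(theta, float), kappa, loc=mu_rad)

    return pdf


def generate(spec: FixtureSpec) -> GeneratedSample:
    """Draw a deterministic sample and its reference entropy.

    Gaussian and uniform fixtures report the closed-form entropy; mixtures
    and von Mises angles report the quadrature of -R p ln p of the analytic
    density (radian convention for angles).  Angles are returned in degrees,
    wrapped to [-180, 180).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.kind == "gaussian":
        mean = p.get("mean", 0.0)
        sigma = p.get("sigma", 1.0)
        values = rng.normal(mean, sigma, spec.n)
        return GeneratedSample(Sample1D(values, label="gaussian"),
                               analytic_gaussian_entropy(sigma))
    if spec.kind == "uniform":
        lo = p.get("low", 0.0)
        hi = p.get("high", 1.0)
        if hi <= lo:
            raise DataError("uniform fixture needs high > low")
        values = rng.uniform(lo, hi, spec.n)
        return GeneratedSample(Sample1D(values, label="uniform"),
                               GAS_CONSTANT * np.log(hi - lo))
    if spec.kind == "mixture":
        pdf, means, sigmas, weights = _mixture_pdf(
            p.get("means", (-2.0, 2.0)),
            p.get("sigmas", (1.0, 1.0)),
            p.get("weights", (0.5, 0.5)),
        )
        comp = rng.choice(means.size, size=spec.n, p=weights)
        values = rng.normal(means[comp], sigmas[comp])
        lo = float(means.min() - 10 * sigmas.max())
        hi = float(means.max() + 10 * sigmas.max())
        true_s = _entropy_by_quadrature(pdf, lo, hi, points=list(means))
        return GeneratedSample(Sample1D(values, label="mixture"), true_s)
    if spec.kind == "von_mises":
        kappa = p.get("kappa", 4.0)
        mu_deg = p.get("mu", 0.0)
        pdf = _von_mises_pdf_rad(kappa, mu_deg / _RAD2DEG)
        theta = rng.vonmises(mu_deg / _RAD2DEG, kappa, spec.n)
        true_s = _entropy_by_quadrature(pdf, -np.pi, np.pi)
        return GeneratedSample(
            Sample1D(wrap_degrees(theta * _RAD2DEG), label="von_mises"), true_s
        )
    if spec.kind == "boosted_dihedral":
        raise DataError("use generate_boosted_dihedral for the boosted_dihedral kind")
    raise DataError(f"unknown fixture kind {spec.kind!r}")


def generate_boosted_dihedral(spec: FixtureSpec) -> BoostedDihedralFixture:
    """Emulate an accelerated-MD dihedral trajectory with a known truth.

    The unbiased density is a two-well von Mises mixture; a smooth,
    non-negative boost potential dV(theta) tilts it to
    p_b ~ p_true * exp(-beta dV).  Frames are drawn from p_b by inverse-CDF
    sampling on a fine circular grid, and each frame carries its dV so the
    Maclaurin reweighting can be tested against the analytic entropy of
    p_true.
    """
    if spec.kind != "boosted_dihedral":
        raise DataError("spec.kind must be 'boosted_dihedral'")
    p = spec.params
    means_deg = np.asarray(p.get("means", (-70.0, 50.0)), float)
    kappas = np.asarray(p.get("kappas", (8.0, 8.0)), float)
    mix = np.asarray(p.get("weights", (0.5, 0.5)), float)
    height = float(p.get("boost_height", 1.0))        # kcal/mol
    center_deg = float(p.get("boost_center", 50.0))
    temperature = float(p.get("temperature", 300.0))
    if np.any(kappas <= 0) or not np.isclose(mix.sum(), 1.0):
        raise DataError("invalid well parameters")
    if height < 0:
        raise DataError("boost height must be non-negative")
    beta = 1.0 / (K_B_KCAL * temperature)
    if beta * height > 700.0:
        raise DataError(
            "boost scale overflows the reweighting; reduce boost_height below "
            f"{700.0 / beta:.3g} kcal/mol"
        )

    means_rad = means_deg / _RAD2DEG
    center_rad = center_deg / _RAD2DEG

    def p_true(theta):
        theta = np.asarray(theta, float)
        return sum(w * stats.vonmises.pdf(theta, k, loc=m)
                   for w, k, m in zip(mix, kappas, means_rad))

    def delta_v(theta):
        return height * 0.5 * (1.0 + np.cos(np.asarray(theta, float) - center_rad))

    # Biased density on a fine circular grid, sampled by inverse CDF.
    grid = np.linspace(-np.pi, np.pi, 1 << 16, endpoint=False)
    step = grid[1] - grid[0]
    biased = p_true(grid) * np.exp(-beta * delta_v(grid))
    biased = biased / (biased.sum() * step)
    cdf = np.concatenate([[0.0], np.cumsum(biased) * step])
    cdf = cdf / cdf[-1]
    edges = np.concatenate([grid, [np.pi]])
    rng = np.random.default_rng(spec.seed)
    theta = np.interp(rng.random(spec.n), cdf, edges)

    true_s = _entropy_by_quadrature(p_true, -np.pi, np.pi)
    series = DihedralSeries(wrap_degrees(theta * _RAD2DEG), name="boosted")
    boost = BoostSeries(delta_v(theta), temperature=temperature,
                        order=int(p.get("order", 10)))
    return BoostedDihedralFixture(series, boost, p_true, true_s)
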