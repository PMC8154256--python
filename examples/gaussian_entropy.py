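"""Entropy of generic 1D data, validated against a closed form.

Draws 10^4 standard-normal samples, runs the full pipeline (auto
resolution, plug-in bandwidth, spectral KDE, Simpson integration) and
compares with the analytic value R/2 ln(2 pi e sigma^2).
"""

import numpy as np

from kdentropy import analytic_gaussian_entropy, density_1d, entropy_1d

rng = np.random.default_rng(0)
samples = rng.normal(loc=0.0, scale=1.0, size=10_000)

density = density_1d(samples)
result = entropy_1d(samples)
truth = analytic_gaussian_entropy(1.0)

print(f"resolution          : {density.grid.resolution} bins")
print(f"kernel bandwidth    : {density.bandwidth.sigma_data:.4f} (data units)")
print(f"estimated entropy   : {result.value:.3f} J/(mol K)")
print(f"analytic entropy    : {truth:.3f} J/(mol K)")
print(f"relative error      : {100 * abs(result.value - truth) / truth:.2f} %")
# The ~1% deviation is the smoothing bias of integrating a kernel-smoothed
# density; it shrinks as the sample grows and the bandwidth tightens.
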