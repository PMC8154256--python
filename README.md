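# kdentropy

Binned Gaussian kernel density estimation with automatic plug-in bandwidth
selection, and the differential entropies computed from it — built for
residuewise backbone-dihedral conformational entropies from molecular-dynamics
trajectories, but usable on any binnable 1D data.

## The problem

Proteins fluctuate between conformations, and much of that local flexibility
is captured by the distributions of the backbone torsion angles φ and ψ. A
residue's dihedral entropy,

```
S = −R ∫ p(x) ln p(x) dx        [J/(mol K),  R = 8.314462618 J/(mol K)]
```

is an alignment-free flexibility measure: broad angle distributions give high
entropy, rigid residues give low (possibly negative) entropy. Summing the
per-dihedral terms per residue approximates the local contribution to the
conformational entropy (correlations between dihedrals are neglected — this is
deliberately a 1D method).

The hard part is estimating p(x). kdentropy uses a Gaussian KDE,

```
p̂(x) = (1/N) Σᵢ (2πt)^(−1/2) exp(−(x − Xᵢ)² / 2t)
```

with the squared bandwidth `t` chosen automatically by the improved
Sheather–Jones (ISJ) plug-in selector: `t*` solves a fixed-point equation built
from estimates of density-derivative functionals, computed from the discrete
cosine transform of the binned data. The data are binned first (the
"resolution" `r` is the bin count, a power of two) and the smoothing is applied
spectrally, so evaluation costs O(r log r) regardless of sample size.

Dihedral angles get dedicated handling: samples are wrapped to [−180°, 180°),
the bandwidth comes from a phase-blind periodic variant of the selector, the
density is smoothed on a triple-replicated grid so that mass flows correctly
across ±180°, and the entropy is integrated over one period with the angle in
radians. Frames from accelerated-MD runs can be reweighted by the truncated
(10th-order Maclaurin) expansion of exp(βΔV) of their boost potentials.

## Worked example

```python
import numpy as np
from kdentropy import analytic_gaussian_entropy, density_1d, entropy_1d

samples = np.random.default_rng(0).normal(0.0, 1.0, 10_000)
density = density_1d(samples)
result  = entropy_1d(samples)
print(density.grid.resolution, density.bandwidth.sigma_data)
print(result.value, analytic_gaussian_entropy(1.0))
```

prints (see `examples/gaussian_entropy.py`):

```
resolution          : 64 bins
kernel bandwidth    : 0.1722 (data units)
estimated entropy   : 11.908 J/(mol K)
analytic entropy    : 11.798 J/(mol K)
relative error      : 0.94 %
```

The estimate sits ~1% above the closed form R/2 ln(2πeσ²): integrating a
kernel-smoothed density always carries a small positive smoothing bias that
shrinks with the bandwidth, i.e. with growing n.

For trajectory data the whole analysis is three lines (angle tables as written
by cpptraj-style tools, columns named like `phi_12`):

```python
from kdentropy import read_dihedral_table, residuewise_entropy
table = read_dihedral_table("dihedrals.dat")
results = residuewise_entropy(table.series)
```

`examples/` contains one short script per capability: generic entropy,
residuewise dihedral entropy, accelerated-MD reweighting, and projecting
per-residue entropies into a PDB's B-factor column for structure colouring.
A thin CLI mirrors the same pipelines (`kdentropy kde`, `kdentropy dihedral`,
`kdentropy fixtures`).

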