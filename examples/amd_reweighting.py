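"""Recovering unbiased entropy from accelerated-MD-style boosted data.

The boosted-dihedral fixture draws angles from a two-well distribution
tilted by a known boost potential dV(theta), exactly as an accelerated-MD
run would sample them.  Weighting each frame by the 10th-order Maclaurin
expansion of exp(beta dV) recovers the unbiased entropy; ignoring the bias
does not.
"""

from kdentropy import (
    FixtureSpec,
    dihedral_entropy,
    generate_boosted_dihedral,
    maclaurin_weights,
)

fix = generate_boosted_dihedral(FixtureSpec("boosted_dihedral", n=100_000, seed=4))
weights = maclaurin_weights(fix.boost)

s_reweighted = dihedral_entropy(fix.series, weights=weights).value
s_ignored = dihedral_entropy(fix.series).value

print(f"analytic truth        : {fix.true_entropy:.3f} J/(mol K)")
print(f"reweighted estimate   : {s_reweighted:.3f} J/(mol K)")
print(f"unreweighted estimate : {s_ignored:.3f} J/(mol K)")
print(f"max boost potential   : {fix.boost.delta_v.max():.2f} kcal/mol "
      f"at T = {fix.boost.temperature:.0f} K")
# The reweighted value lands within a few tenths of a percent of the truth;
# the unreweighted one is biased low because the boost flattens the wells.
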