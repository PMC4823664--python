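"""Design a mixture that reproduces target responses in several OSN types.

A target percept is encoded as the set of responses it evokes in a panel
of OSN types.  If each available odor's action on every OSN type is
known, the mixture concentrations that reproduce the whole target panel
follow from one linear solve in the embedded space — the same
coefficients must work for every OSN because a single physical mixture
is delivered.
"""

import numpy as np

from odormix import ResponseTriple, compose, embed, scale, synthesize_target, unembed

rng = np.random.default_rng(3)

# two available odors, each driving four OSN types differently
available = [[ResponseTriple(*rng.uniform(0.3, 6.0, 3)) for _ in range(2)]
             for _ in range(4)]

# construct a consistent target panel: the mixture 1.3*odor1 + 0.4*odor2
true = np.array([1.3, 0.4])
targets = [compose(scale(a[0], true[0]), scale(a[1], true[1])) for a in available]

coeffs = synthesize_target(targets, available)
print(f"true mixture coefficients:      {true}")
print(f"recovered mixture coefficients: {np.round(coeffs, 10)}")

check = compose(scale(available[0][0], coeffs[0]), scale(available[0][1], coeffs[1]))
t = targets[0]
print(f"OSN 1 target  (n, eta, s) = ({t.n:.4f}, {t.eta:.4f}, {t.s:.4f})")
print(f"OSN 1 mixture (n, eta, s) = ({check.n:.4f}, {check.eta:.4f}, {check.s:.4f})")
print("one pair of concentrations reproduces all four OSN targets at once,")
print("because mixing acts linearly in the embedded response space.")
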