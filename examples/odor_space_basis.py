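"""The odor-response space is 3-dimensional and has primary-response bases.

Every sigmoidal response is a triple (n, eta, s) with s = 1/K.  Mixing is
vector addition after the embedding (n*eta*s, eta*s, s), so the span of
all responses and their mixtures has dimension exactly 3, and any
response inside the coverage region of three independent "primary"
responses is a positive combination of them.
"""

import numpy as np

from odormix import (
    HullRegion,
    ResponseTriple,
    canonical_bases,
    compose,
    decompose,
    embed,
    hull_coverage,
    recompose,
    unembed,
)

rng = np.random.default_rng(0)
triples = [ResponseTriple(*rng.uniform(0.1, 10.0, 3)) for _ in range(20)]
vecs = [embed(t).as_array() for t in triples]
vecs += [embed(compose(triples[i], triples[j])).as_array()
         for i, j in rng.integers(0, 20, (10, 2))]
print(f"rank of {len(vecs)} stacked embedded responses and mixtures: "
      f"{np.linalg.matrix_rank(np.vstack(vecs))}")

bounds = HullRegion(n_min=0.5, n_max=20.0, eta_min=0.1, eta_max=16.0)
b1, b2 = canonical_bases(bounds, s=1e6)
print(f"canonical corner bases valid: E1={b1.valid}, E2={b2.valid}")

ns = np.linspace(bounds.n_min, bounds.n_max, 50)
es = np.linspace(bounds.eta_min, bounds.eta_max, 50)
cover1 = sum(hull_coverage(b1, n, e) for n in ns for e in es)
cover2 = sum(hull_coverage(b2, n, e) for n in ns for e in es)
both = sum(hull_coverage(b1, n, e) or hull_coverage(b2, n, e) for n in ns for e in es)
print(f"coverage of a 50x50 (n, eta) grid: E1 alone {cover1}/2500, "
      f"E2 alone {cover2}/2500, union {both}/2500")

target = ResponseTriple(n=2.0, eta=1.0, s=1e6)
basis = b1 if hull_coverage(b1, target.n, target.eta) else b2
dec = decompose(target, basis)
back = recompose(basis, dec)
print(f"decomposing the target (n={target.n}, eta={target.eta}, s={target.s:.0e}) "
      f"in {'E1' if basis is b1 else 'E2'}:")
print(f"  coefficients alpha = ({dec.alpha1:.4f}, {dec.alpha2:.4f}, {dec.alpha3:.4f})")
print(f"  recomposed triple  = (n={back.n:.6f}, eta={back.eta:.6f}, s={back.s:.4e})")
print("positive coefficients mean the target response is physically obtainable")
print("as a mixture of the three primary responses; the union of the two bases")
print("covers the whole bounded (n, eta) rectangle while neither does alone.")
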