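"""Classify the published two-odor parameter sets into mixture behaviors.

Each set defines two single-odor dose-response curves (Hill coefficient n,
efficacy eta, concentration scale K per odor) and a mixing ratio r with
U = r*V.  The classifier compares the mixture curve with the two component
curves near their asymptotes and names the interaction.
"""

from odormix import (
    PairSpec,
    asymptote,
    builtin_parameter_sets,
    classify_asymptotic,
    effective_fixed_ratio,
)

print(f"{'set':38s} {'max U':>7s} {'max V':>7s} {'max mix':>8s}  behavior")
for key, ps in sorted(builtin_parameter_sets().items()):
    if not isinstance(ps, PairSpec) or not key.startswith("fig1/"):
        continue
    eff = effective_fixed_ratio(ps.U, ps.V, ps.r)
    a_u, a_v = asymptote(ps.U), asymptote(ps.V)
    a_m = asymptote(eff.to_params())
    label = classify_asymptotic(ps.U, ps.V, ps.r)
    print(f"{key:38s} {a_u:7.3f} {a_v:7.3f} {a_m:8.3f}  {label}")

print()
print("max values are asymptotic responses (fraction of the shared F_max);")
print("synergy = mixture above both components, inhibition = below both,")
print("suppression = in between, hypoadditivity/overshadowing = mixture")
print("indistinguishable from one component (the dominant / a weaker one).")
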