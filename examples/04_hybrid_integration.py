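"""The hybrid COBRA/PBPK integration on the fixture gut + brain.

Runs the default 6-h, 15-min-step coupling for the mixed community at 20%
beneficial abundance on a high-fiber diet and prints how gut-derived
oxidative-stress toxins accumulate and depress brain GABA output.
"""

import gutbrain as gb

spec = gb.FixtureSpec()
high_fiber, _ = gb.make_toy_diets(spec)
community = gb.make_toy_community(spec=spec, diet=high_fiber)
weights = gb.compute_weights(
    20,
    [community.biomass_reactions[t] for t in spec.beneficial_tags],
    [community.biomass_reactions[t] for t in spec.harmful_tags],
    host_id=community.biomass_reactions[community.host_tag],
)

trajectory = gb.run_integration(
    pbpk_params=gb.make_toy_pbpk_params(),
    config=gb.CouplingConfig(),            # dt 15 min, 6 h, C0 = 1e-4 M
    gut_community=community,
    brain_model=gb.make_toy_brain(),
    gut_weights=weights,
)

gaba = trajectory.objectives.query("reaction == 'DM_gaba'")["flux"].values
print("hour   gut H2O2 (M)  brain H2O2 (M)  GABA demand (mmol/gDW/hr)")
for step in range(0, 25, 4):
    t = trajectory.times[step]
    gut = trajectory.series("h2o2", "gut").values[step]
    brain = trajectory.series("h2o2", "brain").values[step]
    g = gaba[min(step, len(gaba) - 1)]
    print(f"{t:4.1f}   {gut:.4e}    {brain:.4e}      {g:.3f}")

print(
    "\nToxins produced by harmful members rise monotonically toward a plateau "
    "where renal clearance balances gut production; the brain's NADPH-costly "
    "detoxification of the arriving toxins progressively lowers the "
    "attainable GABA demand flux."
)
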