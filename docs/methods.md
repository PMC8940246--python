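# Methods

This note documents the modeling assumptions, numerical choices and
limitations of `gutbrain`. The README states the governing equations; here
we record why the pieces look the way they do.

## Constraint-based layer

Models are `cobra.Model` objects; FBA and FVA are thin contracts over the
GLPK backend (`solve_fba`, `run_fva`). FBA flux vectors are not unique —
only objective values and FVA ranges are solver-invariant, and everything
downstream (metrics, rankings, acceptance checks) relies on those alone.
Where a flux vector must be reported (secretion attribution), it is labeled
a representative optimum.

One numerical safeguard deserves mention: GLPK auto-scales the problem, and
on near-infeasible instances it can report "optimal" for a primal point
that violates a mass balance by ~10⁻³. All feasibility decisions inside the
pareto searches therefore re-validate the returned primal explicitly
(`‖S v‖∞` and bound violations below 10⁻⁹ × the largest flux magnitude),
making them solver-independent. For the same reason, pinned bounds are set
exactly (`lb = ub = v`) rather than as hair-width intervals, which GLPK's
scaled simplex can reject outright.

### Community assembly

Member/host ids are suffixed with the member tag; luminal transport
reactions `IEX_<met>_lu_<tag>` (positive flux = secretion into the lumen)
connect every extracellular metabolite to the shared `lu` compartment, and
each lumen metabolite gets a diet exchange (`EX_<met>_lu_diet`, uptake
only, closed until a diet opens it) and a fecal exchange
(`EX_<met>_lu_fecal`, secretion only). The member's own extracellular
exchange reactions are removed — the lumen boundary replaces them — while
internal sinks and demands are kept. The host is linked to the lumen
exactly like a member. Diet allowances are mmol/hr per community; member
abundance is encoded in the pareto weights, never in the stoichiometry.
Underscore suffixes (`_diet`/`_fecal`) are used instead of the
parenthesized convention some community-modeling tools print, because
parentheses are not valid SBML identifier characters and would not
round-trip.

Subsystem labels are needed by the pathway score; they are read from SBML
groups or notes and default to "unassigned". Our own writer persists them
as reaction notes, which keeps the SBML output byte-deterministic (group
membership order is not deterministic across processes).

### Pareto optimization

Both searches start at the per-objective minima under current constraints
and stop on a maximum iteration count (default 100) or when the step norm
falls below the tolerance (default 10⁻⁶, Euclidean). The linear search uses
per-objective increments of (max − min)/max_iterations; because the
feasible region is convex and contains the start, feasibility along the ray
is monotone, so the integer scan is implemented as a bisection over the
step count (identical result, logarithmic LP count), followed by
step-halving until the tolerance is met so the returned point sits on the
pareto front rather than on the last integer grid point. The weighted
search bisects the scaling of the ray whose direction is the weight vector.
Feasibility of a candidate objective vector is tested by raising the
objective reactions' lower bounds to the candidate and solving — matching
"advance until infeasible" semantics. At the returned point the sum of
objectives is maximized once to extract a concrete flux vector; this cannot
introduce dominance (any dominating point would have a larger sum inside
the same region).

The weighting rule fixes the host at 1/6 and splits the remaining 5/6
between the beneficial and harmful classes by the beneficial-abundance
percentage, equally within each class. Weights that round to four decimals
reproduce the published scheme at 20/40/60/80% (the 0.0555 printed in one
row is the 4-decimal rounding wobble of 1/18).

## PBPK layer

The six-tissue parameter set shipped for the fixtures uses order-1 volumes
and flows (L, L/hr), permeability–surface products of 1 L/hr, partition
coefficients of 1, blood volume 1 L and renal clearance 5 L/hr; organ gram
weights follow rat-scale values (small intestine 7.26 g, brain 2 g) because
the flux/concentration bridge divides by organ gram weight. The left-hand
volume factors `f·V_T/(1+f)` (vascular) and `V_T/(1+f)` (extravascular) are
implemented exactly as the governing equations are written, and the
conservation helper `total_amount` uses the same effective volumes, so mass
balance closes exactly when clearance and source terms vanish. The blood
pool is a single well-mixed arterial compartment with flow-weighted venous
return; renal clearance acts on the arterial concentration (the standard
minimal closure; an intrinsic per-tissue elimination rate is available per
tissue if clearance at the kidney extravascular site is preferred).

Integration uses LSODA with rtol 10⁻⁸ and atol 10⁻¹² M, sampled on the
coupling grid. Concentrations that undershoot zero (possible when a
consumption term drains a pool faster than permeation refills it within a
step) are clipped to zero with a logged warning.

## Hybrid coupling

Operator splitting is explicit and COBRA-first: bounds are derived from
start-of-step concentrations, the organ LPs are solved, and their realized
fluxes drive the ODEs as constant terms for one step. The
concentration→bound conversion is
`C (M) × V_EV (L) × 10⁹ / gram weight (g) / Δt (hr)` on the nmol/g/hr
scale — the whole extravascular pool may be consumed within one step (the
static-dFBA assumption). As written without the 10⁹ and the Δt division the
conversion would carry units of mol/g, so both factors are made explicit
here; model fluxes in mmol/gDW/hr are bridged with a constant 10⁶ nmol per
flux unit, and the organ's gDW is equated to its gram weight. The inverse
conversion (flux → mol/hr source term) needs only the gram weight; the
round trip recovers the concentration exactly.

Within a step the stages are pinned sequentially: pareto growth (weighted
for the gut community, ATP maintenance for the brain), then maximal toxin
output exchanges with the input reactions temporarily closed — so
generation measures internal production rather than an uptake/re-export
pass-through — then maximal toxin inputs under the pinned outputs
(consumption), then GABA/glutamate demand fluxes under the fully pinned
state. For coupled toxin species the community's fecal outlet is closed
during coupling so every toxin molecule crossing the organ boundary is
attributed either to the PBPK pool or to metabolic detoxification; without
this the LP can launder the entire extravascular pool through the lumen
into feces each step, which both overstates "consumption" and makes the
equilibrium step-size-dependent. Steady state is reported at the first step
whose relative concentration change drops below 10⁻⁶.

At the default conditions the per-step generation and consumption terms are
capacity-limited rather than pool-limited after the first step, so the
trajectory is insensitive to the step size: halving Δt from 15 to 7.5 and
3.75 min moves 2-h endpoints by parts in 10⁸ or less. Refinement tests
therefore assert that endpoint changes are bounded and do not grow beyond
the solver noise floor, rather than a strict decrease between two numbers
that are already numerically identical.

## Comparison layer

`mean_shift` is absolute (symmetric in the two states); `range_change` is
kept signed, as the defining expression has no absolute value, and ranking
uses its descending value to break mean-shift ties (residual ties break
lexicographically so rankings are reproducible). A reaction counts as
"shifted" for the pathway score when its mean shift exceeds a threshold
(default 10⁻⁶ flux units, the numerical-noise floor; configurable). No
significance test is attached to pathway scores — they are reported raw.
Secretion ranking closes each metabolite's own diet uptake while maximizing
its fecal exchange, so a diet component flowing through the lumen untouched
is not reported as a secretion product; member attribution reads the
luminal transport fluxes at the maximizing solution and is unique only when
a single member can produce the metabolite.

The toxic/non-toxic protocol forces the toxin exchange lower bounds to the
steady-state fluxes from the hybrid integration (toxic) or to that value
scaled by a low-exchange fraction, default 0 (non-toxic), and compares the
two states by FVA at 100% of the pinned objective (no optimality
relaxation; the fraction an external study would use is not specified
anywhere we could anchor to, and 100% matches the pinned-state semantics).

## Fixtures: what they emulate and what they do not

The fixtures are hand-designed minimal networks with analytically known
optima, not random networks, so every test is hand-checkable. Beneficial
members ferment fiber at 2 carbon units per fiber (1 per glucose); harmful
members prefer glucose (2 per glucose, 1 per fiber) and co-secrete 0.3 H₂O₂
and 0.3 superoxide per unit biomass; every member's biomass requires 0.02
O₂ so anaerobic conditions stop growth without oxygen ever being the
binding constraint under the default diets. The host grows on glucose,
degrades at most 0.1 mmol/gDW/hr of H₂O₂ and carries superoxide dismutase
(2 H⁺ + 2 O₂˙⁻ → O₂ + H₂O₂) — which, as in the real system, converts a
superoxide burden into additional H₂O₂. The brain routes glucose into an
energy branch (ATP + NADPH) and a carbon branch (glutamate); GABA synthesis
and toxin detoxification compete for NADPH, so toxin influx lowers the
attainable GABA demand while the bounded ATP-maintenance demand stays
feasible. The two diets carry equal total carbon (12 mmol/hr) weighted
oppositely between fiber and glucose, so diet effects are compositional,
not caloric.

The default layout is five members (2 beneficial, 3 harmful) plus host,
mirroring the five-microbe community scale; a ten-member layout doubles it.
Default coupling conditions are a 15-min step, 6-h horizon and 10⁻⁴ M
initial toxin concentrations. Test problem sizes are deliberately
desk-scale: the bookkeeping and refinement properties run the harmful-only
community over 1–2 h horizons.

Passing tests on these fixtures demonstrate that the machinery — assembly,
pareto search, unit bridge, ODE transport, statistics — is correct and that
the qualitative intervention effects (probiotic addition lowers toxin
levels; a high-fiber diet lowers harmful-community toxin output) follow
from resource competition as designed. They do not demonstrate anything
about real gut communities: genome-scale reconstructions have thousands of
reactions, redundant pathways, and secretion spectra the ~12-reaction toys
cannot imitate, and quantitative outputs (growth rates, secretion counts,
pathway lists) require those external models and curated diets as inputs.

## Known limitations

- The coupling is first-order (Lie splitting) with a fixed grid; no
  adaptive step control or fully ODE-embedded dFBA.
- Generation/consumption terms are constant within a step, so a consumption
  term can transiently overdraw a small pool (clipped at zero).
- LP degeneracy makes secretion attribution representative, not unique.
- No thermodynamic or loopless constraints; no gap-filling or curation of
  input models.
- QSPR estimation of partition coefficients, permeabilities and clearances
  is out of scope; these are user-supplied parameters.
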