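# Methods

## Model and units

A network is a `CompartModel`: metabolites with concentration bounds
(mol/L), reactions with stoichiometry, flux bounds (mmol/gDW/h),
optional standard transformed reaction Gibbs energies ΔrG′° (kJ/mol,
with uncertainty) and optional catalytic efficiencies kcat/MW
(h⁻¹/kDa), plus a proteome budget E_total (g enzyme/gDW).
Concentrations are stored in mol/L and all logarithms are natural logs
of the numeric value in mol/L (reference state 1 M), so ΔrG′ = ΔrG′°
exactly at unit concentrations. Because kDa = g/mmol, an enzyme cost
v/(kcat/MW) comes out directly in g enzyme per gDW.

Defaults follow physiological practice for E. coli-like cells:
RT = 2.579 kJ/mol (310 K); concentration window 0.5 µM–20 mM for
ordinary metabolites, with special windows for dissolved O₂
(0.5–200 µM), CO₂ (0.1–100 µM) and ammonium (10 µM–1 mM); E_total =
0.13 g/gDW. Redox cofactor pairs can carry a concentration-ratio
constraint (ln c_a − ln c_b within log ratio bounds).

Reactions without a ΔrG′° — exchanges, biomass, lumped sinks — are
*exempt* from thermodynamic constraints rather than assigned 0;
reactions without an efficiency are exempt from the enzyme budget.
Boundary metabolites are excluded from mass balance and carry no
concentration variable. Reversible reactions are split into
irreversible forward/`_reverse` pairs with negated stoichiometry and
ΔrG′°; both directions inherit the reaction's single efficiency unless
the parameter table provides direction-specific rows.

## The MDF mixed-integer program

Variables: fluxes v ≥ 0 (after splitting), log-concentrations x within
their bounds, binary activity indicators z for thermodynamically
constrained reactions, and the free MDF variable B. Constraints:

* mass balance S·v = 0 over non-boundary metabolites;
* optional enzyme budget Σ v_i/eff_i ≤ E_total;
* indicator linking v_i ≤ ub_i·z_i (infinite bounds capped at
  `flux_cap` = 1000 mmol/gDW/h so the coefficient stays finite);
* driving force f_i = −(ΔrG′°_i + RT Σ_j s_ij x_j) ≥ B − M(1 − z_i)
  with big-M default 1000 kJ/mol, audited at assembly time against
  |ΔrG′°| + RT·(stoichiometry-weighted log-bound span) per reaction;
* concentration-ratio constraints on designated metabolite pairs.

B is unconstrained in sign: a negative optimum is reported as is and
"thermodynamically infeasible" is a label for B < 0, not a solver
constraint. Everything is solved with HiGHS through
`scipy.optimize.milp`; pure LPs (the concentration-side analyses) use
`scipy.optimize.linprog`. HiGHS is deterministic on these problem
sizes, so re-running a configuration reproduces the numbers exactly.

Four solve modes share the assembly: FBA; parsimonious FBA as a
lexicographic two-stage solve (fix the objective within
`flux_tol` = 1e-6, then minimise total flux); max-MDF at a required
product flux; and max product flux at a required MDF. When max-MDF is
called with zero demand, a Σz ≥ 1 constraint keeps B bounded and the
result is the best achievable driving force of any single reaction.

## Staircase profiling

`sweep_mdf_curve` evaluates max-MDF on a uniform demand grid from 0 to
the FBA maximum (default 50 points) and bisects every MDF drop until
the turning point is localised within 1e-3 flux units. Stages are
detected by greedy left-to-right grouping with `stage_tol` =
0.01 kJ/mol — wide enough to absorb solver noise, far below the
spacing of distinct pathway MDF levels. Stage flux ranges are
half-open (lo, hi], so each turning point belongs to the stage it
terminates. The zero-demand grid point is evaluated at an
infinitesimal positive demand (100·`flux_tol`, safely above the MIP
feasibility tolerance): the staircase profiles the *product pathway*,
whereas a literal zero demand would profile the best single reaction
anywhere in the network.

## Bottlenecks, limiting metabolites, key enzymes

The bottleneck procedure runs five steps in order: (1) max MDF B* at
the requested demand; (2) max product flux with B ≥ B*; (3) pFBA at
that flux and MDF; (4) with fluxes *fixed to the pFBA witness*,
maximise each active reaction's driving force individually while all
active reactions keep f ≥ B* (an LP over log-concentrations); (5)
reactions whose individual maximum equals B* within `mdf_tol` =
1e-4 kJ/mol are the bottlenecks — one is *localized*, several are
*distributed*. Fixing fluxes to one witness follows the procedure's
step order; alternate pFBA optima could in principle shift the set,
which is why diagnostics are reported together with the variability
analyses rather than from a single witness alone.

Concentration variability then minimises/maximises each ln c_j of the
metabolites touched by bottleneck reactions over the same feasible
set. A metabolite is *limiting* when its range collapses
(conc_max/conc_min ≤ 1 + `var_tol`, `var_tol` = 1e-3): the reason is
the bound it sits on when within `var_tol` of a concentration bound
(the bound reason wins), otherwise *balanced* — it appears with
opposite signs in different bottleneck reactions and its level is
pinned by their opposing driving-force requirements.

Enzyme-cost variability fixes the product flux and MDF as constraints,
leaves fluxes otherwise free, and minimises/maximises each
e_i = v_i/eff_i (a MILP per reaction). A reaction `is_key` when its
cost range is below `key_tol` = 1e-6 g/gDW *and* the budget binds —
established by checking that even the minimum total cost sits within
`bind_tol` = 1e-6 of E_total, so the budget is tight over the entire
constrained slice, not just at one witness. Raw ranges are always
reported so users can re-threshold.

## Microcompartment merging

`merge_reactions` replaces ≥ 2 irreversible partials by their
multiplier-weighted stoichiometric sum. Intermediate detection is
automatic (net coefficient below 1e-9); declared intermediates are an
audit that must cancel exactly, and a merge in which nothing cancels is
a warning (pure lumping), not an error. Merged parameters: ΔrG′° =
weighted sum (overridable, with the additivity value still logged);
uncertainty = root-sum-square of the parts' uncertainties
(independence assumption); efficiency = minimum kcat/MW over parts
(a catalytic cycle is limited by its weakest step); genes = union;
flux cap = min(part cap / multiplier). Parts are shut — status data,
not deletion — and a `reversible_pair` flag adds the mirrored reaction.
Multipliers are positive integers; fractional lumping is out of scope.

Two exact properties follow algebraically and are verified
numerically: driving forces add (f_merged = Σ mult·f_part at every
concentration vector, because the intermediate log terms cancel), and
therefore merging active reactions can never lower a non-negative MDF
(Σ mult·f ≥ (Σ mult)·B ≥ B). The converse trade-off — merging never
*raises* the stoichiometric flux maximum, since it removes degrees of
freedom — is checked on the coupled motif.

The redundancy scan flags orphan-substrate and dead-end-product
reactions structurally and blocked reactions by flux variability. The
mirror direction of a split reversible pair is not counted as a
producer/consumer for its partner: the pair alone can only run a
futile cycle, which would otherwise hide isolated-stereoisomer
substrates from both the structural scan and plain FVA.

## Synthetic generators

The generators produce the study conditions for every analysis stage
without external downloads; all are deterministic given their config
(default concentration window 1e-6–1e-2 M, uptake 10 mmol/gDW/h,
kcat/MW 100–4000 h⁻¹/kDa bracketing typical central-metabolic values,
E_total 0.13 g/gDW). They return `(model, thermo_config)` pairs
because ratio constraints live in the thermodynamic config.

* `gen_linear_chain`: uptake → M0 → … → sink with assigned ΔrG′° per
  step. (−5, +10) is the canonical *distributed* fixture — the two
  steps must share the feasible span, MDF = (5 − 10 + RT ln 10⁴)/2 ≈
  9.377 kJ/mol; (−30, +30) is the canonical *localized* fixture —
  the +30 step alone pins MDF = −30 + RT ln 10⁴ ≈ −6.247 kJ/mol.
* `gen_coupled_motif`: unfavorable U (+30) and favorable F (−34)
  share a gene and a cofactor pair with ratio window [0.5, 2]; an
  independent parallel branch (+18) sets the post-merge ceiling, so
  merging raises the MDF from −4.459 to +5.753 kJ/mol, and widening
  the ratio window to the full concentration range makes merging
  neutral — the motif isolates exactly what the ratio constraint does.
* `gen_branched_network`: a high-MDF route capped at 3 flux units in
  parallel with a low-MDF uncapped route, giving a two-stage staircase
  with its turning point at the cap.
* `gen_random_model`: a random backbone chain (occasional coefficient-2
  steps to exercise integer merge multipliers) with dead-end side
  branches. Feasibility by construction: a concentration vector is
  sampled inside the bounds first and each backbone ΔrG′° is then
  drawn so that vector gives the step a driving force in
  [0.1, 5] kJ/mol — guaranteeing pre-merge MDF ≥ 0.1 without rejection
  sampling, which the merge-monotonicity property test requires.

What the generators do *not* emulate: genome-scale topology (cofactor
coupling across many pathways, biomass drains), ΔrG′° estimation error
structure, and enzyme saturation. Passing tests therefore demonstrate
the correctness of the procedures on networks with the assumed
structure, not the numerical behaviour of any particular genome-scale
reconstruction; genome-scale models are supported as inputs through
the BiGG-JSON/TSV interface but are deliberately outside the test
scope.

## Numerical choices and degenerate inputs

MILP integrality/feasibility tolerances are HiGHS defaults; optima are
re-imposed as constraints with a 1e-7 slack to absorb round-off.
Problem sizes in the bundled analyses are small (≤ ~30 reactions), for
which every solve is well under a millisecond to a few milliseconds;
the property suites use 100 seeded models and 5–8-point staircases to
keep a full run in tens of seconds. Ties between alternate optima are
broken by the solver; diagnostics never rely on a single witness where
a variability analysis exists. Degenerate cases: shut reactions keep
their stored bounds but present effective bounds (0, 0); a merge whose
stoichiometry cancels completely is an error; zero or negative
concentration bounds on non-boundary metabolites are validation
findings (the log is undefined); `detect_stages` stops at the first
infeasible (NaN) staircase point.

## The brute-force oracle

`mdflux.bruteforce` evaluates driving forces directly on a dense
log-concentration grid (no linear programming), chunking over the
first axis to keep memory at n^(k−1); it is exponential in the number
of metabolites (≤ 5) and exists purely as an independent cross-check
of the MILP. At 200 points per axis the discretization error of the
reported optimum is below 0.05 kJ/mol on the two-step chains, which is
the agreement tolerance used in the tests.

## Known limitations

* GPR rules are stored but not evaluated; gene sets are flat (shared
  enzymes are detected by gene identity only).
* No loopless-FBA or pathway enumeration; futile cycles are handled
  only where the redundancy scan's sibling rule applies.
* Transport thermodynamics (membrane potential, proton motive force)
  and enzyme saturation/temperature effects beyond the RT·ln(ratio)
  term are out of scope.
* Merged-reaction kinetics use the minimum-efficiency attribution; a
  channelled complex could in reality be faster or slower than its
  weakest isolated step.
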