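# Methods

## Model class and rate-law convention

Every reaction is reversible mass action with a single rate constant and an
equilibrium constant folded into the reverse term,

    v = k (Π_reactants [X]^|n| − Π_products [X]^n / K_eq),

exponents equal to absolute stoichiometric coefficients. Irreversible
reactions carry a `K_eq = ∞` flag rather than a large number, so the
reverse term is dropped exactly instead of contributing round-off. This
convention makes the rate constant directly solvable from a reference flux
and concentration set (the PERC relation below); it is the reason the
package does not use Michaelis–Menten or Hill forms anywhere.

Protons and water appear in stoichiometries but are clamped at unit
activity (biochemical standard state at constant pH); all equilibrium
constants are therefore apparent constants at pH ≈ 7. Concentrations are
mmol/L, time is hours.

## The base network

Glycolysis (HEX, PGI, PFK, ALD, TPI, GAPDH, PGK, PGM, ENO, PYK) plus
lactate dehydrogenase, adenylate kinase, an ATP-hydrolysis load
(ATP + H₂O → ADP + H⁺ + Pᵢ, the perturbation handle), transmembrane
phosphate exchange, boundary exchanges (glucose import against a fixed
plasma concentration, first-order lactate export, a pyruvate exchange at
equilibrium), and optionally the Rapoport–Luebering shunt (DPGM, DPGase)
with a one-step hemoglobin/2,3-DPG binding equilibrium. Inorganic phosphate
is dynamic. With the shunt disabled, its PGK bypass flux and its phosphate
release are folded back into PGK and the ATP load so the reduced network
still balances.

## Parameterization (PERCs)

Given a reference state (concentrations x*, net fluxes v*, equilibrium
constants), every rate constant is the pseudo-elementary rate constant

    k_i = v_i* / (Π x*_reactants − Π x*_products / K_eq,i).

The denominator's sign must match the flux sign; a mismatch is reported as
a thermodynamic-infeasibility error naming the reaction, never silently
absorbed into a negative k. Reactions carrying zero net flux at reference
(adenylate kinase, the exchanges, hemoglobin binding) cannot be solved this
way; they must sit at equilibrium (Γ = K_eq is checked) and take their rate
constants from the reference data. By construction the parameterized model
satisfies S·v(x*) = 0 to round-off, which the steady-state verifier and a
1000-hour drift test confirm.

## Enzyme modules

Mechanisms (R = relaxed/active, T = tense/inactive):

* **PFK** — homotetramer, MWC. R₀⇌T₀; sequential AMP binding R_i → R_{i+1}
  (4 steps); sequential ATP binding on T (4); on each R_i ordered catalytic
  binding (ATP then F6P) and one irreversible termolecular release
  R_i·ATP·F6P → R_i + FDP + ADP + H⁺. 24 reactions, 20 forms, 15 active.
* **PYK** — homotetramer, MWC, FDP activation, ATP inhibition on T,
  random-order PEP/ADP binding, irreversible catalysis. 34 reactions,
  25 forms, 20 active.
* **HEX** — monomer, random-order GLC/ATP binding, irreversible catalysis,
  three dead-end inhibitor complexes: E·G6P, E·2,3-DPG, and E·GLC·ADP
  (ADP product inhibition at the ATP subsite). 8 reactions, 7 forms,
  4 active.

Allosteric sites are independent: the sequential activator/inhibitor steps
share one dissociation constant and carry no statistical multiplicity
factors. T-state forms bind no catalytic-site ligands. Catalysis fires from
every R_i, including R₀, with one shared k_cat. Product release is a single
termolecular step; two-step release schemes would need elementary constants
that are not identifiable from a steady state.

The active set is every R-conformation (or monomer) form free of dead-end
inhibitors, and f_A is its summed concentration over E_total.

### Module parameterization

Binding steps are assigned k_off = κ_fast and k_on = κ_fast/K_d, i.e.
binding equilibrates fast relative to turnover; κ_fast defaults to 10⁶ hr⁻¹
(HEX, PFK) and 10⁸ hr⁻¹ (PYK — its solved k_cat is ~1.7·10⁶ hr⁻¹ because
PEP occupancy is far below saturation, so binding must be faster still or
the mechanism cannot carry the reference flux; the higher value corresponds
to a diffusion-limited on-rate). A ten-fold change in κ_fast moves
metabolite trajectories by less than 1% (tested), so results do not hinge
on this scale.

Form concentrations are initialized from the binding polynomial
(w = L^[T] · Π [ligand]/K_d, normalized to E_total), k_cat is set to the
reference flux over the summed ternary complexes, and then the module's
internal steady state (metabolites clamped at reference) is solved exactly
— the form balances are linear, so Newton converges in one step — and k_cat
rescaled until the cycle flux matches the reference flux to 10⁻⁹ relative.
Splicing removes the lumped reaction (after verifying the module's net
catalytic-cycle stoichiometry equals it exactly) and adds the forms at
their solved concentrations, so the spliced model starts at a verified
steady state and the enzyme total appears as a conserved pool.

## Simulation

`solve_ivp` with LSODA (stiff/non-stiff switching) and an analytic
Jacobian; default rtol 10⁻⁹, atol 10⁻¹² because enzyme-form concentrations
(10⁻⁶–10⁻⁴ mM) coexist with millimolar metabolites and binding rates span
eight orders of magnitude. The output grid merges log-spaced early points
(fast binding transients) with a uniform grid over the window. Small
negative solver excursions are clipped at zero in rate evaluations;
excursions beyond tolerance abort with the last good time. Conserved pools
are found as the exact rational left null space of the stoichiometric
matrix restricted to dynamic species.

## Analyses

* **Energy charge** EC = (ATP + ADP/2)/(ATP + ADP + AMP), of the free
  (unbound) adenylates.
* **Catalytic-potential curve**: f_A per enzyme against EC along a
  trajectory, with quadrants I–IV defined relative to the initial
  homeostatic point.
* **Net ATP usage**: per time point, the sum of each reaction's net
  contribution to the ATP balance, split into formation and consumption
  pools (reverse microscopic fluxes are not separated out). Zero at any
  steady state; negative means net consumption.
* **SSE disturbance metric**: squared deviations of net ATP usage from the
  zero setpoint summed over a fixed uniform grid (default 1000 points over
  the simulation window) so values are comparable across models.
* **Perturbation protocol**: a sustained step in the ATP-hydrolysis rate
  constant at t = 0, simulated for 1000 h (both the +50% and −15% steps use
  the same window).
* **Phase portraits**: paired f_A series for two kinases with the sign of
  their Spearman rank correlation; directionality statements throughout use
  Spearman correlation over the stored trajectory grid.

## Cohort sensitivity

Randomized states are drawn log-uniformly within per-metabolite bounds and
accepted only if sign(v)·(1 − Γ/K_eq) > 0 for every flux-carrying reaction
(an explicit accept/reject predicate rather than an external sampler);
zero-flux reversible reactions are then re-centred at equilibrium so the
sample can be parameterized.

Synthetic cohorts multiply each dynamic concentration by a log-normal
factor (σ = 0.2 by default) and re-derive each reaction's K_eq so the
individual's disequilibrium ratio ρ = Γ/K_eq is the nominal one raised to a
log-normal power — ρ^t stays in (0,1) for t > 0, so every individual is
feasible by construction and equilibrium reactions stay at equilibrium. One
designated individual can carry fold-changed module dissociation constants
(default: PFK's catalytic ATP- and F6P-binding K_d ×3), emulating a subject
whose PFK binding affinities deviate. Cohort labels carry the source-study
individual ids (2, 4, 5, 6, 7, 8, 10, 16, 18 for the nine-member cohort).

Per-reaction PERC vectors across the cohort are screened with Dixon's Q
(gap to the nearest neighbour of the point farthest from the median, over
the range), compared against a Monte-Carlo critical value: the confidence
quantile of Q = max(x₍₂₎−x₍₁₎, x₍ₙ₎−x₍ₙ₋₁₎)/(x₍ₙ₎−x₍₁₎) over ≥10⁵ samples
of n iid standard normals. This reproduces the published two-sided r₁₀
tables (e.g. 0.598 for n = 9 at 99%) to within 0.01. Vectors that are
constant across the cohort (the case for module binding constants when no
individual deviates) are skipped with a note, not flagged.

## The nominal reference state: what it is and is not

The packaged nominal state is a curated, thermodynamically consistent RBC
steady state, not a measurement: concentrations sit at standard literature
values, the flux vector is built in the null space of S (glycolytic
throughput 1.12 mmol/L/hr, 0.25 mmol/L/hr through the shunt), and apparent
K_eq values respect known directionality, with near-equilibrium steps
(PGI, ALD, PGK, PGM) close to their mass-action ratios.

Where the quantitative source parameterization was not available, values
were fixed once, inside physiological ranges, so that the model reproduces
the qualitative RBC behaviors the analysis is built to display:

* intracellular glucose 2.0 mM against 5.0 mM plasma — enough transport
  headroom to stabilize the unregulated base model, without the glucose
  surge that an overly steep gradient produces;
* HEX K_m(ATP) = 0.5 mM (substantially ATP-saturated at rest), G6P
  inhibition at 10 µM, 2,3-DPG inhibition in the weak millimolar range, and
  ADP product inhibition at 1 mM — together these tie f_A(HEX) to the
  adenylate pool (direct relation with energy charge) rather than to the
  2,3-DPG pool;
* a 4.0 mM 2,3-DPG reservoir turning over in ~16 h chemically (~50–70 h
  for the network mode) — the dominant slow mode of the load response, as
  in vivo, and the reason disturbance-rejection differences between model
  variants are resolved on the SSE grid;
* PYK: FDP half-activation near the resting FDP concentration, weak
  allosteric ATP inhibition (K_d 2.5 mM), L = 2 — a moderate FDP coupling
  that preserves the direct f_A–EC relation without throttling the lower
  pathway so hard that regulation becomes counterproductive;
* enzyme totals of a few tens of nanomolar, giving turnover numbers of
  ~17 s⁻¹ (PFK), ~25 s⁻¹ (HEX) and ~480 s⁻¹ (PYK).

Passing tests therefore demonstrate internal consistency and the
qualitative regulatory physics on a physiologically plausible synthetic
state; they are not a quantitative fit to any individual's data. The
synthetic cohort emulates multiplicative inter-individual variation only —
no covariance structure between metabolites, no plasma compartment.

## Numerical choices and degenerate inputs

* PERC solving errors on an equilibrium denominator with nonzero flux and
  on sign mismatches; zero-flux reactions without a supplied rate constant
  get k = 0 with a note.
* Module parameterization errors when the ternary complex is vanishingly
  populated (all-tense limit) and warns with k_cat = 0 when the reference
  flux is zero.
* Dixon's Q errors for n < 3 and zero range; the screening layer converts
  the zero-range case into a "constant; skipped" note.
* Empty models produce empty steady-state reports; empty cohorts are valid.
* Suspect selection in Dixon's Q is the value farthest from the median;
  ties resolve to the first index (numpy argmax).

## Known limitations

* Saturation enters only through explicit enzyme-form occupancy; all other
  reactions are first-order mass action, so lumped steps over-respond to
  substrate accumulation.
* Magnesium complexation, pH dynamics, the pentose phosphate pathway and
  oxygen-dependent hemoglobin substates are outside the network boundary;
  hemoglobin is a single 2,3-DPG binding equilibrium.
* The MWC mechanisms use one dissociation constant per ligand class;
  cooperative (KNF) schemes and two-step product release are not modeled.
* The SSE metric depends on its evaluation grid; comparisons are only
  meaningful between models run under the same protocol.
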