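# Methods

## The model and its assumptions

`picompete` implements classical resource-competition theory for two
consumers on two substitutable resources: *Prochlorococcus* and
*Synechococcus* growing on nitrate and ammonium. Growth equals the sum
of the two Michaelis–Menten specific uptake rates minus a constant
specific mortality; nutrient balances subtract quota-weighted uptake
from a constant external supply. The formulation deliberately omits
light, temperature, phosphorus, iron, urea and organic nitrogen, as
well as intracellular nitrogen pools or any decoupling of uptake from
growth — uptake is converted to growth instantaneously through the
fixed cellular quota QN. Grazing and viral loss are folded into the
single mortality term. These simplifications restrict the model to
N-limited, well-mixed settings (nanomolar surface waters, prefiltered
bottle incubations) on timescales of days to the quasi-steady state.

Units are fixed package-wide: days, nmol N L⁻¹, cells L⁻¹,
nmol N cell⁻¹, nmol N L⁻¹ d⁻¹.

Two trait summaries matter at low nutrients. The affinity
`A = Vmax/K` is the initial slope of the uptake curve and decides
competition when concentrations are depleted. The preference
crossover, `c* = (Vmax_NO3·K_NH4 − Vmax_NH4·K_NO3)/(Vmax_NH4 −
Vmax_NO3)`, is the concentration at which the two uptake rates are
equal; it is reported as absent when the two Vmax are equal or the
root is non-positive (one substrate is then preferred at every
concentration).

## Reference parameterization

The package ships a reference trait set (`default_config`) encoding
the qualitative structure inferred from nanomolar N-addition
incubations in the subtropical NW Pacific, with clean round numbers
chosen to satisfy all of the following simultaneously:

| parameter | Pro | Syn | unit |
|---|---|---|---|
| Vmax (NO₃⁻ / NH₄⁺) | 0.1 / 1.2 | 0.6 / 1.0 | d⁻¹ |
| K (NO₃⁻ / NH₄⁺) | 45 / 8 | 15 / 51 | nmol L⁻¹ |
| m | 0.12 | 0.12 | d⁻¹ |
| QN | 5·10⁻⁷ | 1.5·10⁻⁶ | nmol cell⁻¹ |

Supply defaults are S_NO3 = 2.5, S_NH4 = 7.5 nmol L⁻¹ d⁻¹ (ratio 1:3);
ambient initial conditions are 2.5·10⁷ Pro and 4·10⁶ Syn cells L⁻¹ with
5 nM of each nutrient.

The constraints: *Prochlorococcus* holds the lower ammonium
half-saturation and *Synechococcus* the lower nitrate one;
*Synechococcus* has the larger nitrate Vmax; both genera take up
ammonium faster than nitrate at saturation; *Synechococcus*' nitrate
affinity exceeds its ammonium affinity, with the preference flipping
to ammonium at exactly 39 nM; the community coexists stably at the
1:3 supply ratio with Pro drawing ~95% of its N from NH₄⁺ and Syn
~87% from NO₃⁻; and a +100 nM NH₄⁺ amendment is drawn below the 6 nM
detection limit on day 3 of a bottle incubation (not earlier). Quotas
correspond to ~7 fg N per Pro cell and ~21 fg N per Syn cell. With
equal mortalities and strong specialisation the equilibrium biomass
ratio N_Pro/N_Syn tends to S_NH4/S_NO3; at the defaults it is ≈ 3.1.
Config files use the conventional symbol names (VmaxNO3Pro, KNH4Syn,
mPro, QNPro, SNO3, …), so an externally fitted table can be pasted in
verbatim.

## Time integration

`integrate` uses LSODA (stiff-capable, variable step) with relative
tolerance 10⁻⁸ and absolute floors of 10⁻³ cells L⁻¹ and
10⁻⁶ nmol L⁻¹. State components are clipped to zero inside the RHS
rather than event-stopping: amendments can drive nutrients to
numerical zero and the Michaelis–Menten form is well behaved there.
The total-N budget identity, d(N_tot)/dt = S_NO3 + S_NH4 − Σ_i m_i QN_i
X_i, holds algebraically at every RHS evaluation and is conserved to
≤10⁻⁶ relative error along closed-budget trajectories — this is the
package's primary integration diagnostic.

## Steady states and zone classification

Setting each genus' growth to zero defines its zero-net-growth
isocline (ZNGI). For Michaelis–Menten kinetics the ZNGI inverts in
closed form ([NO₃⁻] as a function of [NH₄⁺]), so the interior
(coexistence) equilibrium is found by a bracketed scalar root-find
(`brentq`) on the difference of the two inverted isoclines, rather
than a 2-D Newton iteration; a genus with zero nitrate uptake has a
horizontal isocline and is handled as a special case. The contract is
the post-condition, not the algorithm: the model RHS vanishes at any
reported equilibrium to ≤10⁻⁸ in every component. Biomasses then come
from the 2×2 linear nutrient-balance system; coexistence is valid only
when both are strictly positive. Identical genera make that system
rank-deficient and raise a degeneracy error.

Single-resident equilibria are fully closed-form: zero net growth
forces the two uptake rates to sum to the mortality, and the nutrient
balances force them to split in proportion to the supply fluxes, so
`u_j = m·S_j/ΣS`, `[j]* = u_j K_j/(Vmax_j − u_j)`, `n = ΣS/m`. When
the required `u_j` exceeds `Vmax_j` the resident cannot absorb that
supply; since the model has no abiotic nutrient sink, that nutrient
grows without bound and is reported as `inf`, its balance is dropped,
and the absent genus sees it as saturating in the invasion test. This
matches the model's own asymptotics but means single-genus "states" in
those regions are not true steady states of the full system — a known
structural limitation inherited from the two-equation nutrient budget.

`classify_zone` accepts the interior equilibrium only if it is locally
asymptotically stable (numerical 4×4 Jacobian, eigenvalue real parts
negative); otherwise it falls back to uninvadable single-resident
states. Two simultaneously uninvadable boundary states are reported
with a `bistable` flag rather than resolved. Coexistence is split into
domain iv (Pro takes >50% of its N from NH₄⁺ *and* Syn >50% from
NO₃⁻ at equilibrium) versus domain i (the mirrored specialisation);
for mixed patterns the label follows the dominant joint
specialisation. The 50% uptake-fraction rule is the package's
discriminator for a distinction that is otherwise only verbal.

Sweeps: the zone map varies K_Pro/K_Syn ratios on a log-spaced 30×30
grid over [10⁻², 10²]² (figure-resolution default; per-node failures
are recorded as `none`), holding Syn's K fixed. The resource sweep
holds S_NH4 at baseline and varies S_NO3 — scenarios are phrased as
increasing or doubling the nitrate resource. Inside the coexistence
window the nitrate specialist's biomass share rises monotonically with
S_NO3/S_NH4 (a consequence of the linearity of the biomass system in
the supplies), so N_Pro/N_Syn is nonincreasing in domain iv and
nondecreasing in the mirrored domain i.

## Synthetic incubations

`generate_incubation` emulates deck-board microcosm bioassays:
triplicate bottles, treatments {control, +100 nM NO₃⁻, +100 nM NH₄⁺},
daily sampling over 3 days (defaults), ambient initial N below 10 nM.
Counts get multiplicative log-normal noise (default σ = 0.05 log₁₀
units — flow-cytometric counts span orders of magnitude, and
replicate-level variance of real cruise counts is not published, so
this default is a stand-in exposed in the design); nutrient values are
the model truth censored at the assay detection limits (3 nM
NO₃⁻+NO₂⁻, 6 nM NH₄⁺, 3 nM SRP) and reported *at* the limit with a
below-detection flag. Grazing is absent by construction, mirroring
prefiltration of the inoculum. Urea and phosphate treatments can be
generated as placeholders whose population truth follows the control;
they are excluded from fitting because the two-nutrient model does not
represent them.

What passing tests on these data do and do not show: the generator's
noise is exactly the error model the likelihood assumes (well
specified by construction), bottles are closed except for the constant
supply term, and initial states are known. Real incubations add
bottle effects, counting bias, day-to-day irradiance variation and
community interactions that none of this captures; recovery results
here are therefore a best case.

## Likelihood and Metropolis–Hastings calibration

The likelihood is Gaussian on log₁₀ abundances with a per-genus
residual scale σ estimated alongside the kinetic parameters; by
default the fit targets treatment-mean log₁₀ series (per-replicate
fitting by flag). Each treatment is simulated from its own
amendment-adjusted initial state. Nutrient observations contribute
Gaussian densities on the concentration scale (σ_nutrient = 2 nM
default, reflecting nanomolar colorimetric precision); censored
records contribute the log tail probability below the detection limit
instead of a point density. Failed integrations score −∞ and are
rejected.

Sampling is random-scan Metropolis–Hastings: one randomly chosen free
parameter per iteration, multiplicative log-normal proposal (scale
0.25 on the natural log, giving 30–45% acceptance here), positive
per-class bounds (Vmax 10⁻³–10² d⁻¹, K 10⁻²–10⁴ nM, m 10⁻³–2 d⁻¹,
σ 10⁻³–1). Quotas and supplies are held fixed during fitting — the
parameter count is already large, and they are constrained by other
information (cell size, field setting). Defaults are 20 000 iterations
with 5 000 burn-in, sized for desk-scale reruns of the bundled
experiments; chains are deterministic for a fixed seed.

Priors. A 100k-iteration diagnostic showed that with flat priors on
the log-parameters the 10-parameter posterior is not identified at
this data volume (3 replicates × 4 days): Vmax–K ridges let weakly
constrained pairs — especially *Prochlorococcus*' nitrate kinetics,
whose uptake is small everywhere — wander over decades, and the
posterior probability of the correct K-ratio ordering approaches a
coin flip. The calibration step is therefore framed the way it is used
in practice: as *refinement of a manual pre-fit*. A weakly informative
log-normal prior with σ = 0.3 decades (a factor ≈ 2 at 1σ) is centred
on the starting parameterization, anchoring unidentified directions
near the pre-fit while the data dominate wherever they are
informative. `prior_sigma_log10=None` restores flat priors for users
who want the unregularized posterior. In the bundled recovery
experiment the pre-fit is the truth perturbed by up to ×1.4 per
parameter; with this setup the K-ratio orderings are recovered in
20/20 seeded repeats and the central 90% intervals cover the true
kinetic parameters ~90% of the time.

The K-swap falsification exchanges one half-saturation constant
between the genera at fixed everything-else and re-simulates all
treatments; on data generated under the original traits the swap
cannot improve the fit, and it degrades it most in the amendment
treatment matching the swapped substrate.

## Numerical choices and degenerate inputs

- Sampling-path integrations use LSODA at rtol 10⁻⁵ (errors ~3·10⁻⁵
  log₁₀ units, orders of magnitude below observation noise); reported
  trajectories use the strict 10⁻⁸ tolerances.
- Crossover with equal Vmax: reported absent, not an error.
- A genus with mortality ≥ total Vmax can never persist; construction
  warns but does not forbid (such configurations arise legitimately
  inside samplers and sweeps).
- Duplicate design rows, non-positive abundances and malformed tables
  raise schema errors naming the offending rows or fields.
- Zone-map nodes where classification fails (degenerate or infeasible)
  are recorded as `none` rather than aborting the sweep.
- The ODE-based zone oracle used in the tests extends its horizon
  adaptively (chunks of 5 000 d up to 80 000 d): near domain
  boundaries invasion rates are small and competitive exclusion can
  take tens of thousands of days, so any fixed horizon misclassifies
  slow exclusions as coexistence.

## Known limitations

- No abiotic nutrient loss term, so single-resident regions of trait
  space have an unbounded unconsumed nutrient (handled as saturating
  for invaders; see above).
- Mortality is constant and genus-specific differences in loss
  processes (grazing selectivity, viral lysis) are not resolved; they
  could independently contribute to coexistence.
- The fitted σ conflates observation and process noise; the bottle
  model has no process stochasticity.
- Bistable (founder-controlled) parameter regions are flagged but the
  realised outcome then depends on initial conditions, which a
  steady-state map cannot summarise.
- The recovery experiment's error model matches the generator by
  construction; transfer to real incubation data is untested here.
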