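# Methods

## The design problem

`moodkit` tunes the kinetic parameters of a synthetic incoherent type-1
feed-forward loop (I1-FFL) so the circuit shows *adaptation*: after a step
of extracellular inducer, the output protein C shoots up to a transient
peak and then returns to (near) its pre-stimulus level even though the
stimulus persists. Because peak size (sensitivity) and return quality
(precision) pull the parameters in opposite directions, the tuning problem
is posed as a constrained bi-objective optimization, and the deliverable is
not a single parameter set but (i) the Pareto front/set of optimal
trade-offs and (ii) qualitative wet-lab guidelines distilled from it.

## Circuit model

The reduced deterministic model has nine ODE states — mRNAs and proteins of
genes gA, gB, gC, the inducer inside (`x3`) and outside (`x9`) the cell,
and the transcription-factor dimer (A·I)₂ (`x4`) — plus one algebraic
species, the monomer A·I concentration `M`, the quasi-steady state of the
fast binding reactions:

```
M = [ -(dAI+k-2) + sqrt((dAI+k-2)^2 + 8 k3 (k2 x2 x3 + 2 k-3 x4)) ] / (4 k3)
```

Gene gB is activated by the dimer through a Hill term with constant γ1;
gene gC carries a hybrid promoter activated by the dimer and repressed by
protein B, with coefficients γ2–γ5 and basal coefficients β1, β2. The
printed numerator of the gC activity is `x4 + β1 γ4 x6 + β2 γ5 x4 x6`; an
optional extra basal constant (`basal_c`, default 0) is exposed as a hook.
Inducer transport couples `x3` and `x9` through the culture-volume ratio
`K_cells = Vcell·Ncells/Vmedium` (2.4·10⁻⁴ for the default 180 µL culture
of E. coli at OD 0.3). All units are nM and minutes.

The downstream-load extension adds a reversible binding of C to a load
species (total `LT`, rates `K1`, `K2`), appending free-load and complex
states whose sum is conserved exactly.

Ten parameters are tunable in the wet lab (promoter strength × copy
number, RBS strengths, degradation tags, promoter mutations); their search
ranges are the characterized wet-lab ranges. `kmA_CgA` follows `kmC_CgC`
because gA and gC share a plasmid (an untied variant is available for
exploration).

## Stimulus protocol and pre-equilibration

The experiment pre-equilibrates the circuit with zero inducer, applies a
step `Ie_step` to `x9` at `t0 = 0` and integrates to `tf`. With no inducer
the model has an exact closed-form fixed point (only the constitutive gA
branch is on), so pre-equilibration costs nothing; the residual is checked
and numeric refinement is a fallback for model variants.

Defaults: `Ie_step = 1000 nM`, `tf = 300 min`, equilibration horizon
5000 min (all configurable). `tf` matters because the extracellular
inducer degrades (`dIe = 0.0164 min⁻¹`, half-life ≈ 42 min): the input
variation `x9(tf) − x9(t0)` that normalizes both objectives decays with
the experiment length. At 300 min the adaptation pulse is complete for
every design in the search box while the input variation (≈ 7.3 nM for a
1000 nM step) remains well above numerical noise; a much longer horizon
drives both objective numerator and denominator toward zero and makes the
indexes meaningless, a much shorter one truncates the pulse of
slow-repressor designs.

Integration uses LSODA (stiff-capable, adaptive) at `rtol 1e-8`,
`atol 1e-10 nM`. The two total-variation integrals the objectives need —
∫|dx8/dt|dt and ∫|dx6/dt|dt — are accumulated as augmented quadrature
states during integration, so their accuracy is tolerance-controlled
rather than grid-limited. Integrator outputs are clipped at zero;
negativity beyond `max(10³·atol, 1e-7) nM` is treated as a solver failure.
Linear invariants (the load sum `x10 + x11 = LT`) are conserved by the
multistep method to rounding, which the tests assert at 10⁻⁶ nM.

## Objectives, constraint, pertinency

With `x9(t0)` the pre-step value (0 after equilibration):

* `J1 = 2 (x9(tf) − x9(t0)) / ∫|dx8/dt|dt` — inverse sensitivity. The
  total absolute variation of the output is half the accumulated
  |derivative|, so J1 is the input change over the output's total
  variation; a big clean pulse gives a small J1.
* `J2 = (x8(tf) − x8(t0)) / (x9(tf) − x9(t0))` — inverse precision, the
  residual output offset normalized by the input change; perfect
  adaptation gives J2 = 0.
* `P = ∫|dx6/dt|dt`, constrained to `1 < P < 10⁴`, bounds the repressor-B
  excursion: without it the optimizer buys precision with unrealistically
  high repressor levels. (The constraint is also printed once with a 10⁵
  ceiling; the default here is the value stated with the constraint's
  rationale, and the ceiling is configurable.)

Solutions must lie in the pertinency box `J1 ∈ [10⁻³, 200]`,
`J2 ∈ [10⁻⁴, 20]`; outside it the response is no longer considered
adaptive at all. A zero-variation (flat) output maps to a `J1 = +inf`
sentinel and is never pertinent; denominators are floored at 10⁻⁹ nM.

## Optimizer

A differential-evolution multi-objective optimizer (DE/rand/1/bin,
`F = 0.5`, `CR = 0.9`, population 50, 15,000 evaluations) with three
archive mechanisms:

* an external archive of pertinent, feasible, mutually non-dominated
  solutions, updated every generation;
* archive feedback: half the mutation bases are drawn from the archive, so
  evolution keeps working along the whole stored front instead of wherever
  the population drifts (without this the population converges to a narrow
  section of the front);
* spherical pruning: the archived objectives, normalized to the archive's
  ideal/nadir box, are binned into angular sectors of the quarter circle
  and only the solution closest to the ideal point survives per sector.
  The sector count (default 33) caps the archive size and enforces an even
  spread; ~33 well-spread designs is a practical number to carry into
  guideline extraction.

Constraints use Deb's rules (feasible beats infeasible; infeasible compare
by a normalized violation of the P/pertinency ranges; among feasible the
trial survives unless the parent dominates it — elitism lives in the
archive, not the population). Out-of-bounds mutants are reflected into the
box; simulation failures score as infeasible with a large violation
instead of aborting the run. Everything is driven by one seeded generator,
so a run is bit-reproducible given its seed.

A brute-force sampler (uniform or full-factorial grid + admissibility +
dominance filter) provides the independent reference front used by the
tests: on the convex analytic benchmark the evolved front must reach the
closed-form Pareto curve, and on a 2-variable circuit reduction no point
of a 50×50 grid may dominate any archive member beyond solver tolerance.

## Guideline extraction

The Pareto front (min-max normalized objectives; parameters can optionally
be appended) is clustered agglomeratively under the Euclidean metric with
weighted-centroid (WPGMC/median) linkage. The tree is cut at every k from
10 down to 2; at each cut every tunable parameter is tested with a
Kruskal-Wallis test against the cluster labels, and the k with the most
significantly cluster-dependent parameters wins, ties toward fewer
clusters.

`alpha` (default 0.05) is interpreted family-wise: each cut tests all ten
parameters and the selection scans nine cuts, so individual tests are held
to the Bonferroni threshold `alpha/10`. With raw per-test thresholds the
max-count rule chases false positives — in planted-cluster simulations it
picked the true k = 2 only ~73% of the time, versus ~97% with the
correction. `correction="none"` restores the raw behavior.

Parameters then classify as:

* **cluster-specific** tuning knobs (significant at the corrected level):
  reported with per-cluster ranges — these encode the trade-off
  strategies (e.g. high-sensitivity vs high-precision designs);
* **general** guidelines (not cluster-dependent, but the optimized overall
  range is ≤ 0.6× the initial search width): a range required for
  adaptation regardless of strategy (e.g. dB pinned at its lower bound);
* **unconstrained** otherwise.

The 0.6 shrink factor quantifies the otherwise qualitative "optimized
range differs from the initial interval" and is configurable.

## Level Diagrams

For visualization, each solution gets one score, the p-norm (default
p = 2) of its min-max-normalized objective vector — its distance to the
ideal corner. Plotting that score against each objective and each decision
variable, colored by cluster, lets the eye trace a single solution across
panels. The canonical artifact is the data table (CSV); PNG rendering is
optional so the module works headless.

## Application scenarios

*Knob sweep*: from a chosen Pareto solution, one tunable parameter is
swept over a (default log-spaced) grid with everything else fixed. The
robustness claim — a single-knob wet-lab edit moves the design *along* the
front — is quantified as: admissible swept points are not dominated by any
front member by more than a 5% margin in normalized objective space.

*Load analysis*: every Pareto solution is re-simulated once with the
downstream load (defaults `K1 = 40 nM⁻¹min⁻¹`, `K2 = 20 min⁻¹`,
`LT = 800 nM`); the loaded system is pre-equilibrated jointly so the
free/bound load split starts at its steady state. Only |front| extra
simulations are needed — no re-optimization. Under this load the free-C
objectives shift; because the load sequesters C, J2 *decreases* for every
solution, and the displacement |ΔJ2| is largest for low-sensitivity
designs whose peaks are comparable to `LT` — the positive rank correlation
between unloaded J1 and |ΔJ2| is the asserted robustness property.

## Synthetic fixtures: what they do and do not show

* The analytic benchmark (f1 = θ², f2 = (θ−2)²) verifies optimizer
  convergence against a closed form; it says nothing about the circuit
  landscape, which the grid-oracle test covers instead.
* Planted-cluster data (two objective blobs; three parameters shifted
  between blobs, seven iid) verifies cluster-count selection and guideline
  classification with known ground truth. Real Pareto sets are curves, not
  blobs, so the planted test validates the mechanism, not the biological
  conclusion; the biological check is that real runs select k = 2 and
  recover the expected dB/γ1 guidelines.
* Analytic pulses give exact objective values (J1 = step/peak, J2 =
  residual/step) independent of any ODE solving.

None of these emulate measurement noise, cell-to-cell variability or model
mismatch; passing tests certify the pipeline's mathematics, not the wet-lab
transferability of any specific parameter value.

## Problem sizes used by the test suite

The acceptance tests run the full 15,000-evaluation optimization for three
seeds (the archive size and the k = 2 clustering are properties of the
full-budget run; at 3,000 evaluations the archive is still filling and the
cluster count is less stable). The engine-correctness checks use 2,000
evaluations (benchmark) and 1,000 + 2,500 (grid oracle). One full run
takes a few minutes on a single core; the compiled right-hand side
evaluates one stimulus response in ~10 ms.

## Known limitations

* The stimulus amplitude and horizon are design choices (see above); all
  reported quantities depend mildly on them, and figure-level point
  positions of any particular optimization run are not reproducible across
  seeds — only the structural properties are asserted.
* Median/WPGMC linkage can produce non-monotone merge heights; cluster
  counts from tree cuts are still well-defined, but dendrogram heights
  should not be over-interpreted.
* The SBML export is a compact writer for this one model (species, rate
  rules, assignment rule); it is schema-well-formed but not validated
  against the full SBML consistency-check suite.
* A dC sweep away from an optimized design degrades the response shape but
  can remain inside the (wide) pertinency box, so "adaptation destroyed"
  is not always visible as a box-flag flip.
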