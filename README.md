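# moodkit

Multi-objective, model-based tuning of synthetic gene circuits, instantiated
on the incoherent type-1 feed-forward loop (I1-FFL) adaptation circuit.

## The problem

Synthetic biologists who want a circuit with a prescribed dynamic behavior
must pick concrete biological parts — plasmid origins, promoters, RBS
sequences, degradation tags — whose kinetic parameters realize that
behavior. For an adaptation circuit the goals conflict: a big transient
output peak (high **sensitivity**) and a clean return to the pre-stimulus
level (high **precision**) pull the kinetics in opposite directions, so no
single "best" parameter set exists. `moodkit` treats part selection as a
constrained bi-objective optimization over the tunable kinetic parameters,
computes the Pareto-optimal set of trade-offs, and distills it into
qualitative wet-lab tuning guidelines.

The circuit: protein A (constitutive) binds an externally applied inducer;
the (A·I)₂ dimer activates both the output gene *gC* and the repressor
gene *gB*, and B represses *gC* — so a step of inducer produces a pulse of
C that B subsequently shuts down. The reduced kinetic model (nine ODE
states plus the algebraic monomer M, in nM and minutes) and its
characterized constants are built in; ten parameters with wet-lab handles
are the decision variables.

With the input step applied at t₀ and the experiment ending at t_f, the
minimized indexes are

```
J1(θ) = 2 (x9(tf) − x9(t0)) / ∫ |dx8/dt| dt        (inverse sensitivity)
J2(θ) = (x8(tf) − x8(t0)) / (x9(tf) − x9(t0))       (inverse precision)
```

subject to the circuit dynamics, the pertinency box J1 ∈ [10⁻³, 200],
J2 ∈ [10⁻⁴, 20], and a bound 1 < P(θ) < 10⁴ on the repressor-B excursion
P = ∫|dx6/dt|dt. The optimizer is a differential-evolution algorithm with
an external archive, spherical pruning for spread, and a pertinency bound
mechanism; the Pareto set is then clustered (Euclidean distance on
normalized objectives, weighted-centroid linkage, cluster count chosen by
Kruskal-Wallis significance maximization) to classify every parameter as a
cluster-specific tuning knob, a general guideline, or unconstrained.
Level-Diagram tables, single-knob sweeps and downstream-load (retroactivity)
re-evaluation complete the workflow. See `docs/methods.md` for the details
and the design choices.

## Worked example

```python
import moodkit as mk
from moodkit.guidelines import cluster_tree, extract_guidelines, select_k
from moodkit.model import BOUNDS, DECISION_NAMES
from moodkit.optimize import MOOConfig, run

problem = mk.CircuitProblem()                       # default protocol & box
pareto = run(problem, MOOConfig(max_evals=15000, seed=1))
front = pareto.front()

clustering = select_k(cluster_tree(front), pareto.thetas(),
                      names=list(DECISION_NAMES))
report = extract_guidelines(clustering, pareto.thetas(), BOUNDS)
```

Output (the full 15,000-simulation study budget, ~2 min on one core):

```
archive: 31 Pareto-optimal designs (15000 simulations)
J1 (inverse sensitivity): 0.0032 .. 0.0277
J2 (inverse precision):   0.315 .. 2.784
clusters selected: k = 2
  kmB_CgB  general          [1, 1.03]
  kmC_CgC  general          [1.03, 8.82]
  kpB      general          [1, 1.02]
  kpC      general          [1.1, 11.8]
  dB       general          [0.01, 0.0105]
  dC       general          [0.296, 0.3]
  gamma1   general          [191, 200]
  gamma3   general          [0.000103, 0.000313]
  gamma4   general          [3.52, 4.98]
  gamma5   general          [1, 1.03]
```

Reading it: 31 mutually non-dominated designs span roughly an order of
magnitude in both objectives — from high-sensitivity/low-precision to the
reverse — and the clustering splits them into two tuning strategies
(high-sensitivity vs high-precision). The guidelines recover the known requirements for adaptation:
the repressor's degradation rate `dB` and RBS strength `kpB` must sit at
their lower bounds, the gB Hill constant `gamma1` stays in its upper
region, and `gamma3` must be minimal, regardless of which trade-off you
implement. Each simulation integrates the stiff 9-state model plus
quadrature states in ~10 ms.

The same workflow is scriptable from the shell:

```sh
moodkit optimize  --config run.yaml     # pareto.csv + manifest
moodkit guidelines --outdir results     # guidelines.csv, stats JSON
moodkit leveldiagram --outdir results --plot
moodkit sweep --param kpC --start 5 --stop 0.05 --outdir results
moodkit loadcheck --outdir results      # retroactivity re-evaluation
moodkit export-sbml --outdir results    # SBML L3V1 of the model
```

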