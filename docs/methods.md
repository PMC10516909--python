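# Methods

## Model and procedure

fluxscan implements an enforced-objective-flux scan over a
constraint-based metabolic model at steady state: fluxes `v` satisfy
`S·v = 0` with `lb ≤ v ≤ ub`, and growth is represented by a biomass
pseudo-reaction. The scan raises the *lower* bound of the target sink
reaction in equal steps and re-maximises biomass at each step. Using the
lower bound (rather than pinning both bounds) means the optimiser may
overshoot the enforced production when that helps growth, and keeps
feasibility monotone in the step index: if step k is feasible, every
smaller enforcement is too.

Assumptions inherited from flux balance analysis apply: the cell is at
metabolic steady state, regulation is ignored, and the biomass
composition is fixed. The scan additionally assumes the target sink can
carry positive flux at all (`v_T^max > 0`) — otherwise there is nothing
to couple and initialisation fails with an explicit error.

### Alternate optima

A plain FBA optimum is a vertex chosen arbitrarily by the solver, so
per-reaction flux profiles — the scan's raw material — would not be
reproducible. By default each step is therefore solved parsimoniously:
the biomass optimum is fixed as a constraint and the total absolute
flux is minimised, yielding a canonical vector. A `deterministic=False`
flag restores raw solver output for comparison with vertex-based
implementations; classifications obtained that way can differ on
degenerate networks.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_steps` | 5 | – | enough points to see a monotone trend without multiplying LP cost |
| `cap_fraction` | 0.9 | – | last enforced value at 90% of `v_T^max`; at 100% biomass collapses to ~0 and coupling is undefined |
| `monotonicity_tol` | 1e-4 (rel), 1e-9 floor | – | "steadily changing" filter; above LP round-off, below any real trend |
| `change_tol` | 0.01 (rel), 1e-9 floor | – | |flux| change step 1→5 below 1% counts as unaffected |
| `essentiality_fraction` | 1e-3 | fraction of wild-type growth | separates numerically-zero growth from solver noise; not a fitness cutoff |
| solver tolerance | 1e-9 feasibility, 1e-6 comparisons | – | GLPK defaults tightened for reproducibility |
| `swf_variant` | `deviation` | % | see below |

The enforced schedule is `(k/n)·cap·v_T^max`, k = 1..n: equally spaced,
anchored at a positive first step and ending exactly at the cap.

### Step-weighted factor

The scoring rule is stated in the literature as
`SWF = Σ_k v_k / v̄ · 100%`, but that expression is algebraically the
constant `100·n` whenever `v̄` is the profile's arithmetic mean — it
cannot rank anything (a regression test documents this). The
accompanying description, "how much each flux value changes versus the
mean", corresponds to `SWF = Σ_k |v_k − v̄| / |v̄| · 100%`, which is
zero exactly for constant profiles, invariant under profile scaling,
and grows with coupling strength. The deviation form is therefore the
default; the literal form is retained behind `variant="literal"`.
Scores are used ordinally (ranking), not as calibrated magnitudes.

### Classification and direction

Reactions are classified on |flux| so that reversible reactions written
right-to-left are handled symmetrically; the direction (sign of the
peak-magnitude flux) is reported separately and combines with the trend
into the four proportionality partitions
(Positive/Negative × directly/contra). The flux-increasing,
flux-decreasing and unaffected sets are disjoint by construction and
cover every retained profile.

## What the fixtures emulate — and what they do not

`build_toy1` and `build_random_toy` generate small branched networks
(≤ 15 reactions) in which the coupled, anti-coupled and unaffected
reactions are known by construction. Random fixtures are trees: one
carbon source, a backbone to the biomass drain, a target branch tapped
at a random node (in either stoichiometric orientation), dead-end or
secretion side branches, and optionally a forced maintenance drain.
Tree topology guarantees a unique optimal flux vector at every step, so
fixture truth is exact.

Real genome-scale models differ in ways the fixtures deliberately do
not reproduce: thousands of reactions, cofactor cycles and parallel
pathways (hence massive degeneracy), compartments, and realistic
biomass stoichiometry. Passing the fixture tests shows the algorithm is
implemented correctly, not that candidate lists on a specific GEM are
biologically right — on degenerate networks the retained/classified
sets can shift with the solve mode, which is why both modes are
exposed.

## The oracle

`toyfixtures.oracle_scan` is an independent implementation used only in
tests: it builds the dense stoichiometric matrix itself and solves
every LP with `scipy.optimize.linprog` (HiGHS), never cobrapy. At each
step it computes every reaction's feasible flux range with biomass
pinned at the step optimum and classifies the range *midpoints* —
robust to alternate optima. Midpoints below 1e-6 in magnitude are
snapped to zero because the biomass-pinning slack (≈1e-9) otherwise
leaks microscopic flux into secretion branches and fabricates trends at
the tolerance floor. Oracle/main-path disagreement on a fixture is a
test failure, not a tolerance case.

## Numerical choices and degenerate inputs

- Enforced values above the target's upper bound make the step LP
  unposable; the step is flagged infeasible (all profiles lose
  `all_feasible`) rather than raising.
- An infeasible step inside the schedule is likewise flagged; the
  validity filter then drops every profile, which is the correct
  outcome for an over-constrained scan.
- Deletion that renders the model infeasible reports growth 0.0.
- Zero-mean profiles have no relative scale; their SWF is undefined and
  they are excluded from ranking with a log entry.
- Ranking ties are broken lexicographically by reaction id, making
  end-to-end runs byte-identical (the report CSVs contain no
  timestamps; the YAML sidecar does).
- The biomass trajectory is asserted non-increasing on every run; a
  violation indicates a solver or model defect and raises.

## Design choices

- `cobra.Model` is the in-memory model container; SBML L3+FBC and COBRA
  JSON io, FBA and pFBA go through cobrapy/optlang (GLPK). The scan,
  scoring, classification, essentiality logic and reporting are this
  package's own.
- Uptake rates in constraint files may be given as positive magnitudes
  (`uptake:` section) and are negated onto exchange bounds, matching
  how gas-exchange and exometabolome rates are reported; raw signed
  bounds (`bounds:`) are applied verbatim.
- Essentiality is screened at the reaction level; gene-level (GPR)
  deletion is out of scope, so candidate tables carry the
  gene-association strings for downstream interpretation.
- CSV is the canonical report format (diffable, testable); the XLSX
  workbook mirrors it for parity with spreadsheet-based workflows,
  including the historical `Var10` column name for the stoichiometry
  text.
- The test and acceptance problem sizes (a 6-reaction toy plus twenty
  ≤ 15-reaction random fixtures, 5-step scans) were chosen so the
  brute-force oracle — O(steps × reactions) LPs per model — stays
  exhaustive while the whole suite runs in seconds.

## Known limitations

- No enzyme-constrained or thermodynamic extensions; flux bounds are
  the only capacity information.
- No flux-variability envelope is reported per step beyond the
  feasibility check; candidate calls rest on the deterministic vector.
- Double deletions / synthetic lethality are not screened.
- SWF magnitudes are not comparable across models or to externally
  reported scores; only the ordering within one run is meaningful.
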