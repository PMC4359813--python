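# Methods

## Problem and model

The package simulates a single blood bank issuing red-cell units against
daily transfusion requests for the eight ABO/Rhesus types. Each day's
cross-matching is a compatibility-constrained multiple-knapsack problem:
one knapsack per type with positive demand, capacity equal to the demanded
unit count, items of unit weight, and a placement constraint that a
knapsack of type *r* accepts only units of types *r* can receive. Since
every knapsack must end exactly full (unmet demand is imported, and the
external source is assumed unlimited), profit maximization collapses to
minimizing the count of imported units; that count is the fitness used
everywhere.

Only red cells are modelled: no plasma/platelet components, no emergency
bypass events, no cross-match failures or returns, and no rationing —
demand is always satisfied the same day.

### Compatibility matrix

The receiver → donor matrix follows standard ABO/Rh practice: identical
type always; Rh− serves the matching Rh+; O serves A, B and AB of equal or
stronger Rh; AB+ (written C+) receives all eight and O− only itself. The
total number of compatible (receiver, donor) pairs is 27, which normalizes
the per-type value used by the optimizer: value(t) = |donors(t)| / 27,
stored as an exact rational (`fractions.Fraction`); the familiar
two-decimal figures (0.15, 0.07, …) are display rounding only.

### Cross-match preference order

When a request cannot be filled from its own type, stock is drawn from the
remaining compatible donors in ascending *donor reach* (the number of
receiver types that donor can serve), so the least flexible stock is spent
first and O− — reach 8 — is always the last resort. Reach ties are broken
by same-Rhesus-as-receiver first, then alphabetically. This ordering is a
design choice: the greedy baseline needs a total order, and preserving
flexible stock is the operational intent, but no static order is optimal
on every instance (see Limitations).

## Inventory

Each type has a FIFO queue; donations enqueue at the back with their
donation day, issues dequeue from the front (oldest first). Expiry is
strict: a unit is usable on the day its age equals the 30-day shelf life
and incinerated after (`age > shelf_life`), at end of day. Units donated
the same day keep stable insertion order so runs are deterministic under a
fixed seed. Initial stock is allocated across types by largest-remainder
rounding of the normalized population proportions and carries donation day
0 — the youngest defensible choice, avoiding an artificial mass expiry
during warm-up. Imported units are transfused immediately and never enter
the queues.

## Demand and donation generator

For each day and each type independently, a percentage u ~ Uniform(lower,
upper) is drawn and the volume is round-half-up of
`u/100 × p(type) × initial_volume × turnover`, where p is the normalized
population proportion (the printed percentages total 101 and are divided
by 101 wherever a distribution is needed) and `turnover` (default 1.0)
scales the per-day base. Requests and donations use separate substreams of
the scenario seed, as does the swarm, so optimizer and baseline runs can
be compared on identical streams. The built-in scenario grid crosses
initial volumes 500/1000/2000 with horizons of 90 and 365 days and
balanced ([25,75]/[25,75]) or skewed ([25,75]/[30,75] and [30,75]/[25,75])
bounds.

What the generator emulates: independent day-to-day volume noise whose
per-type scale tracks the population mix, and demand/donation imbalance
via the bounds. What it does not: weekday or seasonal structure,
correlated shocks, an emergency request class, or multi-site logistics.
Consequences for interpretation: with equal bounds the bank holds roughly
two days of demand, so type-level shortages (hence imports) occur at a
modest steady rate, and FIFO turnover keeps every unit far from the 30-day
limit — the no-wastage outcome says stock is young under fast turnover,
not that wastage is impossible in real banks.

## Assignment engines

**Bottom-up greedy.** Knapsacks are processed in the fixed canonical order
(O+, O−, A+, A−, B+, B−, C+, C−); each is filled from a working stock copy
along the preference order; any residual after O− is booked as an import
of the requested type. Each day the greedy import count is at least the
exact minimum, with equality on most instances (empirically ≈ 99.9% of
simulated days).

**Exact oracle.** The minimum import count equals total demand minus the
value of a maximum flow on source → donor types (stock capacities) →
compatible receivers → sink (demand capacities); computed with networkx.
It lower-bounds every engine and provides the early-stop target.

**Discrete PSO.** Particles are assignment strings. For velocity
arithmetic each symbol becomes its type value; velocities follow
`v' = ωv + c1 r1 (pbest−x) + c2 r2 (gbest−x)` with r1, r2 one scalar pair
per particle per iteration (per-dimension draws are a config switch), no
velocity clamping, initial velocities zero. Per dimension, a uniform μ is
drawn and the symbol is resampled when μ ≤ S(v'); a resampled dimension
chooses uniformly among the compatible donors of its knapsack's receiver
(the [0,1) interval split into k equal parts over the preference-ordered
donor list), a separate uniform making that choice. Gating *whether* to
resample and choosing *which* donor are deliberately driven by independent
draws. A repair operator replaces any incompatible symbol with the
knapsack's own type; in the optimizer it is an identity guard because
donor choices are drawn from the compatible list.

Defaults ω = 0.715, c1 = c2 = 1.7 (a standard constriction-equivalent
setting), 50 particles, at most 1000 iterations. Particle 0 is seeded with
the greedy solution; personal and global bests update only on strict
improvement with first-found tie-breaking, so the returned plan equals the
greedy one unless the swarm strictly improves on it. Because fitness is a
non-negative integer bounded below by the flow oracle, the run stops as
soon as the global best reaches the bound — including at initialization,
where the seed particle would be the first-found best anyway; this cannot
change any result, only the runtime.

Decoding the best string into a supply plan caps each type's used count at
its stock and books the residual as imports of the *placed* type; the
greedy baseline instead always imports the requested type. Both
conventions are exposed (optimizer vs baseline mode) since either reading
of "import relative to the request" is defensible.

## Daily loop

Per day: record opening stock → draw requests → solve the day's assignment
(swarm or greedy) → dequeue supplied units FIFO and book imports → draw
and enqueue donations → expire. Requests bind before the day's donations
arrive, so shortages can occur even when the day's net flow is positive;
each day is optimized myopically with no lookahead. Summaries are plain
horizon means per type plus totals and the import-to-request ratio.

## Numerical and reproducibility choices

* All unit counts are integers; fractional draws are rounded half-up.
* The scenario seed feeds `numpy.random.SeedSequence([seed, stream])` with
  distinct stream tags for requests, donations and the swarm, and the
  swarm's tag is further qualified by the day index, so a day's
  optimization is unaffected by how many draws earlier days consumed.
* Largest-remainder ties in the initial allocation go to the larger
  population share, then canonical order.
* Degenerate inputs: zero total demand yields an empty assignment with
  fitness 0; zero stock routes everything to importation; an over-draw
  from a queue raises (it would indicate an assignment-layer bug).

## Problem sizes used in the test and acceptance suites

Structural and statistical checks run at the scales that make their claims
meaningful while keeping the suite quick: 100 random instances of ≤ 30
units for swarm-vs-oracle equivalence, 30 seeds × 90 days of the smallest
scenario for the import/wastage summaries, 10 paired seeds of the
demand-heavy scenario for the optimizer-vs-baseline comparison, and
20,000-day Monte Carlo for generator means.

## Limitations

* No static greedy order is instance-optimal: with the Rh-matching
  tie-break, an A+ request served from O+ can starve a later B+ request
  that had no other donor (the package's worked example). Such days are
  rare in simulation (≈ 1 in 2700 on the smallest balanced scenario) and
  the flow oracle quantifies the gap exactly.
* The sigmoid gate resamples a dimension with probability 0.5 once
  velocities decay toward zero, so on full-size days (hundreds of
  dimensions) the swarm explores too aggressively to coordinate multi-unit
  exchanges and typically cannot improve a near-optimal greedy seed; on
  small instances (tens of units) it reliably reaches the exact optimum.
  Consequently the optimizer's practical value at scale comes from the
  greedy seed plus the oracle bound, with the swarm contributing on small
  or loosely-constrained days. For the same reason a consensus swarm does
  not freeze its strings even as velocities vanish.
* Import totals depend on the booking convention for forced shortfalls
  (requested type vs placed type); per-type import summaries should be
  read with that convention in mind.
* The generator's uniform-percentage model makes mean demand scale with
  initial volume; absolute import/expiry rates therefore reflect the
  roughly two-day buffer this implies, not any calibrated real-world
  turnover.
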