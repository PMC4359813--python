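"""Paired comparison of the swarm optimizer against the greedy baseline.

Both modes replay the identical request/donation streams (the scenario
seed drives separate substreams for demand, donations and the swarm), so
any difference in total imports is due to the assignment engine alone.
"""

from bloodassign import dataset, run

print("dataset 5 (1000 units, 90 days, requests [30,75] vs donations [25,75])")
print(f"{'seed':>4} {'pso':>6} {'baseline':>9}")
for seed in range(5):
    pso = run(dataset(5, seed=seed), mode="pso").summary.total_imported
    base = run(dataset(5, seed=seed), mode="baseline").summary.total_imported
    print(f"{seed:>4} {pso:>6} {base:>9}")
print("\nTotals are total units imported over the horizon; the optimizer "
      "never exceeds the baseline on a shared stream, and equals it whenever "
      "the greedy seed already attains the daily max-flow bound.")
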