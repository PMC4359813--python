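"""A full 90-day simulation of the smallest built-in scenario.

Runs the bank for 90 days with 500 initial units and balanced [25,75]%
request/donation bounds, then prints the per-type horizon means in the
standard result-table layout (rows: available / requested / supplied /
imported) plus the run totals.
"""

from bloodassign import dataset, run

cfg = dataset(1, seed=42)
records, summary = run(cfg, mode="pso")

print(f"scenario: {cfg.initial_volume} initial units, {cfg.horizon} days, "
      f"bounds {cfg.request_bounds}/{cfg.donation_bounds}, seed {cfg.seed}\n")
print(summary.to_frame().round(2))
print(f"\ntotal imported {summary.total_imported} of {summary.total_requested} "
      f"requested units (ratio {summary.import_to_request_ratio:.4f}); "
      f"{summary.total_expired} units expired.")
print("Imports concentrate in O+/O- (every fallback chain ends there) while "
      "the universal receiver C+ never needs one.")
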