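"""Windowed multi-caller consensus on a simulated call ensemble.

Five simulated callers (sensitivity 0.9, 5% false-positive rate,
positional jitter up to 100 bp) call 100 true TA-site insertions;
nonreference calls are compared on 1,000-bp windows and per-window
support tallied.
"""

import numpy as np

from bergerac.simulate import SimConfig, simulate_caller_outputs, simulate_genome, \
    simulate_insertions
from bergerac.te_calls import consensus_windows, round_half_up, support_fractions

rng = np.random.default_rng(11)
cfg = SimConfig(chromosome_lengths={"chrI": 2_000_000, "chrII": 2_000_000},
                n_insertions=100, n_reference_elements=0, strain="sim")
genome = simulate_genome(cfg, rng)
truth = simulate_insertions(genome, cfg, rng)
callsets = simulate_caller_outputs(truth, genome, cfg, rng)

table = consensus_windows(callsets)
full, near = support_fractions(table)

print(f"true insertions:        {len(truth)}")
print(f"unique 1,000-bp windows: {table.n_windows}")
print("windows by support level:", table.support_counts())
print(f"full 5-caller support:  {round_half_up(100 * full)}%")
print(f"support >= 4 callers:   {round_half_up(100 * near)}%")
print("\nMost windows are supported by several callers: window-level "
      "consensus absorbs breakpoint jitter, while false positives appear "
      "as low-support singleton windows.")
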