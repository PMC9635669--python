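"""Chromatin-state enrichment of insertions with motif-site exposures.

A 2x insertion bias is planted in the repressed-chromatin (H3K27me3)
category; the enrichment test compares observed in/out counts against
expectations proportional to the number of integration-motif sites per
category, with Holm-Bonferroni control across the five states.
"""

import numpy as np
import pandas as pd

from bergerac.enrichment import binary_category_counts, enrich_test, holm_bonferroni
from bergerac.genome import Interval, overlap_mask
from bergerac.simulate import SimConfig, simulate_genome, simulate_insertions

rng = np.random.default_rng(7)
cfg = SimConfig(chromosome_lengths={c: 3_000_000 for c in ("chrI", "chrII", "chrIII")},
                rate_multipliers={"H3K27me3": 2.0})
genome = simulate_genome(cfg, rng)
truth = simulate_insertions(genome, cfg, rng)
calls = [Interval(r.chrom, r.t_pos, r.t_pos + 1) for r in truth.itertuples()]

results = {}
for state, track in genome.chromatin_tracks.items():
    sites_in = sum(overlap_mask(genome.motif_sites, track))
    cc = binary_category_counts(
        calls, track, genome.build.total_bp(), state,
        exposure_inside=sites_in,
        exposure_outside=len(genome.motif_sites) - sites_in,
        model="motif_sites")
    results[state] = enrich_test(cc)

adj = holm_bonferroni([r.p for r in results.values()])
rows = [{"state": s, "observed": int(r.observed[0]), "expected": round(r.expected[0], 1),
         "fold": round(r.fold[0], 2), "chi2": round(r.chi2, 2),
         "p_adj": float(f"{pa:.2e}")}
        for (s, r), pa in zip(results.items(), adj)]
print(pd.DataFrame(rows).to_string(index=False))
print("\nOnly the biased H3K27me3 state shows a fold well above 1 with a "
      "small adjusted p; the remaining states sit near (or slightly below) "
      "their motif-availability expectations.")
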