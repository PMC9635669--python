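"""Aggregate per-caller Tc1 copy-number estimates into a summary table.

Each strain's five caller estimates (ngs_te_mapper2, RelocaTE, TEMP2,
RetroSeq, TEFLoN) are pooled with the normalized-coverage estimate into
range/mean/median columns; the reference strain N2 has no RetroSeq
value, so its summary pools five values.
"""

import pandas as pd

from bergerac.te_calls import summarize_copy_number

ESTIMATES = {
    "N2": ({"ngs_te_mapper2": 28, "RelocaTE": 28, "TEMP2": 26, "TEFLoN": 30}, 30, 29),
    "CB4851": ({"ngs_te_mapper2": 448, "RelocaTE": 455, "TEMP2": 463,
                "RetroSeq": 435, "TEFLoN": 444}, 546, 455),
    "RW6999": ({"ngs_te_mapper2": 582, "RelocaTE": 551, "TEMP2": 601,
                "RetroSeq": 580, "TEFLoN": 578}, 668, 610),
    "RW7000": ({"ngs_te_mapper2": 741, "RelocaTE": 755, "TEMP2": 759,
                "RetroSeq": 741, "TEFLoN": 723}, 836, 882),
}

rows = []
for strain, (counts, coverage, ddpcr) in ESTIMATES.items():
    s = summarize_copy_number(counts, coverage_estimate=coverage,
                              strain=strain, ddpcr=ddpcr)
    rows.append({"strain": strain, "range": f"{int(s.min)}-{int(s.max)}",
                 "mean": s.mean_display, "median": s.median_display,
                 "ddPCR": ddpcr})

print(pd.DataFrame(rows).to_string(index=False))
print("\nThe Bergerac strains carry hundreds of Tc1 copies (non-overlapping "
      "ranges), an order of magnitude above the ~28 copies of the N2 control; "
      "ddPCR runs higher than the caller medians, suggesting the medians are "
      "underestimates.")
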