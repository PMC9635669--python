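"""Molecular-clock dating of strain divergence from mtDNA SNP counts.

Each Bergerac strain differs from the N2 control by 4 mtDNA SNPs; with
mu = 4.32e-8 substitutions/site/generation over the 13,794-bp
mitochondrial genome, divergence time in generations is S/(2 mu L),
converted to years under three wild generation-time scenarios.
"""

from bergerac.divergence import divergence_table

table = divergence_table(snps=4)
print(table.round(1).to_string(index=False))
print("\nAll scenarios put the Bergerac-N2 split within the last few "
      "centuries - recent laboratory-era divergence, not an ancient split.")
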