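"""Codon usage and RSCU from published codon counts.

Loads the packaged published codon counts of the Lysmata vittata
mitochondrial protein-coding genes and computes RSCU under both family
presets.  RSCU = observed codon count / mean count of its synonymous family:
1 means no bias; values far above 1 mark strongly preferred codons.
"""

import mitoprofile as mp
from mitoprofile import datasets
from mitoprofile.utils import round_half_up

counts = mp.counts_from_dict(datasets.lvittata_codon_counts())

for preset in ("table3-compat", "invertebrate-mito"):
    values = dict(zip(mp.CODONS, mp.rscu(counts, preset)))
    top = sorted(values, key=values.get, reverse=True)[:3]
    print(f"preset {preset}: most biased codons "
          + ", ".join(f"{c}={round_half_up(values[c])}" for c in top))

totals = mp.aa_totals(counts, "table3-compat", split_sixfold=True)
ranked = sorted(totals, key=totals.get, reverse=True)
print("\nmost common amino acids:",
      ", ".join(f"{aa} ({totals[aa]})" for aa in ranked[:3]))
print("rarest:", ", ".join(f"{aa} ({totals[aa]})" for aa in ranked[-2:]))
print("\nNote: the two presets group AGA/AGG and UGA differently "
      "(standard code vs invertebrate mitochondrial code), so RSCU values "
      "are only comparable within a named preset.")
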