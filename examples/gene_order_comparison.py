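"""Circular gene-order rearrangement comparison.

Compares the packaged (reconstructed) Lysmata vittata gene order against the
ancestral pancrustacean arrangement, then shows the same machinery on a
controlled single translocation.  Moved genes are those outside the longest
common subsequence; breakpoints count ancestral gene adjacencies lost in the
query.
"""

import mitoprofile as mp
from mitoprofile import datasets

ref = datasets.ancestral_gene_order()
qry = datasets.lvittata_gene_order()
rep = mp.compare_gene_orders(qry, ref)
print("query vs ancestral pancrustacean order:")
print(f"  moved genes: {sorted(rep.moved_genes)}")
print(f"  breakpoints: {rep.n_breakpoints}")
print(f"  largest conserved block: {max(map(len, rep.conserved_blocks))} genes")

moved = mp.perturb_order(ref, [("trnD", "nad6")])
rep2 = mp.compare_gene_orders(moved, ref)
print(f"\nafter relocating trnD next to nad6: moved = {sorted(rep2.moved_genes)}"
      f" ({rep2.n_breakpoints} breakpoints) - a single translocation is"
      " attributed to exactly one gene.")
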