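# mitoprofile

Descriptive statistics for annotated circular mitochondrial genomes, built
for the kind of mitogenome announcement analysis done for small metazoans
(shrimp-sized genomes of 15–22 kb with 13 protein-coding genes, 22 tRNAs,
2 rRNAs and one or more AT-rich control regions):

* **Composition and strand skew** — base percentages, A+T content, and the
  strand-asymmetry statistics AT skew = (A−T)/(A+T) and
  GC skew = (G−C)/(G+C), per gene, per gene class, genome-wide, and in
  sliding windows around the circle.
* **Codon usage and RSCU** — codon counts over the protein-coding genes,
  start/stop classification including incomplete (polyadenylation-completed)
  stop codons, per-amino-acid totals, and relative synonymous codon usage
  RSCU(c) = n_c · |f| / Σ_{c′∈f} n_{c′} for codon *c* in synonymous family
  *f*, under explicit, named genetic-code family presets.
* **Genome architecture** — overlapping gene pairs, intergenic spacers, and
  control-region candidates (long unannotated AT-rich stretches) on the
  circular molecule.
* **Gene-order rearrangement** — strand-signed circular gene orders compared
  against a reference arrangement (ancestral pancrustacean order packaged):
  moved genes, conserved blocks, breakpoint counts.
* **Synthetic genomes** — a deterministic generator of annotated circular
  mitogenomes with a full truth set, so every stage is testable end to end
  without downloads.

Inputs are GenBank flat files or FASTA plus a TSV feature table; coordinates
are 1-based inclusive with wrap-around features supported on circular
records.

## Why two RSCU presets

Invertebrate mitochondria use NCBI translation table 5 (UGA = Trp,
AGA/AGG = Ser, AUA = Met), but widely used codon-usage software computes
RSCU under the *standard* code's synonymous families, with the three
standard stop codons pooled — and published mitogenome RSCU tables often
follow that convention. `mitoprofile` therefore ships both groupings as
explicit presets, `invertebrate-mito` (default) and `table3-compat`, and
always prints the preset name in its reports; values from different presets
are not comparable.

## Worked example

```python
import mitoprofile as mp
from mitoprofile import datasets
from mitoprofile.utils import round_half_up

# strand skew straight from a composition table's printed percentages
print(round_half_up(mp.skew_from_fractions(34.35, 37.15)))   # -0.04 (AT skew)
print(round_half_up(mp.skew_from_fractions(11.80, 16.69)))   # -0.17 (GC skew)

# RSCU from the packaged published codon counts
counts = mp.counts_from_dict(datasets.lvittata_codon_counts())
values = dict(zip(mp.CODONS, mp.rscu(counts, "table3-compat")))
print(round_half_up(values["UUA"]))                          # 3.13
print(mp.aa_totals(counts, "table3-compat")["I"])            # 499 (Ile)

# full pipeline on a synthetic genome with known truth
record, truth = mp.generate(mp.SyntheticSpec(seed=42))
report = mp.region_composition_report(record)
print(int(report.loc["whole genome", "size_bp"]))            # 20469
```

The skews say both A-vs-T and G-vs-C are biased toward the lighter-strand
pattern typical of these genomes (more T than A, more C than G); the RSCU of
3.13 marks UUA as the most over-used leucine codon; 499 is the isoleucine
codon total across the 13 protein-coding genes.

More narrative scripts, one per capability, live in `examples/`.

## Command line

```bash
mitoprofile simulate --seed 1 --out fixture/
mitoprofile profile --fasta fixture/genome.fasta --table fixture/features.tsv --out report/
mitoprofile codons --genbank fixture/genome.gb --preset table3-compat
```

`profile` writes a deterministic bundle (composition.tsv, codon_usage.tsv,
overlaps/spacers/control_regions.tsv, rearrangement.json, sliding_window.csv,
manifest.json); every number in the bundle is recomputable by calling the
owning library function with the manifest's recorded parameters.

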