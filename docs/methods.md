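# Methods

## Coordinate model

Externally (GenBank, feature tables, reports) coordinates are 1-based
inclusive; internally every computation converts to 0-based half-open slices
at the point of use. A feature that crosses the origin of a circular record
is stored as exactly two spans, the first ending at the record length and
the second starting at base 1; extraction concatenates spans in F-strand
reading order and reverse-complements for R-strand features. Gene names are
normalized to lowercase field tokens (`cox1`, `nad4l`, `trnS1`, `rrnL`,
`CR1`); duplicated leucine/serine tRNAs are disambiguated by an explicit
copy suffix or by anticodon (both the true anticodon and the codon-family
spellings seen in annotations are accepted), and an ambiguous `trnL`/`trnS`
is flagged rather than guessed.

## Composition and skew

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C). `N` bases are kept in the
sequence but excluded from all denominators, so the four base percentages
always total 100; a region with a zero denominator returns skew 0 with a
warning rather than NaN, keeping report tables total while remaining
auditable. `skew_from_fractions` applies the same formula to printed
percentages, which is what makes published composition tables checkable
from their own columns.

Per-gene report rows are computed on each gene's own coding strand by
default: minority-strand genes then show sign-flipped skews relative to
majority-strand genes, which is how published per-gene skew tables behave.
A majority-strand mode (`strand="F"`) is provided because some published
pooled tRNA/rRNA rows do not state which convention they used.

Sliding windows advance by `step` from base 1 and wrap the origin on
circular records, giving ceil(length/step) windows; each point is simply the
composition of its window, verified in tests against a naive per-window
recount. Rounding: percentages and skews print at 2 decimals in
table-replication contexts (half-up, via `utils.round_half_up`, matching how
published tables round), full precision is always available on the
underlying objects.

## Codon usage and RSCU

CDS sequences are split into frame-0 triplets; the trailing 0–2 base remnant
(an incomplete stop codon, completed to UAA by transcript polyadenylation)
is reported separately and never counted. Complete terminal stop codons are
included in counts and RSCU (published codon tables list them) but excluded
from amino-acid totals. Start codons are classed `ATN` versus
`nonstandard`; TTG and GTG starts are routine in invertebrate mitochondria.

RSCU(c) = count(c) × |f| / Σ_{c′∈f} count(c′) over the synonymous family
partition of a named `CodonTable` preset. A family with zero total gets
RSCU 0 throughout; a singleton family is 1 whenever observed. Two presets
are registered and the preset name is always printed in output:

* `invertebrate-mito` (default): NCBI translation table 5 families — the
  correct code for these genomes (UGA=Trp, AGA/AGG=Ser, AUA=Met; 8-codon
  serine family, 2-codon stop family).
* `table3-compat`: standard-code families with the three standard stops
  {UAA, UAG, UGA} pooled as one family. Published mitogenome RSCU tables
  computed with general-purpose codon-usage software follow this grouping
  (it is the only family structure under which such printed tables'
  count→RSCU arithmetic closes), so it is shipped as a first-class,
  clearly-labeled preset rather than silently adopted or rejected.

Total-codon bookkeeping is exposed in both conventions — per-gene flooring
Σ floor(len_g/3) and joint flooring floor(Σ len_g/3) — because published
totals variously follow either; reporting both makes any discrepancy
auditable instead of hidden.

## Architecture

Features (control regions excluded) are sorted by start coordinate;
consecutive pairs, plus the circular closure pair, are classified by their
gap: positive → spacer, negative → overlap, zero → abutting (reported in
neither list). Control-region candidates are maximal unannotated stretches
of at least `min_len` bp (closed threshold; default 200 bp), merged across
the origin on circular records, labeled CR1..CRk in coordinate order and
reported with AT content — reflecting how control regions in practice are
the large AT-rich leftovers of annotation. Whether CR-flanking gaps count
as "intergenic spacers" varies between publications, so the spacer list
simply reports every positive gap and leaves the bookkeeping to the reader.

## Gene-order comparison

Orders are strand-signed circular sequences canonicalized by rotation to a
shared anchor. Moved genes are those outside a longest common subsequence
(strand-sensitive, so an in-place strand flip counts as moved); conserved
blocks are LCS runs contiguous in both orders; breakpoints are reference
adjacencies (circular closure included) absent from the query, a signed
adjacency counting as preserved also in inverted form. When the LCS is
ambiguous (e.g. a swap of two adjacent genes, where either one "moved"),
the reconstruction prefers the branch extending the current conserved run
and then the lexicographically smaller token, and sets a `tie_occurred`
flag; exhaustively enumerating all optimal subsequences would be
exponential and would still leave the attribution arbitrary, so the flag is
the honest output. Genes private to either order are dropped before
comparison and reported separately. Inversion-distance/DCJ optimization is
out of scope; the breakpoint count is a descriptive statistic, not a
parsimony estimate.

The packaged ancestral pancrustacean order is an editable text file; all
correctness tests use synthetic orders so nothing depends on that file's
provenance. The packaged *L. vittata* order is a reconstruction from stated
facts about that genome (strand counts, rRNA/CR neighborhoods, the
trnA/trnR translocation), labeled synthetic in its filename and header; the
exact placement of the translocated pair within those constraints is
arbitrary, and tests assert only the translocation containment.

## Synthetic generator

The generator emulates a shrimp-like mitogenome at the ~20 kb scale with
known truth. Defaults are fixed to the emulated genome's published summary
quantities: the 13 PCG lengths (11144 bp total, e.g. cox1 1614, nad5 1732),
start codons (ATG/ATT/ATC plus TTG for cox1 and nad4l, GTG for cox3), stop
codons (TAA, TAG for cox1, incomplete T for nad4 and nad5 — enforced
consistent with length mod 3), rRNA lengths 1494/821, 22 tRNAs of 60–77 bp,
whole-genome base pool (A,T,G,C) = (0.3435, 0.3715, 0.1180, 0.1669) ≈ 71.5%
AT, three unannotated control regions of 650/3821/888 bp with AT biases
80.46/72.23/77.25%, four gene overlaps (longest 23 bp at trnL1/rrnL), and
small intergenic spacers. Internal PCG codons are drawn i.i.d. from the
published codon-usage profile with the genetic code's stop codons zeroed
(stops occur only terminally); an exact mode distributes a user-fixed
internal-codon multiset instead, giving discrete truth recovery without
sampling noise. Realized defaults come to ≈20.5 kb — the annotated gene and
CR complement of the emulated genome without its residual unannotated
stretches; an optional `length_target` pads to a requested size.

All randomness flows from one `numpy` generator seeded in the spec; the
same seed gives byte-identical output, and there is no global state.
Overlaps reuse the upstream gene's emitted bases, so a plan whose
*downstream* overlap partner is a PCG is rejected as infeasible before
sampling (it would corrupt planned codon content); overlap plans therefore
target tRNA/rRNA-downstream boundaries by default. What the generator does
*not* emulate: within-gene compositional heterogeneity, codon
autocorrelation, tRNA cloverleaf structure, sequencing error, or
length-variable repeats inside control regions — so passing truth-recovery
tests demonstrates the correctness of the statistics, not robustness to
messy real annotations.

## Numerical and degenerate-input choices

Empty/all-N sequences are errors ("no informative bases"); empty report
groups are omitted with a warning; a CDS shorter than 3 bases is an error;
zero skew denominators return 0 with a warning; duplicate (name, span)
features are rejected; RSCU of an all-zero family is 0; table-comparison
rounding is half-up at 2 decimals.

## Problem sizes

Tests and the acceptance script run the full pipeline on generated genomes
of ≈20.5 kb (37 genes), the natural size of the system being emulated;
property-based checks use short random sequences and random 64-vectors.
The headline published-statistic checks are desk-scale: they recompute
skews and RSCU directly from packaged printed percentages and counts.
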