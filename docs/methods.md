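# Methods

## Problem and model

In an allotetraploid genome such as cultivated peanut, a typical SSR
primer pair binds the homoeologous copies of its locus in both
subgenomes and yields multi-band, ambiguous genotypes. The remedy
implemented here is an *in silico* uniqueness screen: design a primer
pair for every detected SSR, place the pair across the whole assembly
by electronic PCR, and keep only pairs that amplify exactly one site.
Such single-locus markers behave as ordinary codominant markers — they
segregate 1:2:1 in an F₂ and support per-locus allele frequencies, Ho
and PIC in diversity panels.

## SSR detection

Perfect tandem repeats of primitive 1–6 nt units are reported when the
repeat count reaches the per-unit-length minimum (12, 6, 4, 3, 3, 3 for
mono- through hexanucleotides). Rules the scanner enforces:

* **Maximality** — a tract cannot be extended by one more full unit on
  either side; partial unit copies in the flank are not counted.
  Each repeat region is reported once per unit length, under its
  leftmost phase (an alternating stretch like `TATATAT…` is one tract,
  not several phase-shifted copies).
* **Primitivity** — a unit that is a repetition of a shorter unit is
  never used, so a poly-A run is not double-counted as AA/AAA….
* **Ambiguity** — tracts containing N are not reported; primer design
  over ambiguous bases would be undefined.
* **Canonical classes** — the class of a unit is the lexicographic
  minimum over all cyclic rotations of the unit and of its reverse
  complement. Each class contains at most 2 × unit-length raw motifs,
  and only A and C survive as mononucleotide classes.

Adjacent tracts separated by at most 100 bp (configurable) are flagged
as components of one compound SSR. Components keep their own class and
coordinates and are counted separately in every summary, so perfect
tracts plus compound components always add up to the catalog total.

## Primer design

Primer choice is a deterministic, exhaustively enumerated optimisation
rather than a heuristic: every (left window, right window, length)
combination whose amplicon fully contains the tract is scored, subject
to hard bounds — length 18–27 nt, Tm 55–65 °C, GC 30–70 %, product
100–300 bp, primers entirely within the flanks. The penalty is the
weighted absolute deviation from the optima (length 20 nt, Tm 60 °C,
GC 50 %; unit weights per nt, °C and %-point, configurable), summed
over both primers. Ties are broken by smaller product, then leftmost
left-primer start, then shorter primer, making the designer a pure
function of (locus, scaffold, constraints). No dimer/hairpin screening
is applied by default.

Melting temperatures use the nearest-neighbour model with the unified
thermodynamic parameter set (via Biopython's `Tm_NN`), at 50 mM
monovalent salt and 50 nM primer with the entropy salt correction
0.368 (N−1) ln[Na⁺]. Absolute Tm values therefore depend on these
conditions; only the constraint logic, not any published primer
sequence, is meant to be reproduced.

## Electronic PCR

A primer site is keyed by its 3′-end position. The 3′-terminal seed
word (11 nt) must match the genome exactly — 3′-proximal mismatches
abolish extension, and the exact word bounds the genome-wide search —
while the 5′ remainder is aligned with a per-primer budget of
2 mismatches and 1 indel. Gaps do not count toward the mismatch
budget. N in the genome matches nothing. Amplimers require the two
primers in opposing orientations at admissible spacing: product length
within the absolute 50–1000 bp bounds and, when the designed product
size is supplied, within ±50 bp of it (the margin). Hits with an
identical (scaffold, span, orientation) are reported once at the lowest
(mismatch, gap) cost: a locus is a site, not an alignment. Markers are
classified `none` / `single_locus` / `multi_locus` by their genome-wide
hit count; ids (`AHGA` + zero-padded serial) are assigned in (scaffold
order, position) order for determinism.

Both-primer amplification is required; single-primer (inverted repeat)
amplimers are not considered.

## Validation statistics

* **Allele frequencies** are counted over non-missing calls, two
  observations per typed diploid individual.
* **Ho** = 1 − Σ p_uu, the fraction of typed individuals that are
  heterozygous.
* **PIC** = 1 − Σ p_i² − 2 Σ_{i<j} p_i² p_j², evaluated exactly as
  written (the cross term over unordered pairs, doubled). PIC never
  exceeds expected heterozygosity 1 − Σ p_i².
* **Segregation** is tested by the Pearson χ² against (¼, ½, ¼),
  df = 2, no continuity correction; for df = 2 the p-value has the
  closed form exp(−χ²/2), used as an independent oracle in tests.
  A marker passes at p ≥ α (α = 0.01 by default; equality passes).
* **Polymorphism rate** per group (motif class or repeat-number bin) is
  the percentage of tested markers showing ≥ 2 alleles.
* **Similarity** between individuals is the simple-matching coefficient
  over markers typed in both (identical unordered genotype = match);
  a Dice (shared-allele) alternative is provided. Pairs with no shared
  typed marker are recorded missing.
* **Clustering** is UPGMA (size-weighted average linkage) on
  d = 1 − s, ties broken by the smallest (row, column) pair, output as
  a rooted ultrametric tree in Newick with branch lengths in distance
  units. UPGMA is implemented directly so the tie-break and output are
  fully specified; tests cross-check cophenetic distances against
  SciPy's average linkage and a naive agglomeration oracle.

Missing genotypes are excluded pairwise for per-marker statistics and
listwise per pair for similarity.

## Synthetic data

The generators define the conditions every test runs under.

* **Genomes** — background bases are i.i.d. at 38 % GC (matching the
  draft-assembly composition the pipeline targets). Planted tracts are
  written at well-separated positions (≥ ~900 bp apart, ≥ 450 bp from
  scaffold ends); flanks are rejection-sampled until no unintended
  tract meets the scanner thresholds and until a primer pair exists
  under the default constraints (the truth table promises a
  copy-number verdict, which presupposes a designed pair). Duplicated
  segments copy a tract plus 350 bp of flank on each side — wider than
  the 300 bp maximum reach of any admissible primer — so a pair
  designed against one copy amplifies the other exactly. The truth
  table lists every expected scanner hit (copies included) with the
  verdict the pipeline should reach. Defaults: 4 × 25 kb scaffolds,
  30 planted SSRs, 15 % duplicated. All randomness flows from one
  explicit seed; a seed reproduces the FASTA byte-for-byte.
* **F₂ panels** — multinomial draws of (AA, Aa, aa) at (¼, ½, ¼) by
  default, n = 154 individuals.
* **Natural panels** — 96 individuals × 100 markers by default. The
  inbred model draws one allele per call and makes a call heterozygous
  (two distinct alleles) with probability 0.01, so realised mean Ho is
  ≈ 0.01; the outbred model draws two independent alleles
  (Hardy–Weinberg). Allele-frequency vectors are Dirichlet(1) over
  2–6 alleles unless supplied.

What the generators do **not** emulate: sequencing error, assembly
gaps/Ns, imperfect (interrupted) repeats, genome-wide repeat families,
base-composition heterogeneity, null alleles and PCR artefacts.
Passing tests therefore demonstrate the correctness of the scanning,
design, placement and statistical machinery under clean conditions,
not the wet-lab success rate of designed primers on real DNA.

## Numerical choices and scale

* Scaffolds shorter than 200 bp are dropped; the threshold is
  inclusive (≥ 200) and configurable.
* GC fraction excludes N from the denominator. Coordinates are 1-based
  inclusive everywhere; BED is converted on ingest.
* N50 is the largest L whose ≥ L sequences cover at least half the
  total length, computed by a descending cumulative scan.
* Reported percentages are rounded half-up at the printed precision;
  density is per Mb and spacing in kbp.
* Test and acceptance problem sizes — ~100 kb genomes with 30 planted
  SSRs for end-to-end recovery, 30 kb × 200 primer pairs for the
  e-PCR oracle equivalence, 10 kb × 100 seeds for the scanner oracle,
  1,000 replicates for χ² calibration — were chosen so each suite
  completes in seconds to a couple of minutes while keeping every
  verdict class and budget boundary exercised.

## Known limitations

* Primer penalties are not those of the primer3 objective; pairs will
  differ from primer3's picks even under identical bounds. The
  uniqueness screen, not primer aesthetics, is the point.
* The e-PCR site definition requires the 3′-terminal 11-mer to match
  exactly; very degenerate binding modes (mismatches inside the seed)
  are treated as non-amplifying.
* Whether a genome region was screened (e.g. for contamination) before
  the uniqueness count is outside this package: copy numbers are
  counted over exactly the scaffold set given.
* The similarity coefficient for qualitative genotype data is a
  convention (simple matching by default, Dice optional); subgroup
  cut-offs on similarity are therefore not comparable across
  coefficient choices.
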