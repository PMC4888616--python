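# unilocus

Genome-wide development and validation of **single-locus SSR
(microsatellite) markers** from a draft genome assembly, aimed at
polyploid crops where most SSR primer pairs amplify several homoeologous
loci at once and give ambiguous genotypes.

A marker is *single-locus* when its primer pair amplifies exactly one
site in the whole assembly. `unilocus` reproduces that screen in
software:

1. **Scan** scaffolds (≥ 200 bp) for perfect SSRs of 1–6 nt units with
   minimum repeat numbers 12/6/4/3/3/3 (mono→hexa); tracts separated by
   ≤ 100 bp are flagged as compound components. Motifs are pooled into
   canonical classes under cyclic rotation and reverse complementation
   (TTA, ATT, TAA → AAT), so the dinucleotide classes are exactly
   {AC, AG, AT, CG}.
2. **Design** one flanking primer pair per locus: length 18–27 nt,
   Tm 55–65 °C (nearest-neighbour, unified parameters, 50 mM Na⁺,
   50 nM primer), GC 30–70 %, product 100–300 bp; a deterministic
   penalty (weighted |deviation| from length 20 / Tm 60 °C / GC 50 %)
   picks the pair, ties broken by smaller product then leftmost start.
3. **Place** every pair genome-wide by electronic PCR: per primer up to
   2 mismatches and 1 indel, an exactly matching 3′-terminal 11-nt seed
   word, product inside 50–1000 bp and within ±50 bp (the *margin*) of
   the expected size.
4. **Classify** each pair as `none` / `single_locus` / `multi_locus`
   from its genome-wide hit count and serialise single-locus markers as
   an `AHGA`-prefixed catalog.
5. **Validate** marker panels: allele counts *A*, observed
   heterozygosity `Ho = 1 − Σ p_uu`, polymorphism information content
   `PIC = 1 − Σ p_i² − 2 Σ_{i<j} p_i² p_j²`, the Pearson χ² test of
   1:2:1 F₂ segregation (df = 2, `p = exp(−χ²/2)`), polymorphism rates
   by motif class or repeat number, simple-matching similarity and
   UPGMA clustering with Newick output.

A seeded synthetic-data module generates genomes with planted SSRs
(optionally inside duplicated segments) plus a truth table, F₂ panels
and natural-population genotype matrices, so the entire pipeline is
testable without any external data.

## Worked example

Simulate a small two-scaffold genome with four planted SSRs, one of
them inside a duplicated segment, then run the full pipeline:

```console
$ unilocus simulate --seed 11 --n-scaffolds 2 --scaffold-length 8000 \
      --n-ssrs 4 --frac-duplicated 0.25 --out-dir sim
2 scaffolds, 5 planted tracts -> sim
$ unilocus develop --fasta sim/genome.fasta --out-dir dev
{
  "n_scaffolds": 2,
  "n_loci": 5,
  "n_designed": 5,
  "n_undesigned": 0,
  "partition": {
    "none": 0,
    "single_locus": 3,
    "multi_locus": 2
  },
  "single_locus_pct": 60.0
}
```

Five tracts are planted (4 originals + 1 duplicated copy). The three
loci with unique flanks come back `single_locus`; the duplicated locus
and its copy are both caught by the uniqueness screen as
`multi_locus` — exactly the truth table written by the simulator:

```console
$ cut -f1-3,8 sim/truth.tsv
seq_id      start  end    expected_verdict
scaffold_1  1578   1589   single_locus
scaffold_1  3997   4014   single_locus
scaffold_1  6391   6402   multi_locus
scaffold_2  2169   2180   multi_locus
scaffold_2  5696   5707   single_locus
```

`dev/markers.tsv` holds the joined catalog (locus, primers, Tm/GC,
expected product, hit count, verdict), e.g.

```
marker_id   seq_id      start  end   motif  motif_class  unit_length  repeat_count  kind
AHGA00001   scaffold_1  1578   1589  CCTA   ACCT         4            3             perfect
AHGA00002   scaffold_1  3997   4014  ACT    ACT          3            6             perfect
```

Other subcommands: `scan` (locus catalog TSV), `report` (summary tables
by unit length and canonical class), `stats` (1:2:1 segregation
report), `diversity` (per-marker A / Ho / PIC with panel means).
Everything is also available as a plain Python API
(`unilocus.develop_markers`, `unilocus.pic`, …).

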