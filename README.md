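# plastcomp

Comparative chloroplast-genome analysis for plant molecular evolution:
quadripartite structure and region statistics, repeat landscapes,
substitution spectra, selection estimates, junction dynamics, and the
spatial correlation of mutational events — the standard analysis battery
applied to congeneric plastome sets (e.g. the *Chimonanthus* /
Calycanthaceae genomes), implemented as a tested, reusable Python library
with a thin command-line front end.

## What it computes

A land-plant chloroplast genome is a circle of ~120–170 kb organised as
LSC + IRb + SSC + IRa, where the two inverted-repeat copies are reverse
complements of each other. Over that layout the package provides:

- **Structure** — automated IR detection (seed-and-extend on 21-mers between
  the doubled circle and its reverse complement), rotation normalisation to
  LSC-first coordinates, per-region lengths and GC, and a gene census that
  separates unique genes from IR-duplicated copies.
- **Microsatellites (SSRs)** — maximal perfect repeats of 1–6 bp units under
  MISA-style copy thresholds (mono ≥ 10, di ≥ 5, tri ≥ 4, tetra/penta/hexa
  ≥ 3), classified by motif class × region × coding context.
- **Oligonucleotide repeats** — maximal repeat pairs ≥ 30 bp at ≥ 90%
  Hamming identity in the four REPuter orientations (forward, reverse,
  complement, palindromic); the genome-scale IR is flagged so tallies can
  exclude it.
- **Pairwise events** — anchored global alignment of near-identical genomes
  (unique 21-mer chaining + affine-gap DP; match +1, mismatch −2, gap open
  −5, extend −1), substitutions classified into the six unordered
  base-pair categories with Ts/Tv (`Ts = C/T + A/G`), InDels as maximal gap
  runs left-shifted to canonical coordinates.
- **Selection and codon usage** — NG86 Ka/Ks (pathway-averaged counts,
  Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)`), selection bands
  (purifying < 0.80 ≤ ~neutral < 0.95 ≤ neutral ≤ 1.05 < positive), pooled
  codon counts, RSCU and amino-acid frequencies.
- **Junctions** — genes spanning or flanking JLB/JSB/JSA/JLA with per-side
  overhangs and distances; IR-truncated pseudogene fragments are labelled.
- **Hotspot correlation** — events histogrammed into 250 bp bins, Pearson r
  between the substitution/InDel/repeat tracks with the conventional
  strength labels, and event-level co-occurrence percentages
  (share of X events in bins holding ≥ 1 Y event).
- **Synthetic plastomes** — a generator that emits quadripartite genomes
  with planted genes, SSRs, repeats, junction offsets and controlled
  divergence (Ts:Tv bias, InDel length law, optional hotspot rate
  landscape), logging ground truth so every stage is testable closed-loop.

## Worked example

```bash
python examples/01_structure_and_census.py
```

prints, for a canonical synthetic plastome:

```
genome: synthetic, 153,000 bp, IR identity 1.000
  LSC:  87,000 bp   GC 0.461
  IRb:  23,000 bp   GC 0.400
  SSC:  20,000 bp   GC 0.475
  IRa:  23,000 bp   GC 0.400
  whole-genome GC: 0.445
gene census: 113 unique (+15 IR-duplicated) = 128 total
  by category: {'protein_coding': 79, 'rRNA': 4, 'tRNA': 30}
```

The four regions tile the circle (87,000 + 20,000 + 2 × 23,000 = 153,000)
and the census reproduces the canonical plastome arithmetic: 113 unique
genes plus 15 IR-duplicated copies = 128 genes. The other scripts under
`examples/` walk through repeats (02), substitution spectra and Ka/Ks (03),
junctions and hotspot correlations (04), and the full pipeline (05).

From the shell, the same stages are available as subcommands:

```bash
plastcomp simulate --seed 3 --out-prefix demo
plastcomp structure demo.fasta
plastcomp ssr demo.fasta --min-mono 10 --min-di 5
plastcomp all --config pipeline.yaml
```

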