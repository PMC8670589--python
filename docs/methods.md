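# Methods

This note documents the models, conventions and numerical choices behind
plastcomp, and what the synthetic-data tests do and do not establish about
real data.

## Quadripartite structure detection

The plastome is treated as a circle tiled LSC + IRb + SSC + IRa with IRa
the reverse complement of IRb. Detection is fully automated (published
comparative studies often curate IR boundaries by eye): the doubled
sequence is compared against its reverse complement with exact 21-mer
seeds; seeded diagonals are extended into maximal high-identity windows
(Hamming model); candidate copy pairs are mapped back to the circle,
deduplicated across the doubled images, and the longest disjoint pair
wins. Ties between distinct maximal candidates raise an ambiguity error
rather than guessing.

Two conventions follow the field's presentation of such genomes:
coordinates are 1-based inclusive (GenBank style) and are reported in the
rotation-normalised frame in which the LSC starts at base 1; the longer
single-copy arc is the LSC, and IRb is the IR copy immediately downstream
of it. Defaults: minimum IR length 10 kb (real plastome IRs are ~15–30 kb;
anything shorter is not a canonical IR), minimum copy identity 0.99 (the
two copies are homogenised by copy correction but may differ at a handful
of sites).

### Window maximality and end-trimming

A window on a diagonal is *valid* when its ends are matching columns, its
mismatch count is at most (1 − identity)·length, and it meets the length
floor. Maximal-by-inclusion valid windows are found exactly with a
suffix-minimum walk over the per-diagonal match array. A maximal window
can, however, soak up sparse chance matches at its flanks on the global
mismatch budget (at 99% identity a 23 kb window tolerates ~230
mismatches); the reported window is therefore end-trimmed by a local rule:
terminal match-run units whose local identity, run/(run + adjacent gap),
falls below the identity floor are dropped, from both ends, to a fixed
point. The same definition is applied by the oligonucleotide repeat
finder, and is re-implemented independently in the test oracle.

## SSR scanning

Maximal perfect tandem repeats of unit 1–6 bp are found by direct period-u
run extension; thresholds default to the MISA convention used in plastome
surveys (mono ≥ 10 copies, di ≥ 5, tri ≥ 4, tetra/penta/hexa ≥ 3). A run
is reported only at its smallest unit (a poly-A stretch is a
mononucleotide repeat, not a di- or trinucleotide one) and only for
primitive motifs. Compound/interrupted SSRs are out of scope: the surveys
this reproduces report simple counts. For reporting, motifs are
canonicalised to the lexicographically smallest rotation and merged with
their reverse complement (A/T, AT/AT, …), which makes summaries invariant
under strand flips. Both IR copies are scanned (the genome is one linear
string); a per-unique-region mode is available via the structure's region
assignment downstream. N terminates every run.

## Oligonucleotide repeats

The four classic orientations are defined by the transform applied to the
second copy before position-wise comparison: forward (identity), reverse
(reversal only), complement (complementation only), palindromic (reverse
complement). Identity is Hamming — mismatches but no gaps — which keeps
the detector exactly checkable against a brute-force oracle; gapped
(edit-distance) repeats are out of scope. Defaults 30 bp / 90% follow
standard REPuter-style settings for plastome surveys. Exact 11 bp seeds
locate candidate diagonals; windows shorter than ~40 bp with maximally
spread mismatches can in principle contain no 11-mer run (the pigeonhole
bound is 7), so the test oracle seeds at 7 bp — on all tested corpora the
two agree exactly. The genome-scale IR duplication is itself a palindromic
repeat; it is reported but flagged `is_genomic_ir` (by interval match with
the detected structure) so per-genome tallies can exclude it, as published
counts plainly do.

## Pairwise alignment and event extraction

Congeneric plastomes are ≥ 95% identical, so a full DP alignment is
unnecessary: shared unique 21-mers are chained (longest increasing
subsequence in query coordinates), merged into exact blocks, and the short
inter-anchor segments are closed with affine-gap Needleman–Wunsch (match
+1, mismatch −2, gap open −5, gap extend −1 — exposed in the API). Inputs
without an anchor chain, or with an unanchored segment above 20 kb, raise
a divergence error directing the user to an external aligner; multiple
sequence alignment is out of scope.

Gap runs are normalised by left-shifting to the lowest reference
coordinate, making InDel coordinates deterministic inside homopolymers and
other repeats. One InDel event per maximal gap run; insertions anchor to
the preceding reference base. Substitutions are read off mismatching
non-gap columns (columns containing N are skipped) and classified into the
six unordered pair categories; C/T and A/G are transitions. Adjacent but
distinct gap runs separated by at least one match column remain separate
events. Where a substitution sits within a few bases of an InDel the
event decomposition of a sequence pair is genuinely ambiguous (several
equal-score alignments exist); the left-shift convention picks one
deterministically, and the generator's default 10 bp guard gap keeps
planted truth outside the ambiguous regime.

## NG86 selection estimates

Ka/Ks uses the Nei–Gojobori (1986) counting method: per-codon synonymous
site fractions over the nine single-base changes (changes creating stops
count as non-synonymous), sites averaged over both sequences; observed
differences averaged over all minimal mutational pathways, pathways
through stop codons excluded; Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p), undefined at p ≥ 3/4. The method was chosen for
determinism and oracle-checkability (the implementation agrees with the
independent Bio.codonalign NG86 routine to numerical precision in the
tests); ML codon models (Goldman–Yang, codeml branch-site) are out of
scope. The standard genetic code is used; internal stops are errors, and
table-11 start-codon relaxation is not enforced.

Selection bands: > 1.05 positive, 0.95–1.05 neutral, 0.80–0.95
approximately neutral, < 0.80 purifying, undefined ratios unclassified.
The two middle bands are inferred from how published plastome studies
label their own ratios (0.96 "neutral", 0.86 "approximate neutral"); the
thresholds are configurable.

Codon profiling pools counts over CDS sets, reports amino-acid
frequencies excluding stops, RSCU (observed count × family size / family
total, so each synonymous family averages 1), and the third-position
A/T- vs G/C-ending tally.

## Junction reports

For each of JLB, JSB, JSA, JLA the report names the gene spanning the
boundary (with bases on each side summing to the gene length) or the
nearest gene on either side within a 2 kb window. Distances count the
bases strictly between gene and junction, so a gene ending exactly at a
junction has distance 0 — matching the phrasing of published junction
figures ("11–14 bases downstream of the LSC start"). A fragment sharing
its name with a gene that spans the mirrored junction on the other IR copy
is labelled a pseudogene fragment (the ycf1-at-JSB pattern). No graphical
junction plot is produced; the TSV is the artifact.

## Hotspot binning, correlation and co-occurrence

Events are histogrammed into fixed bins anchored at base 1 (default
250 bp, final partial bin retained); each repeat *copy* contributes one
count at its start, substitutions and InDels count at their reference
position. Pearson r is computed over all bins, empty bins included — the
alternative of dropping empty bins is not offered because it changes the
estimand silently; zero-variance tracks yield an undefined r rather than
a number. Strength labels use half-open bands on |r|: [0, 0.1) none,
[0.1, 0.2) negligible/very weak, [0.2, 0.3) weak, [0.3, 0.4) moderate,
[0.4, 0.7) strong, [0.7, 1.0) very strong, 1.0 perfect. The printed scales
in the literature leave gaps between bands (0.19 → 0.20); the half-open
convention closes them deterministically.

Co-occurrence "X with Y" is, by default, the percentage of X *events*
lying in bins that contain at least one Y event. The event-level
denominator is what reproduces the non-round percentages published for
such analyses (16 of 23 InDels → 69.57%); a bin-level variant (share of
X-bearing bins that also bear Y) is available behind a flag.

## Synthetic plastome generator

The generator's defaults emulate the canonical congeneric study
conditions: 87 kb LSC + 20 kb SSC + 23 kb IRs (~153 kb total), background
GC 0.38, a catalog of 79 protein-coding + 30 tRNA + 4 rRNA unique genes
with 15 IR-duplicated (4/7/4 by category), genus-level divergence of a few
hundred substitutions per pair at Ts:Tv 1.5 with ~10× fewer InDels of
geometric length (mean 4 bp, capped at 50 bp). Protein genes are in-frame
ORFs free of internal stops, so selection analyses are well-posed;
tRNA/rRNA bodies are plain background composition. Because coding bodies
draw codons uniformly, realised GC runs above the configured background —
region GC statistics on synthetic data test the bookkeeping, not plastome
base composition.

Determinism: one integer-seeded numpy generator drives every draw; two
runs with one seed are byte-identical.

Details that make closed-loop testing exact rather than approximate:

- Planted SSRs get flanking bases chosen to break the repeat period, and
  accidental background SSRs are scrubbed (a middle base substituted,
  codon-aware inside CDS), so the planted set is exactly the detectable set.
- Planted repeat pairs get mismatching flank columns under their own kind
  transform, so the detector cannot extend them for free.
- The columns just outside the IR copies are pinned to mismatch, making
  the planted IR exactly maximal — otherwise a 1-in-4 chance match at a
  junction legitimately lengthens the detected IR by one base.
- Divergence events are logged in left-shift-canonical coordinates (the
  aligner's own convention) and keep a 10 bp guard gap around InDels; both
  are what make "extracted events == logged events" an exact assertion.
- `preserve_ir` confines events to the single-copy regions, mimicking IR
  copy correction; without it, heavy divergence on miniature test genomes
  can push the IR copies below the 99% identity floor, which real
  genus-level divergence never does at full scale.
- An optional gamma-distributed rate landscape (shared window multipliers
  applied to substitution and InDel intensities alike) models mutation
  hotspots; it is what gives deeper divergence a higher substitution–InDel
  bin correlation than shallow divergence, the qualitative pattern seen in
  family- versus genus-level comparisons.

What passing these tests shows: the detectors, aligner, estimators and
bookkeeping are correct against enumerable ground truth at the stated
scales. What they do not show: anything about annotation quality, assembly
artefacts, gapped repeats, compound SSRs, or base-composition effects in
real sequence — real-data runs remain subject to those upstream factors.

## Problem sizes in the tests and acceptance script

Unit and property tests run on miniature genomes (15–50 kb with a ~17-gene
catalog) so the whole suite stays fast; the gene-census check runs the
full 153 kb canonical catalog. The acceptance script uses 30 × 5 kb
sequences for the SSR oracle corpus, 12 × 2 kb for the repeat oracle
corpus, 10,000 pooled substitutions for Ts:Tv recovery, 300 × 100-codon
pairs for ω recovery (reported as the ratio of mean Ka to mean Ks — the
mean of per-pair ratios is Jensen-biased upward at low divergence), and
500 × 600-bin replicates for Pearson ρ recovery. These sizes were chosen
so each estimate's sampling error is comfortably inside the tolerance it
is judged against.

## Known limitations

- IR detection assumes exactly one canonical IR pair; plastomes with lost
  or highly reduced IRs raise "no IR found" by design.
- The aligner is for near-identical pairs only; it refuses divergent input
  rather than degrading silently.
- Oligo-repeat discovery seeds at 11 bp (configurable); a ≥ 30 bp repeat
  at exactly 90% identity with maximally spread mismatches can in theory
  lack an 11-mer seed. Lower the seed to 7 for provable completeness at
  the default thresholds.
- Annotations that wrap the circle origin after rotation are refused; in
  practice plastome records start in the LSC and no standard gene spans
  the JLA origin.
- Event-level co-occurrence and all-bins Pearson r are conventions; both
  alternatives (bin-level numerators, dropping empty bins) exist in the
  literature, and the flags make the choice explicit rather than silent.
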