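import numpy as np
import pytest

from plastcomp.records import GeneAnnotation, PlastomeRecord, rotate_record
from plastcomp.structure import (
    NoIRFoundError,
    QuadripartiteStructure,
    detect_and_normalize,
    detect_quadripartite,
    find_inverted_duplications,
    gene_census,
    region_stats,
)
from plastcomp.util import revcomp

from conftest import random_dna, small_config
from oracles import gc_count, oracle_longest_inverted_duplication
from plastcomp.simulate import generate_plastome


def _planted_ir_genome(rng, lsc=5000, ssc=1500, ir=1000):
    l = random_dna(rng, lsc)
    irb = random_dna(rng, ir)
    s = random_dna(rng, ssc)
    return l + irb + s + revcomp(irb), (lsc, ssc, ir)


def test_planted_exact_ir_recovered(rng):
    """Exact planted 1 kb IR copies in a 10 kb circle are recovered exactly
    (up to the one-column junction ambiguity, pinned here)."""
    seq, (lsc, ssc, ir) = _planted_ir_genome(rng)
    seq = list(seq)
    # pin junction columns so the planted repeat is exactly maximal
    if seq[lsc + ir + ssc - 1] == revcomp(seq[lsc + ir])[0]:
        seq[lsc + ir + ssc - 1] = next(b for b in "ACGT" if b != seq[lsc + ir + ssc - 1])
    if seq[lsc - 1] == revcomp(seq[0])[0]:
        seq[lsc - 1] = next(b for b in "ACGT" if b != seq[lsc - 1])
    rec = PlastomeRecord(id="p", sequence="".join(seq))
    st = detect_quadripartite(rec, min_ir_len=500)
    assert (st.lsc, st.irb, st.ssc, st.ira) == (
        (1, lsc), (lsc + 1, lsc + ir), (lsc + ir + 1, lsc + ir + ssc),
        (lsc + ir + ssc + 1, rec.length),
    )
    assert st.ir_identity == 1.0


def test_detection_matches_bruteforce_oracle(rng):
    """Seed-and-extend inverted-duplication finder equals the exhaustive
    O(n^2) longest-duplication oracle on a 5 kb sequence with one plant."""
    seq = random_dna(rng, 5000)
    core = random_dna(rng, 80)
    seq = seq[:1000] + core + seq[1080:3500] + revcomp(core) + seq[3580:]
    expected = oracle_longest_inverted_duplication(seq, min_len=40)
    got = find_inverted_duplications(seq, min_len=40, min_identity=1.0, seed_k=21)
    assert got, "planted duplication missed"
    a, b, L, mism = got[0]
    assert mism == 0
    assert (a, b, L) == expected[0]


def test_rotation_and_revcomp_invariance(small_genome):
    rec, _ = small_genome
    st = detect_quadripartite(rec, min_ir_len=1000)
    lengths = (st.lsc[1], st.irb[1] - st.irb[0] + 1, st.ssc[1] - st.ssc[0] + 1)
    # rotation: same normalized coordinates, different origin offset
    rot = rotate_record(
        PlastomeRecord(id="r", sequence=rec.sequence), 4321
    )
    st2 = detect_quadripartite(rot, min_ir_len=1000)
    assert (st2.lsc, st2.irb, st2.ssc, st2.ira) == (st.lsc, st.irb, st.ssc, st.ira)
    # reverse complement: same region lengths
    rc = PlastomeRecord(id="rc", sequence=revcomp(rec.sequence))
    st3 = detect_quadripartite(rc, min_ir_len=1000)
    assert (st3.lsc[1], st3.irb[1] - st3.irb[0] + 1, st3.ssc[1] - st3.ssc[0] + 1) == lengths


def test_no_ir_raises(rng):
    rec = PlastomeRecord(id="flat", sequence=random_dna(rng, 6000))
    with pytest.raises(NoIRFoundError):
        detect_quadripartite(rec, min_ir_len=500)


def test_structure_invariants_and_tiling(small_genome):
    rec, _ = small_genome
    nrec, st = detect_and_normalize(rec, min_ir_len=1000)
    n = nrec.length
    assert st.ira[1] == n
    # tiling: concatenating the four regions reconstructs the sequence
    parts = [nrec.sequence[iv[0] - 1 : iv[1]] for iv in (st.lsc, st.irb, st.ssc, st.ira)]
    assert "".join(parts) == nrec.sequence
    # IRa is the reverse complement of IRb at the reported identity
    irb = nrec.sequence[st.irb[0] - 1 : st.irb[1]]
    ira = nrec.sequence[st.ira[0] - 1 : st.ira[1]]
    mism = sum(1 for x, y in zip(irb, revcomp(ira)) if x != y)
    assert 1 - mism / len(irb) >= st.ir_identity - 1e-9


def test_tiling_validation_rejects_bad_structure():
    with pytest.raises(ValueError):
        QuadripartiteStructure(lsc=(1, 10), irb=(12, 20), ssc=(21, 25), ira=(26, 34),
                               ir_identity=1.0)
    with pytest.raises(ValueError):  # LSC must exceed SSC
        QuadripartiteStructure(lsc=(1, 5), irb=(6, 15), ssc=(16, 25), ira=(26, 35),
                               ir_identity=1.0)


def test_region_stats_against_count_oracle(small_genome):
    """Region lengths and GC equal a direct per-region recount."""
    rec, _ = small_genome
    st = detect_quadripartite(rec, min_ir_len=1000)
    rs = region_stats(rec, st)
    assert rs.total_length == rec.length
    assert sum(rs.lengths.values()) == rec.length
    for name, iv in (("LSC", st.lsc), ("IRb", st.irb), ("SSC", st.ssc), ("IRa", st.ira)):
        sub = rec.sequence[iv[0] - 1 : iv[1]]
        assert rs.lengths[name] == len(sub)
        assert rs.gc[name] == pytest.approx(gc_count(sub))
    assert rs.total_gc == pytest.approx(gc_count(rec.sequence))


def test_gc_excludes_ambiguous_bases():
    rec = PlastomeRecord(id="n", sequence="GGNNAA" + "ACGT" * 500 + "GG" + "C" * 1200 + "A" * 1200 + "T" * 100)
    # direct check of the helper semantics via region_stats on a fake structure
    from plastcomp.util import gc_fraction

    assert gc_fraction("GGNNAA") == pytest.approx(0.5)
    assert gc_fraction("GGGG") == 1.0
    assert gc_fraction("NNNN") != gc_fraction("NNNN")  # NaN


def test_gene_census_closed_loop(small_genome):
    """Census equals the generator's catalog: uniques, IR duplicates, total."""
    rec, truth = small_genome
    st = detect_quadripartite(rec, min_ir_len=1000)
    cen = gene_census(rec, st)
    g = truth.config.genes
    uniq = g.n_protein_coding + g.n_trna + g.n_rrna
    dup = g.ir_protein_coding + g.ir_trna + g.ir_rrna
    assert cen.unique_genes == uniq
    assert cen.duplicated_in_ir == dup
    assert cen.total_genes == uniq + dup
    assert cen.unique_by_category == {
        "protein_coding": g.n_protein_coding, "tRNA": g.n_trna, "rRNA": g.n_rrna,
    }


def test_gene_census_empty_annotations(small_genome):
    rec, _ = small_genome
    st = detect_quadripartite(rec, min_ir_len=1000)
    bare = PlastomeRecord(id="bare", sequence=rec.sequence)
    cen = gene_census(bare, st)
    assert (cen.unique_genes, cen.duplicated_in_ir, cen.total_genes) == (0, 0, 0)
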