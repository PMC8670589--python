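import numpy as np
import pytest

from plastcomp.alignment import (
    DivergenceError,
    PairwiseAlignment,
    align_near_identical,
    concatenate_genes,
    extract_events,
    summarize_substitutions,
    summary_from_counts,
)
from plastcomp.records import GeneAnnotation, PlastomeRecord
from plastcomp.simulate import DivergenceSpec, diverge
from plastcomp.util import revcomp

from conftest import random_dna
from oracles import alignment_score, nw_affine


def test_identical_sequences_align_gap_free(rng):
    seq = random_dna(rng, 10_000)
    aln = align_near_identical(seq, seq)
    assert aln.ref_aln == aln.qry_aln == seq
    subs, indels = extract_events(aln)
    assert subs == [] and indels == []


def test_planted_single_sub_and_deletion(rng):
    ref = random_dna(rng, 4000)
    qry = list(ref)
    qry[1000] = next(b for b in "ACGT" if b != qry[1000])
    del qry[2000:2005]
    aln = align_near_identical(ref, "".join(qry))
    subs, indels = extract_events(aln)
    assert [(e.ref_pos, e.ref_base + ">" + e.qry_base) for e in subs] == [
        (1001, ref[1000] + ">" + qry[1000])
    ]
    assert len(indels) == 1
    ind = indels[0]
    assert ind.kind == "deletion" and ind.length == 5
    # left-shift normalization: position is the lowest equivalent coordinate
    p = 2001
    while p > 1 and ref[p - 2] == ref[p + 5 - 2]:
        p -= 1
    assert ind.ref_pos == p


def test_alignment_rows_restore_inputs(rng):
    ref = random_dna(rng, 3000)
    der, _ = diverge(
        PlastomeRecord(id="a", sequence=ref), DivergenceSpec(n_substitutions=30, n_indels=6),
        seed=5,
    )
    aln = align_near_identical(ref, der.sequence)
    assert aln.ref_seq == ref
    assert aln.qry_seq == der.sequence


def test_gotoh_matches_unbanded_nw_oracle(rng):
    """Anchored aligner yields alignments of the same optimal affine score as
    a plain unbanded Needleman-Wunsch, and identical extracted events on
    well-separated edits."""
    for seed in range(5):
        ref = random_dna(rng, 300)
        der, truth = diverge(
            PlastomeRecord(id="a", sequence=ref),
            DivergenceSpec(n_substitutions=4, n_indels=1),
            seed=seed,
        )
        aln = align_near_identical(ref, der.sequence, k=15)
        score, oa, ob = nw_affine(ref, der.sequence)
        assert alignment_score(aln.ref_aln, aln.qry_aln) == score
        subs, indels = extract_events(aln)
        osubs, oindels = extract_events(
            _left_shifted(PairwiseAlignment("r", "q", oa, ob))
        )
        assert {(e.ref_pos, e.ref_base, e.qry_base) for e in subs} == {
            (e.ref_pos, e.ref_base, e.qry_base) for e in osubs
        }
        assert {(e.ref_pos, e.length, e.kind) for e in indels} == {
            (e.ref_pos, e.length, e.kind) for e in oindels
        }


def _left_shifted(aln):
    from plastcomp.alignment import _left_shift_gaps

    return _left_shift_gaps(aln)


def test_divergent_inputs_rejected(rng):
    a = random_dna(rng, 50_000)
    b = random_dna(rng, 50_000)
    with pytest.raises(DivergenceError):
        align_near_identical(a, b)


def test_event_extraction_skips_n_columns():
    aln = PairwiseAlignment("r", "q", "ACNT", "AGGT")
    subs, _ = extract_events(aln)
    assert [(e.ref_pos, e.pair_category) for e in subs] == [(2, "C/G")]


def test_worked_example_columns():
    """Columns (A|G)(C|C)(T|-)(T|-) give one A/G substitution and one
    2 bp deletion."""
    aln = PairwiseAlignment("r", "q", "ACTT", "GC--")
    subs, indels = extract_events(aln)
    assert len(subs) == 1 and subs[0].pair_category == "A/G" and subs[0].is_transition
    assert len(indels) == 1
    assert indels[0].kind == "deletion" and indels[0].length == 2 and indels[0].ref_pos == 3


def test_insertion_anchored_to_preceding_base():
    aln = PairwiseAlignment("r", "q", "AC--GT", "ACTAGT")
    _, indels = extract_events(aln)
    assert indels == [type(indels[0])(ref_pos=2, length=2, kind="insertion")]


def test_summary_counts_and_symmetry(rng):
    ref = random_dna(rng, 6000)
    der, truth = diverge(
        PlastomeRecord(id="a", sequence=ref),
        DivergenceSpec(n_substitutions=120, n_indels=10),
        seed=3,
    )
    fwd = align_near_identical(ref, der.sequence)
    rev = align_near_identical(der.sequence, ref)
    s_f, i_f = extract_events(fwd)
    s_r, i_r = extract_events(rev)
    sum_f = summarize_substitutions(s_f)
    sum_r = summarize_substitutions(s_r)
    # pair categories are unordered: swapping ref/qry preserves all counts
    assert sum_f.counts == sum_r.counts
    assert sum_f.ts_tv_ratio == sum_r.ts_tv_ratio
    assert sum_f.ts_count + sum_f.tv_count == len(s_f)
    # indel kinds swap under exchange of the sequences
    assert sorted(e.kind for e in i_f) == sorted(
        {"insertion": "deletion", "deletion": "insertion"}[e.kind] for e in i_r
    )


def test_empty_summary_ratio_na():
    s = summarize_substitutions([])
    assert s.ts_count == s.tv_count == 0
    assert s.ts_tv_ratio is None


def test_concatenate_genes_strand_and_order():
    #          1234567890123456789012
    seq = "ATGAAATTTGGGCCCTTTAAAT"
    rec = PlastomeRecord(
        id="g", sequence=seq,
        annotations=[
            GeneAnnotation("b", "protein_coding", "-", ((13, 18),)),
            GeneAnnotation("a", "protein_coding", "+", ((1, 6),)),
        ],
    )
    out = concatenate_genes(rec, ["a", "b"])
    assert out == seq[0:6] + revcomp(seq[12:18])
    assert out == concatenate_genes(rec, ["b", "a"])  # genome order, not list order
    assert out == concatenate_genes(rec, ["a", "b"])  # deterministic
    with pytest.raises(KeyError):
        concatenate_genes(rec, ["a", "missing"])


def test_multi_exon_splice():
    seq = "AAATTTCCCGGGAAATTTCCCGGG"
    rec = PlastomeRecord(
        id="g", sequence=seq,
        annotations=[GeneAnnotation("m", "protein_coding", "+", ((4, 6), (10, 12)))],
    )
    assert concatenate_genes(rec, ["m"]) == seq[3:6] + seq[9:12]
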