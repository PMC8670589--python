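import numpy as np
import pytest

from plastcomp.alignment import align_near_identical, extract_events, summarize_substitutions
from plastcomp.records import PlastomeRecord
from plastcomp.structure import detect_quadripartite
from plastcomp.simulate import (
    DivergenceSpec,
    GeneratorConfig,
    PlantingError,
    diverge,
    generate_plastome,
)
from plastcomp.util import revcomp

from conftest import SMALL_CATALOG, small_config


def test_layout_and_total_length():
    cfg = small_config(seed=2)
    rec, truth = generate_plastome(cfg)
    assert rec.length == 8000 + 2000 + 2 * 2500
    # IRa is the exact reverse complement of IRb
    irb = rec.sequence[8000:10500]
    ira = rec.sequence[12500:15000]
    assert ira == revcomp(irb)
    st = detect_quadripartite(rec, min_ir_len=1000)
    assert (st.lsc, st.irb, st.ssc, st.ira) == (
        (1, 8000), (8001, 10500), (10501, 12500), (12501, 15000),
    )


def test_seed_determinism_byte_identical():
    a, _ = generate_plastome(small_config(seed=9))
    b, _ = generate_plastome(small_config(seed=9))
    c, _ = generate_plastome(small_config(seed=10))
    assert a.sequence == b.sequence
    assert [x.exons for x in a.annotations] == [x.exons for x in b.annotations]
    assert a.sequence != c.sequence


def test_zero_rates_identity():
    rec, _ = generate_plastome(small_config(seed=4))
    der, truth = diverge(rec, DivergenceSpec(substitution_rate=0.0, indel_rate=0.0), seed=1)
    assert der.sequence == rec.sequence
    assert truth.substitutions == [] and truth.indels == []


def test_divergence_event_counts_and_log_consistency():
    rec, _ = generate_plastome(small_config(seed=4))
    der, truth = diverge(rec, DivergenceSpec(n_substitutions=150, n_indels=15), seed=2)
    assert len(truth.substitutions) == 150
    assert len(truth.indels) == 15
    # log suffices to reconstruct: replaying events on the ancestor gives the
    # derived genome length
    delta = sum(e.length if e.kind == "insertion" else -e.length for e in truth.indels)
    assert der.length == rec.length + delta
    for e in truth.substitutions:
        assert rec.sequence[e.ref_pos - 1] == e.ref_base
        assert e.ref_base != e.qry_base


def test_ts_tv_ratio_recovery_pooled():
    """Configured Ts:Tv of 1.5 is recovered within 0.05 over pooled draws."""
    rec, _ = generate_plastome(small_config(seed=0))
    ts = tv = 0
    for s in range(20):
        _, truth = diverge(
            rec,
            DivergenceSpec(n_substitutions=500, n_indels=0, avoid_cds_stops=False),
            seed=s,
        )
        summ = summarize_substitutions(truth.substitutions)
        ts += summ.ts_count
        tv += summ.tv_count
    assert ts + tv == 10_000
    assert abs(ts / tv - 1.5) <= 0.05


def test_round_trip_event_recovery():
    """Alignment-based extraction recovers the logged events exactly."""
    rec, _ = generate_plastome(small_config(seed=6))
    der, truth = diverge(rec, DivergenceSpec(n_substitutions=200, n_indels=20), seed=8)
    subs, indels = extract_events(align_near_identical(rec.sequence, der.sequence))
    assert {(e.ref_pos, e.ref_base, e.qry_base) for e in subs} == {
        (e.ref_pos, e.ref_base, e.qry_base) for e in truth.substitutions
    }
    assert {(e.ref_pos, e.length, e.kind) for e in indels} == {
        (e.ref_pos, e.length, e.kind) for e in truth.indels
    }


def test_preserve_ir_keeps_structure_detectable():
    rec, _ = generate_plastome(small_config(seed=3))
    st = detect_quadripartite(rec, min_ir_len=1000)
    der, truth = diverge(
        rec,
        DivergenceSpec(n_substitutions=300, n_indels=10, preserve_ir=True),
        seed=5,
        structure_regions=(st.lsc, st.ssc),
    )
    st2 = detect_quadripartite(der, min_ir_len=1000)
    assert st2.ir_identity == 1.0
    for e in truth.substitutions:
        assert st.lsc[0] <= e.ref_pos <= st.lsc[1] or st.ssc[0] <= e.ref_pos <= st.ssc[1]


def test_planting_capacity_error():
    from plastcomp.simulate import PlantedSSRSpec

    cfg = small_config(
        seed=1,
        ssc_len=600, lsc_len=2000, ir_len=700,
        ssrs=tuple(PlantedSSRSpec(motif="A", copies=15, region="SSC") for _ in range(40)),
    )
    with pytest.raises(PlantingError):
        generate_plastome(cfg)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(lsc_len=0)
    with pytest.raises(ValueError):
        GeneratorConfig(gc=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(lsc_len=1000, ssc_len=2000)
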