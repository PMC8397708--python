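"""Interconnection graph and complex-event classification rules."""

import numpy as np
import pytest

from cnsig.events import (
    EventConfig,
    build_event_graph,
    classify_components,
    oscillating_cn_in_footprint,
    sample_has_chromothripsis,
)
from cnsig.io import SvBreakpointPair, SvCatalog

from conftest import chain_profile, make_profile


def pair(c1, p1, c2, p2, sv_type, pid):
    return SvBreakpointPair(c1, p1, "+", c2, p2, "-", sv_type, pid)


def diploid(chroms=("1", "2", "3", "4"), length=200_000_000):
    return make_profile({c: [(1, length, 2)] for c in chroms})


# ---------------------------------------------------------------------------
# graph


def test_nearby_pairs_form_one_component():
    cat = SvCatalog("S", [
        pair("1", 10_000_000, "1", 11_000_000, "deletion", "a"),
        pair("1", 11_100_000, "1", 12_000_000, "deletion", "b"),
    ])
    comps = build_event_graph(cat)
    assert len(comps) == 1 and len(comps[0]) == 2


def test_distant_translocations_stay_separate():
    cat = SvCatalog("S", [
        pair("1", 10_000_000, "2", 10_000_000, "translocation", "a"),
        pair("3", 50_000_000, "4", 50_000_000, "translocation", "b"),
    ])
    assert [len(c) for c in build_event_graph(cat)] == [1, 1]


def test_translocation_chain_links_across_chromosomes():
    cat = SvCatalog("S", [
        pair("1", 10_000_000, "2", 20_000_000, "translocation", "a"),
        pair("2", 20_500_000, "3", 30_000_000, "translocation", "b"),
        pair("3", 30_500_000, "1", 10_500_000, "translocation", "c"),
    ])
    comps = build_event_graph(cat)
    assert len(comps) == 1 and {p.id for p in comps[0]} == {"a", "b", "c"}


# ---------------------------------------------------------------------------
# oscillation in footprint


def _ct_catalog(n_pairs, chrom="1", start=10_000_000, step=400_000):
    pairs = []
    for i in range(n_pairs):
        p1 = start + 2 * i * step
        pairs.append(pair(chrom, p1, chrom, p1 + step, "deletion", f"ct{i}"))
    return SvCatalog("S", pairs)


def _oscillating_profile(n_segs, chrom="1", start=9_500_000, width=400_000, states=(2, 3)):
    triples = [(1, start - 1, 2)]
    pos = start
    for i in range(n_segs):
        triples.append((pos, pos + width - 1, states[i % 2]))
        pos += width
    triples.append((pos, 200_000_000, 2))
    return make_profile({chrom: triples})


def test_oscillation_detected_in_footprint():
    cat = _ct_catalog(11)
    prof = _oscillating_profile(24)
    osc, longest = oscillating_cn_in_footprint(prof, cat.pairs)
    assert osc and longest["1"] >= 6


def test_monotone_staircase_not_oscillating():
    cat = _ct_catalog(4, step=2_000_000)
    prof = make_profile({"1": [
        (1, 9_999_999, 2), (10_000_000, 14_000_000, 3), (14_000_001, 18_000_000, 4),
        (18_000_001, 22_000_000, 5), (22_000_001, 200_000_000, 6),
    ]})
    osc, _ = oscillating_cn_in_footprint(prof, cat.pairs)
    assert not osc


def test_flat_cn_not_oscillating():
    osc, _ = oscillating_cn_in_footprint(diploid(), _ct_catalog(11).pairs)
    assert not osc


# ---------------------------------------------------------------------------
# classification rules


def test_eleven_pairs_with_oscillation_is_chromothripsis():
    cat = _ct_catalog(11)
    prof = _oscillating_profile(24)
    calls = classify_components(cat, prof)
    assert len(calls) == 1
    assert calls[0].event_class == "chromothripsis"
    assert sample_has_chromothripsis(calls)


def test_exactly_ten_pairs_is_not_chromothripsis():
    cat = _ct_catalog(10)
    prof = _oscillating_profile(22)
    calls = classify_components(cat, prof)
    assert calls[0].n_pairs == 10
    assert calls[0].oscillating_cn
    assert calls[0].event_class == "complex_nos"


def test_chromoplexy_translocation_ring_with_deletion_bridges():
    # t(1;2), t(2;3), t(3;1) with CN=1 bridges at the breakends
    prof = make_profile({
        "1": [(1, 9_999_999, 2), (10_000_000, 10_200_000, 1), (10_200_001, 200_000_000, 2)],
        "2": [(1, 19_999_999, 2), (20_000_000, 20_200_000, 1), (20_200_001, 200_000_000, 2)],
        "3": [(1, 29_999_999, 2), (30_000_000, 30_200_000, 1), (30_200_001, 200_000_000, 2)],
    })
    cat = SvCatalog("S", [
        pair("1", 10_200_000, "2", 20_000_000, "translocation", "a"),
        pair("2", 20_200_000, "3", 30_000_000, "translocation", "b"),
        pair("3", 30_200_000, "1", 10_000_000, "translocation", "c"),
    ])
    calls = classify_components(cat, prof)
    assert len(calls) == 1
    assert calls[0].event_class == "chromoplexy"
    assert calls[0].cn_loss_associated


def test_single_translocation_with_focal_gain_is_templated_insertion():
    prof = make_profile({
        "1": [(1, 9_999_999, 2), (10_000_000, 10_500_000, 3), (10_500_001, 200_000_000, 2)],
        "2": [(1, 19_999_999, 2), (20_000_000, 20_400_000, 3), (20_400_001, 200_000_000, 2)],
    })
    cat = SvCatalog("S", [pair("1", 10_000_000, "2", 20_000_000, "translocation", "t")])
    calls = classify_components(cat, prof)
    assert calls[0].event_class == "templated_insertion_simple"


def test_templated_insertion_over_three_chromosomes_is_complex():
    prof = make_profile({
        c: [(1, s - 1, 2), (s, s + 400_000, 3), (s + 400_001, 200_000_000, 2)]
        for c, s in [("1", 10_000_000), ("2", 20_000_000), ("3", 30_000_000)]
    })
    cat = SvCatalog("S", [
        pair("1", 10_400_000, "2", 20_000_000, "translocation", "a"),
        pair("2", 20_400_000, "3", 30_000_000, "translocation", "b"),
        pair("3", 30_400_000, "1", 10_000_000, "translocation", "c"),
    ])
    calls = classify_components(cat, prof)
    assert calls[0].event_class == "templated_insertion_complex"


def test_three_balanced_inversions_are_complex_nos():
    cat = SvCatalog("S", [
        pair("1", 10_000_000 + i * 300_000, "1", 10_150_000 + i * 300_000, "inversion", f"i{i}")
        for i in range(3)
    ])
    calls = classify_components(cat, diploid())
    assert calls[0].event_class == "complex_nos"


def test_lone_deletion_is_single():
    cat = SvCatalog("S", [pair("1", 10_000_000, "1", 12_000_000, "deletion", "d")])
    calls = classify_components(cat, diploid())
    assert calls[0].event_class == "single"


def test_classification_invariant_to_pair_order(rng):
    cat = _ct_catalog(12)
    prof = _oscillating_profile(26)
    base = classify_components(cat, prof)
    order = rng.permutation(len(cat.pairs))
    shuffled = SvCatalog("S", [cat.pairs[i] for i in order])
    again = classify_components(shuffled, prof)
    assert [c.event_class for c in base] == [c.event_class for c in again]
    assert [sorted(c.member_ids) for c in base] == [sorted(c.member_ids) for c in again]


def test_every_pair_in_exactly_one_component():
    cat = SvCatalog("S", (
        _ct_catalog(5).pairs
        + [pair("2", 50_000_000, "2", 60_000_000, "deletion", "lone")]
    ))
    comps = build_event_graph(cat)
    seen = [p.id for comp in comps for p in comp]
    assert sorted(seen) == sorted(p.id for p in cat.pairs)
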