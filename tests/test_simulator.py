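"""Simulator determinism, planted-truth consistency and scenario presets."""

import numpy as np
import pytest

from cnsig.events import classify_components
from cnsig.features import oscillation_chain_lengths
from cnsig.io import ValidationError, apply_filters
from cnsig.simulate import (
    SimulationConfig,
    read_cohort,
    scenario_presets,
    simulate_cohort,
    write_cohort,
)


@pytest.fixture(scope="module")
def mm_cohort(assets=None):
    return simulate_cohort(SimulationConfig(n_samples=100, seed=7))


def test_prevalence_within_binomial_bounds(mm_cohort):
    positives = int(mm_cohort.truth["chromothripsis"].sum())
    # binomial(100, 0.24): +-3 sd around 24
    assert 11 <= positives <= 37


def test_same_seed_byte_identical(tmp_path, mm_cohort):
    again = simulate_cohort(SimulationConfig(n_samples=100, seed=7))
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_cohort(mm_cohort, d1)
    write_cohort(again, d2)
    for f1 in sorted(d1.iterdir()):
        assert f1.read_bytes() == (d2 / f1.name).read_bytes(), f1.name


def test_different_seed_differs():
    a = simulate_cohort(SimulationConfig(n_samples=10, seed=1))
    b = simulate_cohort(SimulationConfig(n_samples=10, seed=2))
    assert a.truth.to_csv() != b.truth.to_csv() or [
        len(c.pairs) for c in a.catalogs
    ] != [len(c.pairs) for c in b.catalogs]


def test_planted_events_recovered_noise_free(assets):
    cfg = SimulationConfig(
        n_samples=80, seed=13, passenger_sv_mean=0.0, passenger_cna_mean=0.0,
        chromothripsis_prevalence=0.5, chromoplexy_rate=0.4,
        templated_insertion_rate=0.4, complex_nos_rate=0.4,
    )
    cohort = simulate_cohort(cfg)
    prof = {p.sample_id: p for p in cohort.profiles}
    cat = {c.sample_id: c for c in cohort.catalogs}
    assert len(cohort.events) >= 100
    for ev in cohort.events:
        fp, fc = apply_filters(prof[ev.sample_id], cat[ev.sample_id], assets)
        calls = classify_components(fc, fp)
        matched = [c for c in calls if set(c.member_ids) == set(ev.member_ids)]
        assert matched, f"{ev.event_class} component not found intact"
        assert matched[0].event_class == ev.event_class


def test_truth_labels_consistent_with_events(mm_cohort):
    by_sample = {}
    for ev in mm_cohort.events:
        by_sample.setdefault(ev.sample_id, []).append(ev.event_class)
    for sample, row in mm_cohort.truth.iterrows():
        planted = by_sample.get(sample, [])
        assert row["chromothripsis"] == int("chromothripsis" in planted)
        assert row["n_events"] == len(planted)


def test_chromothripsis_pair_counts_match_config(mm_cohort):
    ns = [e.n_pairs for e in mm_cohort.events if e.event_class == "chromothripsis"]
    assert ns and min(ns) >= 11
    assert 15 <= float(np.median(ns)) <= 35


def test_invalid_configs_rejected():
    with pytest.raises(ValidationError, match="exceed 10"):
        simulate_cohort(SimulationConfig(n_samples=2, ct_min_pairs=8))
    with pytest.raises(ValidationError, match="prevalence"):
        SimulationConfig(chromothripsis_prevalence=1.5).validate()


def test_mm_like_respects_cn_ceiling(mm_cohort):
    assert max(s.total_cn for p in mm_cohort.profiles for s in p.segments) <= 9


def test_quiet_preset_has_no_complex_events():
    cohort = simulate_cohort(scenario_presets("quiet", n_samples=20, seed=5))
    assert cohort.events == []
    assert cohort.truth["chromothripsis"].sum() == 0


def test_solid_like_longer_oscillation_chains():
    mm = simulate_cohort(scenario_presets("mm_like", n_samples=40, seed=9))
    solid = simulate_cohort(scenario_presets("solid_like", n_samples=40, seed=9))

    def mean_chain(cohort):
        lengths = []
        for p in cohort.profiles:
            lengths.extend(v for v in oscillation_chain_lengths(p) if v > 0)
        return np.mean(lengths) if lengths else 0.0

    assert mean_chain(solid) > mean_chain(mm)


def test_write_cohort_round_trip_and_force(tmp_path, mm_cohort):
    small = simulate_cohort(SimulationConfig(n_samples=1, seed=0))
    out = tmp_path / "cohort"
    write_cohort(small, out)
    assert len(list(out.iterdir())) == 3  # segments.tsv, one BEDPE, truth.tsv
    profiles, catalogs, truth = read_cohort(out)
    assert profiles[0].segments == small.profiles[0].segments
    assert catalogs[0].pairs == small.catalogs[0].pairs
    assert truth["chromothripsis"].tolist() == small.truth["chromothripsis"].tolist()
    with pytest.raises(FileExistsError):
        write_cohort(small, out)
    write_cohort(small, out, force=True)
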