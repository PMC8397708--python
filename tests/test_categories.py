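"""Category-scheme fitting, hard assignment and the CN count matrix."""

import numpy as np
import pandas as pd
import pytest

from cnsig.categories import (
    CategoryScheme,
    Component,
    FeatureCategories,
    FIXED_CN_STATE_LABELS,
    assign_counts,
    build_cn_matrix,
    component_responsibilities,
    fit_category_scheme,
    fit_poisson_mixture,
)
from cnsig.features import FEATURE_NAMES, CnFeatureValues
from cnsig.io import ValidationError

from oracles import mixture_posterior_brute


def make_values(sample="S1", **overrides) -> CnFeatureValues:
    base = {name: [] for name in FEATURE_NAMES}
    base.update(overrides)
    return CnFeatureValues(sample, base)


@pytest.fixture(scope="module")
def toy_cohort(rng=None):
    """Two-mode data on every fitted feature, well separated."""
    r = np.random.default_rng(7)
    cohort = []
    for i in range(20):
        cohort.append(
            make_values(
                sample=f"S{i}",
                bkpt_per_10mb=list(r.poisson(0.2, 40)) + list(r.poisson(12, 10)),
                bkpt_per_arm=list(r.poisson(0.3, 30)) + list(r.poisson(20, 8)),
                oscillation_len=list(r.poisson(0.1, 20)) + list(r.poisson(15, 6)),
                cn_jump=list(np.clip(np.round(r.normal(1, 0.1, 30)), 1, None))
                + list(np.clip(np.round(r.normal(5, 0.3, 10)), 1, None)),
                segment_cn=list(r.integers(0, 7, 40)),
                segment_size=list(10 ** r.normal(5.0, 0.15, 30))
                + list(10 ** r.normal(7.5, 0.15, 20)),
            )
        )
    return cohort


@pytest.fixture(scope="module")
def toy_scheme(toy_cohort):
    return fit_category_scheme(toy_cohort, seed=3, n_restarts=8)


def test_fixed_cn_states_installed_verbatim(toy_scheme):
    comps = toy_scheme.features["segment_cn"].components
    assert [c.label for c in comps] == list(FIXED_CN_STATE_LABELS)
    assert [c.state for c in comps] == [0, 1, 2, 3, 4]


def test_fixed_state_mapping_including_high_cn():
    scheme = CategoryScheme(
        {
            name: FeatureCategories(
                name,
                [Component(family="poisson", label=f"{name}:1", rate=1.0)]
                if name != "segment_cn"
                else [
                    Component(family="fixed_state", label=lab, state=i)
                    for i, lab in enumerate(FIXED_CN_STATE_LABELS)
                ],
            )
            for name in FEATURE_NAMES
        }
    )
    row = assign_counts(make_values(segment_cn=[0, 1, 2, 3, 4, 7]), scheme)
    assert [row[lab] for lab in FIXED_CN_STATE_LABELS] == [1, 1, 1, 1, 2]
    with pytest.raises(ValidationError):
        assign_counts(make_values(segment_cn=[-1]), scheme)


def test_bic_selects_two_components_for_bimodal_sizes(toy_scheme):
    assert len(toy_scheme.features["segment_size"].components) == 2
    means = [c.mean for c in toy_scheme.features["segment_size"].components]
    assert means == sorted(means)
    assert len(toy_scheme.features["bkpt_per_10mb"].components) == 2


def test_degenerate_cohort_single_component_per_feature():
    constant = [
        make_values(sample="A", segment_cn=[2], segment_size=[1_000_000], cn_jump=[1],
                    bkpt_per_10mb=[0], bkpt_per_arm=[0], oscillation_len=[0]),
    ]
    with pytest.warns(UserWarning):
        scheme = fit_category_scheme(constant, seed=0, n_restarts=2)
    # 5 fitted singletons + 5 fixed states
    assert scheme.total_categories == 10


def test_assignment_matches_brute_posterior(toy_scheme):
    fc = toy_scheme.features["bkpt_per_10mb"]
    for v in [0, 1, 3, 8, 15, 30]:
        mine = component_responsibilities(v, fc)
        brute = mixture_posterior_brute(v, fc.components)
        np.testing.assert_allclose(mine, brute, atol=1e-9)


def test_per_feature_count_conservation(toy_cohort, toy_scheme):
    for values in toy_cohort:
        row = assign_counts(values, toy_scheme)
        for name in FEATURE_NAMES:
            cols = toy_scheme.features[name].labels
            assert row[cols].sum() == len(values[name]), name


def test_matrix_rows_follow_cohort_order_and_duplicates(toy_cohort, toy_scheme):
    m = build_cn_matrix(toy_cohort, toy_scheme)
    assert list(m.index) == [v.sample_id for v in toy_cohort]
    m2 = build_cn_matrix(toy_cohort[::-1], toy_scheme)
    pd.testing.assert_frame_equal(m.iloc[::-1], m2)
    # identical samples get identical rows
    clone = CnFeatureValues("S0b", dict(toy_cohort[0].values))
    twin = [toy_cohort[0], clone]
    tm = build_cn_matrix(twin, toy_scheme).to_numpy()
    assert (tm[0] == tm[1]).all()


def test_fit_invariant_to_sample_order(toy_cohort):
    a = fit_category_scheme(toy_cohort, seed=3, n_restarts=4)
    b = fit_category_scheme(toy_cohort[::-1], seed=3, n_restarts=4)
    assert a.column_labels == b.column_labels
    for name in FEATURE_NAMES:
        for ca, cb in zip(a.features[name].components, b.features[name].components):
            assert ca.location == pytest.approx(cb.location, abs=1e-6)


def test_component_count_recovery_on_duplicated_cohort(toy_cohort):
    a = fit_category_scheme(toy_cohort, seed=3, n_restarts=4)
    b = fit_category_scheme(toy_cohort + toy_cohort, seed=3, n_restarts=4)
    for name in FEATURE_NAMES:
        assert len(a.features[name].components) == len(b.features[name].components)


def test_poisson_mixture_em_separates_two_rates(rng):
    r = np.random.default_rng(1)
    data = np.concatenate([r.poisson(0.3, 800), r.poisson(10, 200)])
    weights, rates, ll = fit_poisson_mixture(data, 2, np.random.default_rng(0), n_restarts=10)
    rates = np.sort(rates)
    assert rates[0] == pytest.approx(0.3, abs=0.15)
    assert rates[1] == pytest.approx(10.0, abs=1.0)


def test_scheme_yaml_round_trip(tmp_path, toy_scheme):
    path = tmp_path / "scheme.yaml"
    toy_scheme.to_yaml(path)
    back = CategoryScheme.from_yaml(path)
    assert back.column_labels == toy_scheme.column_labels
    for name in FEATURE_NAMES:
        for ca, cb in zip(toy_scheme.features[name].components, back.features[name].components):
            assert ca.family == cb.family
            assert ca.location == pytest.approx(cb.location)
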