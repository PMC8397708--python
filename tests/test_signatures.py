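"""Signature extraction invariants, exposures and cosine similarity."""

import numpy as np
import pandas as pd
import pytest

from cnsig.io import ValidationError
from cnsig.signatures import (
    ExposureMatrix,
    HdpConfig,
    SignatureSet,
    cosine_similarity,
    extract_hdp,
    extract_nmf,
    fit_exposures,
    match_signatures,
)


def synthetic_matrix(n=60, C=20, k=3, seed=0, events=(60, 150)):
    rng = np.random.default_rng(seed)
    truth = rng.dirichlet(np.ones(C) * 0.3, size=k)
    expo = rng.dirichlet(np.ones(k) * 0.5, size=n)
    counts = np.vstack(
        [rng.multinomial(rng.integers(*events), e @ truth) for e in expo]
    )
    m = pd.DataFrame(counts, index=[f"S{i}" for i in range(n)],
                     columns=[f"c{j}" for j in range(C)])
    return m, truth


def test_cosine_similarity_examples():
    assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)
    assert cosine_similarity([0, 0], [1, 1]) == 0.0


def test_signature_rows_must_be_simplex():
    with pytest.raises(ValidationError):
        SignatureSet(names=["a"], categories=["x", "y"], weights=np.array([[0.5, 0.6]]))
    with pytest.raises(ValidationError):
        ExposureMatrix(sample_ids=["s"], names=["a", "b"], weights=np.array([[0.5, 0.2]]))


def test_repeated_row_matrix_gives_single_signature():
    row = np.array([5, 0, 3, 2, 0])
    m = pd.DataFrame([row, row * 2, row * 3], index=list("abc"),
                     columns=[f"c{i}" for i in range(5)])
    sigs, expo = extract_hdp(m, HdpConfig(chains=2, burnin=50, posterior_samples=10, thin=2), seed=0)
    assert sigs.k == 1
    np.testing.assert_allclose(sigs.weights[0], row / row.sum(), atol=0.05)
    np.testing.assert_allclose(expo.weights, 1.0)


def test_non_integer_matrix_rejected():
    m = pd.DataFrame([[0.5, 1.2], [1.0, 2.0]], index=["a", "b"], columns=["x", "y"])
    with pytest.raises(ValidationError, match="integer"):
        extract_hdp(m)


def test_all_zero_matrix_rejected():
    m = pd.DataFrame(np.zeros((3, 4), dtype=int), index=list("abc"),
                     columns=[f"c{i}" for i in range(4)])
    with pytest.raises(ValidationError):
        extract_nmf(m)


def test_rank1_matrix_nmf_selects_k1():
    row = np.array([10, 5, 0, 1])
    m = pd.DataFrame([row, row * 2, row * 4], index=list("abc"),
                     columns=[f"c{i}" for i in range(4)])
    sigs, expo = extract_nmf(m, k_range=range(1, 4), n_restarts=4, seed=0)
    assert sigs.k == 1
    np.testing.assert_allclose(expo.weights, 1.0)


def test_nmf_k_range_capped_at_rank():
    m, _ = synthetic_matrix(n=5, C=6, k=2, seed=1)
    with pytest.warns(UserWarning, match="capping"):
        extract_nmf(m, k_range=range(1, 12), n_restarts=2, seed=0)


def test_nmf_recovers_planted_signatures():
    m, truth = synthetic_matrix(n=120, C=24, k=3, seed=3, events=(100, 220))
    sigs, _ = extract_nmf(m, k_range=range(1, 7), n_restarts=6, seed=2)
    assert sigs.k == 3
    _, cosines = match_signatures(truth, sigs.weights)
    assert min(cosines) >= 0.95


def test_hdp_and_nmf_agree_on_separated_data():
    m, truth = synthetic_matrix(n=120, C=24, k=3, seed=3, events=(100, 220))
    hs, _ = extract_hdp(m, HdpConfig(chains=2, burnin=150, posterior_samples=15, thin=3), seed=1)
    ns, _ = extract_nmf(m, k_range=range(1, 7), n_restarts=6, seed=2)
    _, cosines = match_signatures(hs.weights, ns.weights)
    assert min(cosines) >= 0.9


def test_hdp_seed_stability():
    m, _ = synthetic_matrix(n=80, C=20, k=3, seed=5, events=(100, 200))
    cfg = HdpConfig(chains=2, burnin=150, posterior_samples=15, thin=3)
    a, _ = extract_hdp(m, cfg, seed=11)
    b, _ = extract_hdp(m, cfg, seed=99)
    assert a.k == b.k
    _, cosines = match_signatures(a.weights, b.weights)
    assert min(cosines) >= 0.99
    # same seed -> byte identical
    a2, _ = extract_hdp(m, cfg, seed=11)
    np.testing.assert_array_equal(a.weights, a2.weights)


# ---------------------------------------------------------------------------
# exposures


@pytest.fixture(scope="module")
def orthogonal_sigs():
    w = np.zeros((2, 6))
    w[0, :3] = 1 / 3
    w[1, 3:] = 1 / 3
    return SignatureSet(names=["A", "B"], categories=[f"c{i}" for i in range(6)], weights=w)


def test_exposure_identity_on_pure_sample(orthogonal_sigs):
    m = pd.DataFrame([[34, 33, 33, 0, 0, 0]], index=["pure"],
                     columns=orthogonal_sigs.categories)
    expo = fit_exposures(m, orthogonal_sigs)
    np.testing.assert_allclose(expo.weights, [[1.0, 0.0]], atol=1e-9)


def test_exposure_half_half_mixture(orthogonal_sigs):
    m = pd.DataFrame([[50, 50, 50, 50, 50, 50]], index=["mix"],
                     columns=orthogonal_sigs.categories)
    expo = fit_exposures(m, orthogonal_sigs)
    np.testing.assert_allclose(expo.weights, [[0.5, 0.5]], atol=0.01)


def test_exposure_empty_sample_is_zero_row(orthogonal_sigs):
    m = pd.DataFrame([[0] * 6], index=["empty"], columns=orthogonal_sigs.categories)
    expo = fit_exposures(m, orthogonal_sigs)
    assert (expo.weights == 0).all()
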