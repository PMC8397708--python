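"""De novo signature extraction from CN/SV count matrices.

Two backends produce a :class:`SignatureSet` (signatures x categories, each
row a probability distribution) and an :class:`ExposureMatrix` (samples x
signatures, each row on the simplex, or all-zero for an empty sample):

* :func:`extract_hdp` — a hierarchical Dirichlet process mixture over
  categorical events.  Each observed event (one unit of one category in
  one sample) is assigned to a latent component; components are shared
  across samples through a top-level Dirichlet process, so the number of
  signatures is inferred rather than fixed.  Inference is a direct-
  assignment Gibbs sampler (Teh et al.'s Chinese-restaurant-franchise
  scheme) run over several independent chains; posterior components are
  consolidated across chains by cosine-similarity clustering into
  consensus signatures.

* :func:`extract_nmf` — Kullback-Leibler non-negative matrix factorization
  with random restarts; the rank is chosen by restart stability plus a
  reconstruction-error elbow.

Exposures are obtained by projecting the count matrix onto the fixed
signatures with simplex-constrained multinomial EM (:func:`fit_exposures`),
so the simplex invariants hold exactly for both backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from .io import ValidationError

__all__ = [
    "SignatureSet",
    "ExposureMatrix",
    "HdpConfig",
    "extract_hdp",
    "extract_nmf",
    "fit_exposures",
    "cosine_similarity",
    "match_signatures",
]


@dataclass
class SignatureSet:
    """Named signatures over a fixed category space; rows sum to 1."""

    names: list[str]
    categories: list[str]
    weights: np.ndarray  # (k, C)
    uncertainty: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.names), len(self.categories)):
            raise ValidationError("signature matrix shape mismatch")
        if (self.weights < -1e-12).any():
            raise ValidationError("negative signature weights")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("signature rows must sum to 1")

    @property
    def k(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.names, columns=self.categories)


@dataclass
class ExposureMatrix:
    """Per-sample relative signature contributions; rows sum to 1 or are all zero."""

    sample_ids: list[str]
    names: list[str]
    weights: np.ndarray  # (n, k)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.sample_ids), len(self.names)):
            raise ValidationError("exposure matrix shape mismatch")
        if (self.weights < -1e-12).any():
            raise ValidationError("negative exposures")
        sums = self.weights.sum(axis=1)
        if not np.all(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)):
            raise ValidationError("exposure rows must sum to 1 (or 0 for empty samples)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.sample_ids, columns=self.names)


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two non-negative category vectors (0 for a zero vector)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_signatures(a: np.ndarray, b: np.ndarray) -> tuple[list[tuple[int, int]], list[float]]:
    """Hungarian matching of two signature matrices by maximal cosine."""
    sim = np.array([[cosine_similarity(x, y) for y in b] for x in a])
    ri, ci = linear_sum_assignment(-sim)
    return list(zip(ri.tolist(), ci.tolist())), [float(sim[i, j]) for i, j in zip(ri, ci)]


def _validate_count_matrix(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if (x < 0).any():
        raise ValidationError("count matrix must be non-negative")
    if not np.allclose(x, np.round(x)):
        raise ValidationError("count matrix must be integer-valued")
    return np.round(x).astype(np.int64)


# ---------------------------------------------------------------------------
# HDP direct-assignment Gibbs sampler


@dataclass(frozen=True)
class HdpConfig:
    chains: int = 4
    burnin: int = 300
    posterior_samples: int = 25
    thin: int = 4
    alpha: float = 1.0        # per-sample DP concentration
    gamma: float = 1.0        # top-level DP concentration
    eta: float = 0.2          # symmetric Dirichlet base over categories
    k_init: int = 4
    k_max: int = 40
    cosine_threshold: float = 0.9
    min_cluster_occupancy: float = 0.5  # fraction of posterior draws a consensus
                                        # signature must appear in


@njit(cache=True)
def _gibbs_sweep(cat, samp, z, njk, mkc, mk, beta, K_active, alpha, eta, gamma,
                 u_choice, u_stick, probs):
    C = mkc.shape[1]
    Kmax = mkc.shape[0]
    for i in range(cat.shape[0]):
        c = cat[i]
        j = samp[i]
        k = z[i]
        njk[j, k] -= 1.0
        mkc[k, c] -= 1.0
        mk[k] -= 1.0
        tot = 0.0
        for k2 in range(K_active):
            p = (njk[j, k2] + alpha * beta[k2]) * (mkc[k2, c] + eta) / (mk[k2] + C * eta)
            probs[k2] = p
            tot += p
        pnew = alpha * beta[K_active] / C
        tot += pnew
        r = u_choice[i] * tot
        knew = -1
        acc = 0.0
        for k2 in range(K_active):
            acc += probs[k2]
            if r <= acc:
                knew = k2
                break
        if knew < 0:
            if K_active < Kmax:
                knew = K_active
                b = 1.0 - (1.0 - u_stick[i]) ** (1.0 / gamma)
                beta[K_active + 1] = beta[K_active] * (1.0 - b)
                beta[K_active] = beta[K_active] * b
                K_active += 1
            else:
                knew = K_active - 1
        z[i] = knew
        njk[j, knew] += 1.0
        mkc[knew, c] += 1.0
        mk[knew] += 1.0
    return K_active


def _compact(z, njk, mkc, mk, beta, K_active):
    """Drop empty components, folding their stick weight back into the remainder."""
    active = [k for k in range(K_active) if mk[k] > 0]
    if len(active) == K_active:
        return K_active
    remap = -np.ones(K_active, dtype=np.int64)
    freed = 0.0
    for new, old in enumerate(active):
        remap[old] = new
    for k in range(K_active):
        if remap[k] < 0:
            freed += beta[k]
    K_new = len(active)
    njk[:, :K_new] = njk[:, active]
    njk[:, K_new:] = 0.0
    mkc[:K_new] = mkc[active]
    mkc[K_new:] = 0.0
    mk[:K_new] = mk[active]
    mk[K_new:] = 0.0
    beta[:K_new] = beta[active]
    beta[K_new] = beta[K_active] + freed
    beta[K_new + 1 :] = 0.0
    z[:] = remap[z]
    return K_new


def _sample_tables_and_beta(rng, njk, beta, mk, K_active, alpha, gamma):
    """Chinese-restaurant table counts per (sample, component), then the
    top-level stick weights beta ~ Dirichlet(T_1..T_K, gamma)."""
    T = np.zeros(K_active)
    for k in range(K_active):
        a = alpha * beta[k]
        if a <= 0:
            continue
        col = njk[:, k]
        for n in col[col > 0]:
            i = np.arange(int(n))
            T[k] += (rng.random(int(n)) < a / (a + i)).sum()
    T = np.maximum(T, (mk[:K_active] > 0).astype(float))
    draw = rng.dirichlet(np.concatenate([T, [gamma]]))
    beta[: K_active + 1] = draw
    beta[K_active + 1 :] = 0.0


def _run_chain(counts: np.ndarray, config: HdpConfig, seed: int):
    """One Gibbs chain; returns posterior draws of (phi, weight) components."""
    n_samples, C = counts.shape
    samp_idx, cat_idx = np.nonzero(counts)
    reps = counts[samp_idx, cat_idx]
    samp = np.repeat(samp_idx, reps).astype(np.int64)
    cat = np.repeat(cat_idx, reps).astype(np.int64)
    n_items = len(cat)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    samp, cat = samp[perm], cat[perm]

    K = min(config.k_init, config.k_max)
    z = rng.integers(0, K, n_items).astype(np.int64)
    njk = np.zeros((n_samples, config.k_max))
    mkc = np.zeros((config.k_max, C))
    mk = np.zeros(config.k_max)
    for i in range(n_items):
        njk[samp[i], z[i]] += 1
        mkc[z[i], cat[i]] += 1
        mk[z[i]] += 1
    beta = np.zeros(config.k_max + 1)
    beta[: K + 1] = rng.dirichlet(np.ones(K + 1))

    probs = np.zeros(config.k_max)
    draws = []
    n_sweeps = config.burnin + config.posterior_samples * config.thin
    for sweep in range(n_sweeps):
        u_choice = rng.random(n_items)
        u_stick = rng.random(n_items)
        K = _gibbs_sweep(cat, samp, z, njk, mkc, mk, beta, K, config.alpha,
                         config.eta, config.gamma, u_choice, u_stick, probs)
        K = _compact(z, njk, mkc, mk, beta, K)
        _sample_tables_and_beta(rng, njk, beta, mk, K, config.alpha, config.gamma)
        if sweep >= config.burnin and (sweep - config.burnin) % config.thin == 0:
            phi = (mkc[:K] + config.eta) / (mk[:K, None] + C * config.eta)
            draws.append((phi.copy(), mk[:K].copy(), K))
    return draws


def _consolidate(draws_per_chain, C, threshold, min_occupancy):
    """Cosine-cluster posterior components across chains into consensus signatures."""
    records = []  # (weight, phi, draw_id)
    draw_id = 0
    for chain_draws in draws_per_chain:
        for phi, mk, K in chain_draws:
            for k in range(K):
                records.append((float(mk[k]), phi[k], draw_id))
            draw_id += 1
    total_draws = draw_id
    records.sort(key=lambda r: -r[0])
    centroids: list[np.ndarray] = []
    csum: list[np.ndarray] = []
    cweight: list[float] = []
    cdraws: list[set] = []
    for w, phi, did in records:
        best, best_cos = -1, threshold
        for ci, cen in enumerate(centroids):
            cs = cosine_similarity(phi, cen)
            if cs >= best_cos:
                best, best_cos = ci, cs
        if best < 0:
            csum.append(w * phi)
            cweight.append(w)
            centroids.append(phi.copy())
            cdraws.append({did})
        else:
            csum[best] += w * phi
            cweight[best] += w
            centroids[best] = csum[best] / cweight[best]
            cdraws[best].add(did)
    total_w = sum(cweight)
    sigs, sds, weights = [], [], []
    for ci in range(len(centroids)):
        occupancy = len(cdraws[ci]) / max(total_draws, 1)
        if occupancy < min_occupancy or cweight[ci] < 0.01 * total_w:
            continue
        v = np.maximum(csum[ci] / cweight[ci], 0)
        sigs.append(v / v.sum())
        weights.append(cweight[ci])
    order = np.argsort(weights)[::-1]
    return [sigs[i] for i in order]


def extract_hdp(
    matrix: pd.DataFrame,
    config: HdpConfig = HdpConfig(),
    seed: int = 0,
    name_prefix: str = "SIG",
) -> tuple[SignatureSet, ExposureMatrix]:
    """De novo signature extraction via the hierarchical Dirichlet process.

    Deterministic given ``seed`` and the chain count.  A large disagreement
    in the number of components across chains is recorded as a convergence
    warning in the returned set's ``metadata`` (never an exception).
    """
    counts = _validate_count_matrix(matrix)
    if counts.sum() == 0:
        raise ValidationError("count matrix is all zero")
    C = counts.shape[1]
    draws_per_chain = []
    k_per_chain = []
    for chain in range(config.chains):
        draws = _run_chain(counts, config, seed=(seed * 9973 + chain) % (2**31 - 1))
        draws_per_chain.append(draws)
        k_per_chain.append(float(np.mean([d[2] for d in draws])))
    sigs = _consolidate(
        draws_per_chain, C, config.cosine_threshold, config.min_cluster_occupancy
    )
    if not sigs:  # degenerate fallback: pooled profile
        pooled = counts.sum(axis=0).astype(float)
        sigs = [pooled / pooled.sum()]
    metadata = {"k_per_chain": k_per_chain, "backend": "hdp", "seed": seed}
    if max(k_per_chain) - min(k_per_chain) > 2.0:
        metadata["convergence_warning"] = (
            "chains disagree on the number of components; consider longer burn-in"
        )
        warnings.warn(metadata["convergence_warning"])
    return _package(matrix, np.array(sigs), name_prefix, metadata)


# ---------------------------------------------------------------------------
# NMF backend


def extract_nmf(
    matrix: pd.DataFrame,
    k_range=range(1, 9),
    n_restarts: int = 10,
    seed: int = 0,
    stability_threshold: float = 0.8,
    elbow_improvement: float = 0.05,
    name_prefix: str = "SIG",
) -> tuple[SignatureSet, ExposureMatrix]:
    """KL-divergence NMF with restarts; rank chosen by restart stability and
    a reconstruction-error elbow (largest k that is stable and still improves
    the fit by at least ``elbow_improvement`` relative to the previous rank)."""
    counts = _validate_count_matrix(matrix).astype(float)
    if counts.sum() == 0:
        raise ValidationError("count matrix is all zero")
    rank_cap = int(min(counts.shape))
    ks = sorted(set(int(k) for k in k_range))
    if any(k > rank_cap for k in ks):
        warnings.warn(f"k_range exceeds matrix rank; capping at {rank_cap}")
        ks = [k for k in ks if k <= rank_cap] or [rank_cap]
    results = {}
    for k in ks:
        fits = []
        for r in range(n_restarts):
            model = NMF(
                n_components=k,
                beta_loss="kullback-leibler",
                solver="mu",
                init="random",
                max_iter=600,
                random_state=seed * 1009 + r,
                tol=1e-6,
            )
            with warnings.catch_warnings():
                # restarts are compared by final loss; per-restart iteration
                # caps are expected to trigger
                warnings.filterwarnings("ignore", message="Maximum number of iterations")
                W = model.fit_transform(counts)
            fits.append((model.reconstruction_err_, model.components_.copy(), W))
        fits.sort(key=lambda f: f[0])
        err, H_best, W_best = fits[0]
        ref = H_best / np.maximum(H_best.sum(axis=1, keepdims=True), 1e-12)
        cosines = []
        for _, H, _ in fits[1:]:
            Hn = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-12)
            _, cs = match_signatures(ref, Hn)
            cosines.extend(cs)
        stability = float(np.mean(cosines)) if cosines else 1.0
        results[k] = (stability, err, H_best, W_best)

    chosen = ks[0]
    prev_err = results[ks[0]][1]
    for k in ks[1:]:
        stability, err, _, _ = results[k]
        improvement = (prev_err - err) / max(prev_err, 1e-12)
        if stability >= stability_threshold and improvement >= elbow_improvement:
            chosen = k
        prev_err = err
    _, _, H, _ = results[chosen]
    sigs = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-12)
    metadata = {
        "backend": "nmf",
        "seed": seed,
        "k_selected": chosen,
        "stability": {k: results[k][0] for k in ks},
        "reconstruction_error": {k: results[k][1] for k in ks},
    }
    return _package(matrix, sigs, name_prefix, metadata)


# ---------------------------------------------------------------------------
# exposures


def _em_exposures(x: np.ndarray, sigs: np.ndarray, n_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Multinomial EM projection of one count vector onto fixed signatures."""
    k = sigs.shape[0]
    total = x.sum()
    if total == 0:
        return np.zeros(k)
    e = np.full(k, 1.0 / k)
    S = np.maximum(sigs, 1e-300)
    prev = None
    for _ in range(n_iter):
        mix = e @ S  # (C,)
        r = (e[:, None] * S) / np.maximum(mix[None, :], 1e-300)  # (k, C)
        e = (r * x[None, :]).sum(axis=1) / total
        if prev is not None and np.abs(e - prev).max() < tol:
            break
        prev = e.copy()
    e = np.maximum(e, 0)
    return e / e.sum()


def fit_exposures(matrix: pd.DataFrame, signatures: SignatureSet) -> ExposureMatrix:
    """Project samples onto fixed signatures (simplex-constrained EM).

    A sample drawn exactly from one signature gets exposure 1 on it; an
    empty sample gets an all-zero row.
    """
    if list(matrix.columns) != signatures.categories:
        matrix = matrix[signatures.categories]
    x = matrix.to_numpy(dtype=float)
    expo = np.vstack([_em_exposures(row, signatures.weights) for row in x])
    return ExposureMatrix(
        sample_ids=[str(s) for s in matrix.index],
        names=list(signatures.names),
        weights=expo,
    )


def _package(
    matrix: pd.DataFrame, sigs: np.ndarray, name_prefix: str, metadata: dict
) -> tuple[SignatureSet, ExposureMatrix]:
    """Order signatures by descending mean exposure, name them, fit exposures."""
    k = sigs.shape[0]
    tmp = SignatureSet(
        names=[f"tmp{i}" for i in range(k)],
        categories=[str(c) for c in matrix.columns],
        weights=sigs,
    )
    expo = fit_exposures(matrix, tmp)
    order = np.argsort(expo.weights.mean(axis=0))[::-1]
    names = [f"{name_prefix}{i + 1}" for i in range(k)]
    sigset = SignatureSet(
        names=names,
        categories=tmp.categories,
        weights=sigs[order],
        metadata=metadata,
    )
    exposures = ExposureMatrix(
        sample_ids=expo.sample_ids, names=names, weights=expo.weights[:, order]
    )
    return sigset, exposures
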