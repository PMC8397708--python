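"""Cohort-level CN feature categorization and the samples x categories matrix.

Each feature's value distribution is cut into categories:

* count features (``bkpt_per_10mb``, ``bkpt_per_arm``, ``oscillation_len``)
  get Poisson mixture components, the number chosen by BIC;
* ``cn_jump`` gets Gaussian mixture components on the raw values and
  ``segment_size`` on log10 values, again chosen by BIC;
* ``segment_cn`` bypasses fitting entirely: five fixed copy-number states
  (0 = bi-allelic deletion, 1 = monoallelic deletion, 2 = diploid,
  3 = single gain, >=4 = two or more gains).

Values are then hard-assigned to the component with maximal posterior
responsibility (ties to the lower-indexed component), which keeps the count
matrix integer and makes per-feature conservation exact.  The total number
of categories is a data-dependent outcome of the BIC scans, not a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.mixture import GaussianMixture

from .features import FEATURE_NAMES, CnFeatureValues
from .io import ValidationError

__all__ = [
    "Component",
    "FeatureCategories",
    "CategoryScheme",
    "FIXED_CN_STATE_LABELS",
    "fit_category_scheme",
    "assign_counts",
    "build_cn_matrix",
    "fit_poisson_mixture",
]

COUNT_FEATURES = ("bkpt_per_10mb", "bkpt_per_arm", "oscillation_len")
GAUSSIAN_FEATURES = ("cn_jump", "segment_size")

FIXED_CN_STATE_LABELS = (
    "segment_cn:homdel",      # total CN 0, bi-allelic deletion
    "segment_cn:del",         # total CN 1, monoallelic deletion
    "segment_cn:diploid",     # total CN 2
    "segment_cn:gain",        # total CN 3, single gain
    "segment_cn:multigain",   # total CN >= 4, two or more gains
)


@dataclass(frozen=True)
class Component:
    """One category of one feature: a mixture component or a fixed CN state."""

    family: str  # "poisson" | "gaussian" | "fixed_state"
    label: str
    weight: float = 1.0
    rate: float | None = None    # poisson
    mean: float | None = None    # gaussian
    sd: float | None = None      # gaussian
    state: int | None = None     # fixed_state

    @property
    def location(self) -> float:
        if self.family == "poisson":
            return self.rate
        if self.family == "gaussian":
            return self.mean
        return float(self.state)


@dataclass
class FeatureCategories:
    feature: str
    components: list[Component]
    transform: str | None = None  # "log10" for segment_size

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]


@dataclass
class CategoryScheme:
    """Per-feature category definitions; fixes the count-matrix column space."""

    features: dict[str, FeatureCategories] = field(default_factory=dict)

    @property
    def column_labels(self) -> list[str]:
        out: list[str] = []
        for name in FEATURE_NAMES:
            out.extend(self.features[name].labels)
        return out

    @property
    def total_categories(self) -> int:
        return len(self.column_labels)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            name: {
                "transform": fc.transform,
                "components": [
                    {k: v for k, v in asdict(c).items() if v is not None}
                    for c in fc.components
                ],
            }
            for name, fc in self.features.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryScheme":
        payload = yaml.safe_load(Path(path).read_text())
        features = {
            name: FeatureCategories(
                feature=name,
                transform=block.get("transform"),
                components=[Component(**c) for c in block["components"]],
            )
            for name, block in payload.items()
        }
        return cls(features)


# ---------------------------------------------------------------------------
# Poisson mixture EM (weighted, on the collapsed value histogram)


def fit_poisson_mixture(
    values: np.ndarray,
    n_components: int,
    rng: np.random.Generator,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """EM fit of a Poisson mixture; returns (weights, rates, loglik).

    Values are collapsed to their histogram, so cost scales with the number
    of distinct counts, not observations.  Restarts draw initial rates from
    the data quantiles with jitter; the best log-likelihood wins.
    """
    uniq, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    w = counts.astype(float)
    n = w.sum()
    best = None
    for _ in range(n_restarts):
        q = rng.uniform(0, 1, n_components)
        rates = np.maximum(np.quantile(np.repeat(uniq, counts), np.sort(q)), 1e-3)
        rates = rates * rng.uniform(0.8, 1.25, n_components)
        weights = np.full(n_components, 1.0 / n_components)
        prev_ll = -np.inf
        for _ in range(max_iter):
            logp = stats.poisson.logpmf(uniq[:, None], rates[None, :]) + np.log(
                np.maximum(weights, 1e-300)
            )
            mx = logp.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
            ll = float((w * lse).sum())
            resp = np.exp(logp - lse[:, None])
            nk = (w[:, None] * resp).sum(axis=0)
            weights = nk / n
            rates = np.maximum((w[:, None] * resp * uniq[:, None]).sum(axis=0) / np.maximum(nk, 1e-12), 1e-6)
            if ll - prev_ll < tol * max(1.0, abs(ll)):
                prev_ll = ll
                break
            prev_ll = ll
        if best is None or prev_ll > best[2]:
            best = (weights, rates, prev_ll)
    return best


def _poisson_bic(ll: float, k: int, n: int) -> float:
    return -2.0 * ll + (2 * k - 1) * np.log(n)


def _fit_count_feature(
    values: np.ndarray,
    max_components: int,
    rng: np.random.Generator,
    n_restarts: int,
) -> list[tuple[float, float]]:
    """BIC scan over 1..max_components Poisson components; returns (weight, rate)."""
    n_distinct = len(np.unique(values))
    kmax = max(1, min(max_components, n_distinct))
    best = None
    for k in range(1, kmax + 1):
        weights, rates, ll = fit_poisson_mixture(values, k, rng, n_restarts=n_restarts)
        bic = _poisson_bic(ll, k, len(values))
        if best is None or bic < best[0]:
            best = (bic, weights, rates)
    _, weights, rates = best
    order = np.argsort(rates)
    return [(float(weights[i]), float(rates[i])) for i in order]


def _fit_gaussian_feature(
    values: np.ndarray,
    max_components: int,
    seed: int,
    n_restarts: int,
) -> list[tuple[float, float, float]]:
    """BIC scan over Gaussian components; returns (weight, mean, sd) sorted by mean."""
    x = np.sort(values.astype(float)).reshape(-1, 1)
    n_distinct = len(np.unique(x))
    kmax = max(1, min(max_components, n_distinct))
    best = None
    for k in range(1, kmax + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_restarts,
            init_params="k-means++",
            reg_covar=1e-4,
            random_state=seed,
            max_iter=500,
        ).fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    means = gm.means_[:, 0]
    sds = np.sqrt(gm.covariances_[:, 0, 0])
    order = np.argsort(means)
    return [
        (float(gm.weights_[i]), float(means[i]), float(max(sds[i], 1e-6)))
        for i in order
    ]


def _fixed_state_components() -> list[Component]:
    return [
        Component(family="fixed_state", label=lab, state=st)
        for st, lab in enumerate(FIXED_CN_STATE_LABELS)
    ]


def fit_category_scheme(
    cohort: Sequence[CnFeatureValues],
    max_components: int = 10,
    seed: int = 0,
    n_restarts: int = 20,
) -> CategoryScheme:
    """Fit the per-feature category definitions from pooled cohort values.

    Deterministic given ``seed``; invariant to sample order (pooled values
    are sorted before fitting).  An all-constant feature collapses to a
    single component with a warning.
    """
    if len(cohort) < 2:
        warnings.warn("fitting a category scheme from fewer than 2 samples")
    pooled = {
        name: np.sort(np.concatenate([np.asarray(s[name], dtype=float) for s in cohort]))
        if any(len(s[name]) for s in cohort)
        else np.array([])
        for name in FEATURE_NAMES
    }
    rng = np.random.default_rng(seed)
    features: dict[str, FeatureCategories] = {}
    for name in FEATURE_NAMES:
        if name == "segment_cn":
            features[name] = FeatureCategories(name, _fixed_state_components())
            continue
        vals = pooled[name]
        transform = "log10" if name == "segment_size" else None
        if transform == "log10":
            vals = np.log10(np.maximum(vals, 1.0))
        if len(vals) == 0 or len(np.unique(vals)) == 1:
            warnings.warn(f"feature {name}: constant or empty values; single category")
            loc = float(vals[0]) if len(vals) else 0.0
            comp = (
                Component(family="poisson", label=f"{name}:1", rate=max(loc, 1e-6))
                if name in COUNT_FEATURES
                else Component(family="gaussian", label=f"{name}:1", mean=loc, sd=1e-6)
            )
            features[name] = FeatureCategories(name, [comp], transform=transform)
            continue
        if name in COUNT_FEATURES:
            params = _fit_count_feature(vals, max_components, rng, n_restarts)
            comps = [
                Component(family="poisson", label=f"{name}:{i + 1}", weight=w, rate=r)
                for i, (w, r) in enumerate(params)
            ]
        else:
            params = _fit_gaussian_feature(vals, max_components, seed, n_restarts)
            comps = [
                Component(family="gaussian", label=f"{name}:{i + 1}", weight=w, mean=m, sd=sd)
                for i, (w, m, sd) in enumerate(params)
            ]
        features[name] = FeatureCategories(name, comps, transform=transform)
    return CategoryScheme(features)


# ---------------------------------------------------------------------------
# assignment


def _assign_fixed_state(value: float) -> int:
    if value < 0:
        raise ValidationError(f"negative copy number {value}")
    return int(min(value, 4))


def _log_responsibilities(vals: np.ndarray, fc: FeatureCategories) -> np.ndarray:
    """Unnormalized log posterior responsibilities, shape (n_values, n_components)."""
    logs = np.empty((len(vals), len(fc.components)))
    for i, c in enumerate(fc.components):
        lw = np.log(max(c.weight, 1e-300))
        if c.family == "poisson":
            logs[:, i] = lw + stats.poisson.logpmf(np.round(vals).astype(int), c.rate)
        elif c.family == "gaussian":
            logs[:, i] = lw + stats.norm.logpdf(vals, c.mean, c.sd)
        else:
            raise ValueError("fixed_state components have no responsibilities")
    return logs


def component_responsibilities(value: float, fc: FeatureCategories) -> np.ndarray:
    """Posterior responsibility of each component for one (transformed) value."""
    logs = _log_responsibilities(np.array([float(value)]), fc)[0]
    logs -= logs.max()
    p = np.exp(logs)
    return p / p.sum()


def assign_counts(values: CnFeatureValues, scheme: CategoryScheme) -> pd.Series:
    """Hard-assign one sample's feature values to categories; returns the
    count-matrix row (ties go to the lower-indexed component)."""
    counts = pd.Series(0, index=scheme.column_labels, dtype=int)
    for name in FEATURE_NAMES:
        fc = scheme.features[name]
        vals = np.asarray(values[name], dtype=float)
        if len(vals) == 0:
            continue
        if name == "segment_cn":
            for v in vals:
                counts[fc.components[_assign_fixed_state(v)].label] += 1
            continue
        if fc.transform == "log10":
            vals = np.log10(np.maximum(vals, 1.0))
        if len(fc.components) == 1:
            counts[fc.components[0].label] += len(vals)
            continue
        idx = np.argmax(_log_responsibilities(vals, fc), axis=1)
        for i, n in zip(*np.unique(idx, return_counts=True)):
            counts[fc.components[int(i)].label] += int(n)
    return counts


def build_cn_matrix(
    cohort: Sequence[CnFeatureValues], scheme: CategoryScheme
) -> pd.DataFrame:
    """Samples x categories count matrix, rows in cohort order."""
    rows = [assign_counts(s, scheme) for s in cohort]
    return pd.DataFrame(
        rows, index=[s.sample_id for s in cohort]
    )[scheme.column_labels]
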