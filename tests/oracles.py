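"""Independent brute-force reference implementations used only by tests.

These deliberately avoid sharing code (and, where possible, algorithms)
with the package: features are recomputed by explicit enumeration, the
piecewise-constant fit by exhaustive partition search, AUC by pair
counting, and mixture assignment by direct posterior evaluation.
"""

from collections import defaultdict
from itertools import combinations

import numpy as np


def junctions_brute(profile):
    """(chrom, position) of every CN breakpoint, by explicit adjacent scan."""
    by = defaultdict(list)
    for s in profile.segments:
        by[s.chrom].append(s)
    out = []
    for chrom, ss in by.items():
        ss = sorted(ss, key=lambda x: x.start)
        for a, b in zip(ss, ss[1:]):
            if a.total_cn != b.total_cn:
                out.append((chrom, b.start))
    return out


def bkpt_per_10mb_brute(profile, assets, window=10_000_000):
    juncs = junctions_brute(profile)
    out = []
    for chrom in assets.included_chromosomes():
        length = assets.chrom_lengths[chrom]
        nw = (length + window - 1) // window
        for w in range(nw):
            lo, hi = w * window + 1, (w + 1) * window
            if w == nw - 1:
                hi = max(hi, length)  # junctions cannot exceed length anyway
            out.append(sum(1 for c, p in juncs if c == chrom and lo <= p <= hi))
    return out


def bkpt_per_arm_brute(profile, assets):
    juncs = junctions_brute(profile)
    out = []
    for chrom in assets.included_chromosomes():
        cs, ce = assets.centromeres[chrom]
        out.append(sum(1 for c, p in juncs if c == chrom and p < cs))
        out.append(sum(1 for c, p in juncs if c == chrom and p > ce))
    return out


def segment_cn_brute(profile):
    return [s.total_cn for s in profile.segments]


def segment_size_brute(profile):
    return [s.end - s.start + 1 for s in profile.segments]


def cn_jump_brute(profile):
    by = defaultdict(list)
    for s in profile.segments:
        by[s.chrom].append(s)
    out = []
    for ss in by.values():
        ss = sorted(ss, key=lambda x: x.start)
        for a, b in zip(ss, ss[1:]):
            out.append(abs(b.total_cn - a.total_cn))
    return out


def _is_alternating(cn):
    return (
        len(cn) >= 3
        and len(set(cn)) == 2
        and all(cn[t] != cn[t + 1] for t in range(len(cn) - 1))
        and all(cn[t] == cn[t + 2] for t in range(len(cn) - 2))
    )


def oscillation_runs_brute(cn):
    """Maximal non-overlapping alternating runs, by exhaustive window search."""
    runs, i, n = [], 0, len(cn)
    while i < n:
        best = None
        for j in range(n, i + 2, -1):
            if _is_alternating(cn[i:j]):
                best = j
                break
        if best is not None:
            runs.append(best - i)
            i = best
        else:
            i += 1
    return runs


def oscillation_brute(profile, assets):
    by = defaultdict(list)
    for s in profile.segments:
        by[s.chrom].append(s)
    out = []
    for chrom in assets.included_chromosomes():
        ss = sorted(by.get(chrom, []), key=lambda x: x.start)
        runs = oscillation_runs_brute([s.total_cn for s in ss])
        out.extend(runs if runs else [0])
    return out


FEATURE_ORACLES = {
    "bkpt_per_10mb": lambda p, a: bkpt_per_10mb_brute(p, a),
    "segment_cn": lambda p, a: segment_cn_brute(p),
    "cn_jump": lambda p, a: cn_jump_brute(p),
    "bkpt_per_arm": lambda p, a: bkpt_per_arm_brute(p, a),
    "oscillation_len": lambda p, a: oscillation_brute(p, a),
    "segment_size": lambda p, a: segment_size_brute(p),
}


def pcf_brute(values, gamma):
    """Optimal penalized segmentation by exhaustive search over all
    2^(n-1) boundary subsets; returns (cost, boundaries)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    best = (np.inf, None)
    for k in range(n):
        for cuts in combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            cost = gamma * k
            for i, j in zip(bounds, bounds[1:]):
                seg = v[i:j]
                cost += float(((seg - seg.mean()) ** 2).sum())
            if cost < best[0]:
                best = (cost, bounds)
    return best


def auc_brute(scores, labels):
    """AUC by concordant-pair counting with 0.5 credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


def mixture_posterior_brute(value, components):
    """Direct posterior over mixture components given (family, weight, params)."""
    from scipy import stats

    dens = []
    for c in components:
        if c.family == "poisson":
            dens.append(c.weight * stats.poisson.pmf(int(round(value)), c.rate))
        else:
            dens.append(c.weight * stats.norm.pdf(value, c.mean, c.sd))
    dens = np.asarray(dens)
    return dens / dens.sum()


def random_profile(rng, assets, max_segments=20, max_cn=6):
    """A random multi-chromosome segment profile (merged, non-overlapping)."""
    from cnsig.io import Segment, SegmentProfile

    chroms = rng.choice(assets.included_chromosomes(), size=rng.integers(1, 5), replace=False)
    segs = []
    budget = int(rng.integers(1, max_segments + 1))
    for chrom in chroms:
        n = int(rng.integers(1, max(2, budget // len(chroms) + 1)))
        length = assets.chrom_lengths[str(chrom)]
        cuts = np.sort(rng.integers(1, length, size=2 * n))
        pos = 1
        for i in range(n):
            start = max(pos, int(cuts[2 * i])) if rng.random() < 0.3 else pos
            end = int(cuts[2 * i + 1])
            if end <= start:
                continue
            segs.append(Segment(str(chrom), start, end, int(rng.integers(0, max_cn + 1))))
            pos = end + 1
    if not segs:
        segs = [Segment("1", 1, 10_000_000, 2)]
    return SegmentProfile("rnd", segs).normalized()
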